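"""Synthetic benchmark generator: hierarchical mass-action EMT trajectories.

The generative model is a three-layer system over pseudotime s in [0, 1]:

    dX_i/ds = sum_{j!=i} a_ij X_i X_j + sum_l b_il X_i Y_l - d_i  X_i   (AS)
    dY_l/ds = sum_{k!=l} c_lk Y_l Y_k + sum_p e_lp Y_l Z_p - d'_l Y_l   (RBP)
    dZ_p/ds = sum_{q!=p} g_pq Z_p Z_q                       - d''_p Z_p (TF)

with sparse random coefficients: regulation flows TF -> RBP -> AS (plus
within-layer coupling), never the other way.  Curves are sampled on a
pseudotime grid, optionally corrupted by multiplicative noise, and the
samples are randomly permuted to emulate a cross-sectional study in which
the temporal order is unknown.  Ground truth (pseudotime, coefficients,
adjacency, permutation) is kept for benchmarking.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EPITHELIAL, MESENCHYMAL, OmicsPanel

# Families of regulatory coefficients, keyed by (target_layer, source_layer).
COEF_FAMILIES = ("a", "b", "c", "e", "g")
FAMILY_LAYERS = {
    "a": ("AS", "AS"),
    "b": ("AS", "RBP"),
    "c": ("RBP", "RBP"),
    "e": ("RBP", "TF"),
    "g": ("TF", "TF"),
}

STATE_LOWER = 1e-6
STATE_UPPER = 1e3


class TrajectoryUnstable(RuntimeError):
    """Signals a coefficient draw whose trajectory left [1e-6, 1e3]."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the benchmark scale: 2 TFs, 3 RBPs, 5 AS events observed
    at 100 equally spaced pseudotime points; coefficient families are
    independently sparse at density 0.4 with magnitudes in [0.5, 1.5] and
    random sign; degradation rates are positive.
    """

    n_as: int = 5
    n_rbp: int = 3
    n_tf: int = 2
    n_samples: int = 100
    density: float = 0.4
    coef_range: tuple[float, float] = (0.5, 1.5)
    degradation_range: tuple[float, float] = (0.2, 1.0)
    init_range: tuple[float, float] = (0.5, 1.5)
    noise_mean: float = 0.0
    noise_cv: float = 0.0
    seed: int = 0
    max_resample: int = 50
    rk4_step: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.n_as, self.n_rbp, self.n_tf, self.n_samples) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        for name in ("coef_range", "degradation_range", "init_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be ordered positive")
        if not 0.0 <= self.noise_mean <= 0.10:
            raise ValueError("noise_mean must lie in [0, 0.10]")
        if not 0.0 <= self.noise_cv <= 0.20:
            raise ValueError("noise_cv must lie in [0, 0.20]")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_samples)

    @property
    def as_names(self) -> list[str]:
        return [f"AS{i + 1}" for i in range(self.n_as)]

    @property
    def rbp_names(self) -> list[str]:
        return [f"RBP{i + 1}" for i in range(self.n_rbp)]

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i + 1}" for i in range(self.n_tf)]


@dataclass
class SimTruth:
    """Ground truth attached to an emitted panel.

    Coefficient matrices are target-by-source (entry [i, j] couples source j
    into the equation of target i); diagonals of the within-layer matrices
    are structurally zero because self-effects live in the degradations.
    ``pseudotime`` is indexed like the emitted (permuted) sample axis;
    ``permutation[j]`` gives the grid index placed at emitted column j.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    e: np.ndarray
    g: np.ndarray
    d_as: np.ndarray
    d_rbp: np.ndarray
    d_tf: np.ndarray
    config: SimConfig
    pseudotime: pd.Series | None = None
    permutation: np.ndarray | None = None
    curves: pd.DataFrame | None = None  # feature x grid-point, unpermuted

    def coefficient_matrix(self, family: str) -> np.ndarray:
        return {"a": self.a, "b": self.b, "c": self.c, "e": self.e, "g": self.g}[family]

    def node_names(self, layer: str) -> list[str]:
        return {
            "AS": self.config.as_names,
            "RBP": self.config.rbp_names,
            "TF": self.config.tf_names,
        }[layer]

    def edges(self) -> pd.DataFrame:
        """Directed true adjacency as an edge table (nonzero coefficients only)."""
        rows = []
        for fam in COEF_FAMILIES:
            tgt_layer, src_layer = FAMILY_LAYERS[fam]
            mat = self.coefficient_matrix(fam)
            tgt_names = self.node_names(tgt_layer)
            src_names = self.node_names(src_layer)
            for i, tgt in enumerate(tgt_names):
                for j, src in enumerate(src_names):
                    if tgt_layer == src_layer and i == j:
                        continue
                    if mat[i, j] != 0.0:
                        rows.append(
                            {
                                "source": src,
                                "source_layer": src_layer,
                                "target": tgt,
                                "target_layer": tgt_layer,
                                "coefficient": float(mat[i, j]),
                            }
                        )
        return pd.DataFrame(
            rows, columns=["source", "source_layer", "target", "target_layer", "coefficient"]
        )

    def edge_indicator(self) -> pd.Series:
        """0/1 truth over every allowed candidate edge, keyed (source, target)."""
        out = {}
        for fam in COEF_FAMILIES:
            tgt_layer, src_layer = FAMILY_LAYERS[fam]
            mat = self.coefficient_matrix(fam)
            for i, tgt in enumerate(self.node_names(tgt_layer)):
                for j, src in enumerate(self.node_names(src_layer)):
                    if tgt_layer == src_layer and i == j:
                        continue
                    out[(src, tgt)] = int(mat[i, j] != 0.0)
        return pd.Series(out, dtype=int)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {k: v for k, v in asdict(self.config).items()},
            "coefficients": {f: self.coefficient_matrix(f).tolist() for f in COEF_FAMILIES},
            "degradations": {
                "AS": self.d_as.tolist(),
                "RBP": self.d_rbp.tolist(),
                "TF": self.d_tf.tolist(),
            },
            "pseudotime": None
            if self.pseudotime is None
            else {k: float(v) for k, v in self.pseudotime.items()},
            "permutation": None if self.permutation is None else self.permutation.tolist(),
            "edges": self.edges().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _sparse_matrix(
    rng: np.random.Generator,
    shape: tuple[int, int],
    density: float,
    coef_range: tuple[float, float],
    zero_diagonal: bool,
) -> np.ndarray:
    mask = rng.random(shape) < density
    mag = rng.uniform(coef_range[0], coef_range[1], size=shape)
    sign = rng.choice([-1.0, 1.0], size=shape)
    mat = np.where(mask, sign * mag, 0.0)
    if zero_diagonal:
        np.fill_diagonal(mat, 0.0)
    return mat


def sample_system(config: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Draw one sparse coefficient set respecting the TF->RBP->AS hierarchy."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m, h = config.n_as, config.n_rbp, config.n_tf
    return SimTruth(
        a=_sparse_matrix(rng, (n, n), config.density, config.coef_range, True),
        b=_sparse_matrix(rng, (n, m), config.density, config.coef_range, False),
        c=_sparse_matrix(rng, (m, m), config.density, config.coef_range, True),
        e=_sparse_matrix(rng, (m, h), config.density, config.coef_range, False),
        g=_sparse_matrix(rng, (h, h), config.density, config.coef_range, True),
        d_as=rng.uniform(*config.degradation_range, size=n),
        d_rbp=rng.uniform(*config.degradation_range, size=m),
        d_tf=rng.uniform(*config.degradation_range, size=h),
        config=config,
    )


def _rhs(truth: SimTruth, x: np.ndarray, y: np.ndarray, z: np.ndarray):
    dx = x * (truth.a @ x) + x * (truth.b @ y) - truth.d_as * x
    dy = y * (truth.c @ y) + y * (truth.e @ z) - truth.d_rbp * y
    dz = z * (truth.g @ z) - truth.d_tf * z
    return dx, dy, dz


def integrate_trajectory(
    truth: SimTruth,
    initial_state: np.ndarray,
    grid: np.ndarray,
    step: float | None = None,
) -> pd.DataFrame:
    """Integrate the system with classical fixed-step RK4 and sample it on ``grid``.

    ``initial_state`` concatenates (AS, RBP, TF) values at s = grid[0].
    Raises :class:`TrajectoryUnstable` if any state leaves [1e-6, 1e3].
    """
    cfg = truth.config
    step = cfg.rk4_step if step is None else step
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    n, m = cfg.n_as, cfg.n_rbp
    state = np.asarray(initial_state, dtype=float).copy()
    if state.shape != (n + m + cfg.n_tf,):
        raise ValueError("initial_state length must be n_as + n_rbp + n_tf")
    if np.any(state <= 0):
        raise ValueError("initial_state must be positive")

    def f(s_state: np.ndarray) -> np.ndarray:
        dx, dy, dz = _rhs(truth, s_state[:n], s_state[n : n + m], s_state[n + m :])
        return np.concatenate([dx, dy, dz])

    out = np.empty((state.size, grid.size))
    out[:, 0] = state
    s = grid[0]
    for gi in range(1, grid.size):
        target = grid[gi]
        while s < target - 1e-15:
            h = min(step, target - s)
            k1 = f(state)
            k2 = f(state + 0.5 * h * k1)
            k3 = f(state + 0.5 * h * k2)
            k4 = f(state + h * k3)
            state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            s += h
            if not np.all(np.isfinite(state)) or np.any(
                (state < STATE_LOWER) | (state > STATE_UPPER)
            ):
                raise TrajectoryUnstable(f"state left [{STATE_LOWER}, {STATE_UPPER}] at s={s:.4f}")
        out[:, gi] = state
        s = target
    names = cfg.as_names + cfg.rbp_names + cfg.tf_names
    return pd.DataFrame(out, index=names, columns=[f"g{j}" for j in range(grid.size)])


def emit_panel(
    curves: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[OmicsPanel, SimTruth]:
    """Permute grid samples into a cross-sectional panel and record the truth.

    Sample j of the panel carries grid point ``permutation[j]``; labels are
    epithelial for true pseudotime < 0.5 and mesenchymal otherwise.
    """
    grid = config.grid
    perm = rng.permutation(config.n_samples)
    sample_ids = [f"S{j + 1:03d}" for j in range(config.n_samples)]
    values = curves.to_numpy()[:, perm]
    true_s = grid[perm]
    labels = pd.Series(
        np.where(true_s < 0.5, EPITHELIAL, MESENCHYMAL), index=sample_ids, name="label"
    )
    n, m = config.n_as, config.n_rbp
    panel = OmicsPanel(
        as_matrix=pd.DataFrame(values[:n], index=config.as_names, columns=sample_ids),
        rbp_matrix=pd.DataFrame(values[n : n + m], index=config.rbp_names, columns=sample_ids),
        tf_matrix=pd.DataFrame(values[n + m :], index=config.tf_names, columns=sample_ids),
        labels=labels,
    )
    truth.pseudotime = pd.Series(true_s, index=sample_ids, name="pseudotime")
    truth.permutation = perm
    truth.curves = curves
    return panel, truth


def corrupt(
    panel: OmicsPanel,
    noise_mean: float,
    noise_cv: float,
    rng: np.random.Generator,
) -> OmicsPanel:
    """Multiply every entry by a positive random factor of mean 1+mu and CV cv.

    The factor is Gamma-distributed (shape 1/cv^2, scale (1+mu)*cv^2); at
    cv = 0 the factor degenerates to the constant 1+mu.
    """
    if not 0.0 <= noise_mean <= 0.10:
        raise ValueError("noise_mean must lie in [0, 0.10]")
    if not 0.0 <= noise_cv <= 0.20:
        raise ValueError("noise_cv must lie in [0, 0.20]")

    def factor(shape: tuple[int, int]) -> np.ndarray:
        if noise_cv == 0.0:
            return np.full(shape, 1.0 + noise_mean)
        k = 1.0 / noise_cv**2
        theta = (1.0 + noise_mean) * noise_cv**2
        return rng.gamma(k, theta, size=shape)

    def apply(mat: pd.DataFrame) -> pd.DataFrame:
        return mat * factor(mat.shape)

    return OmicsPanel(
        as_matrix=apply(panel.as_matrix),
        rbp_matrix=apply(panel.rbp_matrix),
        tf_matrix=apply(panel.tf_matrix),
        labels=panel.labels.copy(),
    )


def simulate_panel(config: SimConfig) -> tuple[OmicsPanel, SimTruth]:
    """End-to-end draw: sample coefficients, integrate, permute, corrupt.

    Coefficient sets whose trajectory leaves [1e-6, 1e3] are rejected and
    redrawn (at most ``config.max_resample`` attempts).
    """
    rng = np.random.default_rng(config.seed)
    last_err: Exception | None = None
    for _ in range(config.max_resample):
        truth = sample_system(config, rng)
        init = rng.uniform(*config.init_range, size=config.n_as + config.n_rbp + config.n_tf)
        try:
            curves = integrate_trajectory(truth, init, config.grid)
        except TrajectoryUnstable as err:
            last_err = err
            continue
        panel, truth = emit_panel(curves, truth, config, rng)
        if config.noise_mean > 0 or config.noise_cv > 0:
            panel = corrupt(panel, config.noise_mean, config.noise_cv, rng)
        return panel, truth
    raise TrajectoryUnstable(
        f"no stable system in {config.max_resample} draws (last: {last_err})"
    )
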