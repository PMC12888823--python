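"""Sparse mass-action network inference along pseudotime.

Each node's time derivative is regressed on the product terms its layer's
equation allows: an AS event sees its products with the other AS events and
with every RBP; an RBP sees the other RBPs and every TF; a TF sees only the
other TFs.  The node's own (negated) curve supplies the degradation term.
Coefficients are estimated with a Bayesian Lasso Gibbs sampler (Laplace
shrinkage prior, Park & Casella hierarchy) and an edge is called when its
equal-tailed posterior credible interval excludes zero.  The layer hierarchy
is structural: forbidden couplings (TF->AS, AS->RBP, RBP->TF, AS->TF) never
enter any design matrix, so they can never be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .io import OmicsPanel

LAYER_ORDER = ("AS", "RBP", "TF")
# (same-layer family, upstream family, upstream layer) per target layer
EQUATION_PLAN = {
    "AS": ("a", "b", "RBP"),
    "RBP": ("c", "e", "TF"),
    "TF": ("g", None, None),
}


def kernel_weights(s: np.ndarray, h: float) -> np.ndarray:
    """Row-stochastic Nadaraya–Watson Gaussian kernel matrix along pseudotime.

    Applying it to a series evaluated at ``s`` returns the kernel-smoothed
    series at the same points; ``h`` is the bandwidth in normalized
    pseudotime units.
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    s = np.asarray(s, dtype=float)
    diff = (s[None, :] - s[:, None]) / h
    K = np.exp(-0.5 * diff**2)
    return K / K.sum(axis=1, keepdims=True)


def smooth_curves(values: np.ndarray, s: np.ndarray, h: float = 0.05) -> np.ndarray:
    """Nadaraya–Watson Gaussian-kernel smoothing of each row along pseudotime.

    ``values`` is feature-by-sample in pseudotime order; ``h`` is the kernel
    bandwidth in normalized pseudotime units.
    """
    return np.asarray(values, dtype=float) @ kernel_weights(s, h).T


def estimate_derivative(curve: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Three-point finite differences on an irregular grid, exact for quadratics.

    Interior points use the centred Lagrange formula; both ends use the
    one-sided second-order formula.  Works on 1-D series or feature-by-sample
    arrays (derivative taken along the last axis).
    """
    curve = np.asarray(curve, dtype=float)
    s = np.asarray(s, dtype=float)
    n = s.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.any(np.diff(s) <= 0):
        raise ValueError("pseudotime values must be strictly increasing")
    y = np.atleast_2d(curve)
    out = np.empty_like(y)

    s0, s1, s2 = s[:-2], s[1:-1], s[2:]
    w0 = (s1 - s2) / ((s0 - s1) * (s0 - s2))
    w1 = (2 * s1 - s0 - s2) / ((s1 - s0) * (s1 - s2))
    w2 = (s1 - s0) / ((s2 - s0) * (s2 - s1))
    out[:, 1:-1] = y[:, :-2] * w0 + y[:, 1:-1] * w1 + y[:, 2:] * w2

    for pos, (i0, i1, i2) in (("L", (0, 1, 2)), ("R", (n - 1, n - 2, n - 3))):
        a, b, c = s[i0], s[i1], s[i2]
        d0 = (2 * a - b - c) / ((a - b) * (a - c))
        d1 = (a - c) / ((b - a) * (b - c))
        d2 = (a - b) / ((c - a) * (c - b))
        col = 0 if pos == "L" else n - 1
        out[:, col] = y[:, i0] * d0 + y[:, i1] * d1 + y[:, i2] * d2
    return out[0] if curve.ndim == 1 else out


@dataclass(frozen=True)
class ColumnSpec:
    """One design-matrix column: a candidate edge or the degradation term."""

    kind: str  # "edge" | "degradation"
    family: str  # a, b, c, e, g or d
    source: str
    target: str
    source_layer: str
    target_layer: str


@dataclass
class RegressionProblem:
    """Per-node regression implied by the node's mass-action equation."""

    node: str
    layer: str
    y: np.ndarray  # derivative at interior pseudotime points
    X: np.ndarray  # standardized columns
    columns: list[ColumnSpec]
    scales: np.ndarray  # original-column SDs used for standardization


def build_problem(
    node: str,
    layer: str,
    curves: dict[str, pd.DataFrame],
    derivatives: dict[str, pd.DataFrame],
    smoother: np.ndarray | None = None,
) -> RegressionProblem:
    """Assemble the design matrix for one node's mass-action equation.

    Columns are elementwise products of the node's curve with each allowed
    partner, plus the node's negated curve for the degradation term.  When a
    ``smoother`` (linear operator over pseudotime points, e.g.
    :func:`kernel_weights`) is supplied it is applied to *both* the columns
    and the derivative response — the coefficient identity is exact under
    any linear operator applied to both sides, so smoothing suppresses noise
    without biasing the fit.  Rows are the interior pseudotime points
    (endpoints dropped: one-sided derivative estimates are the least
    reliable).  Columns are standardized to unit SD with the scaling
    recorded for back-transformation.
    """
    same_fam, up_fam, up_layer = EQUATION_PLAN[layer]
    own = curves[layer].loc[node].to_numpy()
    cols: list[np.ndarray] = []
    specs: list[ColumnSpec] = []
    for partner in curves[layer].index:
        if partner == node:
            continue
        cols.append(own * curves[layer].loc[partner].to_numpy())
        specs.append(ColumnSpec("edge", same_fam, str(partner), node, layer, layer))
    if up_fam is not None:
        for src in curves[up_layer].index:
            cols.append(own * curves[up_layer].loc[src].to_numpy())
            specs.append(ColumnSpec("edge", up_fam, str(src), node, up_layer, layer))
    cols.append(-own)
    specs.append(ColumnSpec("degradation", "d", node, node, layer, layer))

    X_raw = np.column_stack(cols)
    y = derivatives[layer].loc[node].to_numpy()
    if smoother is not None:
        X_raw = smoother @ X_raw
        y = smoother @ y
    interior = slice(1, -1)
    X_raw = X_raw[interior]
    y = y[interior]
    if X_raw.shape[0] < 3:
        raise ValueError("need at least 3 interior rows")
    scales = X_raw.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)
    return RegressionProblem(
        node=node, layer=layer, y=y, X=X_raw / scales, columns=specs, scales=scales
    )


@dataclass
class PosteriorSummary:
    """Posterior draws and summaries for one node's coefficients (original scale)."""

    node: str
    layer: str
    columns: list[ColumnSpec]
    draws: np.ndarray  # (kept iterations, p)

    @property
    def post_mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    @property
    def post_sd(self) -> np.ndarray:
        return self.draws.std(axis=0)

    def credible_interval(self, level: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
        alpha = (1.0 - level) / 2.0
        return (
            np.quantile(self.draws, alpha, axis=0),
            np.quantile(self.draws, 1.0 - alpha, axis=0),
        )


def bayesian_lasso_fit(
    problem: RegressionProblem,
    iters: int = 4000,
    burn: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    lambda2_shape: float = 1.0,
    lambda2_rate: float = 0.1,
) -> PosteriorSummary:
    """Park–Casella Gibbs sampler for the Bayesian Lasso.

    Hierarchy: y ~ N(X b, sig2 I); b_j | tau2_j ~ N(0, sig2 tau2_j);
    tau2_j ~ Exp(lam2/2); sig2 ~ 1/sig2 (Jeffreys); lam2 ~ Gamma(shape, rate).
    Full conditionals: b is multivariate normal, 1/tau2_j inverse-Gaussian,
    sig2 inverse-gamma, lam2 gamma.  Draws are returned back-transformed to
    the original column scale.
    """
    if not iters > burn >= 1:
        raise ValueError("need iters > burn >= 1")
    rng = np.random.default_rng(seed)
    X, y = problem.X, problem.y
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    sigma2 = max(float(resid @ resid) / max(n - p, 1), 1e-8)
    tau2 = np.ones(p)
    lam2 = 1.0
    kept = np.empty((iters - burn, p))

    for it in range(iters):
        A = XtX + np.diag(1.0 / tau2)
        cf = cho_factor(A, lower=True)
        mu = cho_solve(cf, Xty)
        z = rng.standard_normal(p)
        # A = L L^T  =>  cov = sig2 A^{-1}; draw mu + sqrt(sig2) L^{-T} z
        beta = mu + np.sqrt(sigma2) * solve_triangular(cf[0], z, lower=True, trans="T")

        ig_mean = np.sqrt(np.clip(lam2 * sigma2 / np.clip(beta**2, 1e-12, None), 1e-10, 1e10))
        inv_tau2 = rng.wald(ig_mean, lam2)
        tau2 = 1.0 / np.clip(inv_tau2, 1e-12, 1e12)

        resid = y - X @ beta
        shape = 0.5 * (n - 1) + 0.5 * p
        rate = 0.5 * float(resid @ resid) + 0.5 * float(np.sum(beta**2 / tau2))
        sigma2 = rate / rng.gamma(shape, 1.0)
        sigma2 = float(np.clip(sigma2, 1e-12, 1e12))

        lam2 = rng.gamma(lambda2_shape + p, 1.0 / (lambda2_rate + 0.5 * float(tau2.sum())))

        if not np.all(np.isfinite(beta)):
            raise RuntimeError(
                f"non-finite draw at iteration {it} for node {problem.node}"
            )
        if it >= burn:
            kept[it - burn] = beta / problem.scales
    return PosteriorSummary(
        node=problem.node, layer=problem.layer, columns=problem.columns, draws=kept
    )


@dataclass
class LayeredNetwork:
    """Inferred signed directed network over the TF/RBP/AS node layers.

    ``edges`` has one row per *candidate* edge with its posterior summary,
    continuous score |posterior mean| and the 0/1 ``called`` flag;
    ``degradations`` holds the per-node self-decay estimates.
    """

    edges: pd.DataFrame
    degradations: pd.DataFrame
    ci_level: float
    posteriors: dict[str, PosteriorSummary] = field(default_factory=dict)

    def called_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["called"] == 1].reset_index(drop=True)

    def edge_scores(self) -> pd.Series:
        """|posterior mean| per candidate edge, keyed (source, target)."""
        key = list(zip(self.edges["source"], self.edges["target"]))
        return pd.Series(self.edges["score"].to_numpy(), index=pd.MultiIndex.from_tuples(key))

    def write_edges(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def call_edges(
    posteriors: list[PosteriorSummary], level: float = 0.9
) -> LayeredNetwork:
    """Build the network: an edge is called when its CI excludes zero."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    edge_rows, deg_rows = [], []
    for post in posteriors:
        lo, hi = post.credible_interval(level)
        mean = post.post_mean
        sd = post.post_sd
        for j, spec in enumerate(post.columns):
            if spec.kind == "degradation":
                deg_rows.append(
                    {"node": spec.target, "layer": spec.target_layer,
                     "post_mean": mean[j], "ci_low": lo[j], "ci_high": hi[j]}
                )
            else:
                edge_rows.append(
                    {
                        "source": spec.source,
                        "source_layer": spec.source_layer,
                        "target": spec.target,
                        "target_layer": spec.target_layer,
                        "family": spec.family,
                        "post_mean": mean[j],
                        "post_sd": sd[j],
                        "ci_low": lo[j],
                        "ci_high": hi[j],
                        "score": abs(mean[j]),
                        "sign": int(np.sign(mean[j])),
                        "called": int(lo[j] > 0 or hi[j] < 0),
                    }
                )
    return LayeredNetwork(
        edges=pd.DataFrame(edge_rows),
        degradations=pd.DataFrame(deg_rows),
        ci_level=level,
        posteriors={p.node: p for p in posteriors},
    )


def node_seed(global_seed: int, node_index: int) -> np.random.SeedSequence:
    """Deterministic per-node seed stream (node fits are independent)."""
    return np.random.SeedSequence(entropy=global_seed, spawn_key=(node_index,))


def infer_network(
    panel: OmicsPanel,
    pseudotime: pd.Series,
    bandwidth: float = 0.05,
    iters: int = 4000,
    burn: int = 1000,
    ci_level: float = 0.9,
    seed: int = 0,
    smooth: bool = True,
) -> LayeredNetwork:
    """Full inference: order, smooth, differentiate, fit every node, call edges.

    ``pseudotime`` gives each sample's coordinate; samples are sorted by it
    (ties broken by sample ID) before smoothing and finite differencing.
    """
    s = pseudotime.reindex(panel.sample_ids)
    order = np.lexsort((np.array(s.index), s.to_numpy()))
    ordered_ids = [s.index[i] for i in order]
    panel = panel.reorder(list(ordered_ids))
    s_sorted = s.to_numpy()[order]
    if np.any(np.diff(s_sorted) <= 0):
        # collapse exact ties onto a strictly increasing grid by rank
        s_sorted = np.linspace(0.0, 1.0, len(s_sorted))

    smoother = kernel_weights(s_sorted, bandwidth) if smooth else None
    curves: dict[str, pd.DataFrame] = {}
    derivatives: dict[str, pd.DataFrame] = {}
    for layer, mat in panel.layers().items():
        vals = mat.to_numpy(dtype=float)
        curves[layer] = pd.DataFrame(vals, index=mat.index, columns=mat.columns)
        derivatives[layer] = pd.DataFrame(
            estimate_derivative(vals, s_sorted), index=mat.index, columns=mat.columns
        )

    posteriors = []
    node_index = 0
    for layer in LAYER_ORDER:
        for node in curves[layer].index:
            problem = build_problem(str(node), layer, curves, derivatives, smoother=smoother)
            posteriors.append(
                bayesian_lasso_fit(
                    problem, iters=iters, burn=burn, seed=node_seed(seed, node_index)
                )
            )
            node_index += 1
    return call_edges(posteriors, level=ci_level)
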