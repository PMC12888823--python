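"""Benchmark metrics and the synthetic evaluation loops.

Pseudotime recovery is scored by Spearman rank correlation and RMSE (both
vectors min–max normalized first); network recovery by ROC AUC of the
continuous edge scores against the true adjacency plus accuracy / PPV /
Matthews correlation at the credible-interval call threshold.  The
robustness sweep repeats the full simulate -> corrupt -> permute ->
pseudotime -> inference pipeline over a grid of multiplicative-noise
settings (mean mu, coefficient of variation cv).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import netinfer, pseudotime as pt
from .simulate import SimConfig, simulate_panel


def spearman_rho(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman correlation: Pearson on mid-ranks (ties averaged)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    if np.std(ra) == 0 or np.std(rb) == 0:
        raise ValueError("zero rank variance")
    return float(np.corrcoef(ra, rb)[0, 1])


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def confusion_metrics(called: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Accuracy, PPV and Matthews correlation from binary vectors."""
    called = np.asarray(called).astype(int)
    truth = np.asarray(truth).astype(int)
    if called.shape != truth.shape:
        raise ValueError("equal-length binary vectors required")
    tp = int(np.sum((called == 1) & (truth == 1)))
    tn = int(np.sum((called == 0) & (truth == 0)))
    fp = int(np.sum((called == 1) & (truth == 0)))
    fn = int(np.sum((called == 0) & (truth == 1)))
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total if total else 0.0
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {"accuracy": float(accuracy), "ppv": float(ppv), "mcc": float(mcc)}


def rmse(a: np.ndarray, b: np.ndarray, normalize: bool = True) -> float:
    """Root mean squared difference; pseudotime vectors are min–max scaled first."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("equal-length vectors required")

    def norm(x: np.ndarray) -> np.ndarray:
        span = x.max() - x.min()
        return (x - x.min()) / span if span > 0 else np.zeros_like(x)

    if normalize:
        a, b = norm(a), norm(b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def wilcoxon_rank_sum(group1: np.ndarray, group2: np.ndarray) -> float:
    """Two-tailed rank-sum p-value.

    Exact enumeration for small tie-free samples (n1+n2 <= 20), otherwise the
    normal approximation with tie and continuity corrections.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([g1, g2])).size < g1.size + g2.size
    small = g1.size + g2.size <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


@dataclass
class BenchmarkResult:
    """Metrics of one simulate -> permute -> recover run."""

    seed: int
    noise_mean: float
    noise_cv: float
    rho: float
    rmse: float
    auc: float | None = None
    accuracy: float | None = None
    ppv: float | None = None
    mcc: float | None = None

    def as_dict(self) -> dict:
        return {
            "seed": self.seed, "noise_mean": self.noise_mean, "noise_cv": self.noise_cv,
            "rho": self.rho, "rmse": self.rmse, "auc": self.auc,
            "accuracy": self.accuracy, "ppv": self.ppv, "mcc": self.mcc,
        }


def benchmark_run(
    config: SimConfig,
    k: int = 10,
    infer_edges: bool = True,
    iters: int = 4000,
    burn: int = 1000,
    bandwidth: float = 0.05,
    ci_level: float = 0.9,
) -> BenchmarkResult:
    """One full benchmark pass on a simulated cross-sectional panel.

    Pseudotime metrics compare the inferred scores with the ground-truth
    pseudotime recorded at emission; network metrics compare edge scores and
    calls against the true adjacency (degradation self-terms excluded).
    """
    panel, truth = simulate_panel(config)
    assignment = pt.infer_pseudotime(panel, k=min(k, config.n_samples - 1))
    true_s = truth.pseudotime.reindex(panel.sample_ids).to_numpy()
    inferred = assignment.scores.reindex(panel.sample_ids).to_numpy()
    result = BenchmarkResult(
        seed=config.seed, noise_mean=config.noise_mean, noise_cv=config.noise_cv,
        rho=spearman_rho(inferred, true_s), rmse=rmse(inferred, true_s),
    )
    if not infer_edges:
        return result
    network = netinfer.infer_network(
        panel, assignment.rank_uniform(), bandwidth=bandwidth,
        iters=iters, burn=burn, ci_level=ci_level, seed=config.seed,
    )
    truth_ind = truth.edge_indicator()
    key = pd.MultiIndex.from_tuples(
        list(zip(network.edges["source"], network.edges["target"]))
    )
    y_true = truth_ind.reindex(key).to_numpy()
    result.auc = roc_auc(network.edges["score"].to_numpy(), y_true)
    cm = confusion_metrics(network.edges["called"].to_numpy(), y_true)
    result.accuracy, result.ppv, result.mcc = cm["accuracy"], cm["ppv"], cm["mcc"]
    return result


def benchmark_suite(
    seeds: list[int],
    base_config: SimConfig | None = None,
    infer_edges: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """Run the clean benchmark over several seeds; one row per seed."""
    base = base_config or SimConfig()
    rows = [
        benchmark_run(replace(base, seed=s), infer_edges=infer_edges, **kwargs).as_dict()
        for s in seeds
    ]
    return pd.DataFrame(rows)


DEFAULT_MU_GRID = (0.0, 0.025, 0.05, 0.075, 0.10)
DEFAULT_CV_GRID = (0.0, 0.05, 0.10, 0.15, 0.20)


def robustness_sweep(
    mu_grid=DEFAULT_MU_GRID,
    cv_grid=DEFAULT_CV_GRID,
    seeds: list[int] = tuple(range(10)),
    base_config: SimConfig | None = None,
    infer_edges: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """Full metric grid over multiplicative-noise settings (mu, cv, seed)."""
    base = base_config or SimConfig()
    rows = []
    for mu in mu_grid:
        for cv in cv_grid:
            for s in seeds:
                cfg = replace(base, noise_mean=mu, noise_cv=cv, seed=s)
                rows.append(benchmark_run(cfg, infer_edges=infer_edges, **kwargs).as_dict())
    return pd.DataFrame(rows)


def perturbation_discrepancy(
    config: SimConfig,
    deltas: tuple[float, ...] = (0.001, 0.05),
    seed: int = 0,
    iters: int = 4000,
    burn: int = 1000,
) -> dict[float, float]:
    """Coefficient discrepancy under L2 perturbation of the pseudotime axis.

    The model is fit once at the true pseudotime and once at s + delta*e for
    each delta (e standard normal, rescaled so the discrete L2 norm of the
    perturbation equals delta; identical e across deltas).  Returns, per
    delta, the summed squared difference of the edge-coefficient posterior
    means against the unperturbed fit.  Continuity of the estimator in the
    pseudotime axis predicts smaller discrepancies for smaller deltas.
    """
    panel, truth = simulate_panel(config)
    true_s = truth.pseudotime.reindex(panel.sample_ids)
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(len(true_s))
    e = e / np.sqrt(np.mean(e**2))  # unit discrete L2 norm

    def fit(s: pd.Series):
        net = netinfer.infer_network(
            panel, s, iters=iters, burn=burn, seed=config.seed
        )
        key = pd.MultiIndex.from_tuples(
            [
                (f, src, tgt)
                for f, src, tgt in zip(
                    net.edges["family"], net.edges["source"], net.edges["target"]
                )
            ]
        )
        return pd.Series(net.edges["post_mean"].to_numpy(), index=key).sort_index()

    base = fit(true_s)
    out = {}
    for delta in deltas:
        pert = pd.Series(true_s.to_numpy() + delta * e, index=true_s.index)
        coef = fit(pert)
        out[float(delta)] = float(((coef - base) ** 2).sum())
    return out


def dynamic_shift_test(panel, network_curves: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wilcoxon rank-sum per AS feature: epithelial vs mesenchymal samples.

    Tests whether each AS event's values differ between the two phenotype
    classes (the stated dichotomy); returns one row per AS feature.
    """
    from .io import EPITHELIAL

    mat = panel.as_matrix if network_curves is None else network_curves
    is_e = (panel.labels == EPITHELIAL).to_numpy()
    rows = []
    for fid in mat.index:
        vals = mat.loc[fid].to_numpy(dtype=float)
        p = wilcoxon_rank_sum(vals[is_e], vals[~is_e])
        direction = "up" if vals[~is_e].mean() > vals[is_e].mean() else "down"
        rows.append({"feature_id": str(fid), "p_value": p, "direction": direction})
    return pd.DataFrame(rows)
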