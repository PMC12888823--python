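"""Trend scoring along pseudotime and top-k feature selection.

A feature's trend score is |beta| / max(sigma_res, eps): the OLS slope of
its values against pseudotime (rescaled to [0, 1], so the slope is the total
linear change) divided by the population standard deviation of the OLS
residuals.  Large scores mean strong, clean monotone change across the
epithelial-to-mesenchymal axis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import OmicsPanel

EPS = 1e-8


def trend_score(values: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    """Return (slope, residual SD, score) for one feature series along pseudotime."""
    values = np.asarray(values, dtype=float)
    s = np.asarray(s, dtype=float)
    if values.shape != s.shape or values.ndim != 1:
        raise ValueError("values and s must be equal-length 1-D arrays")
    if values.size < 3:
        raise ValueError("need at least 3 points")
    span = s.max() - s.min()
    if span == 0:
        raise ValueError("degenerate pseudotime (all values equal)")
    t = (s - s.min()) / span
    t_c = t - t.mean()
    beta = float(t_c @ (values - values.mean()) / (t_c @ t_c))
    intercept = values.mean() - beta * t.mean()
    resid = values - (intercept + beta * t)
    sigma_res = float(np.sqrt(np.mean(resid**2)))
    score = abs(beta) / max(sigma_res, EPS)
    return beta, sigma_res, score


def trend_table(panel: OmicsPanel, pseudotime: pd.Series) -> pd.DataFrame:
    """Score every feature of every layer; returns one row per feature."""
    s = pseudotime.reindex(panel.sample_ids).to_numpy(dtype=float)
    rows = []
    for layer, mat in panel.layers().items():
        vals = mat.to_numpy(dtype=float)
        for i, fid in enumerate(mat.index):
            beta, sigma_res, score = trend_score(vals[i], s)
            rows.append(
                {"feature_id": str(fid), "layer": layer, "beta": beta,
                 "sigma_res": sigma_res, "score": score}
            )
    return pd.DataFrame(rows)


def select_top(
    table: pd.DataFrame, k_as: int = 50, k_rbp: int = 10, k_tf: int = 10
) -> dict[str, list[str]]:
    """Per-layer top-k by descending score, ties broken by feature ID."""
    wanted = {"AS": k_as, "RBP": k_rbp, "TF": k_tf}
    out: dict[str, list[str]] = {}
    for layer, k in wanted.items():
        sub = table[table["layer"] == layer]
        if k > len(sub):
            raise ValueError(f"requested top {k} from layer {layer} with {len(sub)} features")
        ordered = sub.sort_values(
            ["score", "feature_id"], ascending=[False, True], kind="mergesort"
        )
        out[layer] = ordered["feature_id"].head(k).tolist()
    return out


def subset_panel(panel: OmicsPanel, selection: dict[str, list[str]]) -> OmicsPanel:
    """Restrict each layer to the selected features (selection order kept)."""
    return OmicsPanel(
        as_matrix=panel.as_matrix.loc[selection["AS"]],
        rbp_matrix=panel.rbp_matrix.loc[selection["RBP"]],
        tf_matrix=panel.tf_matrix.loc[selection["TF"]],
        labels=panel.labels.copy(),
    )
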