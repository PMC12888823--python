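"""Pseudotime from a similarity-graph random walk anchored by phenotype labels.

Samples are embedded by their TF expression, joined into a symmetric
k-nearest-neighbour graph with Gaussian kernel weights, and scored by the
probability that a weight-proportional random walk is absorbed at the
mesenchymal anchor before the epithelial anchor.  The two anchors are
virtual absorbing nodes attached to every member of their class, so every
real sample — labelled or not — receives a continuous harmonic score.
Scores are min–max rescaled to [0, 1]; the induced ascending order is the
pseudotime order, applied identically to all three panel layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from scipy.spatial.distance import squareform, pdist

from .io import EPITHELIAL, MESENCHYMAL, OmicsPanel


@dataclass
class PseudotimeAssignment:
    """Per-sample pseudotime score in [0, 1] and the induced sample order."""

    scores: pd.Series  # indexed by sample_id

    @property
    def order(self) -> list[str]:
        """Ascending-score order; ties broken lexicographically by sample ID."""
        ids = np.array(self.scores.index)
        order = np.lexsort((ids, self.scores.to_numpy()))
        return [str(ids[i]) for i in order]

    def rank_uniform(self) -> pd.Series:
        """Scores replaced by their rank position mapped to an even grid on [0, 1].

        A strictly monotone transform of the scores (ties broken by sample
        ID), so rank statistics are unchanged while spacing becomes uniform —
        the scale used for derivative estimation downstream.
        """
        order = self.order
        n = len(order)
        grid = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
        return pd.Series(grid, index=order, name="pseudotime").reindex(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        order = self.order
        rank = {sid: r for r, sid in enumerate(order)}
        return pd.DataFrame(
            {
                "sample_id": list(self.scores.index),
                "score": self.scores.to_numpy(),
                "rank": [rank[s] for s in self.scores.index],
            }
        )


def similarity_graph(
    tf_matrix: pd.DataFrame, k: int = 10
) -> tuple[sp.csr_matrix, list[str]]:
    """Symmetric kNN graph over samples with Gaussian kernel weights.

    Features are z-scored before Euclidean distances; an edge exists when
    either endpoint lists the other among its k nearest; weights are
    exp(-d^2 / sigma^2) with sigma the median nonzero kNN distance.  A
    minimum-spanning-tree union guarantees connectivity.
    """
    n = tf_matrix.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    values = tf_matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, keepdims=True)
    mean = values.mean(axis=1, keepdims=True)
    # zero-variance features carry no distance information and are skipped;
    # identical samples therefore yield an all-zero distance matrix
    z = np.where(sd > 0, (values - mean) / np.where(sd == 0, 1.0, sd), 0.0)

    dist = squareform(pdist(z.T, metric="euclidean"))
    # k nearest neighbours of each sample (excluding self)
    neighbor_idx = np.argsort(dist, axis=1, kind="stable")[:, 1 : k + 1]
    knn_mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    knn_mask[rows, neighbor_idx.ravel()] = True
    adj = knn_mask | knn_mask.T

    knn_d = dist[rows, neighbor_idx.ravel()]
    nonzero = knn_d[knn_d > 0]
    sigma = float(np.median(nonzero)) if nonzero.size else 1.0

    weights = np.where(adj, np.exp(-(dist**2) / sigma**2), 0.0)
    np.fill_diagonal(weights, 0.0)

    graph = sp.csr_matrix(weights)
    n_comp, _ = csgraph.connected_components(graph, directed=False)
    if n_comp > 1:
        mst = csgraph.minimum_spanning_tree(sp.csr_matrix(dist)).toarray()
        extra = (mst > 0) | (mst.T > 0)
        # outlying samples can underflow the kernel on every incident edge;
        # flooring all spanning-tree weights guarantees connectivity
        bridge = np.maximum(np.exp(-(dist**2) / sigma**2), 1e-12)
        weights = np.where(adj, np.exp(-(dist**2) / sigma**2), 0.0)
        weights = np.where(extra, bridge, weights)
        np.fill_diagonal(weights, 0.0)
        graph = sp.csr_matrix(weights)
    return graph, [str(c) for c in tf_matrix.columns]


def absorption_pseudotime(
    graph: sp.spmatrix,
    sample_ids: list[str],
    labels: pd.Series,
    anchor_strength: float = 1.0,
) -> PseudotimeAssignment:
    """Harmonic absorption score: P(reach mesenchymal anchor before epithelial).

    A virtual epithelial anchor (value 0) connects to every epithelial sample
    and a mesenchymal anchor (value 1) to every mesenchymal sample, each edge
    weighted ``anchor_strength`` times the sample's graph strength.  Real
    samples are interior nodes of one sparse linear system; the solution is
    min–max rescaled to [0, 1].
    """
    W = sp.csr_matrix(graph)
    n = W.shape[0]
    lab = labels.reindex(sample_ids)
    is_e = (lab == EPITHELIAL).to_numpy()
    is_m = (lab == MESENCHYMAL).to_numpy()
    if not is_e.any() or not is_m.any():
        raise ValueError("both epithelial and mesenchymal samples are required")

    strength = np.asarray(W.sum(axis=1)).ravel()
    w_e = np.where(is_e, anchor_strength * strength, 0.0)
    w_m = np.where(is_m, anchor_strength * strength, 0.0)

    # (D_total - W) h = w_m * 1, with D_total = strength + anchor weights
    d_total = strength + w_e + w_m
    A = sp.diags(d_total) - W
    h = sp.linalg.spsolve(sp.csc_matrix(A), w_m)

    lo, hi = float(h.min()), float(h.max())
    scores = (h - lo) / (hi - lo) if hi > lo else np.zeros(n)
    return PseudotimeAssignment(scores=pd.Series(scores, index=sample_ids, name="score"))


def infer_pseudotime(
    panel: OmicsPanel, k: int = 10, anchor_strength: float = 1.0
) -> PseudotimeAssignment:
    """Similarity graph on the TF layer, then label-anchored absorption scores."""
    graph, ids = similarity_graph(panel.tf_matrix, k=k)
    return absorption_pseudotime(graph, ids, panel.labels, anchor_strength=anchor_strength)


def propagate_order(
    assignment: PseudotimeAssignment, panel: OmicsPanel
) -> OmicsPanel:
    """Reorder all three layers (and labels) by ascending pseudotime score."""
    missing = set(panel.sample_ids) - set(assignment.scores.index)
    if missing:
        raise ValueError(f"assignment misses samples: {sorted(missing)[:5]}")
    return panel.reorder(assignment.order)
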