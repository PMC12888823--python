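"""Infer the sparse signed TF->RBP->AS network from a shuffled panel.

After pseudotime recovery, every node's derivative along the trajectory is
regressed on the mass-action product terms its layer allows, with a
Bayesian Lasso pressing spurious couplings to zero.  Edge scores are
compared against the generating adjacency.
"""

import numpy as np
import pandas as pd

from splicecontrol import SimConfig, simulate_panel, infer_pseudotime, infer_network
from splicecontrol.metrics import roc_auc

cfg = SimConfig(seed=1)
panel, truth = simulate_panel(cfg)
assignment = infer_pseudotime(panel)

network = infer_network(panel, assignment.rank_uniform(), seed=1)

key = pd.MultiIndex.from_tuples(list(zip(network.edges["source"], network.edges["target"])))
y_true = truth.edge_indicator().reindex(key).to_numpy()
auc = roc_auc(network.edges["score"].to_numpy(), y_true)

called = network.called_edges()
print(f"candidate edges: {len(network.edges)}  (all layer-allowed pairs)")
print(f"called edges:    {len(called)}  (90% credible interval excludes 0)")
print(f"true edges:      {int(y_true.sum())}")
print(f"ROC AUC of |posterior mean| vs truth: {auc:.3f}")
print()
print("strongest five called edges (sign +1 activating, -1 repressive):")
top = called.sort_values("score", ascending=False).head(5)
for r in top.itertuples():
    print(f"  {r.source:>5} -> {r.target:<5} coef={r.post_mean:+.3f} sign={r.sign:+d}")
print()
print("AUC near 0.9 shows the credible-interval scores rank true couplings")
print("far above absent ones even though samples arrived unordered.")
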