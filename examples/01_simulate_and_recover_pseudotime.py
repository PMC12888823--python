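"""Simulate a cross-sectional EMT panel and recover its hidden time axis.

A hierarchical mass-action system (2 TFs -> 3 RBPs -> 5 AS events) is
integrated over pseudotime, sampled at 100 points, and the samples are
randomly shuffled so the temporal order is lost — exactly the situation in
a cross-sectional cohort.  The similarity-graph random walk then rebuilds
a per-sample pseudotime score from the TF expression alone.
"""

import numpy as np

from splicecontrol import SimConfig, simulate_panel, infer_pseudotime
from splicecontrol.metrics import spearman_rho

panel, truth = simulate_panel(SimConfig(seed=1))
assignment = infer_pseudotime(panel)

inferred = assignment.scores.reindex(panel.sample_ids).to_numpy()
true_s = truth.pseudotime.reindex(panel.sample_ids).to_numpy()
rho = spearman_rho(inferred, true_s)

print(f"samples:                  {panel.n_samples}")
print(f"epithelial / mesenchymal: {(panel.labels == 1).sum()} / {(panel.labels == 2).sum()}")
print(f"Spearman rho vs truth:    {rho:.5f}")
print()
print("first five samples in recovered order (score, true pseudotime):")
for sid in assignment.order[:5]:
    print(f"  {sid}  score={assignment.scores[sid]:.3g}  true={truth.pseudotime[sid]:.3f}")
print()
print("A rho near 1 means the shuffled cohort was put back onto the")
print("epithelial-to-mesenchymal axis almost perfectly.")
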