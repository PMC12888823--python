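"""How pseudotime and network recovery degrade under multiplicative noise.

Every matrix entry is multiplied by a Gamma factor with mean 1+mu and
coefficient of variation cv, then the whole pipeline reruns from scratch.
A small slice of the (mu, cv) grid is shown; the full grid is available via
``splicecontrol.metrics.robustness_sweep`` or `splicecontrol robustness`.
"""

import numpy as np

from splicecontrol.metrics import robustness_sweep

grid = robustness_sweep(
    mu_grid=(0.0, 0.10),
    cv_grid=(0.0, 0.10, 0.20),
    seeds=[0, 1, 2],
)

print("median metrics per noise setting (3 seeds each):")
print(f"{'mu':>5} {'cv':>5} {'rho':>7} {'rmse':>7} {'auc':>6} {'mcc':>6}")
for (mu, cv), sub in grid.groupby(["noise_mean", "noise_cv"]):
    print(f"{mu:5.2f} {cv:5.2f} {sub['rho'].median():7.3f} "
          f"{sub['rmse'].median():7.3f} {sub['auc'].median():6.3f} "
          f"{sub['mcc'].median():6.3f}")
print()
print("Pure rescaling (cv=0) is invisible to the rank-based pipeline;")
print("entry-level scatter (cv>0) erodes network recovery first while the")
print("pseudotime ordering stays comparatively stable.")
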