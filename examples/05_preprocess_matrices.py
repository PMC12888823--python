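"""The three preprocessing filters applied to a matrix with missing values.

Cohort matrices typically arrive with missing entries and uninformative
rows.  The standard chain is: drop rows with too many missing values,
impute the rest from the k nearest feature rows, and remove rows with zero
variance.
"""

import numpy as np
import pandas as pd

from splicecontrol import filter_missing_rows, knn_impute, drop_zero_variance

rng = np.random.default_rng(0)
mat = pd.DataFrame(
    rng.lognormal(0, 0.5, size=(8, 12)),
    index=[f"GENE{i}" for i in range(8)],
    columns=[f"S{j:02d}" for j in range(12)],
)
mat.iloc[1, :7] = np.nan        # mostly missing -> dropped by the row filter
mat.iloc[3, [0, 5]] = np.nan    # lightly missing -> imputed
mat.iloc[6] = 2.0               # constant -> dropped as zero-variance

print(f"input: {mat.shape[0]} rows, {int(mat.isna().sum().sum())} missing cells")
step1 = filter_missing_rows(mat, max_missing=5)
print(f"after missing-row filter (>=5 missing dropped): {step1.shape[0]} rows")
step2 = knn_impute(step1, k=3)
print(f"after kNN imputation: {int(step2.isna().sum().sum())} missing cells")
print(f"  GENE3 imputed values: "
      f"S00={step2.loc['GENE3', 'S00']:.3f}, S05={step2.loc['GENE3', 'S05']:.3f}")
step3 = drop_zero_variance(step2)
print(f"after zero-variance drop: {step3.shape[0]} rows "
      f"(removed: {sorted(set(step2.index) - set(step3.index))})")
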