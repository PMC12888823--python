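import numpy as np
import pandas as pd
import pytest

from splicecontrol import OmicsPanel, SimConfig, simulate_panel


@pytest.fixture(scope="session")
def clean_sim():
    """One noiseless benchmark-scale panel with ground truth (seed 0)."""
    return simulate_panel(SimConfig(seed=0))


@pytest.fixture()
def tiny_panel():
    """Hand-built 3-layer panel with 6 samples on a known monotone gradient."""
    rng = np.random.default_rng(42)
    samples = [f"S{i}" for i in range(6)]
    grad = np.linspace(0.0, 1.0, 6)

    def mat(prefix, n):
        rows = {}
        for i in range(n):
            slope = rng.uniform(-2, 2)
            rows[f"{prefix}{i + 1}"] = 1.0 + slope * grad + 0.01 * rng.standard_normal(6)
        return pd.DataFrame(rows, index=samples).T

    labels = pd.Series([1, 1, 1, 2, 2, 2], index=samples, name="label")
    return OmicsPanel(
        as_matrix=mat("AS", 4), rbp_matrix=mat("RBP", 3), tf_matrix=mat("TF", 2),
        labels=labels,
    )
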