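import numpy as np
import pandas as pd
import pytest

from omniscreen import synthetic as syn


@pytest.fixture(scope="session")
def glioma_bundle():
    """Default-condition glioma cohort reused by read-only tests."""
    return syn.simulate_glioma_cohort(seed=1)


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Effect-only cohort: zero expression noise, infinite beta precision."""
    return syn.simulate_glioma_cohort(
        effect_sizes={"expr_sigma": 0.0, "beta_precision": np.inf},
        censor_rate=0.0, seed=2,
    )


@pytest.fixture(scope="session")
def tissue_panel():
    expr, truth, site_map = syn.simulate_tissue_panel(
        n_genes=200, n_tissues=30, n_specific=10, specificity_fold=50.0,
        sites_per_tissue=2, seed=7)
    return expr, truth, site_map


@pytest.fixture()
def tiny_profiles():
    """Three genes over three tissues with hand-checkable tau values."""
    return pd.DataFrame(
        {"brain": [10.0, 7.0, 100.0], "liver": [5.0, 7.0, 0.0], "lung": [0.0, 7.0, 0.0]},
        index=["gradient", "housekeeping", "specific"],
    )
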