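import numpy as np
import pytest

from wmhpheno import synthetic
from wmhpheno.regions import N_REGIONS


@pytest.fixture(scope="session")
def small_cohort_spec():
    return synthetic.default_cohort_spec(n_participants=600, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_spec):
    return synthetic.generate_cross_sectional(small_cohort_spec)


@pytest.fixture(scope="session")
def small_longitudinal(small_cohort, small_cohort_spec):
    return synthetic.generate_longitudinal(small_cohort, small_cohort_spec)


@pytest.fixture
def uniform_profile():
    def make(label=1, weight=1.0, median_mL=2.0, log_sd=0.0, conc=1.0):
        return synthetic.ClusterProfileSpec(
            label=label, mixing_weight=weight,
            region_concentration=np.full(N_REGIONS, conc),
            burden_median_mL=median_mL, burden_log_sd=log_sd)
    return make


@pytest.fixture
def blob_data():
    """Two well-separated point clouds in 36-D: (X, labels)."""
    rng = np.random.default_rng(42)
    n = 120
    labels = (np.arange(n) >= n // 2).astype(int)
    X = rng.normal(0, 0.05, (n, N_REGIONS))
    X[labels == 1, 0] += 10.0
    return X, labels
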