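import numpy as np
import pytest

from shortsprint import CohortSpec, CorrectionMode, SplitSet, compare_modes, simulate_cohort

# cohort-mean cumulative gate times (s) at the standard 5/10/20/30/35 m layout
MEAN_DISTANCES = (5.0, 10.0, 20.0, 30.0, 35.0)
MEAN_TIMES = (1.20, 2.00, 3.39, 4.71, 5.36)


@pytest.fixture(scope="session")
def mean_splits() -> SplitSet:
    """Cohort-mean split times of a high-level female soccer cohort."""
    return SplitSet("cohort_mean", MEAN_DISTANCES, MEAN_TIMES,
                    body_mass=62.3, stature=1.674)


@pytest.fixture(scope="session")
def mean_fits(mean_splits):
    """Three-regime fits of the cohort-mean splits."""
    return compare_modes(mean_splits, fixed_correction=0.3)


@pytest.fixture(scope="session")
def recovery_cohort():
    """200 synthetic athletes under default study conditions, with their
    estimated-mode fits; shared across recovery and bias tests."""
    from shortsprint import fit_splits

    cohort = simulate_cohort(CohortSpec(n_athletes=200, seed=2024))
    fits = {
        mode: [fit_splits(s, mode) for s in cohort.splits]
        for mode in CorrectionMode
    }
    return cohort, fits


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
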