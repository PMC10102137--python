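import numpy as np
import pytest

from ahatraj import item_prep as ip
from ahatraj import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-person, 5-wave cohort with missingness applied."""
    cfg = syn.SimConfig(
        n_persons=300, n_waves=5, seed=11, item_bank_sizes=(12, 2),
        basis_loadings=(0.0, 0.3, 0.55, 0.8, 1.0),
        missing_rate=0.05, attrition_hazard=0.08,
    )
    return syn.apply_missingness(syn.simulate_cohort(cfg))


@pytest.fixture(scope="session")
def prepared(small_cohort):
    return ip.prepare_panel(small_cohort)


@pytest.fixture(scope="session")
def irt_cohort():
    """Recovery-test cohort: 500 persons, 20 items, 4 waves, probit GRM truth."""
    cfg = syn.SimConfig(
        n_persons=500, n_waves=4, seed=5, item_bank_sizes=(20, 0),
        basis_loadings=(0.0, 0.4, 0.7, 1.0),
        missing_rate=0.03, attrition_hazard=0.05,
    )
    return syn.apply_missingness(syn.simulate_cohort(cfg))


@pytest.fixture(scope="session")
def growth_scores():
    """Trait matrix (n=2000) from the default three-class growth mixture."""
    cfg = syn.SimConfig(n_persons=2000, seed=3)
    cohort = syn.apply_missingness(syn.simulate_cohort(cfg))
    scores = np.where(cohort.in_panel, cohort.theta, np.nan)
    return scores, cohort
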