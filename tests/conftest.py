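import numpy as np
import pandas as pd
import pytest

from murihaz import CohortTable, SimConfig, simulate_cohort


def make_cohort(ages, statuses=None, sexes=None, sites=None,
                weaning_age_days=0.0) -> CohortTable:
    """Build a minimal valid cohort table from plain arrays."""
    n = len(ages)
    tab = pd.DataFrame(
        {
            "mouse_id": [f"m{i:05d}" for i in range(n)],
            "sex": pd.Categorical(sexes if sexes is not None else ["F"] * n,
                                  categories=["F", "M"]),
            "site": pd.Categorical(sites if sites is not None else ["TJL"] * n,
                                   categories=["TJL", "UM", "UT"]),
            "cohort": 2004,
            "age_days": np.asarray(ages, dtype=float),
            "status": pd.Categorical(
                statuses if statuses is not None else ["died"] * n,
                categories=["died", "censored"]),
            "cage_id": "",
        }
    )
    return CohortTable(tab, provenance="test", weaning_age_days=weaning_age_days)


def exponential_cohort(n, mean_days, seed, sexes=None):
    rng = np.random.default_rng(seed)
    ages = rng.exponential(mean_days, n)
    return make_cohort(ages, sexes=sexes)


@pytest.fixture(scope="session")
def study_like_sim():
    """One mid-sized study-like cohort shared across tests (~3,600/sex)."""
    return simulate_cohort(SimConfig.study_like(n_per_sex_per_site=200, seed=0))


@pytest.fixture(scope="session")
def small_sim():
    """A small study-like cohort for cheap smoke tests (~360/sex)."""
    return simulate_cohort(SimConfig.study_like(n_per_sex_per_site=20, seed=1))
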