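import numpy as np
import pandas as pd
import pytest

from fetalens.simulate import Cohort, SimulationConfig, simulate_cohort

COVARIATE_ZEROS = [
    "maternal_age", "bmi", "smoking_level", "hbp", "cardiac", "diabetes",
    "renal", "other_disease",
]


def make_longitudinal_cohort(rows_subs, rows_long):
    """Cohort + EFW table from explicit (id, birth_ga, bw) and (id, t, y) rows."""
    subs = pd.DataFrame(rows_subs, columns=["id", "birth_ga", "birth_weight"])
    for c in COVARIATE_ZEROS:
        subs[c] = 0.0
    efw = pd.DataFrame(rows_long, columns=["id", "t", "efw"])
    visits = pd.DataFrame(
        {"id": efw["id"], "t": efw["t"], "bpd": 50.0, "mad": 50.0, "fl": 30.0}
    )
    return Cohort(subjects=subs, visits=visits), efw


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-subject default-parameter synthetic cohort (shared, read-only)."""
    return simulate_cohort(SimulationConfig(n_subjects=150, seed=42))


@pytest.fixture(scope="session")
def default_cohort_1115():
    """One full-size cohort at the published dimensions (shared, read-only)."""
    return simulate_cohort(SimulationConfig(n_subjects=1115, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# derandomized hypothesis profile so the suite is reproducible anywhere
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("det", derandomize=True)
_hyp_settings.load_profile("det")
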