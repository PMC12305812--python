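import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ifcea import AnaemiaCEA
from ifcea.cohort import Cohort
from ifcea.states import HB_INTERVALS, AnaemiaState

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

#: Hb values safely inside each state's interval, for fixture cohorts.
HB_BY_STATE = {0: 12.0, 1: 10.5, 2: 8.5, 3: 6.0}


def make_cohort(state_counts, n_ifc=None, seed=0) -> Cohort:
    """Cohort with exact per-state counts and state-consistent Hb."""
    states = np.repeat(np.arange(4), state_counts)
    n = len(states)
    rng = np.random.default_rng(seed)
    rng.shuffle(states)
    ifc = np.zeros(n, dtype=bool)
    if n_ifc:
        ifc[rng.choice(n, size=n_ifc, replace=False)] = True
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "age_band": np.resize(["6-<12", "12-<18", "18-<24"], n),
            "sex": np.resize(["boy", "girl"], n),
            "wealth_quintile": np.resize([1, 2, 3, 4, 5], n),
            "hb": [HB_BY_STATE[s] for s in states],
            "state": states,
            "ifc": ifc,
        }
    )
    return Cohort(df=df, seed=seed, provenance="test fixture")


@pytest.fixture(scope="session")
def small_config():
    return {"seed": 7, "expansion": {"n": 2000}}


@pytest.fixture(scope="session")
def fitted(small_config):
    """A fitted model on a small virtual cohort (shared, read-only)."""
    return AnaemiaCEA.from_config(small_config).fit()


def assert_hb_state_consistent(cohort: Cohort):
    for s in AnaemiaState:
        lo, hi = HB_INTERVALS[s]
        sub = cohort.df.loc[cohort.df["state"] == s.value, "hb"]
        assert ((sub >= lo) & (sub < hi)).all(), f"hb out of interval for {s}"
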