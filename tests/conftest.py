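import numpy as np
import pandas as pd
import pytest

from dynasurv.data import LongitudinalDataset
from dynasurv.simulate import ScenarioConfig, simulate_scenario


def make_dataset(times, events, visit_step=1.0, n_long=2, baseline=None, seed=0):
    """Hand-built dataset: visits every ``visit_step`` from 0 strictly below T."""
    rng = np.random.default_rng(seed)
    rows = []
    ids = [f"s{i}" for i in range(len(times))]
    for sid, T in zip(ids, times):
        ts = np.arange(0.0, T, visit_step)
        for t in ts:
            rows.append({"subject_id": sid, "time": t,
                         **{f"y{q}": rng.normal() for q in range(n_long)}})
    visits = pd.DataFrame(rows)
    idx = pd.Index(ids, name="subject_id")
    if baseline is None:
        baseline = pd.DataFrame({"b1": rng.normal(size=len(ids))}, index=idx)
    else:
        baseline = baseline.set_axis(idx)
    outcomes = pd.DataFrame({"time": np.asarray(times, float),
                             "event": np.asarray(events, int)}, index=idx)
    return LongitudinalDataset(baseline, visits, outcomes).validate()


@pytest.fixture
def toy_ds():
    return make_dataset(times=[2.0, 5.0, 7.0], events=[1, 0, 1])


@pytest.fixture(scope="session")
def sim1():
    return simulate_scenario(ScenarioConfig(scenario=1, n_subjects=300, seed=42))


@pytest.fixture(scope="session")
def sim3():
    return simulate_scenario(ScenarioConfig(scenario=3, n_subjects=300, seed=43))
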