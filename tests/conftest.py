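import numpy as np
import pandas as pd
import pytest

from actisurv import simulate as sim


def make_survival(n, beta, seed, baseline_rate=0.1, censoring_rate=0.0,
                  horizon=8.0, p=None):
    """Single/multi-feature standardized cohort with PH mortality."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = beta.size if p is None else p
    names = tuple(f"x{j}" for j in range(p))
    spec = sim.CohortSpec(
        n=n, feature_names=names, means=np.zeros(p), sds=np.ones(p),
        correlation=np.eye(p),
        beta={f"x{j}": float(beta[j]) for j in range(beta.size)},
        covariates=[], baseline_rate=baseline_rate,
        horizon_years=horizon, censoring_rate=censoring_rate, seed=seed)
    X, truth = sim.simulate_feature_cohort(spec)
    y = sim.simulate_survival(truth.linear_predictor, spec)
    return pd.concat([X, y], axis=1), truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def single_state_profile(state="SB", waking=960, days=1):
    dists = {
        "SB": sim.EmissionDistribution(14.0, 9.0, 0.0, 40.0),
        "LIPA": sim.EmissionDistribution(60.0, 14.0, 40.0, 100.0),
        "MVPA": sim.EmissionDistribution(140.0, 45.0, 100.0, 500.0),
    }
    return sim.ActivityProfile(
        states=(state,),
        bout_dist={state: sim.BoutDistribution(10.0)},
        emission={state: dists[state]},
        transition={},
        waking_minutes=waking, waking_sd_minutes=0.0, days=days,
        between_sd=0.0)


def constructed_trace():
    """One 960-min day: 600 epochs at 20 mg, 300 at 60 mg, 60 at 150 mg."""
    enmo = np.concatenate([np.full(600, 20.0), np.full(300, 60.0),
                           np.full(60, 150.0)])
    return pd.DataFrame({
        "participant_id": 0,
        "day_index": 0,
        "epoch_index": np.arange(960),
        "enmo_mg": enmo,
        "waking": 1,
    })
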