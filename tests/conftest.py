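import logging

import numpy as np
import pandas as pd
import pytest

import seroprog as sp

logging.getLogger("seroprog").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter cohort, n=300, eligibility filter applied."""
    cfg = sp.SimulationConfig(n_subjects=300, seed=11)
    return sp.simulate_cohort(cfg, apply_filter=True)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (unfiltered) for marginal checks."""
    return sp.simulate_cohort(sp.SimulationConfig(n_subjects=1138, seed=7))


def make_subjects(n, rng, arm=None, event_time=None, event=None):
    """Minimal subjects table with the nine survival covariates."""
    arm = rng.integers(0, 2, n) if arm is None else np.asarray(arm)
    event_time = (rng.uniform(1, 50, n) if event_time is None
                  else np.asarray(event_time, dtype=float))
    event = (np.ones(n, dtype=int) if event is None
             else np.asarray(event, dtype=int))
    cause = np.where(event == 1, "prostate_cancer", "censored")
    return pd.DataFrame({
        "id": np.arange(n), "arm": arm,
        "ecog_ge1": rng.integers(0, 2, n),
        "skeletal_ge10": rng.integers(0, 2, n),
        "liver_met": rng.integers(0, 2, n),
        "nodal_n1": rng.integers(0, 2, n),
        "gleason_9_10": rng.integers(0, 2, n),
        "worst_pain": rng.integers(0, 11, n),
        "baseline_hb": rng.normal(13.0, 1.5, n).clip(6),
        "baseline_psa": rng.lognormal(2.8, 1.5, n),
        "baseline_nlr": rng.lognormal(0.8, 0.4, n),
        "baseline_plr": rng.lognormal(4.9, 0.4, n),
        "baseline_lmr": rng.lognormal(1.55, 0.35, n),
        "event_time": event_time, "event": event, "cause": cause,
    })
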