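import numpy as np
import pandas as pd
import pytest

from actirisk.preprocess import EpochSeries
from actirisk.simulate import (
    EffectConfig,
    MissingnessConfig,
    NoiseConfig,
    SimConfig,
    simulate_cohort,
)


def make_series(values, imputed=None, epoch_seconds=60, start="2014-06-02", pid="P000000"):
    return EpochSeries(
        participant_id=pid,
        start=pd.Timestamp(start),
        epoch_seconds=epoch_seconds,
        values=np.asarray(values, dtype=float),
        imputed=imputed,
    )


@pytest.fixture(scope="session")
def clean_config():
    """7-day 1-min generator with no noise and no missingness."""
    return SimConfig(
        n_participants=3,
        seed=11,
        noise=NoiseConfig(ar1=0.0, innovation_sd=0.0, sigma=0.0),
        missingness=MissingnessConfig(expected_hours_per_day=0.0),
    )


@pytest.fixture(scope="session")
def null_cohort():
    """n=4,000 cohort with all effect coefficients zero, ~120 events."""
    cfg = SimConfig(
        n_participants=4000,
        seed=29,
        effects=EffectConfig.null(),
        event_target=120,
    )
    cohort, _, truth = simulate_cohort(cfg, with_activity=False)
    return cohort, truth


@pytest.fixture(scope="session")
def effect_cohort():
    """n=12,000 cohort with a true T1-vs-T3 amplitude log-HR of log(1.5)."""
    cfg = SimConfig(
        n_participants=12000,
        seed=31,
        effects=EffectConfig.null(
            rar_t1_loghr=float(np.log(1.5)), rar_t2_loghr=float(np.log(1.5)) / 2
        ),
        event_target=300,
    )
    cohort, _, truth = simulate_cohort(cfg, with_activity=False)
    return cohort, truth


@pytest.fixture(scope="session")
def rich_cohort():
    """Cohort with the default effect menu (age, sex, smoking, PRS, rhythm)."""
    cfg = SimConfig(n_participants=12000, seed=37, event_target=350)
    cohort, _, truth = simulate_cohort(cfg, with_activity=False)
    return cohort, truth
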