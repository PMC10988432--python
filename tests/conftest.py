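import numpy as np
import pandas as pd
import pytest

from myoquant import default_config, generate_cohort
from myoquant.cohort import EpochSeries
from myoquant.config import AccelProfile


@pytest.fixture(scope="session")
def small_cohort():
    """A 6+4-subject cohort with short recordings, for structural tests."""
    cfg = default_config(n_esld=6, n_hc=4, accel=AccelProfile(days=3))
    return cfg, generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-sized cohort (n=39 ESLD, n=18 HC) at a fixed seed."""
    cfg = default_config()
    return cfg, generate_cohort(cfg, seed=1)


def make_series(
    day_mags,
    epoch_s=300,
    wear_hours=24.0,
    calibration_error=0.004,
    start="2021-03-01",
):
    """Build an EpochSeries from per-day magnitude specs.

    ``day_mags``: list of per-day scalars (constant magnitude) or arrays.
    Non-wear time, when wear_hours < 24, is a trailing block each day.
    """
    n_day = 86400 // epoch_s
    wear_n = int(round(wear_hours * 3600 / epoch_s))
    mags, wear = [], []
    for spec in day_mags:
        day = np.full(n_day, float(spec)) if np.isscalar(spec) else np.asarray(spec, float)
        assert day.size == n_day
        w = np.zeros(n_day, dtype=bool)
        w[:wear_n] = True
        day = np.where(w, day, 0.0)
        mags.append(day)
        wear.append(w)
    return EpochSeries(
        start=pd.Timestamp(start),
        epoch_length=float(epoch_s),
        magnitudes=np.concatenate(mags),
        wear=np.concatenate(wear),
        calibration_error=calibration_error,
    )
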