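"""Shared fixtures: hand-constructed workout streams and simulated
cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from marathon_response.features import EARTH_RADIUS_M
from marathon_response.pipeline import run_simulated
from marathon_response.simulate import (
    SimConfig,
    ramped_intensity_config,
    recovery_config,
)
from marathon_response.stream_io import make_stream

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

M_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0


def east_stream(
    speeds,
    dt: int = 1,
    t0: int = 0,
    hr=None,
    hr_dt: int | None = None,
    subject_id: str = "s",
    workout_id: str = "w",
):
    """Workout stream running due east along the equator at the given
    per-interval speeds [m/s]; on the equator consecutive great-circle
    distances equal the planar eastward steps exactly."""
    v = np.asarray(speeds, dtype=float)
    east = np.concatenate(([0.0], np.cumsum(v * dt)))
    t = t0 + np.arange(len(east), dtype=np.int64) * dt
    lon = east / M_PER_DEG
    lat = np.zeros_like(lon)
    if hr is None:
        hr_t, hr_v = [], []
    else:
        hr_v = np.asarray(hr, dtype=float)
        step = hr_dt if hr_dt is not None else dt
        hr_t = t0 + np.arange(len(hr_v), dtype=np.int64) * step
    return make_stream(subject_id, workout_id, t, lat, lon, hr_t, hr_v)


@pytest.fixture(scope="session")
def recovery_run():
    """Parameter-recovery cohort: 90 subjects, 30 per response tier,
    1 Hz sampling, low noise; full pipeline output plus ground truth."""
    return run_simulated(recovery_config(1))


@pytest.fixture(scope="session")
def ramped_run():
    """Same cohort conditions, but high responders ramp intensity from
    LIT toward threshold/HIT across the four training blocks."""
    return run_simulated(ramped_intensity_config(1))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 12-subject cohort at 5 s sampling for structural tests."""
    from marathon_response.simulate import simulate_cohort

    cfg = SimConfig(n_subjects=12, seed=11, sampling_interval_gps=5, sampling_interval_hr=5)
    return simulate_cohort(cfg)
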