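"""Shared fixtures and pipeline helpers for the test suite.

All image fixtures are generated programmatically from the synthetic module;
nothing is loaded from disk except files the tests themselves write.
"""
from __future__ import annotations

import numpy as np
import pytest

from gelswitch import (
    SyntheticTruth,
    area_tracking,
    imaging_io,
    synthetic,
    transition,
)

# Synthetic switching videos are sampled at 5 s intervals (instead of the
# camera's 1/0.9 s) to keep rendering tractable; the smoothing sigma is scaled
# to the same ~55 s time constant as the 50-sample default at 0.9 fps.
PIPELINE_DT = 5.0
PIPELINE_SIGMA = 11.0


def make_ramp_trace(
    T_t: float = 40.0,
    stroke: float = 0.8,
    width: float = 0.7,
    noise_sd: float = 0.005,
    seed: int = 0,
    rate: float = 0.04,
    t_low: float = 30.0,
    t_high: float = 45.0,
    dt: float = PIPELINE_DT,
):
    profile = synthetic.make_temperature_profile("ramp", t_low, t_high, rate, sampling_dt=dt)
    truth = SyntheticTruth(T_t=T_t, stroke_area=stroke, width_w=width, seed=seed)
    trace, truth = synthetic.make_contraction_trace(profile, truth, noise_sd=noise_sd)
    return profile, trace, truth


def full_pipeline_transition(
    T_t: float,
    seed: int,
    stroke: float = 0.8,
    noise_sd: float = 0.005,
    method: str = "threshold",
    sigma: float = PIPELINE_SIGMA,
):
    """render -> align -> track -> find_transition on a synthetic ramp video."""
    profile, trace, truth = make_ramp_trace(T_t=T_t, stroke=stroke, noise_sd=noise_sd, seed=seed)
    series = synthetic.render_contraction_frames(trace, pixel_size=0.02, seed=seed)
    aligned = imaging_io.align_temperature(series, profile)
    measured = area_tracking.track_area(aligned, method=method, sigma=sigma)
    return transition.find_transition(measured), truth


def make_cyclic_trace(
    loss: float = 0.0034,
    noise_sd: float = 0.002,
    seed: int = 0,
    n_cycles: int = 20,
    stroke: float = 0.8,
    T_t: float = 40.0,
    width: float = 0.7,
    dt: float = 2.0,
):
    profile = synthetic.make_temperature_profile(
        "cyclic", 28.0, 42.0, 0.04, n_cycles=n_cycles, dwell=300.0, sampling_dt=dt
    )
    truth = SyntheticTruth(T_t=T_t, stroke_area=stroke, width_w=width,
                           loss_per_cycle=loss, seed=seed)
    trace, truth = synthetic.make_contraction_trace(profile, truth, noise_sd=noise_sd)
    return profile, trace, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ramp_profile():
    return synthetic.make_temperature_profile("ramp", 30.0, 45.0, 0.04, sampling_dt=PIPELINE_DT)
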