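"""Shared fixtures: small analytic traces with known kinetics."""

import numpy as np
import pytest

from calsig import AnalysisConfig, NormalizedTrace, Trace


def make_normalized(times, ratio, stim_time, cell_id="cell",
                    baseline_sd=0.01):
    """Construct a NormalizedTrace directly from a ratio series."""
    return NormalizedTrace(
        cell_id=cell_id, times=np.asarray(times, dtype=float),
        ratio=np.asarray(ratio, dtype=float), f0=100.0,
        baseline_sd_ratio=baseline_sd, stim_time=stim_time)


def ramp_trace(stim=20.0, peak=2.0, ramp_s=10.0, dt=0.5, total=100.0):
    """Ratio 1 until the stimulus, linear climb to ``peak`` over
    ``ramp_s`` seconds, then held at the peak."""
    times = np.arange(0.0, total + dt / 2, dt)
    ratio = np.ones_like(times)
    climbing = (times >= stim) & (times <= stim + ramp_s)
    ratio[climbing] = 1.0 + (peak - 1.0) * (times[climbing] - stim) / ramp_s
    ratio[times > stim + ramp_s] = peak
    return make_normalized(times, ratio, stim)


def rectangle_trace(stim=20.0, level=2.0, dt=0.5, total=120.0):
    """Ratio 1 before the stimulus, ``level`` from the stimulus to the
    end of the recording (a rectangular pulse cut off by the end)."""
    times = np.arange(0.0, total + dt / 2, dt)
    ratio = np.where(times >= stim, level, 1.0)
    return make_normalized(times, ratio, stim)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def flat_trace():
    times = np.arange(0.0, 100.0, 0.5)
    return make_normalized(times, np.ones_like(times), stim_time=30.0)
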