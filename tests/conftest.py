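"""Shared fixtures and helpers for the test suite."""

from pathlib import Path

import numpy as np
import pytest

from caosc.trace_io import Trace

DATA_DIR = Path(__file__).parent / "data"
DT = 7.5  # acquisition sampling interval, seconds


def make_trace(values, dt=DT, stimulus=0.0, egg_id="egg", group="A", mode="strontium"):
    return Trace(
        egg_id=egg_id,
        group=group,
        mode=mode,
        replicate="r1",
        sampling_interval_s=dt,
        stimulus_time_s=stimulus,
        values=np.asarray(values, dtype=float),
    )


def square_pulse_trace(
    baseline=0.8, amp=0.5, start_s=300.0, dur_s=60.0, total_s=900.0, dt=DT, **kw
):
    """Noiseless trace with one rectangular elevation (closed-form everything)."""
    t = np.arange(int(round(total_s / dt)) + 1) * dt
    v = np.full_like(t, baseline)
    v[(t >= start_s) & (t < start_s + dur_s)] += amp
    return make_trace(v, dt=dt, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def data_dir():
    return DATA_DIR
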