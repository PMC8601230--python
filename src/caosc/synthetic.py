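"""Seeded synthetic calcium-trace generator with per-egg ground truth.

The generator emulates the oscillation regimes seen after egg activation:
after a latency from the stimulus, a first transient that is larger and
longer than the rest, followed by shorter transients recurring every few
minutes whose spacing slowly stretches, until a per-egg cessation time.
Slow linear baseline drift and i.i.d. Gaussian noise are added last, so the
noiseless signal (and hence every downstream feature) has a closed form that
oracle tests can use.

Transient shape
---------------
A transient of duration ``d`` and amplitude ``a`` rises linearly over the
first ``RISE_FRACTION`` of ``d`` and then decays exponentially with time
constant ``tau = (1 - RISE_FRACTION) * d / DECAY_E_FOLDS``, truncated to
zero at ``d``.  With five e-folds the residual at truncation is < 1% of the
amplitude, and the area above baseline is analytically

    AUC = a * (RISE_FRACTION * d / 2 + tau * (1 - exp(-DECAY_E_FOLDS))).

Latencies, durations, inter-transient intervals and cessation times are
truncated-Gaussian draws (floored so invariants hold); intervals are
redrawn when a transient would overlap its successor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from .trace_io import Trace, TraceSet

__all__ = [
    "SimulationParams",
    "RISE_FRACTION",
    "DECAY_E_FOLDS",
    "transient_shape",
    "transient_auc",
    "simulate_trace",
    "simulate_experiment",
    "scenario",
    "SCENARIO_NAMES",
]

#: fraction of a transient's duration spent on the linear rise
RISE_FRACTION = 0.2
#: e-folds of exponential decay packed into the remaining duration
DECAY_E_FOLDS = 5.0

SCENARIO_NAMES = ("sr_null", "sr_paper", "ivf_null", "ivf_shift")


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for one group's synthetic traces.

    Times are seconds, amplitudes are ratio units above baseline.  Defaults
    are the strontium-activation regime: a ~5 min latency to a first
    transient that is larger and longer than the subsequent ones, two to
    three transients per 10 min with geometrically stretching spacing, and
    widely heterogeneous per-egg cessation times (eggs whose cessation
    exceeds the recording are the censored class downstream).
    """

    n_eggs: int = 75
    baseline: float = 0.8
    noise_sd: float = 0.0125
    drift_per_min: float = 5e-05
    latency_mean_s: float = 300.0
    latency_sd_s: float = 75.0
    first_dur_mean_s: float = 120.0
    first_dur_sd_s: float = 40.0
    sub_dur_mean_s: float = 110.0
    sub_dur_sd_s: float = 35.0
    amp_first: float = 0.43
    amp_sub: float = 0.42
    amp_cv: float = 0.3
    iti_mean_s: float = 240.0
    iti_sd_s: float = 120.0
    iti_slowdown: float = 1.05
    cessation_mean_s: float = 3300.0
    cessation_sd_s: float = 3300.0
    recording_len_s: float = 6600.0
    sampling_interval_s: float = 7.5
    stimulus_time_s: float = 60.0
    responder_frac: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        nonneg = (
            "noise_sd latency_mean_s latency_sd_s first_dur_mean_s first_dur_sd_s "
            "sub_dur_mean_s sub_dur_sd_s iti_mean_s iti_sd_s cessation_mean_s "
            "cessation_sd_s stimulus_time_s"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.amp_cv < 0:
            raise ValueError(f"amp_cv must be >= 0, got {self.amp_cv}")
        if not (0.0 <= self.responder_frac <= 1.0):
            raise ValueError(f"responder_frac must be in [0, 1], got {self.responder_frac}")
        if self.iti_slowdown < 1.0:
            raise ValueError(f"iti_slowdown must be >= 1, got {self.iti_slowdown}")
        if self.amp_first <= 0 or self.amp_sub <= 0:
            raise ValueError("amp_first and amp_sub must be > 0")
        if self.n_eggs < 0:
            raise ValueError("n_eggs must be >= 0")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be > 0")
        if self.recording_len_s < self.sampling_interval_s:
            raise ValueError(
                "recording_len_s must cover at least one sampling interval "
                f"({self.recording_len_s} < {self.sampling_interval_s})"
            )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimulationParams field(s): {sorted(unknown)}")
        return cls(**d)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    """One truncated-Gaussian draw via rejection (exact; truncation at `floor`)."""
    if sd == 0:
        return max(mean, floor)
    # rejection is cheap because the floor almost always sits in the far tail
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= floor:
            return x
    return floor


def transient_shape(
    t: np.ndarray, onset_s: float, duration_s: float, amplitude: float
) -> np.ndarray:
    """Evaluate one transient's elevation above baseline at times ``t``."""
    rise_end = onset_s + RISE_FRACTION * duration_s
    tau = (1.0 - RISE_FRACTION) * duration_s / DECAY_E_FOLDS
    out = np.zeros_like(t, dtype=float)
    rising = (t >= onset_s) & (t < rise_end)
    if RISE_FRACTION * duration_s > 0:
        out[rising] = amplitude * (t[rising] - onset_s) / (RISE_FRACTION * duration_s)
    decaying = (t >= rise_end) & (t < onset_s + duration_s)
    out[decaying] = amplitude * np.exp(-(t[decaying] - rise_end) / tau)
    return out


def transient_auc(duration_s: float, amplitude: float) -> float:
    """Closed-form area above baseline of one transient (ratio * seconds)."""
    tau = (1.0 - RISE_FRACTION) * duration_s / DECAY_E_FOLDS
    return amplitude * (
        RISE_FRACTION * duration_s / 2.0 + tau * (1.0 - math.exp(-DECAY_E_FOLDS))
    )


def _draw_events(p: SimulationParams, rng: np.random.Generator):
    """Draw onset/duration/amplitude triples for one responder egg."""
    dt = p.sampling_interval_s
    # per-egg response scale: dye loading and egg-to-egg amplitude variation
    if p.amp_cv > 0:
        sigma = math.sqrt(math.log1p(p.amp_cv**2))
        scale = rng.lognormal(-sigma**2 / 2.0, sigma)  # mean 1
    else:
        scale = 1.0
    latency = _trunc_normal(rng, p.latency_mean_s, p.latency_sd_s, dt)
    first_onset = p.stimulus_time_s + latency
    stop = first_onset + _trunc_normal(rng, p.cessation_mean_s, p.cessation_sd_s, 0.0)
    onsets: list[float] = []
    durations: list[float] = []
    amps: list[float] = []
    onset = first_onset
    k = 0
    while onset < min(stop, p.recording_len_s):
        if k == 0:
            dur = _trunc_normal(rng, p.first_dur_mean_s, p.first_dur_sd_s, dt)
            amp = scale * p.amp_first
        else:
            dur = _trunc_normal(rng, p.sub_dur_mean_s, p.sub_dur_sd_s, dt)
            amp = scale * p.amp_sub
        onsets.append(onset)
        durations.append(dur)
        amps.append(amp)
        # next onset: interval stretched geometrically, redrawn on overlap
        mean_iti = p.iti_mean_s * p.iti_slowdown**k
        iti = _trunc_normal(rng, mean_iti, p.iti_sd_s, dt)
        tries = 0
        while iti < dur and tries < 100:
            iti = _trunc_normal(rng, mean_iti, p.iti_sd_s, dt)
            tries += 1
        if iti < dur:
            iti = dur
        onset = onset + iti
        k += 1
    return onsets, durations, amps, stop, latency


def simulate_trace(
    p: SimulationParams,
    rng: np.random.Generator,
    egg_id: str = "egg_000",
    group: str = "A",
    mode: str = "strontium",
    replicate: str = "r1",
) -> tuple[Trace, dict]:
    """Simulate one egg and return (trace, ground-truth row).

    The truth row records the responder flag, every true onset and duration,
    the generative cessation stop time, and whether that stop exceeded the
    recording (the censored class for persistence analysis).
    """
    dt = p.sampling_interval_s
    n = int(round(p.recording_len_s / dt)) + 1
    t = np.arange(n) * dt
    signal = np.full(n, p.baseline, dtype=float)
    signal += p.drift_per_min * t / 60.0

    responder_draw = bool(rng.random() < p.responder_frac)
    onsets: list[float] = []
    durations: list[float] = []
    amps: list[float] = []
    stop = math.nan
    latency = math.nan
    if responder_draw:
        onsets, durations, amps, stop, latency = _draw_events(p, rng)
        for onset, dur, amp in zip(onsets, durations, amps):
            i0 = max(0, int(onset // dt))
            i1 = min(n, int((onset + dur) // dt) + 2)
            signal[i0:i1] += transient_shape(t[i0:i1], onset, dur, amp)
    if p.noise_sd > 0:
        signal = signal + rng.normal(0.0, p.noise_sd, n)

    trace = Trace(
        egg_id=egg_id,
        group=group,
        mode=mode,
        replicate=replicate,
        sampling_interval_s=dt,
        stimulus_time_s=p.stimulus_time_s,
        values=signal,
    )
    responder = bool(onsets)
    truth = {
        "egg_id": egg_id,
        "group": group,
        "responder": responder,
        "n_transients": len(onsets),
        "latency_s": latency if responder else math.nan,
        "first_onset_s": onsets[0] if responder else math.nan,
        "last_onset_s": onsets[-1] if responder else math.nan,
        "cessation_stop_s": stop,
        "cessation_censored": bool(responder and stop > p.recording_len_s),
        "onsets_s": ";".join(repr(v) for v in onsets),
        "durations_s": ";".join(repr(v) for v in durations),
        "amplitudes": ";".join(repr(v) for v in amps),
    }
    return trace, truth


def simulate_experiment(
    p_group_a: SimulationParams,
    p_group_b: SimulationParams,
    seed: int,
    group_names: tuple[str, str] = ("NC", "SOV"),
    mode: str = "strontium",
) -> tuple[TraceSet, pd.DataFrame]:
    """Simulate a paired two-group experiment (one imaging dish).

    Each group gets its own child seed stream, and each egg its own
    grandchild stream, so adding eggs to one group never perturbs the
    other group's traces.
    """
    if p_group_a.recording_len_s != p_group_b.recording_len_s:
        raise ValueError("groups must share recording_len_s")
    if p_group_a.sampling_interval_s != p_group_b.sampling_interval_s:
        raise ValueError("groups must share sampling_interval_s")
    root = np.random.SeedSequence(seed)
    group_ss = root.spawn(2)
    traces: list[Trace] = []
    rows: list[dict] = []
    for gi, (p, gname) in enumerate(zip((p_group_a, p_group_b), group_names)):
        egg_ss = group_ss[gi].spawn(p.n_eggs)
        for i in range(p.n_eggs):
            rng = np.random.Generator(np.random.PCG64(egg_ss[i]))
            trace, truth = simulate_trace(
                p,
                rng,
                egg_id=f"{gname}_{i:03d}",
                group=gname,
                mode=mode,
                replicate=f"r{1 + i % 4}",
            )
            traces.append(trace)
            rows.append(truth)
    ts = TraceSet(traces=traces, mode=mode, provenance="simulated")
    return ts, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# canonical scenarios
# ---------------------------------------------------------------------------

_IVF_BASE = dict(
    n_eggs=68,
    latency_mean_s=900.0,
    latency_sd_s=240.0,
    first_dur_mean_s=210.0,
    first_dur_sd_s=60.0,
    sub_dur_mean_s=150.0,
    sub_dur_sd_s=45.0,
    amp_first=0.5,
    amp_sub=0.4,
    iti_mean_s=540.0,
    iti_sd_s=200.0,
    iti_slowdown=1.05,
    cessation_mean_s=4200.0,
    cessation_sd_s=3000.0,
    recording_len_s=7200.0,
)


def scenario(name: str) -> tuple[SimulationParams, SimulationParams]:
    """Canonical paired parameter sets for the four study scenarios.

    * ``sr_null`` — strontium activation, identical groups (n = 75 / 78).
    * ``sr_paper`` — strontium, group B with latency x 1.15 and first
      transient duration x 1.5 ("slightly delayed onset, ~50% longer first
      transient"), everything else equal.
    * ``ivf_null`` — fertilization regime, identical groups (n = 68 / 92).
    * ``ivf_shift`` — fertilization regime positive control, latency x 1.5.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    if name.startswith("sr"):
        a = SimulationParams(n_eggs=75)
        b = replace(a, n_eggs=78)
        if name == "sr_paper":
            b = replace(
                b,
                latency_mean_s=a.latency_mean_s * 1.15,
                first_dur_mean_s=a.first_dur_mean_s * 1.5,
            )
        return a, b
    a = SimulationParams(**_IVF_BASE)
    b = replace(a, n_eggs=92)
    if name == "ivf_shift":
        b = replace(b, latency_mean_s=a.latency_mean_s * 1.5)
    return a, b
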