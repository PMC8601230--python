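"""Baseline estimation, calcium-transient segmentation, and AUC.

The detector operationalizes "calcium transient" as a maximal run of samples
exceeding ``baseline + max(k_sigma * noise_sd, min_amplitude)``.  The event
extends past the run until the trace falls back below
``baseline + offset_fraction * (peak - baseline)`` (a hysteresis-style
offset); events separated by less than ``min_gap_s`` are merged, and events
shorter than ``min_duration_s`` are discarded as noise blips.  An event
still elevated at the end of the recording keeps its partial duration and is
flagged right-truncated.

Baseline comes from pre-stimulus frames when at least eight are available
(median, with 1.4826 * MAD as the noise scale); otherwise from a rolling
10th percentile of the whole trace (5 min window, collapsed by median), with
the noise scale taken from the lower half of the residuals so transients
cannot inflate it.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .trace_io import Trace

__all__ = [
    "BaselineModel",
    "Transient",
    "DetectionConfig",
    "estimate_baseline",
    "detect_transients",
    "auc_above_baseline",
]

#: minimum number of pre-stimulus samples for the pre-stimulus baseline branch
MIN_PRESTIM_SAMPLES = 8
#: window of the rolling-percentile baseline branch, seconds
ROLLING_WINDOW_S = 300.0
#: Gaussian consistency factor: sigma = 1.4826 * MAD
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class DetectionConfig:
    """Knobs of the transient detector (all recorded in outputs).

    ``min_duration_s = None`` means "two sampling intervals of the trace
    being analyzed", the default guard against single-sample noise spikes.
    """

    k_sigma: float = 3.0
    min_amplitude: float = 0.05
    offset_fraction: float = 0.25
    min_gap_s: float = 30.0
    min_duration_s: float | None = None
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if self.k_sigma < 0:
            raise ValueError("k_sigma must be >= 0")
        if not (0.0 < self.offset_fraction < 1.0):
            raise ValueError("offset_fraction must be in (0, 1)")
        if self.min_gap_s < 0:
            raise ValueError("min_gap_s must be >= 0")
        if self.min_duration_s is not None and self.min_duration_s < 0:
            raise ValueError("min_duration_s must be >= 0")

    def resolved_min_duration(self, sampling_interval_s: float) -> float:
        if self.min_duration_s is None:
            return 2.0 * sampling_interval_s
        return self.min_duration_s

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class BaselineModel:
    """Scalar baseline and noise scale for one trace."""

    baseline: float
    noise_sd: float
    method_tag: str

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"baseline must be > 0, got {self.baseline}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class Transient:
    """A detected calcium release event (times in seconds from recording start)."""

    onset_time_s: float
    peak_time_s: float
    offset_time_s: float
    peak_amplitude: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.onset_time_s <= self.peak_time_s <= self.offset_time_s):
            raise ValueError(
                "require onset <= peak <= offset, got "
                f"({self.onset_time_s}, {self.peak_time_s}, {self.offset_time_s})"
            )
        if self.peak_amplitude <= 0:
            raise ValueError(f"peak_amplitude must be > 0, got {self.peak_amplitude}")

    @property
    def duration_s(self) -> float:
        return self.offset_time_s - self.onset_time_s


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def estimate_baseline(trace: Trace, cfg: DetectionConfig | None = None) -> BaselineModel:
    """Estimate the scalar baseline and noise level of one trace.

    Uses the pre-stimulus segment when it holds at least
    ``MIN_PRESTIM_SAMPLES`` samples (median / scaled MAD); otherwise falls
    back to a rolling 10th percentile of the full trace (5 min window,
    collapsed by median), with the noise scale estimated from residuals at
    or below their median — the lower half is noise-only even when
    transients occupy a sizeable fraction of the recording.
    """
    v = trace.values
    if v.size < 2:
        raise ValueError("need at least 2 samples to estimate a baseline")
    dt = trace.sampling_interval_s
    n_pre = int(np.sum(trace.times < trace.stimulus_time_s))
    if n_pre >= MIN_PRESTIM_SAMPLES:
        pre = v[:n_pre]
        return BaselineModel(
            baseline=float(np.median(pre)),
            noise_sd=MAD_TO_SD * _mad(pre),
            method_tag="prestim_median_mad",
        )
    window = max(1, int(round(ROLLING_WINDOW_S / dt)))
    rolling = (
        pd.Series(v).rolling(window, min_periods=1, center=True).quantile(0.1).to_numpy()
    )
    baseline = float(np.median(rolling))
    resid = v - baseline
    dev = resid - np.median(resid)
    lower = dev[dev <= 0]
    noise_sd = MAD_TO_SD * float(np.median(np.abs(lower))) if lower.size else 0.0
    return BaselineModel(
        baseline=baseline, noise_sd=noise_sd, method_tag="rolling_p10_median"
    )


def detect_transients(
    trace: Trace, b: BaselineModel, cfg: DetectionConfig | None = None
) -> list[Transient]:
    """Segment a trace into calcium transients.

    Returns events sorted by onset, non-overlapping, restricted to onsets at
    or after the stimulus time.  A trace with no events returns an empty
    list.
    """
    cfg = cfg or DetectionConfig()
    v = trace.values
    t = trace.times
    n = v.size
    threshold = b.baseline + max(cfg.k_sigma * b.noise_sd, cfg.min_amplitude)
    above = v > threshold
    if not above.any():
        return []
    # maximal runs of samples above threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [n - 1]))

    raw = []  # [onset_idx, peak_idx, offset_idx, truncated]
    for i0, i1 in zip(starts, ends):
        run = v[i0 : i1 + 1]
        peak_idx = i0 + int(np.argmax(run))
        offset_level = b.baseline + cfg.offset_fraction * (v[peak_idx] - b.baseline)
        # scan from the peak: when offset_level exceeds the threshold the
        # crossing lies inside the above-threshold run itself
        below = np.flatnonzero(v[peak_idx + 1 :] < offset_level)
        if below.size:
            offset_idx = peak_idx + 1 + int(below[0])
            truncated = False
        else:
            offset_idx = n - 1
            truncated = True
        raw.append([i0, peak_idx, offset_idx, truncated])

    # merge events whose gap (previous offset to next onset) is < min_gap_s;
    # overlapping events (offset past the next onset) merge by the same rule
    merged = [raw[0]]
    for ev in raw[1:]:
        prev = merged[-1]
        gap = t[ev[0]] - t[prev[2]]
        if gap < cfg.min_gap_s:
            prev[2] = max(prev[2], ev[2])
            if v[ev[1]] > v[prev[1]]:
                prev[1] = ev[1]
            prev[3] = prev[3] or ev[3]
        else:
            merged.append(ev)

    min_dur = cfg.resolved_min_duration(trace.sampling_interval_s)
    out: list[Transient] = []
    for i0, pk, i2, trunc in merged:
        if t[i2] - t[i0] < min_dur:
            continue
        if t[i0] < trace.stimulus_time_s:
            continue
        out.append(
            Transient(
                onset_time_s=float(t[i0]),
                peak_time_s=float(t[pk]),
                offset_time_s=float(t[i2]),
                peak_amplitude=float(v[pk] - b.baseline),
                truncated=bool(trunc),
            )
        )
    return out


def auc_above_baseline(
    trace: Trace,
    b: BaselineModel,
    window_start_s: float,
    window_end_s: float,
    clip_negative: bool = True,
) -> float:
    """Trapezoidal area of the trace above baseline over a window.

    Window endpoints are snapped outward to sample times.  Negative
    deviations are clipped to zero by default ("signal" means elevation
    above baseline); pass ``clip_negative=False`` for the raw integral.
    Units: ratio * seconds.
    """
    if window_start_s >= window_end_s:
        raise ValueError(
            f"window_start_s must be < window_end_s, got [{window_start_s}, {window_end_s})"
        )
    if window_start_s < 0 or window_end_s > trace.duration_s:
        raise ValueError(
            f"window [{window_start_s}, {window_end_s}] outside recording "
            f"[0, {trace.duration_s}]"
        )
    dt = trace.sampling_interval_s
    i0 = int(np.floor(window_start_s / dt + 1e-12))
    i1 = int(np.ceil(window_end_s / dt - 1e-12))
    i1 = min(i1, trace.n_samples - 1)
    dev = trace.values[i0 : i1 + 1] - b.baseline
    if clip_negative:
        dev = np.maximum(dev, 0.0)
    return float(np.trapezoid(dev, dx=dt))


def transients_to_frame(egg_id: str, transients: Sequence[Transient]) -> pd.DataFrame:
    """Tabulate detected transients, one row per event."""
    return pd.DataFrame(
        {
            "egg_id": egg_id,
            "onset_s": [tr.onset_time_s for tr in transients],
            "peak_s": [tr.peak_time_s for tr in transients],
            "offset_s": [tr.offset_time_s for tr in transients],
            "amplitude": [tr.peak_amplitude for tr in transients],
            "duration_s": [tr.duration_s for tr in transients],
            "truncated": [tr.truncated for tr in transients],
        }
    )
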