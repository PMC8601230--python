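"""Per-egg oscillation metrics and group persistence curves.

From each egg's detected transients this module computes the standard
activation panel: time from stimulus to the first transient, duration of the
first transient, counts of oscillations within 60 and 120 min of the first
onset, mean frequency per 10 min over the first hour, area under the curve
over the first hour, and the cessation time used for persistence analysis.

Conventions (all configurable through :class:`FeatureConfig`):

* the first transient counts as oscillation #1;
* ``freq_per_10min`` is ``n_osc_60 / 6`` by construction (mean count per
  10 min bin over the first 60 min of oscillations);
* the AUC window is anchored at the first transient's onset (the
  alternative, anchoring at the stimulus, is one switch away) and clamped
  to the end of the recording;
* "oscillating at time t" means "has a transient onset after t", so the
  cessation time is the last onset relative to the first;
* an egg whose last onset falls within ``censor_window_min`` of the
  analysis horizon — or whose last transient is right-truncated — is
  censored rather than scored as ceased, one typical inter-transient
  interval of lookahead against edge-of-recording bias.

Eggs without any detected transient are non-responders: their oscillation
fields are undefined (None) and they are excluded from per-metric tests but
still counted in responder tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np

from .detection import BaselineModel, Transient, auc_above_baseline
from .trace_io import Trace

__all__ = [
    "FeatureConfig",
    "EggFeatures",
    "PersistenceCurve",
    "extract_features",
    "persistence_curve",
    "default_horizon_min",
    "FEATURE_METRICS",
]

#: the five scalar metrics compared between groups
FEATURE_METRICS = (
    "time_to_first_s",
    "first_duration_s",
    "freq_per_10min",
    "auc_60",
    "n_osc_120",
)


def default_horizon_min(mode: str) -> float:
    """Analysis horizon by activation mode: 110 min (strontium) / 120 min (IVF)."""
    return 110.0 if mode == "strontium" else 120.0


@dataclass(frozen=True)
class FeatureConfig:
    """Options of the feature stage."""

    auc_anchor: str = "first_transient"  # or "stimulus"
    auc_window_min: float = 60.0
    censor_window_min: float = 10.0

    def __post_init__(self) -> None:
        if self.auc_anchor not in ("first_transient", "stimulus"):
            raise ValueError(
                f"auc_anchor must be 'first_transient' or 'stimulus', got {self.auc_anchor!r}"
            )
        if self.auc_window_min <= 0 or self.censor_window_min < 0:
            raise ValueError("auc_window_min must be > 0 and censor_window_min >= 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class EggFeatures:
    """The per-egg metric panel plus cessation/censoring info.

    Oscillation fields are ``None`` for non-responders.  ``cessation_s`` is
    the last detected onset relative to the first.
    """

    egg_id: str
    group: str
    mode: str
    responder: bool
    time_to_first_s: float | None = None
    first_duration_s: float | None = None
    n_osc_60: int | None = None
    n_osc_120: int | None = None
    freq_per_10min: float | None = None
    auc_60: float | None = None
    cessation_s: float | None = None
    censored: bool | None = None

    def __post_init__(self) -> None:
        if self.responder:
            if self.n_osc_60 is None or self.n_osc_120 is None:
                raise ValueError(f"egg {self.egg_id!r}: responder with missing counts")
            if not (self.n_osc_120 >= self.n_osc_60 >= 1):
                raise ValueError(
                    f"egg {self.egg_id!r}: require n_osc_120 >= n_osc_60 >= 1, "
                    f"got ({self.n_osc_120}, {self.n_osc_60})"
                )
        else:
            osc_fields = (
                self.time_to_first_s,
                self.first_duration_s,
                self.n_osc_60,
                self.n_osc_120,
                self.freq_per_10min,
                self.auc_60,
                self.cessation_s,
                self.censored,
            )
            if any(f is not None for f in osc_fields):
                raise ValueError(
                    f"egg {self.egg_id!r}: non-responder must leave oscillation "
                    "fields undefined"
                )


@dataclass(frozen=True)
class PersistenceCurve:
    """Fraction of responder eggs still oscillating versus time.

    ``times_min`` are minutes from each egg's first onset; the curve starts
    at 1.0 and is non-increasing.
    """

    group: str
    times_min: np.ndarray
    fraction_oscillating: np.ndarray
    n_eggs: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fraction_oscillating, dtype=float)
        if f.size and (f[0] != 1.0 or np.any(np.diff(f) > 1e-12)):
            raise ValueError("persistence curve must start at 1.0 and be non-increasing")


def extract_features(
    trace: Trace,
    transients: Sequence[Transient],
    b: BaselineModel,
    horizon_min: float | None = None,
    cfg: FeatureConfig | None = None,
) -> EggFeatures:
    """Compute the metric panel for one egg from its detected transients."""
    cfg = cfg or FeatureConfig()
    if horizon_min is None:
        horizon_min = default_horizon_min(trace.mode)
    if not transients:
        return EggFeatures(
            egg_id=trace.egg_id, group=trace.group, mode=trace.mode, responder=False
        )
    onsets = np.array([tr.onset_time_s for tr in transients])
    first = transients[0]
    last = transients[-1]
    n60 = int(np.sum(onsets < first.onset_time_s + 60.0 * 60.0))
    n120 = int(np.sum(onsets < first.onset_time_s + 120.0 * 60.0))

    anchor = (
        first.onset_time_s if cfg.auc_anchor == "first_transient" else trace.stimulus_time_s
    )
    w0 = min(anchor, trace.duration_s - trace.sampling_interval_s)
    w1 = min(anchor + cfg.auc_window_min * 60.0, trace.duration_s)
    auc = auc_above_baseline(trace, b, w0, w1)

    cessation = last.onset_time_s - first.onset_time_s
    censored = bool(
        cessation >= (horizon_min - cfg.censor_window_min) * 60.0 or last.truncated
    )
    return EggFeatures(
        egg_id=trace.egg_id,
        group=trace.group,
        mode=trace.mode,
        responder=True,
        time_to_first_s=first.onset_time_s - trace.stimulus_time_s,
        first_duration_s=first.duration_s,
        n_osc_60=n60,
        n_osc_120=n120,
        freq_per_10min=n60 / 6.0,
        auc_60=auc,
        cessation_s=cessation,
        censored=censored,
    )


def persistence_curve(
    features: Iterable[EggFeatures],
    grid_step_min: float = 5.0,
    horizon_min: float = 110.0,
) -> PersistenceCurve:
    """Fraction of one group's responder eggs still oscillating on a time grid.

    An egg counts as oscillating at grid time ``g`` (minutes from its first
    onset) if its cessation time exceeds ``g``; censored eggs count as
    oscillating through the horizon.
    """
    feats = [f for f in features if f.responder]
    if not feats:
        raise ValueError("persistence_curve requires at least one responder egg")
    groups = {f.group for f in feats}
    if len(groups) > 1:
        raise ValueError(f"persistence_curve expects one group, got {sorted(groups)}")
    grid = np.arange(0.0, horizon_min + grid_step_min / 2.0, grid_step_min)
    cess_min = np.array([f.cessation_s / 60.0 for f in feats])
    censored = np.array([f.censored for f in feats], dtype=bool)
    # every responder is oscillating at its own first onset, so the curve is
    # pinned to 1.0 at t = 0 even for eggs with a single transient (cess = 0)
    frac = np.array(
        [1.0 if g == 0.0 else float(np.mean(censored | (cess_min > g))) for g in grid]
    )
    return PersistenceCurve(
        group=groups.pop(),
        times_min=grid,
        fraction_oscillating=frac,
        n_eggs=len(feats),
    )


def features_to_records(features: Iterable[EggFeatures]) -> list[dict]:
    """Flatten features into plain dict records for tabular output."""
    out = []
    for f in features:
        out.append(
            {
                "egg_id": f.egg_id,
                "group": f.group,
                "mode": f.mode,
                "responder": f.responder,
                "time_to_first_s": f.time_to_first_s,
                "first_duration_s": f.first_duration_s,
                "n_osc_60": f.n_osc_60,
                "n_osc_120": f.n_osc_120,
                "freq_per_10min": f.freq_per_10min,
                "auc_60": f.auc_60,
                "cessation_s": f.cessation_s,
                "censored": f.censored,
            }
        )
    return out
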