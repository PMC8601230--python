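"""Reading, writing and validation of calcium trace datasets.

A *trace* is one egg's ratiometric (F340/F380) calcium time series sampled at
a fixed interval.  Datasets travel as plain delimited text in two dialects:

* **long** — tidy table with columns ``egg_id, time_s, ratio`` plus the
  per-egg metadata columns ``group, mode, replicate, stimulus_time_s``
  (self-contained; a metadata sidecar is also accepted instead).
* **wide** — a ``time_s`` column plus one ratio column per egg; per-egg
  metadata live in a YAML sidecar next to the table
  (``<stem>.meta.yaml``).

Values are written with full ``repr`` precision so a round trip reproduces
every sample bit-exactly.  Missing samples are not permitted: acquisition is
gap-free, and a non-uniform time axis is a hard error, never interpolated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trace",
    "TraceSet",
    "TraceValidationError",
    "TraceFormatError",
    "read_traceset",
    "write_traceset",
    "default_meta_path",
]

#: relative tolerance used to decide whether a time axis is uniformly sampled
UNIFORM_RTOL = 1e-6

_META_COLUMNS = ("group", "mode", "replicate", "stimulus_time_s")


class TraceValidationError(ValueError):
    """A trace or trace set violates a structural invariant."""


class TraceFormatError(ValueError):
    """A file does not conform to the documented long/wide grammar."""


@dataclass(frozen=True)
class Trace:
    """One egg's ratio time series with sampling metadata.

    Parameters
    ----------
    egg_id
        Unique identifier within a :class:`TraceSet`.
    group
        Experimental group label (e.g. ``NC`` / ``SOV``); arbitrary strings
        are accepted.
    mode
        Activation mode, ``strontium`` or ``ivf``.
    replicate
        Replicate identifier (free text).
    sampling_interval_s
        Seconds between consecutive samples (> 0).
    stimulus_time_s
        Time of stimulus (strontium addition / insemination) relative to
        recording start, in seconds.  Carried explicitly because recordings
        may include pre-stimulus frames.
    values
        Ratio samples (dimensionless F340/F380), all finite and > 0.
    """

    egg_id: str
    group: str
    mode: str
    replicate: str
    sampling_interval_s: float
    stimulus_time_s: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        v = self.values
        if self.sampling_interval_s <= 0:
            raise TraceValidationError(
                f"trace {self.egg_id!r}: sampling_interval_s must be > 0, "
                f"got {self.sampling_interval_s}"
            )
        if v.ndim != 1 or v.size < 2:
            raise TraceValidationError(
                f"trace {self.egg_id!r}: needs >= 2 samples, got shape {v.shape}"
            )
        bad = ~np.isfinite(v) | (v <= 0)
        if bad.any():
            idx = np.flatnonzero(bad)[:5]
            raise TraceValidationError(
                f"trace {self.egg_id!r}: non-finite or non-positive ratio at "
                f"sample index(es) {idx.tolist()}"
            )
        if self.stimulus_time_s < 0:
            raise TraceValidationError(
                f"trace {self.egg_id!r}: stimulus_time_s must be >= 0"
            )
        if self.stimulus_time_s >= self.duration_s:
            raise TraceValidationError(
                f"trace {self.egg_id!r}: stimulus_time_s ({self.stimulus_time_s}) "
                f"not before end of recording ({self.duration_s} s)"
            )

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        """Recording duration, ``(n_samples - 1) * sampling_interval_s``."""
        return (self.n_samples - 1) * self.sampling_interval_s

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.n_samples) * self.sampling_interval_s


@dataclass
class TraceSet:
    """A collection of traces acquired in one imaging dish.

    All traces share the activation mode; egg ids are unique.
    """

    traces: list[Trace] = field(default_factory=list)
    mode: str = "strontium"
    provenance: str = "loaded"

    def __post_init__(self) -> None:
        ids = [t.egg_id for t in self.traces]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise TraceValidationError(f"duplicate egg_id(s) in set: {sorted(dup)}")
        for t in self.traces:
            if t.mode != self.mode:
                raise TraceValidationError(
                    f"trace {t.egg_id!r} has mode {t.mode!r}, set mode is {self.mode!r}"
                )

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, egg_id: str) -> Trace:
        for t in self.traces:
            if t.egg_id == egg_id:
                return t
        raise KeyError(egg_id)

    @property
    def egg_ids(self) -> list[str]:
        return [t.egg_id for t in self.traces]


# ---------------------------------------------------------------------------
# time-axis checks
# ---------------------------------------------------------------------------

def _infer_interval(times: np.ndarray, label: str) -> float:
    """Infer the sampling interval and verify the axis is uniform.

    Raises :class:`TraceFormatError` naming the offending rows on failure.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise TraceFormatError(f"{label}: need >= 2 time points, got {t.size}")
    diffs = np.diff(t)
    dt = float(diffs[0])
    if dt <= 0:
        raise TraceFormatError(f"{label}: time axis not strictly increasing")
    bad = np.flatnonzero(np.abs(diffs - dt) > UNIFORM_RTOL * dt)
    if bad.size:
        rows = (bad + 1)[:5].tolist()
        raise TraceFormatError(
            f"{label}: non-uniform sampling at time-axis row(s) {rows} "
            f"(expected interval {dt} s)"
        )
    return dt


# ---------------------------------------------------------------------------
# metadata sidecar
# ---------------------------------------------------------------------------

def default_meta_path(path: str | os.PathLike) -> Path:
    """Sidecar path next to a table: ``dir/name.tsv`` -> ``dir/name.meta.yaml``."""
    p = Path(path)
    return p.parent / (p.stem + ".meta.yaml")


def _write_meta(ts: TraceSet, meta_path: Path) -> None:
    eggs = {
        t.egg_id: {
            "group": t.group,
            "replicate": t.replicate,
            "stimulus_time_s": float(t.stimulus_time_s),
        }
        for t in ts.traces
    }
    doc = {"mode": ts.mode, "provenance": ts.provenance, "eggs": eggs}
    with open(meta_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def _read_meta(meta_path: Path) -> dict:
    if not meta_path.exists():
        raise TraceFormatError(f"metadata sidecar not found: {meta_path}")
    with open(meta_path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "eggs" not in doc:
        raise TraceFormatError(f"{meta_path}: malformed metadata sidecar")
    return doc


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_traceset(
    path: str | os.PathLike,
    format: str = "long",
    meta_path: str | os.PathLike | None = None,
) -> TraceSet:
    """Read a trace set from a delimited text file.

    Parameters
    ----------
    path
        TSV file in the chosen dialect.
    format
        ``"long"`` (egg_id, time_s, ratio [+ metadata columns]) or
        ``"wide"`` (time_s plus one column per egg; sidecar metadata).
    meta_path
        Metadata sidecar; defaults to ``<stem>.meta.yaml`` next to *path*.
        Required for wide files and for long files without metadata columns.

    Raises
    ------
    TraceFormatError
        Malformed file: missing columns, non-uniform sampling, duplicates.
    TraceValidationError
        Structurally valid file whose values violate trace invariants.
    """
    p = Path(path)
    if not p.exists():
        raise TraceFormatError(f"no such file: {p}")
    if format not in ("long", "wide"):
        raise TraceFormatError(f"unknown format {format!r}; use 'long' or 'wide'")
    mp = Path(meta_path) if meta_path is not None else default_meta_path(p)
    # round_trip parsing: the default fast parser can be off by 1 ulp,
    # breaking the bit-exact round-trip guarantee
    df = pd.read_csv(p, sep="\t", float_precision="round_trip")
    if format == "long":
        return _read_long(df, p, mp)
    return _read_wide(df, p, mp)


def _trace_from_meta(egg_id, values, dt, mode, egg_meta, label) -> Trace:
    try:
        return Trace(
            egg_id=str(egg_id),
            group=str(egg_meta["group"]),
            mode=mode,
            replicate=str(egg_meta.get("replicate", "r1")),
            sampling_interval_s=dt,
            stimulus_time_s=float(egg_meta.get("stimulus_time_s", 0.0)),
            values=np.asarray(values, dtype=float),
        )
    except KeyError as exc:
        raise TraceFormatError(f"{label}: missing metadata field {exc} for egg {egg_id!r}")


def _read_long(df: pd.DataFrame, p: Path, mp: Path) -> TraceSet:
    required = {"egg_id", "time_s", "ratio"}
    missing = required - set(df.columns)
    if missing:
        raise TraceFormatError(f"{p}: long format missing column(s) {sorted(missing)}")
    inline_meta = all(c in df.columns for c in _META_COLUMNS)
    if inline_meta:
        doc = None
    else:
        doc = _read_meta(mp)
    mode = None
    traces: list[Trace] = []
    seen: set[str] = set()
    if df.empty:
        return TraceSet(traces=[], mode="strontium", provenance="loaded")
    for egg_id, sub in df.groupby("egg_id", sort=False):
        egg_id = str(egg_id)
        if egg_id in seen:  # groupby collapses, but guard anyway
            raise TraceFormatError(f"{p}: duplicate egg_id {egg_id!r}")
        seen.add(egg_id)
        sub = sub.reset_index(drop=True)
        if sub["time_s"].duplicated().any():
            raise TraceFormatError(f"{p}: duplicate time points for egg {egg_id!r}")
        dt = _infer_interval(sub["time_s"].to_numpy(), f"{p} egg {egg_id!r}")
        if inline_meta:
            meta_vals = {c: sub[c].iloc[0] for c in _META_COLUMNS}
            for c in _META_COLUMNS:
                if sub[c].nunique() != 1:
                    raise TraceFormatError(
                        f"{p}: inconsistent metadata column {c!r} for egg {egg_id!r}"
                    )
            egg_meta = {
                "group": meta_vals["group"],
                "replicate": meta_vals["replicate"],
                "stimulus_time_s": float(meta_vals["stimulus_time_s"]),
            }
            egg_mode = str(meta_vals["mode"])
        else:
            eggs = doc["eggs"]
            if egg_id not in eggs:
                raise TraceFormatError(f"{mp}: no metadata for egg {egg_id!r}")
            egg_meta = eggs[egg_id]
            egg_mode = str(doc.get("mode", "strontium"))
        if mode is None:
            mode = egg_mode
        elif egg_mode != mode:
            raise TraceFormatError(f"{p}: mixed activation modes in one set")
        try:
            traces.append(
                _trace_from_meta(egg_id, sub["ratio"].to_numpy(), dt, egg_mode, egg_meta, str(p))
            )
        except TraceValidationError as exc:
            raise TraceValidationError(f"{p}: {exc}") from exc
    provenance = "loaded" if doc is None else str(doc.get("provenance", "loaded"))
    return TraceSet(traces=traces, mode=mode or "strontium", provenance=provenance)


def _read_wide(df: pd.DataFrame, p: Path, mp: Path) -> TraceSet:
    if "time_s" not in df.columns:
        raise TraceFormatError(f"{p}: wide format requires a 'time_s' column")
    egg_cols = [c for c in df.columns if c != "time_s"]
    if len(set(egg_cols)) != len(egg_cols):
        raise TraceFormatError(f"{p}: duplicate egg_id column(s)")
    doc = _read_meta(mp)
    mode = str(doc.get("mode", "strontium"))
    traces: list[Trace] = []
    if df.empty and not egg_cols:
        return TraceSet(traces=[], mode=mode, provenance=str(doc.get("provenance", "loaded")))
    dt = _infer_interval(df["time_s"].to_numpy(), str(p))
    for egg_id in egg_cols:
        if egg_id not in doc["eggs"]:
            raise TraceFormatError(f"{mp}: no metadata for egg {egg_id!r}")
        try:
            traces.append(
                _trace_from_meta(
                    egg_id, df[egg_id].to_numpy(), dt, mode, doc["eggs"][egg_id], str(p)
                )
            )
        except TraceValidationError as exc:
            raise TraceValidationError(f"{p}: {exc}") from exc
    return TraceSet(traces=traces, mode=mode, provenance=str(doc.get("provenance", "loaded")))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_traceset(
    ts: TraceSet,
    path: str | os.PathLike,
    format: str = "long",
    meta_path: str | os.PathLike | None = None,
) -> Path:
    """Write a trace set; the inverse of :func:`read_traceset`.

    Long files are self-contained (metadata columns inline); wide files get a
    YAML sidecar.  A sidecar is written in both cases so either dialect can
    be re-read without the inline columns.
    """
    p = Path(path)
    if format not in ("long", "wide"):
        raise TraceFormatError(f"unknown format {format!r}; use 'long' or 'wide'")
    mp = Path(meta_path) if meta_path is not None else default_meta_path(p)
    if format == "long":
        frames = []
        for t in ts.traces:
            frames.append(
                pd.DataFrame(
                    {
                        "egg_id": t.egg_id,
                        "time_s": t.times,
                        "ratio": t.values,
                        "group": t.group,
                        "mode": t.mode,
                        "replicate": t.replicate,
                        "stimulus_time_s": t.stimulus_time_s,
                    }
                )
            )
        cols = ["egg_id", "time_s", "ratio", *_META_COLUMNS]
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)
        df.to_csv(p, sep="\t", index=False)
    else:
        if ts.traces:
            lengths = {t.n_samples for t in ts.traces}
            intervals = {t.sampling_interval_s for t in ts.traces}
            if len(lengths) > 1 or len(intervals) > 1:
                raise TraceFormatError(
                    "wide format requires equal length and sampling interval "
                    f"across traces (lengths {sorted(lengths)})"
                )
            ref = ts.traces[0]
            data = {"time_s": ref.times}
            for t in ts.traces:
                data[t.egg_id] = t.values
            pd.DataFrame(data).to_csv(p, sep="\t", index=False)
        else:
            pd.DataFrame(columns=["time_s"]).to_csv(p, sep="\t", index=False)
    _write_meta(ts, mp)
    return p
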