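"""Two-group nonparametric inference: Mann-Whitney U and Mantel-Cox log-rank.

Scalar metrics are compared with a two-sided Mann-Whitney U test — exact by
full enumeration of the permutation distribution when the combined sample is
small and tie-free, otherwise the tie-corrected normal approximation with
continuity correction.  Oscillation persistence is compared with the
log-rank (Mantel-Cox) test on cessation times with right censoring.

The reported U is ``min(U_x, U_y)``; p-values are two-sided throughout.  No
multiple-testing correction is applied across the panel by default (each
metric is reported per-panel); Holm correction is available as an option.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats as sps

from .features import FEATURE_METRICS, EggFeatures

__all__ = [
    "MannWhitneyResult",
    "LogrankResult",
    "GroupComparison",
    "SurvivalSample",
    "mann_whitney_u",
    "logrank_test",
    "compare_groups",
    "holm_adjust",
]

#: exact enumeration is used up to this combined sample size (tie-free data)
EXACT_MAX_N = 20


class MannWhitneyResult(NamedTuple):
    u: float
    p_value: float
    method: str  # "mw_exact" | "mw_asymptotic"


class LogrankResult(NamedTuple):
    chi_square: float
    p_value: float


@dataclass(frozen=True)
class SurvivalSample:
    """Per-egg event times with censoring flags for two groups.

    ``time`` in minutes; ``event`` 1 = oscillations ceased, 0 = censored.
    """

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=int)
        g = np.asarray(self.group)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        object.__setattr__(self, "group", g)
        if not (t.size == e.size == g.size):
            raise ValueError("time, event and group must have equal length")
        if np.any(t < 0):
            raise ValueError("event times must be >= 0")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")


@dataclass(frozen=True)
class GroupComparison:
    """One metric's two-group test result."""

    metric: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    test: str  # "mw_exact" | "mw_asymptotic" | "logrank"
    alpha: float = 0.05
    untestable: bool = False
    config_hash: str = ""

    @property
    def significant(self) -> bool:
        return (not self.untestable) and self.p_value < self.alpha


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``method='auto'`` uses the exact permutation distribution when
    ``n_x + n_y <= 20`` and the pooled data are tie-free, and the
    tie-corrected normal approximation with continuity correction otherwise.
    Requesting ``'exact'`` on tied data falls back to the asymptotic branch
    (the tied exact distribution is not implemented).  Returns
    ``U = min(U_x, U_y)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=n_x * n_y / 2.0, p_value=1.0, method="mw_asymptotic")
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (
        method == "exact" or (method == "auto" and n_x + n_y <= EXACT_MAX_N)
    ) and not has_ties
    if use_exact:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        tag = "mw_exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        tag = "mw_asymptotic"
    u_x = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(p):  # zero-variance degenerate case
        p = 1.0
    return MannWhitneyResult(u=min(u_x, n_x * n_y - u_x), p_value=min(p, 1.0), method=tag)


def logrank_test(s: SurvivalSample) -> LogrankResult:
    """Two-group log-rank (Mantel-Cox) test; chi-square with 1 df.

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the risk sets; the squared
    standardized sum is referred to chi-square(1).
    """
    labels = np.unique(s.group)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.tolist()}")
    if int(s.event.sum()) == 0:
        raise ValueError("log-rank test requires at least one event")
    in_a = s.group == labels[0]
    r = _lifelines_logrank(
        s.time[in_a],
        s.time[~in_a],
        event_observed_A=s.event[in_a],
        event_observed_B=s.event[~in_a],
    )
    chi2 = float(r.test_statistic)
    if chi2 < 1e-15:
        return LogrankResult(chi_square=0.0, p_value=1.0)
    return LogrankResult(chi_square=chi2, p_value=float(r.p_value))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, family-wise control)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def _metric_values(features: Iterable[EggFeatures], metric: str) -> np.ndarray:
    vals = [getattr(f, metric) for f in features if f.responder]
    return np.array([v for v in vals if v is not None], dtype=float)


def config_hash(*configs: dict) -> str:
    """Stable short hash over the configuration dicts of a run."""
    payload = json.dumps(configs, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def compare_groups(
    features_a: Sequence[EggFeatures],
    features_b: Sequence[EggFeatures],
    alpha: float = 0.05,
    method: str = "auto",
    holm: bool = False,
    provenance_hash: str = "",
) -> list[GroupComparison]:
    """The six-panel comparison: five Mann-Whitney metrics plus persistence.

    A metric with fewer than three responders in either group is flagged
    ``untestable`` (p = NaN) rather than dropped.  The log-rank row compares
    cessation times in minutes with censored eggs contributing at-risk time.
    """
    rows: list[GroupComparison] = []
    resp_a = [f for f in features_a if f.responder]
    resp_b = [f for f in features_b if f.responder]
    p_raw: list[float] = []
    for metric in FEATURE_METRICS:
        va = _metric_values(resp_a, metric)
        vb = _metric_values(resp_b, metric)
        if va.size < 3 or vb.size < 3:
            rows.append(
                GroupComparison(
                    metric=metric,
                    n_a=int(va.size),
                    n_b=int(vb.size),
                    median_a=float(np.median(va)) if va.size else math.nan,
                    median_b=float(np.median(vb)) if vb.size else math.nan,
                    statistic=math.nan,
                    p_value=math.nan,
                    test="mw_untestable",
                    alpha=alpha,
                    untestable=True,
                    config_hash=provenance_hash,
                )
            )
            p_raw.append(math.nan)
            continue
        res = mann_whitney_u(va, vb, method=method)
        rows.append(
            GroupComparison(
                metric=metric,
                n_a=int(va.size),
                n_b=int(vb.size),
                median_a=float(np.median(va)),
                median_b=float(np.median(vb)),
                statistic=res.u,
                p_value=res.p_value,
                test=res.method,
                alpha=alpha,
                config_hash=provenance_hash,
            )
        )
        p_raw.append(res.p_value)

    # persistence: cessation in minutes, event = not censored
    times = np.array([f.cessation_s / 60.0 for f in resp_a + resp_b])
    events = np.array([0 if f.censored else 1 for f in resp_a + resp_b])
    groups = np.array(["A"] * len(resp_a) + ["B"] * len(resp_b))
    if len(resp_a) < 3 or len(resp_b) < 3 or events.sum() == 0:
        rows.append(
            GroupComparison(
                metric="persistence",
                n_a=len(resp_a),
                n_b=len(resp_b),
                median_a=math.nan,
                median_b=math.nan,
                statistic=math.nan,
                p_value=math.nan,
                test="logrank_untestable",
                alpha=alpha,
                untestable=True,
                config_hash=provenance_hash,
            )
        )
        p_raw.append(math.nan)
    else:
        lr = logrank_test(SurvivalSample(time=times, event=events, group=groups))
        rows.append(
            GroupComparison(
                metric="persistence",
                n_a=len(resp_a),
                n_b=len(resp_b),
                median_a=float(np.median(times[groups == "A"])),
                median_b=float(np.median(times[groups == "B"])),
                statistic=lr.chi_square,
                p_value=lr.p_value,
                test="logrank",
                alpha=alpha,
                config_hash=provenance_hash,
            )
        )
        p_raw.append(lr.p_value)

    if holm:
        testable = [i for i, p in enumerate(p_raw) if not math.isnan(p)]
        adj = holm_adjust([p_raw[i] for i in testable])
        for i, p_adj in zip(testable, adj):
            r = rows[i]
            rows[i] = GroupComparison(
                metric=r.metric,
                n_a=r.n_a,
                n_b=r.n_b,
                median_a=r.median_a,
                median_b=r.median_b,
                statistic=r.statistic,
                p_value=p_adj,
                test=r.test + "_holm",
                alpha=r.alpha,
                untestable=r.untestable,
                config_hash=r.config_hash,
            )
    return rows
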