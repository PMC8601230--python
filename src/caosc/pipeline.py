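"""End-to-end run: simulate or load traces -> detect -> features -> compare.

A run is fully described by a :class:`RunConfig` (loadable from YAML).  All
outputs are plain TSV/JSON and byte-identical across reruns of an identical
(config, seed) pair.  Failures carry the stage name and, where applicable,
the egg id; partial outputs are removed so a failed run leaves no
half-written tables behind.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from .detection import (
    DetectionConfig,
    detect_transients,
    estimate_baseline,
    transients_to_frame,
)
from .features import (
    EggFeatures,
    FeatureConfig,
    default_horizon_min,
    extract_features,
    features_to_records,
    persistence_curve,
)
from .stats import GroupComparison, compare_groups, config_hash
from .synthetic import scenario, simulate_experiment
from .trace_io import TraceSet, read_traceset, write_traceset

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline", "analyze_traceset"]

log = logging.getLogger("caosc")


class PipelineError(RuntimeError):
    """A stage failure with stage and egg context attached."""

    def __init__(self, stage: str, message: str, egg_id: str | None = None):
        self.stage = stage
        self.egg_id = egg_id
        ctx = f"[{stage}]" + (f" egg {egg_id!r}" if egg_id else "")
        super().__init__(f"{ctx}: {message}")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    mode: str = "strontium"
    scenario: str | None = None
    seed: int | None = None
    traces_path: str | None = None
    traces_format: str = "long"
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    horizon_min: float | None = None  # None -> by mode (110 strontium / 120 ivf)
    grid_step_min: float = 5.0
    alpha: float = 0.05
    mw_method: str = "auto"
    holm: bool = False
    n_a: int | None = None  # scenario group-size overrides
    n_b: int | None = None
    out_dir: str | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.scenario is None and self.traces_path is None:
            raise ValueError("config needs either a scenario or a traces_path")
        if self.scenario is not None and self.seed is None:
            raise ValueError("a seed is required when the input source is a scenario")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "detection" in doc and isinstance(doc["detection"], dict):
            doc["detection"] = DetectionConfig(**doc["detection"])
        if "features" in doc and isinstance(doc["features"], dict):
            doc["features"] = FeatureConfig(**doc["features"])
        return cls(**doc)

    def to_dict(self) -> dict:
        """Config echo for the run report; output location is not analysis config."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return d


@dataclass
class RunReport:
    """In-memory result of one pipeline run."""

    config: dict
    config_hash: str
    version: str
    features: list[EggFeatures]
    comparisons: list[GroupComparison]
    persistence: dict  # group -> PersistenceCurve
    decisions: list[str]
    truth: pd.DataFrame | None = None
    traceset: TraceSet | None = None
    transients: pd.DataFrame | None = None

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [c.metric for c in self.comparisons],
                "n_a": [c.n_a for c in self.comparisons],
                "n_b": [c.n_b for c in self.comparisons],
                "median_a": [c.median_a for c in self.comparisons],
                "median_b": [c.median_b for c in self.comparisons],
                "statistic": [c.statistic for c in self.comparisons],
                "test": [c.test for c in self.comparisons],
                "p_value": [c.p_value for c in self.comparisons],
                "significant_at_alpha": [c.significant for c in self.comparisons],
            }
        )


def _obtain_traceset(cfg: RunConfig):
    if cfg.scenario is not None:
        try:
            p_a, p_b = scenario(cfg.scenario)
        except ValueError as exc:
            raise PipelineError("simulate", str(exc))
        if cfg.n_a is not None:
            p_a = dataclasses.replace(p_a, n_eggs=cfg.n_a)
        if cfg.n_b is not None:
            p_b = dataclasses.replace(p_b, n_eggs=cfg.n_b)
        mode = "ivf" if cfg.scenario.startswith("ivf") else "strontium"
        ts, truth = simulate_experiment(p_a, p_b, seed=cfg.seed, mode=mode)
        return ts, truth
    try:
        ts = read_traceset(cfg.traces_path, format=cfg.traces_format)
    except Exception as exc:
        raise PipelineError("load", str(exc))
    return ts, None


def analyze_traceset(
    ts: TraceSet,
    detection: DetectionConfig | None = None,
    features_cfg: FeatureConfig | None = None,
    horizon_min: float | None = None,
):
    """Detection + feature extraction for every trace of a set.

    Returns (features, transients table, per-egg decision log).
    """
    detection = detection or DetectionConfig()
    features_cfg = features_cfg or FeatureConfig()
    feats: list[EggFeatures] = []
    tframes = []
    decisions: list[str] = []
    for trace in ts:
        try:
            b = estimate_baseline(trace, detection)
            trs = detect_transients(trace, b, detection)
            f = extract_features(trace, trs, b, horizon_min=horizon_min, cfg=features_cfg)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("detect/features", str(exc), egg_id=trace.egg_id)
        feats.append(f)
        tframes.append(transients_to_frame(trace.egg_id, trs))
        decisions.append(f"egg {trace.egg_id}: baseline={b.method_tag}")
        if not f.responder:
            decisions.append(f"egg {trace.egg_id}: non-responder (no transients)")
            log.warning("egg %s: non-responder", trace.egg_id)
        elif trs and trs[-1].truncated:
            decisions.append(f"egg {trace.egg_id}: last transient right-truncated")
    transients = (
        pd.concat(tframes, ignore_index=True)
        if tframes
        else pd.DataFrame(
            columns=["egg_id", "onset_s", "peak_s", "offset_s", "amplitude", "duration_s", "truncated"]
        )
    )
    return feats, transients, decisions


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute simulate/load -> detect -> features -> compare and write outputs."""
    written: list[Path] = []
    try:
        ts, truth = _obtain_traceset(cfg)
        mode = ts.mode
        horizon = cfg.horizon_min if cfg.horizon_min is not None else default_horizon_min(mode)
        feats, transients, decisions = analyze_traceset(
            ts, cfg.detection, cfg.features, horizon_min=horizon
        )

        groups = sorted({f.group for f in feats})
        if len(groups) != 2:
            raise PipelineError("compare", f"need exactly two groups, got {groups}")
        fa = [f for f in feats if f.group == groups[0]]
        fb = [f for f in feats if f.group == groups[1]]
        chash = config_hash(cfg.detection.to_dict(), cfg.features.to_dict(),
                            {"alpha": cfg.alpha, "mw_method": cfg.mw_method, "holm": cfg.holm})
        try:
            comparisons = compare_groups(
                fa, fb, alpha=cfg.alpha, method=cfg.mw_method, holm=cfg.holm,
                provenance_hash=chash,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("compare", str(exc))
        for c in comparisons:
            decisions.append(f"metric {c.metric}: test={c.test}")

        persistence = {}
        for gname, gfeats in ((groups[0], fa), (groups[1], fb)):
            try:
                persistence[gname] = persistence_curve(
                    gfeats, grid_step_min=cfg.grid_step_min, horizon_min=horizon
                )
            except ValueError as exc:
                raise PipelineError("persistence", str(exc))

        report = RunReport(
            config=cfg.to_dict(),
            config_hash=chash,
            version=__version__,
            features=feats,
            comparisons=comparisons,
            persistence=persistence,
            decisions=decisions,
            truth=truth,
            traceset=ts,
            transients=transients,
        )
        if cfg.out_dir is not None:
            _write_outputs(cfg, report, written)
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _write_outputs(cfg: RunConfig, report: RunReport, written: list[Path]) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def mark(p: Path) -> Path:
        written.append(p)
        return p

    write_traceset(report.traceset, mark(out / "traces.tsv"), format="long")
    written.append(out / "traces.meta.yaml")
    report.transients.to_csv(mark(out / "transients.tsv"), sep="\t", index=False)
    pd.DataFrame(features_to_records(report.features)).to_csv(
        mark(out / "features.tsv"), sep="\t", index=False
    )
    report.comparison_frame().to_csv(mark(out / "comparison.tsv"), sep="\t", index=False)
    pframes = []
    for gname in sorted(report.persistence):
        c = report.persistence[gname]
        pframes.append(
            pd.DataFrame(
                {
                    "group": gname,
                    "time_min": c.times_min,
                    "fraction_oscillating": c.fraction_oscillating,
                    "n_eggs": c.n_eggs,
                }
            )
        )
    pd.concat(pframes, ignore_index=True).to_csv(
        mark(out / "persistence.tsv"), sep="\t", index=False
    )
    if report.truth is not None:
        report.truth.to_csv(mark(out / "truth.tsv"), sep="\t", index=False)
    doc = {
        "version": report.version,
        "config": report.config,
        "config_hash": report.config_hash,
        "decisions": report.decisions,
    }
    with open(mark(out / "report.json"), "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    if cfg.make_plots:
        _write_plots(report, out, written)


def _write_plots(report: RunReport, out: Path, written: list[Path]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # representative traces with detected transients shaded
    fig, axes = plt.subplots(2, 1, figsize=(10, 5), sharex=True)
    groups = sorted({t.group for t in report.traceset})
    for ax, gname in zip(axes, groups):
        tr = next(t for t in report.traceset if t.group == gname)
        ax.plot(tr.times / 60.0, tr.values, lw=0.7, color="k")
        sub = report.transients[report.transients.egg_id == tr.egg_id]
        for _, row in sub.iterrows():
            ax.axvspan(row.onset_s / 60.0, row.offset_s / 60.0, color="tab:orange", alpha=0.3)
        ax.set_ylabel(f"{gname}\nF340/F380")
    axes[-1].set_xlabel("time (min)")
    fig.tight_layout()
    fig.savefig(written[-1].parent / "traces.png", dpi=120)
    written.append(out / "traces.png")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for gname in sorted(report.persistence):
        c = report.persistence[gname]
        ax.step(c.times_min, 100.0 * c.fraction_oscillating, where="post", label=gname)
    ax.set_xlabel("time from first transient (min)")
    ax.set_ylabel("eggs still oscillating (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "persistence.png", dpi=120)
    written.append(out / "persistence.png")
    plt.close(fig)
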