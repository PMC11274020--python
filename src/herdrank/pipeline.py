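"""One-call orchestration: messages → ranks → statistics → null analysis.

``run_pipeline`` reads a message log and collar map, bins positions, applies
the day-exclusion filter, computes interval/daily/cumulative ranks,
concordance and shape statistics, runs the distance-randomization null with
its Mann–Whitney U comparisons, and writes every table to the output
directory together with a manifest recording the configuration, seeds,
record counts and a content hash of every file — so a run's bookkeeping
(message totals, excluded days, replicate seeds) is auditable afterwards.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from . import __version__
from .ingest import (
    CollarMap,
    apply_collar_map,
    bin_15min,
    exclude_days,
    parse_message_log,
)
from .nullmodel import build_mwu_matrices, cumulative_range, run_null_replicates
from .ranking import (
    cumulative_curve,
    daily_median_rank,
    final_cumulative,
    interval_median_distances,
    rank_distances,
)
from .stats import boxplot_table, density_summary, kendalls_w

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    messages: str
    collars: str
    out_dir: str
    start: date | None = None
    end: date | None = None
    exclusion_threshold: int | None = None  # default: full herd size
    ranking_policy: str = "present-only"
    cumulative_policy: str = "carry-forward"
    null_mode: str = "permute"
    null_reps: int = 10
    jitter_sd_m: float = 5.0
    seed: int = 0
    kde_grid: int = 512
    kde_cut: float = 3.0
    strict: bool = True
    make_plots: bool = False

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("start", "end"):
            if d[k] is not None:
                d[k] = str(d[k])
        return d


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run plus the manifest written."""

    tables: dict = field(default_factory=dict)       # name -> DataFrame
    concordance: dict = field(default_factory=dict)
    day_report: object = None
    null_summary: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Writer:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.files: dict[str, str] = {}

    def csv(self, name: str, df: pd.DataFrame) -> None:
        path = self.out_dir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False, float_format="%.10g")
        self.files[name] = _sha256(path)

    def csv_matrix(self, name: str, df: pd.DataFrame) -> None:
        path = self.out_dir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, float_format="%.10g")
        self.files[name] = _sha256(path)

    def json(self, name: str, payload) -> None:
        path = self.out_dir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        if hasattr(payload, "to_json"):
            path.write_text(payload.to_json())
        else:
            path.write_text(json.dumps(payload, indent=2, default=str))
        self.files[name] = _sha256(path)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle.

    Stage errors abort with the failing stage named.  Returns the bundle
    with all tables still in memory.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    writer = _Writer(out_dir)
    bundle = ReportBundle()
    counts: dict[str, int] = {}

    stage = "parse"
    try:
        parsed = parse_message_log(config.messages, strict=config.strict)
        counts["raw_messages"] = len(parsed.records) + len(parsed.rejected)
        counts["rejected_messages"] = len(parsed.rejected)
        records = parsed.records
        if config.start is not None:
            records = records[records["timestamp"].dt.date >= config.start]
        if config.end is not None:
            records = records[records["timestamp"].dt.date <= config.end]
        counts["messages_in_window"] = len(records)

        stage = "collar-map"
        cmap = CollarMap.from_csv(config.collars)
        mapped = apply_collar_map(records, cmap, strict=config.strict)
        counts["mapped_messages"] = len(mapped.records)

        stage = "binning"
        intervals = bin_15min(mapped.records)
        counts["binned_cow_intervals"] = len(intervals)

        stage = "day-exclusion"
        intervals, day_report = exclude_days(intervals, config.exclusion_threshold)
        counts["kept_days"] = len(day_report.kept_days)
        counts["excluded_days"] = len(day_report.excluded_days)
        bundle.day_report = day_report
        writer.json("day_filter.json", day_report)

        stage = "ranking"
        med = interval_median_distances(intervals)
        iranks = rank_distances(med, policy=config.ranking_policy)
        daily = daily_median_rank(iranks)
        curves = cumulative_curve(daily, policy=config.cumulative_policy)
        finals = final_cumulative(curves)
        bundle.tables["interval_ranks"] = iranks
        bundle.tables["daily_ranks"] = daily
        bundle.tables["cumulative"] = curves
        writer.csv("interval_ranks.csv", iranks)
        writer.csv("daily_ranks.csv", daily)
        writer.csv("cumulative.csv", curves)

        stage = "statistics"
        wide = daily.pivot(index="day", columns="cow_id", values="median_rank")
        complete = wide.dropna(axis=0)
        conc = kendalls_w(complete)
        bundle.concordance = conc.as_dict() | {
            "days_used": len(complete),
            "days_dropped_incomplete": len(wide) - len(complete),
        }
        writer.json("concordance.json", bundle.concordance)
        dens = density_summary(daily, grid_size=config.kde_grid, cut=config.kde_cut)
        box = boxplot_table(daily)
        bundle.tables["density_summary"] = dens
        bundle.tables["boxplot_summary"] = box
        writer.csv("density_summary.csv", dens)
        writer.csv("boxplot_summary.csv", box)

        stage = "null-model"
        null_input = intervals if config.null_mode == "jitter" else med
        reps = run_null_replicates(
            null_input, n_reps=config.null_reps, base_seed=config.seed,
            mode=config.null_mode, ranking_policy=config.ranking_policy,
            jitter_sd_m=config.jitter_sd_m,
        )
        lo, hi = cumulative_range(reps)
        w_per_rep = []
        for rep in reps:
            rw = rep.daily_ranks.pivot(index="day", columns="cow_id",
                                       values="median_rank").dropna(axis=0)
            w_per_rep.append(kendalls_w(rw).w)
        for rep in reps:
            writer.csv(f"null_replicates/rep_{rep.replicate_id}/daily_ranks.csv",
                       rep.daily_ranks)

        stage = "mwu"
        mwu = build_mwu_matrices(daily, reps)
        writer.csv_matrix("mwu_original.csv", mwu.original.p)
        for rep_m, rep in zip(mwu.replicates, reps):
            writer.csv_matrix(f"mwu_rep_{rep.replicate_id}.csv", rep_m.p)
        writer.csv_matrix("mwu_orig_vs_rep.csv", mwu.orig_vs_rep_p)
        bundle.null_summary = {
            "mode": config.null_mode,
            "n_replicates": config.null_reps,
            "replicate_seeds": [list(r.seed) for r in reps],
            "cumulative_range": [lo, hi],
            "original_cumulative_range": [float(finals.min()), float(finals.max())],
            "W_per_replicate": w_per_rep,
            **mwu.summary,
        }
        writer.json("null_summary.json", bundle.null_summary)

        if config.make_plots:
            stage = "plots"
            _write_plots(out_dir, daily, curves, writer)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle.manifest = {
        "herdrank_version": __version__,
        "config": config.as_dict(),
        "counts": counts,
        "files": writer.files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
    logger.info("run_pipeline: wrote %d file(s) to %s", len(writer.files) + 1, out_dir)
    return bundle


def _write_plots(out_dir: Path, daily: pd.DataFrame, curves: pd.DataFrame,
                 writer: _Writer) -> None:
    """Boxplot, time-series, cumulative and density figures (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cows = sorted(daily["cow_id"].unique())

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.boxplot([daily.loc[daily["cow_id"] == c, "median_rank"] for c in cows],
               tick_labels=cows)
    ax.set_ylabel("daily median rank")
    plt.setp(ax.get_xticklabels(), rotation=90)
    fig.savefig(out_dir / "boxplot.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    for name, value in (("timeseries", "median_rank"),):
        fig, ax = plt.subplots(figsize=(10, 4))
        for c in cows:
            sub = daily[daily["cow_id"] == c]
            ax.plot(pd.to_datetime(sub["day"].astype(str)), sub[value], lw=0.8)
        ax.set_ylabel("daily median rank")
        fig.savefig(out_dir / f"{name}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(10, 4))
    for c in cows:
        sub = curves[curves["cow_id"] == c]
        ax.plot(pd.to_datetime(sub["day"].astype(str)), sub["cumulative"], lw=0.8)
    ax.set_ylabel("cumulative daily median rank")
    fig.savefig(out_dir / "cumulative.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(10, 4))
    for c in cows:
        sub = daily.loc[daily["cow_id"] == c, "median_rank"]
        sub.plot.kde(ax=ax, lw=0.8)
    ax.set_xlabel("daily median rank")
    fig.savefig(out_dir / "density.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
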