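"""Report bundle: tidy CSV summaries, figures, and a run log.

Ties the module outputs together the way a study report is organized:
biodistribution mean ± SD per organ/day, the t₀-vs-t_eq ²¹³Bi comparison,
doubling times per group, Kaplan–Meier medians, and the statistical
comparison table.  Outputs are deterministic for a fixed seed/config
(byte-identical CSVs on rerun).
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .efficacy import km_curve

__all__ = ["ReportBundle", "build_report"]

_FLOAT_FORMAT = "%.6g"


@dataclass
class ReportBundle:
    """Paths of everything a report run wrote."""

    outdir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    figures: dict[str, Path] = field(default_factory=dict)
    log: Path | None = None
    absent: list[str] = field(default_factory=list)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


def build_report(outdir, biodistribution: pd.DataFrame | None = None,
                 redistribution: pd.DataFrame | None = None,
                 growth_fits: pd.DataFrame | None = None,
                 survival: pd.DataFrame | None = None,
                 comparisons: list | None = None,
                 config: dict | None = None, seed: int | None = None,
                 make_plots: bool = True,
                 study_end: float = 150.0) -> ReportBundle:
    """Assemble the report bundle from whatever sections are present.

    Absent sections are recorded explicitly rather than silently skipped.
    At least one section must be provided.
    """
    sections = {
        "biodistribution": biodistribution,
        "bismuth_redistribution": redistribution,
        "growth_fits": growth_fits,
        "survival": survival,
    }
    if all(v is None for v in sections.values()) and not comparisons:
        raise ValueError("no upstream output provided")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=outdir)

    for name, df in sections.items():
        if df is None or len(df) == 0:
            bundle.absent.append(name)
            continue
        path = outdir / f"{name}.csv"
        _write_csv(pd.DataFrame(df), path)
        bundle.tables[name] = path

    if survival is not None and len(survival):
        rows = []
        for group, sub in survival.groupby("group", sort=False):
            curve = km_curve(sub, label=str(group))
            rows.append({
                "group": group, "n": len(sub),
                "events": int(sub["event"].sum()),
                "median_survival_day": curve.median_label(study_end),
            })
        path = outdir / "km_medians.csv"
        _write_csv(pd.DataFrame(rows), path)
        bundle.tables["km_medians"] = path

    if growth_fits is not None and len(growth_fits):
        inc = growth_fits[growth_fits["included"]]
        summary = inc.groupby("group", sort=False)["doubling_time_day"].agg(
            mean="mean", sd="std", n="count").reset_index()
        excluded = (growth_fits.groupby("group", sort=False)["included"]
                    .apply(lambda s: int((~s).sum())).rename("n_excluded"))
        summary = summary.merge(excluded, on="group")
        path = outdir / "doubling_time_summary.csv"
        _write_csv(summary, path)
        bundle.tables["doubling_time_summary"] = path

    if comparisons:
        path = outdir / "comparisons.csv"
        _write_csv(pd.DataFrame([asdict(c) for c in comparisons]), path)
        bundle.tables["comparisons"] = path

    if make_plots:
        if biodistribution is not None and len(biodistribution):
            bundle.figures["biodistribution"] = _plot_biodistribution(
                pd.DataFrame(biodistribution), outdir)
        if survival is not None and len(survival):
            bundle.figures["km_curves"] = _plot_km(
                pd.DataFrame(survival), outdir, study_end)

    log = {
        "package": "alphachain",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "config": config or {},
        "sections_written": sorted(bundle.tables),
        "sections_absent": sorted(bundle.absent),
    }
    bundle.log = outdir / "run_log.json"
    bundle.log.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return bundle


def _plot_biodistribution(tidy: pd.DataFrame, outdir: Path) -> Path:
    summary = tidy.groupby(["organ", "timepoint_day"])["pct_ia_per_g"].agg(
        ["mean", "std"]).reset_index()
    fig, ax = plt.subplots(figsize=(8, 4.5))
    organs = summary["organ"].unique()
    days_ = sorted(summary["timepoint_day"].unique())
    width = 0.8 / max(len(days_), 1)
    for i, day in enumerate(days_):
        sub = summary[summary["timepoint_day"] == day].set_index("organ").reindex(organs)
        x = [j + i * width for j in range(len(organs))]
        ax.bar(x, sub["mean"], width=width, yerr=sub["std"], capsize=2,
               label=f"day {day:g}")
    ax.set_xticks([j + 0.4 - width / 2 for j in range(len(organs))])
    ax.set_xticklabels(organs, rotation=45, ha="right")
    ax.set_ylabel("%IA/g")
    ax.legend()
    fig.tight_layout()
    path = outdir / "biodistribution.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _plot_km(survival: pd.DataFrame, outdir: Path, study_end: float) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for group, sub in survival.groupby("group", sort=False):
        curve = km_curve(sub, label=str(group))
        ax.step(curve.times, curve.survival, where="post", label=str(group))
    ax.set_xlabel("days post-inoculation")
    ax.set_ylabel("survival fraction")
    ax.set_xlim(0, study_end * 1.02)
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    path = outdir / "km_curves.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
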