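"""Figure analogues of the portfolio plots.

Boxplots use median / quartile boxes with 1.5x-IQR whiskers; ratio axes are
log-scaled with untransformed tick labels; the calibration plot draws the
identity diagonal, null lines, 95% CI error bars and highlights ranked
outliers; the Bland-Altman plot draws the mean difference and +/- 2 SD
limits.  Every figure is written as both SVG and PNG.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.ticker import FixedLocator, NullFormatter, ScalarFormatter

from .agreement_stats import BlandAltmanResult
from .cohort_concordance import CohortConcordanceRow
from .effect_concordance import ConcordanceRow
from .records_io import StudyPair

logger = logging.getLogger(__name__)

_SAVE_KW = {"bbox_inches": "tight"}


def _save(fig, out_dir: Path, stem: str) -> list[Path]:
    paths = []
    for ext in ("svg", "png"):
        p = out_dir / f"{stem}.{ext}"
        # a fixed Date keeps SVG output byte-stable across reruns
        fig.savefig(p, metadata={"Date": None} if ext == "svg" else None, **_SAVE_KW)
        paths.append(p)
    plt.close(fig)
    return paths


def _log_ratio_axis(ax, axis="y"):
    ticks = [0.25, 0.5, 1.0, 2.0, 4.0]
    target = ax.yaxis if axis == "y" else ax.xaxis
    getattr(ax, f"set_{axis}scale")("log")
    target.set_major_locator(FixedLocator(ticks))
    target.set_major_formatter(ScalarFormatter())
    target.set_minor_formatter(NullFormatter())


def fig_sample_size(rows: Sequence[CohortConcordanceRow], out_dir) -> list[Path]:
    """Boxplots of relative sample size (original/reproduction) by design."""
    groups = {}
    for r in rows:
        groups.setdefault(r.design, []).append(r.rel_sample_size)
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = sorted(groups)
    ax.boxplot([groups[k] for k in labels], tick_labels=[f"{k}\n(N={len(groups[k])})" for k in labels], whis=1.5)
    ax.axhline(1.0, color="gray", linestyle="--", linewidth=1)
    _log_ratio_axis(ax, "y")
    ax.set_ylabel("relative sample size (original / reproduction)")
    return _save(fig, Path(out_dir), "fig1_sample_size")


def fig_covariate_diffs(rows: Sequence[CohortConcordanceRow], out_dir) -> list[Path]:
    """Strip plot of prevalence differences (original - reproduction) per study."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for x, row in enumerate(rows):
        diffs = [d.diff_pct for d in row.covariate_diffs]
        ax.plot([x] * len(diffs), diffs, ".", color="tab:blue", alpha=0.4, markersize=3)
    ax.axhline(0.0, color="gray", linestyle="--", linewidth=1)
    ax.set_xlabel("study")
    ax.set_ylabel("prevalence difference (pct points)")
    return _save(fig, Path(out_dir), "fig2_covariate_diffs")


def fig_risk_rate_calibration(pairs: Sequence[StudyPair], out_dir) -> list[Path]:
    """Original-vs-reproduction calibration of outcome risks (A) and rates (B)."""
    from .cohort_concordance import _rate, _risk, MissingDataError

    risks, rates = [], []
    for pair in pairs:
        for a_o, a_r in zip(pair.original.arms, pair.reproduction.arms):
            try:
                risks.append((_risk(a_o), _risk(a_r)))
            except MissingDataError:
                pass
            try:
                rates.append((_rate(a_o), _rate(a_r)))
            except MissingDataError:
                pass
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, data, label in zip(axes, (risks, rates), ("risk (%)", "rate (per 100 py)")):
        if data:
            arr = np.array(data)
            ax.plot(arr[:, 1], arr[:, 0], "o", markersize=3, alpha=0.6)
            hi = float(arr.max()) * 1.05 or 1.0
            ax.plot([0, hi], [0, hi], "--", color="gray", linewidth=1)
        ax.set_xlabel(f"reproduction {label}")
        ax.set_ylabel(f"original {label}")
    axes[0].set_title("A  risks")
    axes[1].set_title("B  rates")
    fig.tight_layout()
    return _save(fig, Path(out_dir), "fig3_risk_rate_calibration")


def fig_rel_magnitude(rows: Sequence[ConcordanceRow], out_dir) -> list[Path]:
    """Distribution of the relative magnitude ES_o/ES_r on a log axis."""
    vals = [r.rel_magnitude for r in rows]
    fig, ax = plt.subplots(figsize=(5, 4))
    lo = min(min(vals), 1 / 1.1)
    hi = max(max(vals), 1.1)
    bins = np.exp(np.linspace(math.log(lo) - 0.05, math.log(hi) + 0.05, 25))
    ax.hist(vals, bins=bins, color="tab:blue", edgecolor="white")
    ax.axvline(1.0, color="gray", linestyle="--", linewidth=1)
    _log_ratio_axis(ax, "x")
    ax.set_xlabel("relative magnitude (original / reproduction)")
    ax.set_ylabel("studies")
    return _save(fig, Path(out_dir), "fig4_rel_magnitude")


def fig_calibration(
    pairs: Sequence[StudyPair],
    outlier_ids: Sequence[str] = (),
    out_dir=".",
) -> list[Path]:
    """Log-effect calibration scatter with 95% CI error bars and outliers in red."""
    comp = [p for p in pairs if p.original.effect is not None]
    fig, ax = plt.subplots(figsize=(5.5, 5))
    outliers = set(outlier_ids)
    for p in comp:
        o, r = p.original.effect, p.reproduction.effect
        color = "red" if p.study_id in outliers else "tab:blue"
        xerr = yerr = None
        if r.has_ci:
            xerr = [[math.log(r.point) - math.log(r.ci_low)], [math.log(r.ci_high) - math.log(r.point)]]
        if o.has_ci:
            yerr = [[math.log(o.point) - math.log(o.ci_low)], [math.log(o.ci_high) - math.log(o.point)]]
        ax.errorbar(
            math.log(r.point),
            math.log(o.point),
            xerr=xerr,
            yerr=yerr,
            fmt="o",
            color=color,
            markersize=3,
            elinewidth=0.5,
            alpha=0.7,
        )
    lims = ax.get_xlim() + ax.get_ylim()
    lo, hi = min(lims), max(lims)
    ax.plot([lo, hi], [lo, hi], "--", color="black", linewidth=1)
    ax.axhline(0.0, color="gray", linestyle="--", linewidth=0.8)
    ax.axvline(0.0, color="gray", linestyle="--", linewidth=0.8)
    ax.set_xlabel("log effect size, reproduction")
    ax.set_ylabel("log effect size, original")
    return _save(fig, Path(out_dir), "fig5_calibration")


def fig_bland_altman(ba: BlandAltmanResult, out_dir) -> list[Path]:
    """Difference-vs-mean plot with the mean line (blue) and +/- 2 SD limits (red)."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(ba.means, ba.diffs, "o", markersize=4, alpha=0.7, mfc="none", color="black")
    ax.axhline(ba.mean_diff, color="tab:blue", linewidth=1.2)
    ax.axhline(ba.lower_limit, color="red", linewidth=1)
    ax.axhline(ba.upper_limit, color="red", linewidth=1)
    ax.set_xlabel("mean of log effect sizes")
    ax.set_ylabel("difference in log effect size (original - reproduction)")
    return _save(fig, Path(out_dir), "fig6_bland_altman")


def make_figures(
    pairs: Sequence[StudyPair],
    concordance_rows: Sequence[ConcordanceRow],
    cohort_rows: Sequence[CohortConcordanceRow],
    ba: Optional[BlandAltmanResult],
    outlier_ids: Sequence[str],
    out_dir,
) -> list[Path]:
    """Render every figure whose metric table is non-empty; skip the rest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    if cohort_rows:
        paths += fig_sample_size(cohort_rows, out_dir)
        paths += fig_covariate_diffs(cohort_rows, out_dir)
    else:
        logger.info("no cohort rows: skipping sample-size and covariate figures")
    if pairs:
        paths += fig_risk_rate_calibration(pairs, out_dir)
    if concordance_rows:
        paths += fig_rel_magnitude(concordance_rows, out_dir)
        paths += fig_calibration(pairs, outlier_ids, out_dir)
    else:
        logger.info("no concordance rows: skipping effect-size figures")
    if ba is not None:
        paths += fig_bland_altman(ba, out_dir)
    return paths
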