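"""Portfolio-level agreement statistics across reproduced studies.

Given the per-study concordance rows and effect estimates, this module
computes the portfolio summary: unweighted and inverse-variance-weighted
Pearson and Spearman correlations between log effect sizes, a one-way
random-effects intraclass correlation coefficient with its F-based confidence
interval, Bland-Altman limits of agreement on the log scale, agreement
proportions, medians/IQRs, an outlier ranking, and a one-way ANOVA
exploration of variance in means across study subgroups.

Conventions
-----------
* Correlations and the ICC are computed on ln(effect size).
* The inverse-variance weight of a study pair is 1/(se_o^2 + se_r^2) by
  default (pair-level precision), switchable to the original study's 1/se_o^2.
* Quantiles use linear interpolation (numpy default, R type 7).
* Bland-Altman limits sit at mean +/- 2 * SD (sample SD, n-1 denominator) —
  2, not 1.96.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effect_concordance import ConcordanceRow, se_from_ci
from .records_io import EffectEstimate

__all__ = [
    "UndefinedCorrelationError",
    "AgreementSummary",
    "BlandAltmanResult",
    "ivw_weights",
    "pair_ivw_weights",
    "weighted_pearson",
    "weighted_spearman",
    "icc_oneway",
    "bland_altman",
    "top_outliers",
    "summarize",
    "subgroup_variation",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (zero variance in x or y)."""


def ivw_weights(estimates: Sequence[EffectEstimate]) -> np.ndarray:
    """Per-estimate inverse-variance weights w_i = 1/se_i^2 (unnormalised).

    se_i is backed out of the 95% CI on the log scale.  Normalisation, if
    wanted, is the consumer's choice.
    """
    return np.array([1.0 / se_from_ci(e) ** 2 for e in estimates])


def pair_ivw_weights(
    originals: Sequence[EffectEstimate],
    reproductions: Sequence[EffectEstimate],
    variant: str = "combined",
) -> np.ndarray:
    """Pair-level inverse-variance weights for the IVW correlations.

    ``combined`` (default): 1/(se_o^2 + se_r^2);  ``original``: 1/se_o^2.
    """
    se_o = np.array([se_from_ci(e) for e in originals])
    if variant == "original":
        return 1.0 / se_o**2
    if variant != "combined":
        raise ValueError(f"unknown IVW variant {variant!r}")
    se_r = np.array([se_from_ci(e) for e in reproductions])
    return 1.0 / (se_o**2 + se_r**2)


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation with weighted means.

    r_w = sum w (x - xbar_w)(y - ybar_w) /
          sqrt(sum w (x - xbar_w)^2 * sum w (y - ybar_w)^2)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    xm = x - np.average(x, weights=w)
    ym = y - np.average(y, weights=w)
    sxx = np.sum(w * xm**2)
    syy = np.sum(w * ym**2)
    if sxx == 0 or syy == 0:
        raise UndefinedCorrelationError("zero weighted variance in x or y")
    return float(np.sum(w * xm * ym) / np.sqrt(sxx * syy))


def weighted_spearman(x, y, w) -> float:
    """Weighted Spearman: weighted Pearson on mid-ranks (ties get average ranks)."""
    rx = stats.rankdata(np.asarray(x, dtype=float), method="average")
    ry = stats.rankdata(np.asarray(y, dtype=float), method="average")
    return weighted_pearson(rx, ry, w)


def icc_oneway(pairs, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """One-way random-effects intraclass correlation ICC(1) for paired values.

    Treats original and reproduction as two interchangeable measurements of
    the same study (no rater effect).  From the one-way ANOVA with n subjects
    and k = 2 measurements:

        ICC = (MSB - MSW) / (MSB + (k - 1) MSW)

    The confidence interval follows the F distribution of MSB/MSW:
    F_L = F / F_{1-alpha/2; n-1, n(k-1)}, F_U = F * F_{1-alpha/2; n(k-1), n-1},
    with bounds (F_L - 1)/(F_L + k - 1) and (F_U - 1)/(F_U + k - 1).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) array of paired values")
    n, k = arr.shape
    row_means = arr.mean(axis=1)
    grand = arr.mean()
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((arr - row_means[:, None]) ** 2) / (n * (k - 1))
    if msb == 0 and msw == 0:
        raise ValueError("ICC undefined: all values identical")
    if msw == 0:
        return 1.0, (1.0, 1.0)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_obs = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1) / (f_l + k - 1)
    hi = (f_u - 1) / (f_u + k - 1)
    return float(icc), (float(lo), float(hi))


@dataclass
class BlandAltmanResult:
    """Bland-Altman agreement of log effect sizes, limits at mean +/- 2 SD."""

    study_ids: list[str]
    means: np.ndarray  # (ln ES_o + ln ES_r)/2 per study
    diffs: np.ndarray  # ln ES_o - ln ES_r per study
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    outside_limits: list[str]


def bland_altman(log_pairs, study_ids: Optional[Sequence[str]] = None) -> BlandAltmanResult:
    """Bland-Altman construction on (ln ES_o, ln ES_r) pairs.

    Limits are mean difference +/- 2 * sample SD (n-1 denominator).
    """
    arr = np.asarray(log_pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need an (n >= 2, 2) array of log effect pairs")
    n = arr.shape[0]
    ids = list(study_ids) if study_ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("study_ids length mismatch")
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    lower, upper = mean_diff - 2.0 * sd_diff, mean_diff + 2.0 * sd_diff
    outside = [ids[i] for i in range(n) if diffs[i] < lower or diffs[i] > upper]
    return BlandAltmanResult(ids, means, diffs, mean_diff, sd_diff, lower, upper, outside)


def top_outliers(rows: Sequence[ConcordanceRow], k: int) -> list[str]:
    """Study ids of the k most extreme |log ES_o - log ES_r|, descending.

    Ties are broken by lexicographic study_id order (smaller id first).
    """
    if k > len(rows):
        raise ValueError(f"k = {k} exceeds number of rows {len(rows)}")
    ranked = sorted(rows, key=lambda r: (-r.abs_log_diff, r.study_id))
    return [r.study_id for r in ranked[:k]]


def _quantiles(values, qs=(0.25, 0.5, 0.75)):
    return tuple(float(np.quantile(np.asarray(values, dtype=float), q)) for q in qs)


@dataclass
class AgreementSummary:
    """Portfolio-level agreement statistics with per-field denominators."""

    n_studies: int
    pearson_unweighted: float
    pearson_ivw: float
    spearman_unweighted: float
    spearman_ivw: float
    icc: float
    icc_ci: tuple[float, float]
    median_rel_magnitude: float
    iqr_rel_magnitude: tuple[float, float]
    range_rel_magnitude: tuple[float, float]
    prop_within_01: float
    prop_within_02: float
    prop_repro_closer_null: float
    prop_same_side: float
    prop_same_side_with_ci: float
    prop_ci_overlap: float
    prop_signif_discordant: float
    median_p_diff_same_side: Optional[float]
    iqr_p_diff_same_side: Optional[tuple[float, float]]
    mean_abs_log_diff_same_side: Optional[float]
    mean_abs_log_diff_opposite_side: Optional[float]
    denominators: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


def summarize(
    rows: Sequence[ConcordanceRow],
    estimates: Sequence[tuple[EffectEstimate, EffectEstimate]],
    ivw_variant: str = "combined",
    alpha: float = 0.05,
) -> AgreementSummary:
    """Portfolio summary over per-study concordance rows.

    ``estimates`` supplies the (original, reproduction) effect estimates
    aligned with ``rows`` (needed for the log effects and IVW weights).
    Proportions are taken over non-missing denominators; each denominator is
    reported in ``denominators``.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 comparative rows")
    if len(rows) != len(estimates):
        raise ValueError("rows and estimates must be aligned")
    lo = np.array([np.log(o.point) for o, _ in estimates])
    lr = np.array([np.log(r.point) for _, r in estimates])
    equal_w = np.ones(len(rows))

    with_ci = [i for i, (o, r) in enumerate(estimates) if o.has_ci and r.has_ci]
    w = pair_ivw_weights(
        [estimates[i][0] for i in with_ci],
        [estimates[i][1] for i in with_ci],
        variant=ivw_variant,
    )
    icc, icc_ci = icc_oneway(np.column_stack([lo, lr]), alpha=alpha)

    rel = [r.rel_magnitude for r in rows]
    q1, med, q3 = _quantiles(rel)

    def prop(flags):
        flags = [f for f in flags if f is not None]
        if not flags:
            return float("nan"), 0
        return sum(bool(f) for f in flags) / len(flags), len(flags)

    p01, n01 = prop([r.within_01 for r in rows])
    p02, n02 = prop([r.within_02 for r in rows])
    pcn, ncn = prop(
        [r.repro_closer_to_null == "reproduction_closer" for r in rows]
    )
    pss, nss = prop([r.same_side_of_null for r in rows])
    pssci, nssci = prop([r.both_est_and_ci_same_side for r in rows])
    pov, nov = prop([r.ci_overlap for r in rows])
    psd, nsd = prop([r.signif_discordant for r in rows])

    same = [r for r in rows if r.same_side_of_null]
    opp = [r for r in rows if not r.same_side_of_null]
    pdiffs = [r.p_diff for r in same if r.p_diff is not None]
    if pdiffs:
        pq1, pmed, pq3 = _quantiles(pdiffs)
        med_p, iqr_p = pmed, (pq1, pq3)
    else:
        med_p, iqr_p = None, None

    summary = AgreementSummary(
        n_studies=len(rows),
        pearson_unweighted=weighted_pearson(lo, lr, equal_w),
        pearson_ivw=weighted_pearson(lo[with_ci], lr[with_ci], w),
        spearman_unweighted=weighted_spearman(lo, lr, equal_w),
        spearman_ivw=weighted_spearman(lo[with_ci], lr[with_ci], w),
        icc=icc,
        icc_ci=icc_ci,
        median_rel_magnitude=med,
        iqr_rel_magnitude=(q1, q3),
        range_rel_magnitude=(float(min(rel)), float(max(rel))),
        prop_within_01=p01,
        prop_within_02=p02,
        prop_repro_closer_null=pcn,
        prop_same_side=pss,
        prop_same_side_with_ci=pssci,
        prop_ci_overlap=pov,
        prop_signif_discordant=psd,
        median_p_diff_same_side=med_p,
        iqr_p_diff_same_side=iqr_p,
        mean_abs_log_diff_same_side=(
            float(np.mean([r.abs_log_diff for r in same])) if same else None
        ),
        mean_abs_log_diff_opposite_side=(
            float(np.mean([r.abs_log_diff for r in opp])) if opp else None
        ),
        denominators={
            "within_01": n01,
            "within_02": n02,
            "repro_closer_null": ncn,
            "same_side": nss,
            "same_side_with_ci": nssci,
            "ci_overlap": nov,
            "signif_discordant": nsd,
            "ivw": len(with_ci),
            "p_diff_same_side": len(pdiffs),
        },
    )
    return summary


def subgroup_variation(
    rows: Sequence[ConcordanceRow],
    groups: dict[str, str],
):
    """Variance-in-means exploration of |log ES_o - log ES_r| across subgroups.

    ``groups`` maps study_id -> subgroup label.  Returns (table, F, p,
    degenerate) where table lists (group, n, mean, sd).  Classical one-way
    ANOVA, deliberately without multiple-testing adjustment; when every value
    is identical the ANOVA is degenerate and reported as F = 0, p = 1.
    """
    by_group: dict[str, list[float]] = {}
    for r in rows:
        label = groups.get(r.study_id)
        if label is not None:
            by_group.setdefault(label, []).append(r.abs_log_diff)
    usable = {g: v for g, v in by_group.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    table = [
        (g, len(v), float(np.mean(v)), float(np.std(v, ddof=1)))
        for g, v in sorted(usable.items())
    ]
    values = [np.asarray(v) for _, v in sorted(usable.items())]
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        return table, 0.0, 1.0, True
    f_stat, p = stats.f_oneway(*values)
    if not np.isfinite(f_stat):
        return table, 0.0, 1.0, True
    return table, float(f_stat), float(p), False
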