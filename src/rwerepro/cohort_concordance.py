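"""Concordance of cohort construction: sizes, baseline prevalences, risks, rates.

These metrics compare the study *population* rather than the effect estimate:
the relative sample size original/reproduction (summed over compared exposure
groups), per-covariate differences in baseline prevalence in percentage
points, and per-arm differences in outcome risks (percentage points) and
rates (events per 100 person-years).

Large-difference flags use a strict ``> 10`` threshold in the respective
units (a difference of exactly 10 is not flagged); the extreme-size flag
marks ratios strictly below 1/2 or strictly above 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records_io import ArmResult, CovariateEntry, Design, StudyPair

__all__ = [
    "LARGE_DIFF_THRESHOLD",
    "CovariateDiff",
    "ArmDiff",
    "CohortConcordanceRow",
    "relative_sample_size",
    "covariate_differences",
    "risk_difference",
    "rate_difference",
    "cohort_concordance_table",
]

LARGE_DIFF_THRESHOLD = 10.0  # strict ">", percentage points or per 100 py
EXTREME_SIZE_LOW, EXTREME_SIZE_HIGH = 0.5, 2.0  # strict "<" / ">"


class MissingDataError(ValueError):
    pass


def relative_sample_size(pair: StudyPair) -> float:
    """N_original / N_reproduction, each summed over compared exposure groups."""
    n_o, n_r = pair.original.total_n, pair.reproduction.total_n
    if n_r <= 0:
        raise ValueError(f"{pair.study_id}: reproduction sample size is zero")
    if n_o <= 0:
        raise ValueError(f"{pair.study_id}: original sample size is zero")
    return n_o / n_r


def size_extreme(ratio: float) -> bool:
    """Reproduction less than half or more than 2x the original (strict)."""
    return ratio < EXTREME_SIZE_LOW or ratio > EXTREME_SIZE_HIGH


@dataclass(frozen=True)
class CovariateDiff:
    study_id: str
    covariate: str
    arm_id: str
    diff_pct: float  # original - reproduction, percentage points
    large: bool


def covariate_differences(
    entries: Sequence[CovariateEntry],
    threshold: float = LARGE_DIFF_THRESHOLD,
) -> list[CovariateDiff]:
    """Prevalence differences (original - reproduction) with >threshold flags."""
    out = []
    for e in entries:
        diff = e.prev_original_pct - e.prev_reproduction_pct
        out.append(
            CovariateDiff(e.study_id, e.covariate, e.arm_id, diff, abs(diff) > threshold)
        )
    return out


def _risk(arm: ArmResult) -> float:
    if arm.risk_pct is not None:
        return arm.risk_pct
    if arm.events is not None and arm.n > 0:
        return 100.0 * arm.events / arm.n
    raise MissingDataError(f"arm {arm.arm_id}: risk not given and not derivable")


def _rate(arm: ArmResult) -> float:
    if arm.rate_per100py is not None:
        return arm.rate_per100py
    if arm.events is not None and arm.person_years:
        return 100.0 * arm.events / arm.person_years
    raise MissingDataError(f"arm {arm.arm_id}: rate not given and not derivable")


def risk_difference(orig: ArmResult, repro: ArmResult) -> float:
    """Outcome risk difference original - reproduction, percentage points."""
    return _risk(orig) - _risk(repro)


def rate_difference(orig: ArmResult, repro: ArmResult) -> float:
    """Outcome rate difference original - reproduction, per 100 person-years."""
    return _rate(orig) - _rate(repro)


@dataclass
class ArmDiff:
    arm_id: str
    diff: float
    large: bool


@dataclass
class CohortConcordanceRow:
    study_id: str
    design: str
    rel_sample_size: float
    size_extreme: bool
    covariate_diffs: list[CovariateDiff] = field(default_factory=list)
    risk_diffs: list[ArmDiff] = field(default_factory=list)
    rate_diffs: list[ArmDiff] = field(default_factory=list)


def cohort_concordance_table(
    pairs: Sequence[StudyPair],
    covariates: Sequence[CovariateEntry] = (),
    threshold: float = LARGE_DIFF_THRESHOLD,
) -> list[CohortConcordanceRow]:
    """Per-study cohort concordance.

    Comparative studies contribute one risk/rate difference per compared arm;
    descriptive studies contribute their single overall arm.  Arms where
    neither a risk (rate) nor its ingredients are recorded are skipped.
    """
    cov_by_study: dict[str, list[CovariateEntry]] = {}
    for e in covariates:
        cov_by_study.setdefault(e.study_id, []).append(e)
    rows = []
    for pair in pairs:
        ratio = relative_sample_size(pair)
        row = CohortConcordanceRow(
            study_id=pair.study_id,
            design=pair.design.value,
            rel_sample_size=ratio,
            size_extreme=size_extreme(ratio),
            covariate_diffs=covariate_differences(
                cov_by_study.get(pair.study_id, []), threshold
            ),
        )
        for arm_o, arm_r in zip(pair.original.arms, pair.reproduction.arms):
            try:
                d = risk_difference(arm_o, arm_r)
                row.risk_diffs.append(ArmDiff(arm_o.arm_id, d, abs(d) > threshold))
            except MissingDataError:
                pass
            try:
                d = rate_difference(arm_o, arm_r)
                row.rate_diffs.append(ArmDiff(arm_o.arm_id, d, abs(d) > threshold))
            except MissingDataError:
                pass
        rows.append(row)
    return rows
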