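"""Per-study concordance metrics for measures of association.

Each metric compares the original publication's effect estimate (hazard
ratio, risk ratio or odds ratio) with the estimate obtained by an independent
reproduction on the same source data.  All comparisons are made on the
natural-log scale; the null is 1.0 on the ratio scale (0 on the log scale).

The headline per-study quantities are the relative magnitude ES_o/ES_r and
the absolute log difference |ln ES_o - ln ES_r|, supplemented by direction,
confidence-interval-overlap and statistical-significance agreement flags.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

from scipy import stats

from .records_io import Design, EffectEstimate, StudyPair

__all__ = [
    "Z975",
    "CloserToNull",
    "ConcordanceRow",
    "relative_magnitude",
    "abs_log_difference",
    "signed_log_difference",
    "closer_to_null",
    "same_side_of_null",
    "ci_overlap",
    "significance_discordance",
    "se_from_ci",
    "p_from_estimate",
    "concordance_table",
]

logger = logging.getLogger(__name__)

#: two-sided 97.5% standard-normal quantile used to back out SEs from 95% CIs
Z975: float = float(stats.norm.ppf(0.975))

#: |Delta |log|| below this counts as a tie in closer_to_null (strict
#: comparison otherwise; ties are essentially impossible on real data)
TIE_TOL = 1e-12


class CloserToNull(str, enum.Enum):
    reproduction_closer = "reproduction_closer"
    original_closer = "original_closer"
    tie = "tie"


def _check_point(est: EffectEstimate) -> float:
    if not (est.point > 0):
        raise ValueError(f"effect point must be positive, got {est.point}")
    return math.log(est.point)


def relative_magnitude(original: EffectEstimate, reproduction: EffectEstimate) -> float:
    """Relative magnitude ES_original / ES_reproduction (1.0 = perfect agreement)."""
    _check_point(original)
    _check_point(reproduction)
    return original.point / reproduction.point


def signed_log_difference(original: EffectEstimate, reproduction: EffectEstimate) -> float:
    """ln ES_original - ln ES_reproduction."""
    return _check_point(original) - _check_point(reproduction)


def abs_log_difference(original: EffectEstimate, reproduction: EffectEstimate) -> float:
    """|ln ES_original - ln ES_reproduction|; symmetric in its arguments."""
    return abs(signed_log_difference(original, reproduction))


def closer_to_null(original: EffectEstimate, reproduction: EffectEstimate) -> CloserToNull:
    """Which estimate lies closer to the null (1.0), comparing |ln ES|."""
    d = abs(_check_point(reproduction)) - abs(_check_point(original))
    if abs(d) < TIE_TOL:
        return CloserToNull.tie
    return CloserToNull.reproduction_closer if d < 0 else CloserToNull.original_closer


def same_side_of_null(
    original: EffectEstimate,
    reproduction: EffectEstimate,
    require_ci: bool = False,
) -> bool:
    """Do both estimates fall on the same side of the null?

    With ``require_ci`` the 95% CIs must additionally both exclude 1.0 on that
    same side (strict exclusion: a CI touching 1.0 does not count).
    """
    lo = _check_point(original)
    lr = _check_point(reproduction)
    same_points = _sign(lo) == _sign(lr)
    if not require_ci:
        return same_points
    if not (original.has_ci and reproduction.has_ci):
        raise ValueError("require_ci=True needs a 95% CI on both estimates")
    both_above = original.ci_low > 1.0 and reproduction.ci_low > 1.0
    both_below = original.ci_high < 1.0 and reproduction.ci_high < 1.0
    return same_points and (both_above or both_below)


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def ci_overlap(original: EffectEstimate, reproduction: EffectEstimate) -> bool:
    """Nonempty intersection of the two closed 95% CIs (touching counts)."""
    if not (original.has_ci and reproduction.has_ci):
        raise ValueError("ci_overlap needs a 95% CI on both estimates")
    return original.ci_low <= reproduction.ci_high and reproduction.ci_low <= original.ci_high


def significance_discordance(
    p_original: float,
    p_reproduction: float,
    alpha_fail: float = 0.05,
    alpha_reject: float = 0.01,
) -> bool:
    """One p-value above 0.05 while the other is at or below 0.01 (either way)."""
    for p in (p_original, p_reproduction):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {p}")
    return (p_reproduction > alpha_fail and p_original <= alpha_reject) or (
        p_original > alpha_fail and p_reproduction <= alpha_reject
    )


def se_from_ci(est: EffectEstimate) -> float:
    """Log-scale standard error backed out of a 95% CI: (ln U - ln L)/(2 z)."""
    if not est.has_ci:
        raise ValueError("estimate has no CI")
    se = (math.log(est.ci_high) - math.log(est.ci_low)) / (2.0 * Z975)
    if se <= 0:
        raise ValueError(f"degenerate CI ({est.ci_low}, {est.ci_high})")
    return se


def p_from_estimate(est: EffectEstimate) -> float:
    """Two-sided normal-approximation p-value from the point estimate and CI.

    se = (ln U - ln L)/(2 z_0.975), z = ln(point)/se, p = 2 (1 - Phi(|z|)).
    Used when a publication did not print a p-value; rows carry a provenance
    flag marking the approximation.
    """
    se = se_from_ci(est)
    z = _check_point(est) / se
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class ConcordanceRow:
    """All per-study effect-concordance metrics for one comparative study."""

    study_id: str
    rel_magnitude: float
    abs_log_diff: float
    signed_log_diff: float
    within_01: bool
    within_02: bool
    repro_closer_to_null: str
    same_side_of_null: bool
    both_est_and_ci_same_side: Optional[bool]
    ci_overlap: Optional[bool]
    signif_discordant: Optional[bool]
    p_original: Optional[float]
    p_reproduction: Optional[float]
    p_diff: Optional[float]
    p_original_source: Optional[str]  # "reported" | "from_ci"
    p_reproduction_source: Optional[str]

    def as_dict(self) -> dict:
        return asdict(self)


def _p_with_provenance(est: EffectEstimate) -> tuple[Optional[float], Optional[str]]:
    if est.p_value is not None:
        return est.p_value, "reported"
    if est.has_ci:
        return p_from_estimate(est), "from_ci"
    return None, None


def concordance_row(pair: StudyPair, log_diff_thresholds=(0.1, 0.2)) -> ConcordanceRow:
    """Compute every concordance metric for one comparative study pair."""
    if pair.design is not Design.comparative:
        raise ValueError(f"{pair.study_id}: concordance metrics need a comparative study")
    orig, repro = pair.original.effect, pair.reproduction.effect
    d = signed_log_difference(orig, repro)
    have_cis = orig.has_ci and repro.has_ci
    p_o, src_o = _p_with_provenance(orig)
    p_r, src_r = _p_with_provenance(repro)
    t1, t2 = log_diff_thresholds
    return ConcordanceRow(
        study_id=pair.study_id,
        rel_magnitude=relative_magnitude(orig, repro),
        abs_log_diff=abs(d),
        signed_log_diff=d,
        within_01=abs(d) <= t1,
        within_02=abs(d) <= t2,
        repro_closer_to_null=closer_to_null(orig, repro).value,
        same_side_of_null=same_side_of_null(orig, repro),
        both_est_and_ci_same_side=(
            same_side_of_null(orig, repro, require_ci=True) if have_cis else None
        ),
        ci_overlap=ci_overlap(orig, repro) if have_cis else None,
        signif_discordant=(
            significance_discordance(p_o, p_r) if p_o is not None and p_r is not None else None
        ),
        p_original=p_o,
        p_reproduction=p_r,
        p_diff=(p_o - p_r) if p_o is not None and p_r is not None else None,
        p_original_source=src_o,
        p_reproduction_source=src_r,
    )


def concordance_table(
    pairs: Sequence[StudyPair],
    log_diff_thresholds=(0.1, 0.2),
) -> tuple[list[ConcordanceRow], list[tuple[str, str]]]:
    """One :class:`ConcordanceRow` per comparative pair.

    Descriptive pairs are skipped with a logged notice; a failing pair yields
    a (study_id, message) error entry rather than aborting the table.
    """
    rows: list[ConcordanceRow] = []
    errors: list[tuple[str, str]] = []
    for pair in pairs:
        if pair.design is Design.descriptive:
            logger.info("skipping descriptive study %s (no measure of association)", pair.study_id)
            continue
        try:
            rows.append(concordance_row(pair, log_diff_thresholds))
        except ValueError as exc:
            errors.append((pair.study_id, str(exc)))
    return rows, errors
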