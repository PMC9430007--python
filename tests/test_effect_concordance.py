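"""Per-study effect-concordance metrics: examples, hand oracles, invariants."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from rwerepro.effect_concordance import (
    CloserToNull,
    abs_log_difference,
    ci_overlap,
    closer_to_null,
    concordance_row,
    concordance_table,
    p_from_estimate,
    relative_magnitude,
    same_side_of_null,
    signed_log_difference,
    significance_discordance,
)
from rwerepro.records_io import EffectEstimate

from conftest import estimate_with_se, make_estimate, make_pair

points = st.floats(min_value=0.05, max_value=20.0, allow_nan=False)


def est(p, lo=None, hi=None, pv=None):
    return make_estimate(p, lo, hi, pv)


@pytest.mark.parametrize(
    "orig, repro, expected",
    [((2.0, 2.0), None, 1.0), ((1.2, 2.0), None, 0.6), ((0.9, 0.3), None, 3.0)],
)
def test_relative_magnitude_examples(orig, repro, expected):
    assert relative_magnitude(est(orig[0]), est(orig[1])) == pytest.approx(expected)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (1.5, 1.5, 0.0),
        (math.e**0.2, 1.0, 0.2),
        (0.8, 1.25, 0.4462871026284195),  # |ln 0.8 - ln 1.25| by hand
    ],
)
def test_abs_log_difference_examples(a, b, expected):
    assert abs_log_difference(est(a), est(b)) == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(points, points)
def test_relative_magnitude_reciprocal_symmetry(a, b):
    assert relative_magnitude(est(a), est(b)) * relative_magnitude(est(b), est(a)) == pytest.approx(1.0)


@settings(derandomize=True, max_examples=200)
@given(points, points, points)
def test_abs_log_difference_is_a_metric(a, b, c):
    """Symmetry, identity of indiscernibles, and the triangle inequality."""
    dab = abs_log_difference(est(a), est(b))
    assert dab == abs_log_difference(est(b), est(a))
    assert abs_log_difference(est(a), est(a)) == 0.0
    assert dab <= abs_log_difference(est(a), est(c)) + abs_log_difference(est(c), est(b)) + 1e-12


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (0.5, 0.8, CloserToNull.reproduction_closer),
        (1.1, 0.9, CloserToNull.original_closer),  # |ln 1.1| = 0.0953 < |ln 0.9| = 0.1054
        (2.0, 0.5, CloserToNull.tie),  # symmetric around the null
    ],
)
def test_closer_to_null(a, b, expected):
    assert closer_to_null(est(a), est(b)) is expected


def test_nonpositive_point_rejected_at_construction():
    with pytest.raises(ValueError):
        EffectEstimate(point=0.0)
    with pytest.raises(ValueError):
        EffectEstimate(point=-1.2)


def test_same_side_of_null_points_only():
    assert same_side_of_null(est(1.4), est(1.1)) is True
    assert same_side_of_null(est(1.4), est(0.9)) is False


def test_same_side_of_null_with_ci():
    # second CI spans 1.0 -> fails the CI-exclusion requirement
    assert same_side_of_null(est(1.4, 1.1, 1.8), est(1.1, 0.9, 1.3), require_ci=True) is False
    # both CIs entirely below 1.0
    assert same_side_of_null(est(0.7, 0.5, 0.9), est(0.8, 0.6, 0.95), require_ci=True) is True
    with pytest.raises(ValueError):
        same_side_of_null(est(1.4), est(1.1), require_ci=True)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((0.5, 0.9), (0.9, 1.3), True),  # touching endpoints overlap
        ((0.5, 0.8), (0.9, 1.3), False),
        ((0.5, 2.0), (0.9, 1.1), True),  # nesting
    ],
)
def test_ci_overlap(a, b, expected):
    assert ci_overlap(est((a[0] + a[1]) / 2, *a), est((b[0] + b[1]) / 2, *b)) is expected


@pytest.mark.parametrize(
    "p_o, p_r, expected",
    [(0.005, 0.20, True), (0.03, 0.06, False), (0.50, 0.008, True)],
)
def test_significance_discordance(p_o, p_r, expected):
    assert significance_discordance(p_o, p_r) is expected
    assert significance_discordance(p_r, p_o) is expected  # symmetric


def test_significance_discordance_rejects_out_of_range():
    with pytest.raises(ValueError):
        significance_discordance(1.2, 0.5)


def test_p_from_estimate_null_point_gives_one():
    assert p_from_estimate(est(1.0, 0.8, 1.25)) == pytest.approx(1.0)


def test_p_from_estimate_hand_computation():
    # se = (ln 2.23 - ln 1.01) / (2 * 1.959964); z = ln 1.5 / se; p = 2 (1 - Phi)
    assert p_from_estimate(est(1.5, 1.01, 2.23)) == pytest.approx(0.04478366538341331, rel=1e-9)


def test_p_from_estimate_tight_ci_tiny_p():
    assert p_from_estimate(est(2.0, 1.9, 2.1)) < 1e-10


def test_p_from_estimate_degenerate_ci():
    with pytest.raises(ValueError):
        p_from_estimate(est(1.0, 1.0, 1.0))


def test_identical_pair_row_is_perfect():
    e = est(1.5, 1.2, 1.9, 0.003)
    row = concordance_row(make_pair("X", orig_effect=e, repro_effect=e.model_copy()))
    assert row.rel_magnitude == pytest.approx(1.0)
    assert row.abs_log_diff == 0.0
    assert row.within_01 and row.within_02
    assert row.repro_closer_to_null == "tie"
    assert row.same_side_of_null and row.both_est_and_ci_same_side and row.ci_overlap
    assert row.signif_discordant is False
    assert row.p_diff == 0.0


def test_within_01_implies_within_02_and_swap_symmetry():
    o = estimate_with_se(0.30, 0.12)
    r = estimate_with_se(0.05, 0.15)
    row = concordance_row(make_pair("A", orig_effect=o, repro_effect=r))
    swapped = concordance_row(make_pair("A", orig_effect=r, repro_effect=o))
    if row.within_01:
        assert row.within_02
    assert swapped.signed_log_diff == pytest.approx(-row.signed_log_diff)
    assert swapped.abs_log_diff == pytest.approx(row.abs_log_diff)
    assert swapped.ci_overlap == row.ci_overlap
    assert swapped.same_side_of_null == row.same_side_of_null


def test_concordance_table_skips_descriptive_and_counts_rows(identical_pairs):
    descriptive = make_pair("D1", orig_ns=(300,), repro_ns=(250,), design="descriptive")
    rows, errors = concordance_table(identical_pairs + [descriptive])
    assert len(rows) == 5
    assert not errors
    assert {r.study_id for r in rows} == {p.study_id for p in identical_pairs}


def test_concordance_table_matches_cellwise_recomputation(identical_pairs):
    """Every cell equals a direct recomputation from the raw estimate fields."""
    import numpy as np
    from scipy.stats import norm

    rng = np.random.default_rng(3)
    pairs = []
    for i in range(8):
        o = estimate_with_se(rng.normal(0, 0.5), rng.uniform(0.05, 0.3))
        r = estimate_with_se(rng.normal(0, 0.5), rng.uniform(0.05, 0.3))
        pairs.append(make_pair(f"R{i}", orig_effect=o, repro_effect=r))
    rows, _ = concordance_table(pairs)
    z975 = norm.ppf(0.975)
    for row, p in zip(rows, pairs):
        o, r = p.original.effect, p.reproduction.effect
        lo, lr = math.log(o.point), math.log(r.point)
        assert row.rel_magnitude == pytest.approx(o.point / r.point)
        assert row.signed_log_diff == pytest.approx(lo - lr)
        assert row.within_01 == (abs(lo - lr) <= 0.1)
        assert row.within_02 == (abs(lo - lr) <= 0.2)
        assert row.same_side_of_null == ((lo > 0) == (lr > 0))
        assert row.ci_overlap == (o.ci_low <= r.ci_high and r.ci_low <= o.ci_high)
        for estimate, got in ((o, row.p_original), (r, row.p_reproduction)):
            se = (math.log(estimate.ci_high) - math.log(estimate.ci_low)) / (2 * z975)
            assert got == pytest.approx(2 * norm.sf(abs(math.log(estimate.point)) / se))
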