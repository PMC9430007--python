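"""Portfolio agreement statistics against brute-force oracles and invariants."""

import math

import numpy as np
import pytest
from scipy import stats

from rwerepro.agreement_stats import (
    UndefinedCorrelationError,
    bland_altman,
    icc_oneway,
    ivw_weights,
    pair_ivw_weights,
    subgroup_variation,
    summarize,
    top_outliers,
    weighted_pearson,
    weighted_spearman,
)
from rwerepro.effect_concordance import concordance_table

from conftest import estimate_with_se, make_estimate, make_pair


# --- inverse-variance weights ----------------------------------------------

def test_ivw_weight_hand_value():
    # CI spanning exactly 2 * 1.959964 * 0.1 on the log scale -> se 0.1 -> w 100
    e = make_estimate(math.exp(0.0), 1.0, 1.4799270513132077)
    with pytest.raises(ValueError):
        ivw_weights([make_estimate(1.0, 1.0, 1.0)])  # degenerate CI
    assert ivw_weights([e])[0] == pytest.approx(100.0, rel=1e-6)


def test_ivw_equal_log_widths_give_equal_weights():
    es = [estimate_with_se(mu, 0.2) for mu in (-0.5, 0.0, 0.8)]
    w = ivw_weights(es)
    assert np.allclose(w, w[0])


def test_pair_ivw_variants():
    orig = [estimate_with_se(0.0, 0.1), estimate_with_se(0.2, 0.2)]
    repro = [estimate_with_se(0.0, 0.3), estimate_with_se(0.2, 0.1)]
    combined = pair_ivw_weights(orig, repro)
    assert combined[0] == pytest.approx(1 / (0.01 + 0.09), rel=1e-6)
    original_only = pair_ivw_weights(orig, repro, variant="original")
    assert original_only[0] == pytest.approx(100.0, rel=1e-6)


# --- weighted correlations --------------------------------------------------

def _pearson_direct(x, y, w):
    """Direct-summation oracle for the weighted Pearson correlation."""
    xb = sum(wi * xi for wi, xi in zip(w, x)) / sum(w)
    yb = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    num = sum(wi * (xi - xb) * (yi - yb) for wi, xi, yi in zip(w, x, y))
    den = math.sqrt(
        sum(wi * (xi - xb) ** 2 for wi, xi in zip(w, x))
        * sum(wi * (yi - yb) ** 2 for wi, yi in zip(w, y))
    )
    return num / den


def test_weighted_pearson_equal_weights_matches_textbook():
    rng = np.random.default_rng(11)
    for _ in range(20):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r = weighted_pearson(x, y, np.ones(10))
        assert r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)


def test_weighted_pearson_perfect_linearity():
    x = np.array([0.1, 0.7, 1.3, 2.0, 5.0])
    w = np.array([1.0, 2.0, 0.5, 4.0, 1.5])
    assert weighted_pearson(x, 2 * x + 1, w) == pytest.approx(1.0)


def test_weighted_pearson_five_point_fixture_vs_oracle():
    x = [0.2, -0.4, 1.1, 0.6, -1.0]
    y = [0.3, -0.2, 0.9, 0.9, -1.2]
    w = [1.0, 3.0, 0.5, 2.0, 1.2]
    assert weighted_pearson(x, y, w) == pytest.approx(_pearson_direct(x, y, w), abs=1e-12)


def test_weighted_pearson_errors():
    with pytest.raises(UndefinedCorrelationError):
        weighted_pearson([1, 1, 1], [1, 2, 3], [1, 1, 1])
    with pytest.raises(ValueError):
        weighted_pearson([1, 2], [1, 2], [1, 1])
    with pytest.raises(ValueError):
        weighted_pearson([1, 2, 3], [1, 2, 3], [1, -1, 1])


def test_weighted_spearman_monotone_and_reversed():
    x = np.array([0.1, 0.5, 1.2, 2.0, 3.3])
    w = np.ones(5)
    assert weighted_spearman(x, np.exp(x), w) == pytest.approx(1.0)
    assert weighted_spearman(x, -x, w) == pytest.approx(-1.0)


def test_weighted_spearman_ties_vs_midrank_oracle():
    """Mid-ranks computed by enumeration, then the weighted Pearson oracle."""
    x = [1.0, 2.0, 2.0, 3.0, 4.0]
    y = [5.0, 5.0, 7.0, 8.0, 8.0]
    w = [1.0, 2.0, 1.5, 0.5, 1.0]

    def midranks(v):
        out = []
        for vi in v:
            less = sum(1 for u in v if u < vi)
            equal = sum(1 for u in v if u == vi)
            out.append(less + (equal + 1) / 2)
        return out

    expected = _pearson_direct(midranks(x), midranks(y), w)
    assert weighted_spearman(x, y, w) == pytest.approx(expected, abs=1e-12)


# --- intraclass correlation --------------------------------------------------

def _icc1_anova_oracle(pairs):
    """One-way ANOVA by explicit sums of squares (subjects = rows, k = 2)."""
    arr = np.asarray(pairs, float)
    n, k = arr.shape
    grand = arr.mean()
    ss_between = k * sum((row.mean() - grand) ** 2 for row in arr)
    ss_within = sum((v - row.mean()) ** 2 for row in arr for v in row)
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


SIX_PAIRS = [(0.1, 0.2), (-0.4, -0.3), (0.9, 1.1), (0.0, -0.2), (0.5, 0.4), (-1.0, -0.8)]


def test_icc_six_pair_fixture_vs_anova_oracle():
    icc, _ = icc_oneway(SIX_PAIRS)
    assert icc == pytest.approx(_icc1_anova_oracle(SIX_PAIRS), abs=1e-12)


def test_icc_against_pingouin_icc1():
    """Cross-check estimate and CI against an independent implementation."""
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(5)
    subject_effect = rng.normal(0, 1, size=30)
    arr = np.column_stack([subject_effect + rng.normal(0, 0.4, 30) for _ in range(2)])
    icc, (lo, hi) = icc_oneway(arr)
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(30), 2),
            "rater": np.tile([0, 1], 30),
            "score": arr.ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    ref1 = ref[ref["Type"].isin(["ICC1", "ICC(1,1)"])].iloc[0]
    ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
    assert icc == pytest.approx(ref1["ICC"], abs=1e-9)
    assert lo == pytest.approx(ref1[ci_col][0], abs=6e-3)  # pingouin rounds to 2 dp
    assert hi == pytest.approx(ref1[ci_col][1], abs=6e-3)


def test_icc_perfect_agreement():
    pairs = [(x, x) for x in (-0.5, 0.1, 0.4, 1.2)]
    icc, ci = icc_oneway(pairs)
    assert icc == 1.0 and ci == (1.0, 1.0)


def test_icc_independent_coordinates_near_zero():
    rng = np.random.default_rng(12)
    arr = rng.normal(size=(4000, 2))
    icc, _ = icc_oneway(arr)
    assert abs(icc) < 0.05  # ~3 Monte Carlo SEs at n = 4000


def test_icc_monotone_in_added_noise():
    rng = np.random.default_rng(4)
    base = rng.normal(0, 1, size=600)
    iccs = []
    for noise_sd in (0.01, 0.2, 0.6, 1.5):
        arr = np.column_stack(
            [base + rng.normal(0, noise_sd, 600), base + rng.normal(0, noise_sd, 600)]
        )
        iccs.append(icc_oneway(arr)[0])
    assert iccs[0] > 0.99
    assert all(a > b for a, b in zip(iccs, iccs[1:]))


def test_icc_all_identical_undefined():
    with pytest.raises(ValueError):
        icc_oneway([(1.0, 1.0)] * 5)


# --- Bland-Altman -------------------------------------------------------------

def test_bland_altman_all_zero_diffs():
    ba = bland_altman([(0.3, 0.3), (-0.2, -0.2), (0.9, 0.9)])
    assert ba.mean_diff == 0.0 and ba.sd_diff == 0.0
    assert ba.lower_limit == ba.upper_limit == 0.0
    assert ba.outside_limits == []


def test_bland_altman_hand_computation():
    # diffs {-1, +1}: mean 0, sample sd sqrt(2), limits +/- 2 sqrt(2)
    ba = bland_altman([(0.0, 1.0), (1.0, 0.0)])
    assert ba.mean_diff == 0.0
    assert ba.sd_diff == pytest.approx(math.sqrt(2))
    assert ba.upper_limit == pytest.approx(2 * math.sqrt(2))
    assert ba.lower_limit == pytest.approx(-2 * math.sqrt(2))


def test_bland_altman_translation_property():
    rng = np.random.default_rng(2)
    pairs = rng.normal(size=(20, 2))
    shifted = pairs.copy()
    shifted[:, 0] += 0.7
    a, b = bland_altman(pairs), bland_altman(shifted)
    assert b.mean_diff == pytest.approx(a.mean_diff + 0.7)
    assert b.sd_diff == pytest.approx(a.sd_diff)


def test_bland_altman_limits_cover_about_95_percent():
    rng = np.random.default_rng(9)
    diffs = rng.normal(0.1, 0.3, size=2000)
    pairs = np.column_stack([diffs, np.zeros(2000)])
    ba = bland_altman(pairs)
    frac_out = len(ba.outside_limits) / 2000
    # +/- 2 SD keeps ~95.4% inside; binomial 3-sigma band around 0.046
    assert frac_out == pytest.approx(0.0455, abs=0.015)


# --- outlier ranking ----------------------------------------------------------

def _rows_from_log_diffs(diffs):
    pairs = [
        make_pair(f"S{i}", orig_effect=estimate_with_se(d, 0.1), repro_effect=estimate_with_se(0.0, 0.1))
        for i, d in enumerate(diffs)
    ]
    return concordance_table(pairs)[0]


def test_top_outliers_ranking_and_ties():
    rows = _rows_from_log_diffs([0.5, 0.1, 0.5, 0.9])
    assert top_outliers(rows, 4) == ["S3", "S0", "S2", "S1"]
    assert top_outliers(rows, 1) == ["S3"]
    # tie at rank 2: lexicographically smaller id (S0) included
    assert top_outliers(rows, 2) == ["S3", "S0"]
    with pytest.raises(ValueError):
        top_outliers(rows, 5)


# --- summarize ----------------------------------------------------------------

def test_summarize_identical_pairs_perfect(identical_pairs):
    rows, _ = concordance_table(identical_pairs)
    ests = [(p.original.effect, p.reproduction.effect) for p in identical_pairs]
    s = summarize(rows, ests)
    assert s.median_rel_magnitude == pytest.approx(1.0)
    assert s.prop_within_01 == s.prop_within_02 == 1.0
    assert s.prop_same_side == s.prop_ci_overlap == 1.0
    assert s.prop_signif_discordant == 0.0
    assert s.icc == pytest.approx(1.0)


def test_summarize_fields_vs_per_field_recomputation():
    """Every summary field equals an independent recomputation from the rows."""
    rng = np.random.default_rng(21)
    pairs = []
    for i in range(10):
        theta = rng.normal(0, 0.5)
        pairs.append(
            make_pair(
                f"P{i}",
                orig_effect=estimate_with_se(theta + rng.normal(0, 0.1), rng.uniform(0.08, 0.25), p_value=float(rng.uniform())),
                repro_effect=estimate_with_se(theta + rng.normal(0, 0.15), rng.uniform(0.08, 0.25), p_value=float(rng.uniform())),
            )
        )
    rows, _ = concordance_table(pairs)
    ests = [(p.original.effect, p.reproduction.effect) for p in pairs]
    s = summarize(rows, ests)

    lo = [math.log(o.point) for o, _ in ests]
    lr = [math.log(r.point) for _, r in ests]
    assert s.pearson_unweighted == pytest.approx(stats.pearsonr(lo, lr).statistic)
    assert s.spearman_unweighted == pytest.approx(stats.spearmanr(lo, lr).statistic)
    z = stats.norm.ppf(0.975)
    w = [
        1.0
        / (
            ((math.log(o.ci_high) - math.log(o.ci_low)) / (2 * z)) ** 2
            + ((math.log(r.ci_high) - math.log(r.ci_low)) / (2 * z)) ** 2
        )
        for o, r in ests
    ]
    assert s.pearson_ivw == pytest.approx(_pearson_direct(lo, lr, w))
    rel = sorted(r.rel_magnitude for r in rows)
    assert s.median_rel_magnitude == pytest.approx(np.quantile(rel, 0.5))
    assert s.iqr_rel_magnitude[0] == pytest.approx(np.quantile(rel, 0.25))
    assert s.range_rel_magnitude == (pytest.approx(rel[0]), pytest.approx(rel[-1]))
    assert s.prop_within_01 == sum(r.within_01 for r in rows) / 10
    assert s.prop_ci_overlap == sum(r.ci_overlap for r in rows) / 10
    assert s.prop_repro_closer_null == (
        sum(r.repro_closer_to_null == "reproduction_closer" for r in rows) / 10
    )
    same = [r for r in rows if r.same_side_of_null]
    assert s.mean_abs_log_diff_same_side == pytest.approx(
        np.mean([r.abs_log_diff for r in same])
    )
    assert s.denominators["within_01"] == 10


def test_summarize_permutation_invariance():
    rng = np.random.default_rng(31)
    pairs = [
        make_pair(
            f"Q{i}",
            orig_effect=estimate_with_se(rng.normal(0, 0.4), 0.12),
            repro_effect=estimate_with_se(rng.normal(0, 0.4), 0.12),
        )
        for i in range(8)
    ]
    rows, _ = concordance_table(pairs)
    ests = [(p.original.effect, p.reproduction.effect) for p in pairs]
    s1 = summarize(rows, ests)
    order = rng.permutation(8)
    s2 = summarize([rows[i] for i in order], [ests[i] for i in order])
    d1, d2 = s1.as_dict(), s2.as_dict()
    for key, v in d1.items():
        if isinstance(v, float):
            assert d2[key] == pytest.approx(v, abs=1e-12), key


# --- subgroup variation -------------------------------------------------------

def test_subgroup_identical_values_degenerate():
    rows = _rows_from_log_diffs([0.2, 0.2, 0.2, 0.2])
    table, f_stat, p, degenerate = subgroup_variation(
        rows, {"S0": "a", "S1": "a", "S2": "b", "S3": "b"}
    )
    assert degenerate and p == 1.0


def test_subgroup_two_groups_f_equals_t_squared():
    rows = _rows_from_log_diffs([0.1, 0.25, 0.4, 0.15, 0.3, 0.55])
    groups = {f"S{i}": ("a" if i < 3 else "b") for i in range(6)}
    _, f_stat, p, degenerate = subgroup_variation(rows, groups)
    a = [r.abs_log_diff for r in rows[:3]]
    b = [r.abs_log_diff for r in rows[3:]]
    t = stats.ttest_ind(a, b).statistic
    assert not degenerate
    assert f_stat == pytest.approx(t**2)


def test_subgroup_null_p_values_are_uniform():
    """Groups drawn from one distribution: ANOVA p ~ Uniform(0,1) (KS check)."""
    rng = np.random.default_rng(8)
    ps = []
    for _ in range(300):
        rows = _rows_from_log_diffs(rng.normal(0.3, 0.1, size=12))
        groups = {f"S{i}": ("a" if i < 6 else "b") for i in range(12)}
        ps.append(subgroup_variation(rows, groups)[2])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_subgroup_degenerate_grouping_rejected():
    rows = _rows_from_log_diffs([0.1, 0.2, 0.3])
    with pytest.raises(ValueError):
        subgroup_variation(rows, {"S0": "a", "S1": "b", "S2": "b"})
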