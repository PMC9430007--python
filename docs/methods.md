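# Methods

This note documents the statistical definitions, conventions, and modelling
choices behind `rwerepro`, and what the synthetic-data tests do and do not
establish about real reproduction portfolios.

## Setting and data model

The unit of analysis is a *study pair*: a published database (claims/EHR)
study and an independent reproduction of it on the same source data.  A pair
carries a design label (comparative vs descriptive), per-arm cohort results
(subjects, events, outcome risk in percent, outcome rate per 100
person-years, person-time) for both sides, a ratio-scale measure of
association (HR/RR/OR) with 95% CI and optional p-value for comparative
studies, and subgroup attributes (funding source, data source, publication
year, journal impact band, author responsiveness, same-group flag).

Three CSV tables carry a portfolio: `studies.csv` (one row per study arm,
study-level columns repeated and checked for consistency, reference arm last
and flagged), `covariates.csv` (study × covariate × arm prevalences in
percent), `checklist.csv` (study × 54 item responses plus per-category
assumption flags).  Absent numbers are empty strings — absence is meaningful
and never conflated with 0.  Effects are stored on the ratio scale; logs are
taken at computation time.  Readers are total: every row ends in the record
list or a rejection report carrying the violated invariant.  A YAML mapping
file can rename foreign columns and declare source rate units
(per 1,000 person-years etc.), which are rescaled to per-100-py on read.

## Per-study effect concordance

All effect comparisons happen on the natural-log scale with the null at 1.0
(0 on the log scale).  For original and reproduction estimates ES_o, ES_r:

* relative magnitude ES_o/ES_r; signed log difference log ES_o − log ES_r;
  absolute log difference with inclusive flags at ≤ 0.1 and ≤ 0.2;
* closer-to-null compares |log ES_r| against |log ES_o|; ties are declared
  only below 1e-12 (strict comparison otherwise — on continuous estimates a
  tie is a measure-zero event);
* same-side-of-null compares signs of the log points; the CI-strengthened
  variant additionally requires both CIs to exclude 1.0 strictly on that
  side;
* CI overlap uses closed intervals — touching endpoints count as overlap
  (conservative toward agreement);
* significance discordance is (p_r > 0.05 and p_o ≤ 0.01) or vice versa;
  both thresholds sit in `AnalysisConfig`.

When a publication prints no p-value, a two-sided normal-approximation
p-value is derived from the CI: se = (log U − log L)/(2 z₀.₉₇₅),
z = log(point)/se, p = 2(1 − Φ(|z|)).  Each row carries a provenance flag
(`reported` vs `from_ci`); derived p-values are an approximation, and
whether originals used one- or two-sided tests is unknowable from the
tables, so two-sided is the fixed convention.

## Portfolio agreement statistics

Correlations and the ICC are computed on log effects.  The weighted Pearson
uses weighted means and weighted central second moments; the weighted
Spearman is the weighted Pearson applied to mid-ranks (average ranks on
ties) — whether a rank correlation should weight ranks or rank the weighted
data is genuinely open, and this choice is flagged as an assumption.  The
inverse-variance weight of a pair is 1/(se_o² + se_r²) (pair-level
precision) by default, with 1/se_o² as a configurable alternative, since the
variance used by the published analysis is not identifiable from its text.

The ICC is the one-way random-effects ICC(1), treating original and
reproduction as two interchangeable measurements of one study (no rater
effect): ICC = (MSB − MSW)/(MSB + MSW) for k = 2, with the F-based CI using
upper-tail F quantiles at α/2 (F_L = F/F₀.₉₇₅;n−1,n, F_U = F·F₀.₉₇₅;n,n−1).
The variant is a deliberate default: an ordered-rater ICC(A,1) would model a
systematic original-vs-reproduction effect the portfolio design does not
assume.

Bland–Altman limits sit at mean ± **2** × sample SD (n−1 denominator) of the
log-effect differences — 2 by convention here, not 1.96.  Quantiles
throughout use linear interpolation (numpy default, R type 7); this matters
because IQR endpoints are reported numbers.  Outlier ranking orders studies
by descending |Δ log|, ties broken by lexicographic study id.  Proportions
are taken over non-missing denominators, and every denominator is reported
alongside the summary.

Subgroup exploration runs a classical one-way ANOVA of |Δ log| across
attribute-defined groups (≥2 groups with ≥2 members), deliberately without
multiple-testing adjustment — it is a descriptive variance-in-means scan,
not confirmatory inference.  A degenerate ANOVA (all values identical) is
reported as F = 0, p = 1 with a flag.

## Cohort concordance

Relative sample size is N_o/N_r with sizes summed over compared exposure
groups; the extreme flag marks ratios strictly below 1/2 or above 2.
Prevalence, risk and rate differences are original − reproduction in
percentage points (rates per 100 person-years, rescaled from source units
when a mapping declares them).  Large-difference flags are strict > 10 in
the respective unit; a difference of exactly 10 is not flagged.  Comparative
studies contribute one risk/rate difference per arm, descriptive studies one
overall.

## Reporting clarity

Responses are reported / partially reported / not reported / not applicable
per item; per-item proportions divide reported by (n − not applicable).
`partially_reported` counts as *not* reported for headline proportions (the
conservative reading; switchable).  Assumption counts range 0..6 for
comparative and 0..5 for descriptive studies (no exposure category).  The
item-to-category mapping is data, not code: `data/items_synthetic.yaml` is a
constructed stand-in instrument with schematic item texts in the structure
of the consensus reporting checklist; replace it to score the real form.

## Synthetic portfolios

The generator emulates the structure a reproduction portfolio exhibits, at
the summary-statistic level the pipeline consumes (no individual-level
claims are simulated):

* true log effect θ_i ~ N(μ_θ, τ²) shared by both sides;
* sampling se per study from arm event counts, σ_i = √(1/e₁ + 1/e₀); a
  fraction f (`shared_error_fraction`) of the sampling variance is a common
  draw (both teams analyse the same patients), the rest independent:
  log ES_o = θ + ε_s + ε_o, log ES_r = θ + δ + ε_s + ε_r;
* implementation discrepancy δ_i from a two-component normal mixture
  (probability π_big of sd ω_big, else ω_small) — frequent small deviations
  from ambiguous parameters, rare large ones from misread designs;
* cohort-size ratio log-normal (sd `size_ratio_logsd`); reproduction events
  scale with the cohort plus small noise;
* with probability `dataversion_shift_prob` the reproduction's outcome
  rates shift upward by a uniform draw from `rate_shift_band` (13–16 per
  100 py by default), implemented by adding events so the tables stay
  internally consistent — mimicking retroactively updated source data;
* covariate prevalences perturbed by a small/large mixture; original
  p-values are masked (omitted) with probability 1 − `p_report_prob`;
* checklist responses drawn from per-item reporting probabilities in the
  item schema; assumption-category counts binomial with design-specific
  success probabilities.

All draws come from one seeded `numpy.random.default_rng` in a fixed
per-study order (effect block, arms, covariates; then the checklist), so a
seed determines the portfolio byte-for-byte.  The `paper_like` preset
(`data/paper_like.yaml`) fixes the study conditions: 118 comparative + 32
descriptive studies, τ = 0.35, event counts 50–500 (log-scale SEs roughly
0.06–0.2), f = 0.5, mixture (π = 0.07, ω_small = 0.15, ω_big = 0.55), size
ratio sd 0.5.  These were chosen from the closed-form relations between the
model parameters and the portfolio summaries (e.g. the unweighted Pearson is
approximately (τ² + fσ̄²)/√((τ² + σ̄²)(τ² + σ̄² + ω̄²)) ) so that a preset
portfolio lands in realistic neighbourhoods — near-unit median relative
magnitude, correlations in the mid-0.8s, high CI overlap.  The data-version
shift probability (0.05) is an assumption: no quantitative prevalence of
such events is established anywhere; treat it as a scenario knob.

What the generator does **not** emulate: confounding structure, real
between-covariate correlation, non-normal effect heterogeneity, selective
reporting correlated with effect size, or any dependence of discrepancy on
reporting clarity.  Green tests therefore certify the *metric machinery* and
its contracts, not any claim about real-world reproducibility rates.

### Parameter recovery

`recover_parameters` inverts the model by method of moments using only
observable quantities (paired log effects; σ_i from the original CI):

    Var(log ES_o)               = τ² + σ̄²
    Cov(log ES_o, log ES_r)     = τ² + f σ̄²
    Var(log ES_r − log ES_o)    = ω² + 2(1 − f) σ̄²

solved in that order, with negative variance estimates truncated at 0 and f
clipped to [0, 1].  ω is the *marginal* sd of the discrepancy mixture,
√(π ω_big² + (1 − π) ω_small²): the individual mixture components are not
identified from second moments, and higher-moment estimators are too noisy
at realistic n to be useful, so recovery targets the marginal.  SEs come
from a nonparametric bootstrap over studies (200 resamples).  At n = 2,000
studies each recovered parameter lands within ~3 bootstrap SEs of truth; the
whole recovery takes about a second.

## Problem sizes and numerical conventions

The test suite runs portfolios of 5–40 studies for contract tests and 2,000
for moment-recovery and mixture-calibration checks; the acceptance script
uses the 150-study preset plus one 2,000-study recovery portfolio.  CSV
floats are written with shortest round-trip `repr`, so write∘read is the
identity on records and write∘read∘write is byte-identical.  Degenerate
cases are defined explicitly: identical-value ICC is an error (0/0), a
degenerate CI (U = L) is a domain error, zero-variance correlations raise,
and single-study portfolios produce figures but no summary (which needs
n ≥ 3).

## Known limitations

* Difference-scale measures of association (risk differences as the primary
  effect) are out of scope; the effect suite assumes ratio-scale estimates.
* Derived p-values inherit the normal approximation of the CI; for very
  small event counts the printed CI may itself be asymmetric on the log
  scale, and the approximation degrades.
* The IVW weighting variant and the weighted-Spearman construction are
  assumptions (documented above) — alternatives are configurable, and
  portfolio-level conclusions should be checked under both.
* The checklist schema is a synthetic stand-in; per-item results are only
  meaningful relative to whatever instrument file is supplied.
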