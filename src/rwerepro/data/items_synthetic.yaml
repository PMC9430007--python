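# Synthetic stand-in for the 54-item reporting-clarity extraction form.
# The published instrument's exact wording lives in restricted supplementary
# material; this schema mirrors its structure (six study-parameter categories
# plus general transparency items) with schematic item texts.  The mapping is
# versioned data: edit or replace this file to adapt the instrument.
#
# Fields: id, text, category (index_date | inclusion_exclusion | exposure |
# outcome | follow_up | covariates | general), applies_to (both |
# comparative), report_prob (plausible marginal probability that a sampled
# publication reports the item; used only by the synthetic-data generator).
version: 1
items:
  - {id: 1, text: "Criterion defining the cohort entry (index) date", category: index_date, applies_to: both, report_prob: 0.89}
  - {id: 2, text: "Temporal order of index-defining events when multiple qualify", category: index_date, applies_to: both, report_prob: 0.45}
  - {id: 3, text: "Handling of multiple eligible index dates per patient", category: index_date, applies_to: both, report_prob: 0.50}
  - {id: 4, text: "Calendar window for cohort entry", category: index_date, applies_to: both, report_prob: 0.85}
  - {id: 5, text: "Washout window length anchored to the index date", category: index_date, applies_to: both, report_prob: 0.60}
  - {id: 6, text: "Care settings eligible to define the index event", category: index_date, applies_to: both, report_prob: 0.55}
  - {id: 7, text: "Complete list of inclusion criteria", category: inclusion_exclusion, applies_to: both, report_prob: 0.80}
  - {id: 8, text: "Complete list of exclusion criteria", category: inclusion_exclusion, applies_to: both, report_prob: 0.78}
  - {id: 9, text: "Assessment windows for each inclusion-exclusion criterion", category: inclusion_exclusion, applies_to: both, report_prob: 0.40}
  - {id: 10, text: "Whether criteria are applied before or after index selection", category: inclusion_exclusion, applies_to: both, report_prob: 0.35}
  - {id: 11, text: "Clinical code lists for inclusion-exclusion criteria", category: inclusion_exclusion, applies_to: both, report_prob: 0.38}
  - {id: 12, text: "Care setting and diagnosis position for eligibility codes", category: inclusion_exclusion, applies_to: both, report_prob: 0.33}
  - {id: 13, text: "Continuous-enrollment requirement before index", category: inclusion_exclusion, applies_to: both, report_prob: 0.65}
  - {id: 14, text: "Allowed enrollment gaps when defining continuous coverage", category: inclusion_exclusion, applies_to: both, report_prob: 0.25}
  - {id: 15, text: "Age and sex restrictions with measurement date", category: inclusion_exclusion, applies_to: both, report_prob: 0.85}
  - {id: 16, text: "Handling of patients qualifying for both exposure groups", category: inclusion_exclusion, applies_to: comparative, report_prob: 0.45}
  - {id: 17, text: "Operational definition of the exposure of interest", category: exposure, applies_to: comparative, report_prob: 0.82}
  - {id: 18, text: "Operational definition of the comparator", category: exposure, applies_to: comparative, report_prob: 0.75}
  - {id: 19, text: "Drug code lists (NDC/ATC/other) for exposure", category: exposure, applies_to: comparative, report_prob: 0.50}
  - {id: 20, text: "Algorithm for exposure duration from days supply", category: exposure, applies_to: comparative, report_prob: 0.45}
  - {id: 21, text: "Handling of overlapping fills or early refills", category: exposure, applies_to: comparative, report_prob: 0.30}
  - {id: 22, text: "Grace period or extension beyond days supply", category: exposure, applies_to: comparative, report_prob: 0.40}
  - {id: 23, text: "Stockpiling rule for switching and discontinuation", category: exposure, applies_to: comparative, report_prob: 0.28}
  - {id: 24, text: "Exposure risk-window relative to follow-up", category: exposure, applies_to: comparative, report_prob: 0.50}
  - {id: 25, text: "Handling of exposure changes during follow-up", category: exposure, applies_to: comparative, report_prob: 0.48}
  - {id: 26, text: "New-user versus prevalent-user specification", category: exposure, applies_to: comparative, report_prob: 0.70}
  - {id: 27, text: "Operational algorithm for the primary outcome", category: outcome, applies_to: both, report_prob: 0.80}
  - {id: 28, text: "Clinical code list for the outcome", category: outcome, applies_to: both, report_prob: 0.62}
  - {id: 29, text: "Care setting for outcome ascertainment", category: outcome, applies_to: both, report_prob: 0.58}
  - {id: 30, text: "Diagnosis position (primary vs any) for outcome codes", category: outcome, applies_to: both, report_prob: 0.42}
  - {id: 31, text: "Citation to a validation study for the outcome algorithm", category: outcome, applies_to: both, report_prob: 0.45}
  - {id: 32, text: "Consistency between cited validation and implemented algorithm", category: outcome, applies_to: both, report_prob: 0.30}
  - {id: 33, text: "Outcome washout (incident-outcome) requirement", category: outcome, applies_to: both, report_prob: 0.40}
  - {id: 34, text: "Handling of same-day index and outcome events", category: outcome, applies_to: both, report_prob: 0.20}
  - {id: 35, text: "Death ascertainment source and completeness", category: outcome, applies_to: both, report_prob: 0.35}
  - {id: 36, text: "Definition of composite outcome components", category: outcome, applies_to: both, report_prob: 0.55}
  - {id: 37, text: "Start of follow-up relative to index", category: follow_up, applies_to: both, report_prob: 0.72}
  - {id: 38, text: "Censoring criteria and their order of precedence", category: follow_up, applies_to: both, report_prob: 0.52}
  - {id: 39, text: "Maximum follow-up duration or administrative end", category: follow_up, applies_to: both, report_prob: 0.60}
  - {id: 40, text: "Induction or latency period excluded from follow-up", category: follow_up, applies_to: both, report_prob: 0.35}
  - {id: 41, text: "As-treated versus intention-to-treat follow-up", category: follow_up, applies_to: comparative, report_prob: 0.58}
  - {id: 42, text: "Handling of disenrollment during follow-up", category: follow_up, applies_to: both, report_prob: 0.45}
  - {id: 43, text: "Complete list of adjustment covariates", category: covariates, applies_to: comparative, report_prob: 0.75}
  - {id: 44, text: "Assessment window for each covariate", category: covariates, applies_to: both, report_prob: 0.43}
  - {id: 45, text: "Clinical code lists for covariate algorithms", category: covariates, applies_to: both, report_prob: 0.30}
  - {id: 46, text: "Care setting for covariate measurement", category: covariates, applies_to: both, report_prob: 0.28}
  - {id: 47, text: "Modifications to published comorbidity scores", category: covariates, applies_to: both, report_prob: 0.25}
  - {id: 48, text: "Confounder-adjustment method (matching, weighting, model)", category: covariates, applies_to: comparative, report_prob: 0.82}
  - {id: 49, text: "Attrition table or flow diagram of cohort counts", category: general, applies_to: both, report_prob: 0.54}
  - {id: 50, text: "Study design diagram with temporal anchors", category: general, applies_to: both, report_prob: 0.08}
  - {id: 51, text: "Analytic code, macros, or procedures referenced", category: general, applies_to: both, report_prob: 0.07}
  - {id: 52, text: "Software and version used for analysis", category: general, applies_to: both, report_prob: 0.35}
  - {id: 53, text: "Source data version or extraction date", category: general, applies_to: both, report_prob: 0.05}
  - {id: 54, text: "Calendar range of source data actually used", category: general, applies_to: both, report_prob: 0.75}
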