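"""Synthetic paired-study portfolios with known ground truth.

Real reproduction portfolios are built from restricted claims/EHR data, so
the pipeline is exercised on simulated portfolios that emulate the
statistical structure the analysis assumes:

* a shared true log effect theta_i ~ Normal(mu_theta, tau^2) per comparative
  study, estimated twice from the same source data;
* correlated sampling errors — a fraction ``shared_error_fraction`` of the
  sampling variance is common to the original and the reproduction (both
  analyses draw on the same underlying patients);
* an implementation-discrepancy term delta_i added to the reproduction,
  drawn from a two-component normal mixture (frequent small deviations from
  ambiguous parameters, rare large ones from misunderstood designs);
* occasional data-version shift events that raise the reproduction's
  outcome rates by a uniform draw from ``rate_shift_band`` per 100
  person-years (retroactively updated source data);
* cohort-size ratios log-normal around parity, baseline-covariate prevalence
  perturbations from a small/large mixture, and reporting-omission masks on
  printed p-values.

The sampling standard error per study comes from arm event counts,
se = sqrt(1/e_exposed + 1/e_reference) (the usual log-ratio approximation).
All draws come from one seeded generator in a fixed stream order, so a seed
fully determines the portfolio.  ``TruthLedger`` records every latent draw.

``SimConfig.paper_like()`` loads the packaged preset emulating the study
conditions of a 150-study reproduction portfolio (118 comparative, 32
descriptive).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .effect_concordance import Z975, se_from_ci
from .records_io import (
    ArmResult,
    CovariateEntry,
    Design,
    EffectEstimate,
    Measure,
    StudyPair,
    StudyResult,
)
from .reporting_clarity import (
    CATEGORIES_COMPARATIVE,
    CATEGORIES_DESCRIPTIVE,
    ChecklistRecord,
    Response,
    load_items_schema,
)

__all__ = [
    "DiscrepancyMix",
    "CovariateShift",
    "SimConfig",
    "TruthLedger",
    "Portfolio",
    "generate_portfolio",
    "RecoveredParameters",
    "recover_parameters",
]


class DiscrepancyMix(BaseModel):
    """Two-component normal mixture for the implementation discrepancy delta."""

    pi_big: float = 0.07
    omega_small: float = 0.15
    omega_big: float = 0.55

    @model_validator(mode="after")
    def _check(self) -> "DiscrepancyMix":
        if not (0.0 <= self.pi_big <= 1.0):
            raise ValueError("pi_big must be a probability")
        if self.omega_small < 0 or self.omega_big < 0:
            raise ValueError("mixture sds must be nonnegative")
        if self.omega_small > self.omega_big:
            raise ValueError("omega_small must not exceed omega_big")
        return self

    @property
    def marginal_sd(self) -> float:
        """sd of the mixture marginal: sqrt(pi w_b^2 + (1-pi) w_s^2)."""
        return math.sqrt(
            self.pi_big * self.omega_big**2 + (1 - self.pi_big) * self.omega_small**2
        )


class CovariateShift(BaseModel):
    """Small/large mixture perturbing baseline-covariate prevalences (pct pts)."""

    sd_small: float = Field(default=2.2, ge=0)
    prob_large: float = Field(default=0.17, ge=0, le=1)
    magnitude_large: float = Field(default=18.0, ge=0)


class SimConfig(BaseModel):
    """Generator configuration; defaults are the paper-like preset values."""

    n_comparative: int = Field(default=118, ge=0)
    n_descriptive: int = Field(default=32, ge=0)
    mu_theta: float = 0.0
    tau: float = Field(default=0.35, ge=0)
    event_count_range: tuple[int, int] = (50, 500)
    shared_error_fraction: float = Field(default=0.5, ge=0, le=1)
    discrepancy_mix: DiscrepancyMix = Field(default_factory=DiscrepancyMix)
    size_ratio_logsd: float = Field(default=0.5, ge=0)
    dataversion_shift_prob: float = Field(default=0.05, ge=0, le=1)
    rate_shift_band: tuple[float, float] = (13.0, 16.0)
    covariate_shift: CovariateShift = Field(default_factory=CovariateShift)
    n_covariates: int = Field(default=8, ge=0)
    mean_followup_years: float = Field(default=1.5, gt=0)
    p_report_prob: float = Field(default=0.7, ge=0, le=1)
    assume_prob_comparative: float = Field(default=0.65, ge=0, le=1)
    assume_prob_descriptive: float = Field(default=0.6, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        lo, hi = self.event_count_range
        if not (0 < lo <= hi):
            raise ValueError("event_count_range must satisfy 0 < min <= max")
        lo, hi = self.rate_shift_band
        if not (0 <= lo <= hi):
            raise ValueError("rate_shift_band must satisfy 0 <= min <= max")
        return self

    @classmethod
    def paper_like(cls, seed: Optional[int] = None, **overrides) -> "SimConfig":
        """Load the packaged paper-like preset (optionally overriding fields)."""
        text = resources.files("rwerepro").joinpath("data/paper_like.yaml").read_text(
            encoding="utf-8"
        )
        values = yaml.safe_load(text)
        values.update(overrides)
        if seed is not None:
            values["seed"] = seed
        return cls(**values)


@dataclass
class TruthLedger:
    """Latent draws behind a generated portfolio; reproducible from the seed."""

    config: dict
    entries: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"config": self.config, "entries": self.entries}, fh, indent=1)


@dataclass
class Portfolio:
    studies: list[StudyPair]
    covariates: list[CovariateEntry]
    checklist: list[ChecklistRecord]
    ledger: TruthLedger


def _simulate_arms(rng, cfg: SimConfig, arm_specs, sid, ledger_entry):
    """Original and reproduction arms for one study.

    ``arm_specs`` is a list of (arm_id, is_reference, events_original).
    Returns (arms_original, arms_reproduction).
    """
    ratio = float(np.exp(rng.normal(0.0, cfg.size_ratio_logsd))) if cfg.size_ratio_logsd else 1.0
    shifted = bool(rng.random() < cfg.dataversion_shift_prob)
    ledger_entry["size_ratio_repro_over_original"] = ratio
    ledger_entry["dataversion_shift"] = shifted
    arms_o, arms_r = [], []
    for arm_id, is_ref, e_o in arm_specs:
        risk_target = rng.uniform(1.0, 20.0)  # plausible outcome risk in percent
        n_o = max(e_o, int(round(100.0 * e_o / risk_target)))
        py_o = n_o * cfg.mean_followup_years * rng.uniform(0.8, 1.2)
        arms_o.append(
            ArmResult(
                arm_id=arm_id,
                n=n_o,
                events=e_o,
                risk_pct=100.0 * e_o / n_o,
                rate_per100py=100.0 * e_o / py_o,
                person_years=py_o,
                is_reference=is_ref,
            )
        )
        n_r = max(1, int(round(n_o * ratio)))
        e_r = int(round(e_o * ratio * np.exp(rng.normal(0.0, 0.05)))) if cfg.size_ratio_logsd else int(round(e_o * ratio))
        e_r = min(max(e_r, 0), n_r)
        py_r = py_o * ratio
        if shifted:
            extra = rng.uniform(*cfg.rate_shift_band)  # per 100 person-years
            e_r = min(n_r, int(round((100.0 * e_r / py_r + extra) * py_r / 100.0)))
        arms_r.append(
            ArmResult(
                arm_id=arm_id,
                n=n_r,
                events=e_r,
                risk_pct=100.0 * e_r / n_r,
                rate_per100py=100.0 * e_r / py_r,
                person_years=py_r,
                is_reference=is_ref,
            )
        )
    return arms_o, arms_r


def _effect(log_point: float, se: float, p_value, measure=Measure.HR) -> EffectEstimate:
    return EffectEstimate(
        point=float(np.exp(log_point)),
        ci_low=float(np.exp(log_point - Z975 * se)),
        ci_high=float(np.exp(log_point + Z975 * se)),
        p_value=p_value,
        measure=measure,
    )


def _two_sided_p(log_point: float, se: float) -> float:
    from scipy.stats import norm

    return float(2.0 * norm.sf(abs(log_point) / se))


def _simulate_covariates(rng, cfg: SimConfig, sid: str, arm_ids) -> list[CovariateEntry]:
    out = []
    cs = cfg.covariate_shift
    for j in range(cfg.n_covariates):
        for arm_id in arm_ids:
            prev_o = float(rng.uniform(2.0, 70.0))
            if rng.random() < cs.prob_large:
                shift = float(rng.choice([-1.0, 1.0]) * (cs.magnitude_large + rng.normal(0.0, 2.0)))
            else:
                shift = float(rng.normal(0.0, cs.sd_small))
            prev_r = float(np.clip(prev_o - shift, 0.0, 100.0))
            out.append(
                CovariateEntry(
                    study_id=sid,
                    covariate=f"cov_{j + 1:02d}",
                    arm_id=arm_id,
                    prev_original_pct=prev_o,
                    prev_reproduction_pct=prev_r,
                )
            )
    return out


def _simulate_checklist(rng, cfg: SimConfig, sid: str, design: Design, items) -> ChecklistRecord:
    responses = {}
    for item in items:
        if item["applies_to"] == "comparative" and design is Design.descriptive:
            responses[item["id"]] = Response.not_applicable
            continue
        u = rng.random()
        if u < item["report_prob"]:
            responses[item["id"]] = Response.reported
        elif rng.random() < 0.3:
            responses[item["id"]] = Response.partially_reported
        else:
            responses[item["id"]] = Response.not_reported
    cats = CATEGORIES_COMPARATIVE if design is Design.comparative else CATEGORIES_DESCRIPTIVE
    p = cfg.assume_prob_comparative if design is Design.comparative else cfg.assume_prob_descriptive
    k = int(rng.binomial(len(cats), p))
    chosen = set(rng.choice(len(cats), size=k, replace=False).tolist()) if k else set()
    assumptions = {c: (i in chosen) for i, c in enumerate(cats)}
    return ChecklistRecord(study_id=sid, design=design, items=responses, assumptions=assumptions)


def generate_portfolio(config: SimConfig) -> Portfolio:
    """Generate a paired original/reproduction portfolio with known truth.

    Deterministic given ``config.seed``: all randomness flows from one
    ``numpy.random.default_rng`` in the documented per-study draw order
    (effect block, arms, covariates; then the checklist for all studies).
    """
    rng = np.random.default_rng(config.seed)
    items = load_items_schema()
    mix = config.discrepancy_mix
    f = config.shared_error_fraction
    studies, covariates = [], []
    ledger = TruthLedger(config=json.loads(config.model_dump_json()))

    for i in range(config.n_comparative):
        sid = f"C{i + 1:03d}"
        entry: dict = {"study_id": sid, "design": "comparative"}
        theta = float(rng.normal(config.mu_theta, config.tau)) if config.tau else config.mu_theta
        e1 = int(rng.integers(config.event_count_range[0], config.event_count_range[1] + 1))
        e0 = int(rng.integers(config.event_count_range[0], config.event_count_range[1] + 1))
        sigma = math.sqrt(1.0 / e1 + 1.0 / e0)
        eps_shared = float(rng.normal(0.0, math.sqrt(f) * sigma))
        ind_sd = math.sqrt(1.0 - f) * sigma
        eps_o = float(rng.normal(0.0, ind_sd)) if ind_sd else 0.0
        eps_r = float(rng.normal(0.0, ind_sd)) if ind_sd else 0.0
        big = bool(rng.random() < mix.pi_big)
        omega = mix.omega_big if big else mix.omega_small
        delta = float(rng.normal(0.0, omega)) if omega else 0.0
        l_o = theta + eps_shared + eps_o
        l_r = theta + delta + eps_shared + eps_r
        entry.update(
            theta=theta,
            delta=delta,
            big_component=big,
            sigma=sigma,
            eps_shared=eps_shared,
            eps_original=eps_o,
            eps_reproduction=eps_r,
            log_effect_original=l_o,
            log_effect_reproduction=l_r,
        )
        p_o = _two_sided_p(l_o, sigma)
        p_o_printed = p_o if rng.random() < config.p_report_prob else None
        p_r = _two_sided_p(l_r, sigma)
        arm_specs = [("exposed", False, e1), ("reference", True, e0)]
        arms_o, arms_r = _simulate_arms(rng, config, arm_specs, sid, entry)
        studies.append(
            StudyPair(
                study_id=sid,
                design=Design.comparative,
                original=StudyResult(arms=arms_o, effect=_effect(l_o, sigma, p_o_printed)),
                reproduction=StudyResult(arms=arms_r, effect=_effect(l_r, sigma, p_r)),
                attributes=_attributes(rng),
            )
        )
        covariates.extend(_simulate_covariates(rng, config, sid, ["exposed", "reference"]))
        ledger.entries.append(entry)

    for i in range(config.n_descriptive):
        sid = f"D{i + 1:03d}"
        entry = {"study_id": sid, "design": "descriptive"}
        e = int(rng.integers(config.event_count_range[0], config.event_count_range[1] + 1))
        arms_o, arms_r = _simulate_arms(rng, config, [("overall", False, e)], sid, entry)
        studies.append(
            StudyPair(
                study_id=sid,
                design=Design.descriptive,
                original=StudyResult(arms=arms_o),
                reproduction=StudyResult(arms=arms_r),
                attributes=_attributes(rng),
            )
        )
        covariates.extend(_simulate_covariates(rng, config, sid, ["overall"]))
        ledger.entries.append(entry)

    checklist = [
        _simulate_checklist(rng, config, p.study_id, p.design, items) for p in studies
    ]
    return Portfolio(studies, covariates, checklist, ledger)


def _attributes(rng) -> dict[str, str]:
    return {
        "funding_source": str(rng.choice(["industry", "public", "none_declared"])),
        "data_source": str(rng.choice(["claims_a", "claims_b", "claims_c", "ehr_uk"])),
        "publication_year": str(int(rng.integers(2011, 2018))),
        "journal_impact_band": str(rng.choice(["high", "medium", "low"])),
        "author_responsive": str(rng.choice(["yes", "no"])),
        "same_group": str(rng.choice(["yes", "no"], p=[0.05, 0.95])),
    }


@dataclass
class RecoveredParameters:
    """Method-of-moments estimates of the generator parameters with bootstrap SEs."""

    tau: float
    omega: float
    shared_error_fraction: float
    se_tau: float
    se_omega: float
    se_shared_error_fraction: float
    n_studies: int


def recover_parameters(
    pairs: Sequence[StudyPair],
    n_boot: int = 200,
    seed: int = 0,
) -> RecoveredParameters:
    """Recover (tau, omega, shared_error_fraction) blind to the truth ledger.

    Uses only what a consumer of the tables can see: the paired log effects
    and the per-study sampling se backed out of the original 95% CI.  The
    moment equations (sigma2 = mean sampling variance):

        Var(ln ES_o)          = tau^2 + sigma2
        Cov(ln ES_o, ln ES_r) = tau^2 + f * sigma2
        Var(ln ES_r - ln ES_o) = omega^2 + 2 (1 - f) * sigma2

    ``omega`` is the *marginal* sd of the discrepancy mixture; its individual
    components are not identified from second moments.  SEs come from a
    nonparametric bootstrap over studies.
    """
    comp = [p for p in pairs if p.design is Design.comparative]
    if len(comp) < 10:
        raise ValueError(f"need >= 10 comparative studies, got {len(comp)}")
    l_o = np.array([math.log(p.original.effect.point) for p in comp])
    l_r = np.array([math.log(p.reproduction.effect.point) for p in comp])
    sig2 = np.array([se_from_ci(p.original.effect) ** 2 for p in comp])

    def estimate(idx):
        lo, lr, s2 = l_o[idx], l_r[idx], sig2[idx]
        s2bar = s2.mean()
        tau2 = np.var(lo, ddof=1) - s2bar
        cov = np.cov(lo, lr, ddof=1)[0, 1]
        f = np.clip((cov - tau2) / s2bar, 0.0, 1.0)
        omega2 = np.var(lr - lo, ddof=1) - 2.0 * (1.0 - f) * s2bar
        return (
            math.sqrt(max(tau2, 0.0)),
            math.sqrt(max(omega2, 0.0)),
            float(f),
        )

    idx_all = np.arange(len(comp))
    tau, omega, f = estimate(idx_all)
    rng = np.random.default_rng(seed)
    boots = np.array(
        [estimate(rng.integers(0, len(comp), size=len(comp))) for _ in range(n_boot)]
    )
    se = boots.std(axis=0, ddof=1)
    return RecoveredParameters(tau, omega, f, float(se[0]), float(se[1]), float(se[2]), len(comp))
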