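import numpy as np
import pytest

from rwerepro import (
    ArmResult,
    Design,
    EffectEstimate,
    StudyPair,
    StudyResult,
)
from rwerepro.effect_concordance import Z975


def make_estimate(point, ci_low=None, ci_high=None, p_value=None, measure="HR"):
    return EffectEstimate(
        point=point, ci_low=ci_low, ci_high=ci_high, p_value=p_value, measure=measure
    )


def estimate_with_se(log_point: float, se: float, p_value=None) -> EffectEstimate:
    """Effect estimate whose 95% CI encodes exactly the given log-scale SE."""
    return EffectEstimate(
        point=float(np.exp(log_point)),
        ci_low=float(np.exp(log_point - Z975 * se)),
        ci_high=float(np.exp(log_point + Z975 * se)),
        p_value=p_value,
    )


def make_pair(
    study_id,
    orig_effect=None,
    repro_effect=None,
    orig_ns=(500, 500),
    repro_ns=(500, 500),
    design="comparative",
    attributes=None,
    orig_arm_kw=(),
    repro_arm_kw=(),
):
    """Build a StudyPair with minimal arm information."""

    def arms(ns, extra):
        extra = list(extra) or [{} for _ in ns]
        out = []
        for i, (n, kw) in enumerate(zip(ns, extra)):
            last = i == len(ns) - 1
            out.append(
                ArmResult(
                    arm_id=f"arm{i}",
                    n=n,
                    is_reference=last and len(ns) > 1,
                    **kw,
                )
            )
        return out

    return StudyPair(
        study_id=study_id,
        design=design,
        original=StudyResult(arms=arms(orig_ns, orig_arm_kw), effect=orig_effect),
        reproduction=StudyResult(arms=arms(repro_ns, repro_arm_kw), effect=repro_effect),
        attributes=attributes or {},
    )


@pytest.fixture
def comparative_pair():
    return make_pair(
        "S1",
        orig_effect=make_estimate(1.4, 1.1, 1.8, 0.02),
        repro_effect=make_estimate(1.2, 0.95, 1.55),
    )


@pytest.fixture
def identical_pairs():
    """Five pairs whose original and reproduction are exactly identical."""
    rng = np.random.default_rng(7)
    pairs = []
    for i in range(5):
        log_point = rng.normal(0, 0.4)
        est = estimate_with_se(log_point, 0.1, p_value=0.02)
        pairs.append(make_pair(f"I{i}", orig_effect=est, repro_effect=est.model_copy()))
    return pairs
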