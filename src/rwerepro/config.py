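"""Analysis configuration: thresholds and variants mirrored from the metric suite."""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, Field


class AnalysisConfig(BaseModel):
    """Tunable analysis constants.

    The defaults mirror the published metric suite: log-difference thresholds
    0.1/0.2 (inclusive), large-difference threshold 10 (strict, percentage
    points or events per 100 person-years), significance discordance at
    p > 0.05 vs p <= 0.01, pair-level inverse-variance weights, one-way
    random-effects ICC, ten ranked outliers.
    """

    log_diff_thresholds: tuple[float, float] = (0.1, 0.2)
    large_diff_threshold: float = Field(default=10.0, gt=0)
    alpha_fail: float = 0.05
    alpha_reject: float = 0.01
    ivw_variant: str = "combined"  # or "original"
    icc_variant: str = "oneway"
    alpha: float = 0.05
    outlier_k: int = Field(default=10, ge=1)
    partial_counts_as_reported: bool = False

    @classmethod
    def from_yaml(cls, path: Optional[str]) -> "AnalysisConfig":
        if path is None:
            return cls()
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))
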