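"""Scoring of the 54-item reporting-clarity instrument.

Each evaluated publication gets a response per item (reported / partially
reported / not reported / not applicable) plus, for reproduced studies, a
flag per study-parameter *category* recording whether the reproduction team
had to make at least one assumption in that category.  Comparative studies
have six categories (index date, inclusion-exclusion, exposure, outcome,
follow-up, covariates); descriptive studies drop the exposure category.

The item-to-category mapping is data, not code: it ships as an editable
schema file (``data/items_synthetic.yaml``, a constructed stand-in
instrument — see :func:`load_items_schema`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, model_validator

from .records_io import Design

__all__ = [
    "N_ITEMS",
    "Response",
    "CATEGORIES_COMPARATIVE",
    "CATEGORIES_DESCRIPTIVE",
    "ChecklistRecord",
    "ClaritySummary",
    "assumption_category_count",
    "clarity_summary",
    "load_items_schema",
    "CHECKLIST_COLUMNS",
    "checklist_record_from_row",
    "checklist_record_to_row",
]

N_ITEMS = 54

CATEGORIES_COMPARATIVE = (
    "index_date",
    "inclusion_exclusion",
    "exposure",
    "outcome",
    "follow_up",
    "covariates",
)
CATEGORIES_DESCRIPTIVE = tuple(c for c in CATEGORIES_COMPARATIVE if c != "exposure")


class Response(str, enum.Enum):
    reported = "reported"
    partially_reported = "partially_reported"
    not_reported = "not_reported"
    not_applicable = "not_applicable"


class ChecklistRecord(BaseModel):
    study_id: str
    design: Design
    items: dict[int, Response]
    assumptions: dict[str, bool] = {}

    @model_validator(mode="after")
    def _check(self) -> "ChecklistRecord":
        expected = set(range(1, N_ITEMS + 1))
        if set(self.items) != expected:
            missing = sorted(expected - set(self.items))
            extra = sorted(set(self.items) - expected)
            raise ValueError(
                f"checklist must cover items 1..{N_ITEMS}; missing {missing}, extra {extra}"
            )
        allowed = set(
            CATEGORIES_COMPARATIVE
            if self.design is Design.comparative
            else CATEGORIES_DESCRIPTIVE
        )
        bad = set(self.assumptions) - allowed
        if bad:
            raise ValueError(
                f"assumption categories {sorted(bad)} not allowed for "
                f"{self.design.value} studies"
            )
        return self


def assumption_category_count(record: ChecklistRecord) -> int:
    """Number of categories where the reproduction team made >= 1 assumption."""
    return sum(bool(v) for v in record.assumptions.values())


@dataclass
class ClaritySummary:
    """Portfolio reporting-clarity summary.

    ``item_proportions`` maps item_id to the share of applicable studies
    reporting that item; the denominator excludes not-applicable responses.
    """

    n_studies: int
    item_proportions: dict[int, float]
    item_denominators: dict[int, int]
    item_not_applicable: dict[int, int]
    median_categories_comparative: Optional[float] = None
    iqr_categories_comparative: Optional[tuple[float, float]] = None
    median_categories_descriptive: Optional[float] = None
    iqr_categories_descriptive: Optional[tuple[float, float]] = None
    n_zero_assumption_studies: int = 0

    def as_dict(self) -> dict:
        return {
            "n_studies": self.n_studies,
            "item_proportions": {str(k): v for k, v in self.item_proportions.items()},
            "item_denominators": {str(k): v for k, v in self.item_denominators.items()},
            "item_not_applicable": {str(k): v for k, v in self.item_not_applicable.items()},
            "median_categories_comparative": self.median_categories_comparative,
            "iqr_categories_comparative": self.iqr_categories_comparative,
            "median_categories_descriptive": self.median_categories_descriptive,
            "iqr_categories_descriptive": self.iqr_categories_descriptive,
            "n_zero_assumption_studies": self.n_zero_assumption_studies,
        }


def clarity_summary(
    records: Sequence[ChecklistRecord],
    partial_counts_as_reported: bool = False,
) -> ClaritySummary:
    """Summarise reporting clarity over evaluated studies.

    By default ``partially_reported`` counts as not reported for the headline
    proportions (the conservative reading); flip with
    ``partial_counts_as_reported``.
    """
    if not records:
        raise ValueError("need at least one checklist record")
    props, denoms, nas = {}, {}, {}
    counted = {Response.reported}
    if partial_counts_as_reported:
        counted.add(Response.partially_reported)
    for item in range(1, N_ITEMS + 1):
        responses = [r.items[item] for r in records]
        n_na = sum(resp is Response.not_applicable for resp in responses)
        denom = len(responses) - n_na
        n_rep = sum(resp in counted for resp in responses)
        props[item] = (n_rep / denom) if denom else float("nan")
        denoms[item] = denom
        nas[item] = n_na

    def _stats(design: Design):
        counts = [
            assumption_category_count(r) for r in records if r.design is design
        ]
        if not counts:
            return None, None
        q1, med, q3 = np.quantile(counts, [0.25, 0.5, 0.75])
        return float(med), (float(q1), float(q3))

    med_c, iqr_c = _stats(Design.comparative)
    med_d, iqr_d = _stats(Design.descriptive)
    return ClaritySummary(
        n_studies=len(records),
        item_proportions=props,
        item_denominators=denoms,
        item_not_applicable=nas,
        median_categories_comparative=med_c,
        iqr_categories_comparative=iqr_c,
        median_categories_descriptive=med_d,
        iqr_categories_descriptive=iqr_d,
        n_zero_assumption_studies=sum(
            assumption_category_count(r) == 0 for r in records
        ),
    )


def load_items_schema(path=None) -> list[dict]:
    """Load the 54-item schema (id, text, category, applicability, report_prob).

    Without ``path`` the packaged ``items_synthetic.yaml`` is used — a
    synthetic stand-in instrument with the structure of the consensus
    reporting checklist (54 items over the six study-parameter categories
    plus general transparency items), not the verbatim published wording.
    """
    if path is None:
        ref = resources.files("rwerepro").joinpath("data/items_synthetic.yaml")
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    schema = yaml.safe_load(text)
    items = schema["items"]
    if len(items) != N_ITEMS:
        raise ValueError(f"schema must define {N_ITEMS} items, found {len(items)}")
    return items


# --- CSV row mapping (used by records_io.read_checklist/write_checklist) ----

CHECKLIST_COLUMNS = (
    ["study_id", "design"]
    + [f"item_{i}" for i in range(1, N_ITEMS + 1)]
    + [f"assumed_{c}" for c in CATEGORIES_COMPARATIVE]
)


def checklist_record_from_row(row: dict) -> ChecklistRecord:
    items = {i: Response(row[f"item_{i}"]) for i in range(1, N_ITEMS + 1)}
    assumptions = {}
    for c in CATEGORIES_COMPARATIVE:
        cell = row[f"assumed_{c}"].strip()
        if cell != "":
            assumptions[c] = cell.lower() in {"1", "true", "yes"}
    return ChecklistRecord(
        study_id=row["study_id"],
        design=Design(row["design"]),
        items=items,
        assumptions=assumptions,
    )


def checklist_record_to_row(rec: ChecklistRecord) -> dict:
    row = {"study_id": rec.study_id, "design": rec.design.value}
    for i in range(1, N_ITEMS + 1):
        row[f"item_{i}"] = rec.items[i].value
    for c in CATEGORIES_COMPARATIVE:
        if c in rec.assumptions:
            row[f"assumed_{c}"] = "1" if rec.assumptions[c] else "0"
        else:
            row[f"assumed_{c}"] = None
    return row
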