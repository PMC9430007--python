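"""End-to-end pipeline: read tables, compute every metric family, write outputs.

Outputs in the chosen directory: ``concordance.csv``,
``cohort_concordance.csv``, ``summary.json``, ``blandaltman.csv``,
``outliers.csv``, ``subgroup_variation.csv``, ``clarity_summary.json`` (when
a checklist is supplied), six figure analogues (SVG + PNG) and
``manifest.json`` listing a SHA-256 digest for every input and output.  The
pipeline is a pure function of (inputs, config): data-output digests are
stable across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .agreement_stats import bland_altman, subgroup_variation, summarize, top_outliers
from .cohort_concordance import cohort_concordance_table
from .config import AnalysisConfig
from .effect_concordance import concordance_table
from .figures import make_figures
from .records_io import (
    Design,
    StudyPair,
    TableReadResult,
    read_checklist,
    read_covariates,
    read_study_pairs,
)
from .reporting_clarity import clarity_summary

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, float) and not math.isfinite(o):
        return None
    raise TypeError(type(o))


def _write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, allow_nan=False, default=_json_default)
        fh.write("\n")


def _sanitize(obj):
    """Replace non-finite floats with None for strict-JSON serialization."""
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    return obj


def run_pipeline(
    studies_path,
    covariates_path=None,
    checklist_path=None,
    config: Optional[AnalysisConfig] = None,
    out_dir="results",
) -> Path:
    """Run the full concordance analysis; returns the output directory.

    Raises :class:`PipelineError` after writing a failure-marked manifest if
    any stage errors; partial outputs are retained.
    """
    cfg = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "rwerepro",
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "config": cfg.model_dump(),
        "inputs": {},
        "outputs": {},
        "stages": [],
        "status": "running",
    }
    for name, p in (
        ("studies", studies_path),
        ("covariates", covariates_path),
        ("checklist", checklist_path),
    ):
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}
        else:
            manifest["stages"].append({"stage": f"read_{name}", "skipped": True})

    try:
        _run_stages(studies_path, covariates_path, checklist_path, cfg, out, manifest)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        raise PipelineError(str(exc)) from exc
    finally:
        manifest["finished"] = datetime.now(timezone.utc).isoformat()
        _write_json(manifest, out / "manifest.json")
    return out


def _log_stage(manifest, stage, **counts):
    logger.info("stage %-22s %s", stage, " ".join(f"{k}={v}" for k, v in counts.items()))
    manifest["stages"].append({"stage": stage, **counts})


def _run_stages(studies_path, covariates_path, checklist_path, cfg, out, manifest):
    studies = read_study_pairs(studies_path)
    _register_rejections(studies, out, "rejections_studies.csv", manifest)
    _log_stage(manifest, "read_studies", rows=studies.n_input_rows, studies=len(studies))
    pairs: list[StudyPair] = studies.records

    covariates = TableReadResult([], [], 0)
    if covariates_path is not None:
        covariates = read_covariates(covariates_path)
        _register_rejections(covariates, out, "rejections_covariates.csv", manifest)
        _log_stage(
            manifest, "read_covariates", rows=covariates.n_input_rows, entries=len(covariates)
        )

    rows, errors = concordance_table(pairs, cfg.log_diff_thresholds)
    conc_df = pd.DataFrame([r.as_dict() for r in rows])
    conc_df.to_csv(out / "concordance.csv", index=False)
    _register(out / "concordance.csv", manifest)
    _log_stage(manifest, "effect_concordance", rows=len(rows), errors=len(errors))

    cohort_rows = cohort_concordance_table(pairs, covariates.records, cfg.large_diff_threshold)
    _write_cohort_rows(cohort_rows, out / "cohort_concordance.csv")
    _register(out / "cohort_concordance.csv", manifest)
    _log_stage(manifest, "cohort_concordance", rows=len(cohort_rows))

    ba = None
    outlier_ids: list[str] = []
    if len(rows) >= 3:
        by_id = {p.study_id: p for p in pairs}
        estimates = [
            (by_id[r.study_id].original.effect, by_id[r.study_id].reproduction.effect)
            for r in rows
        ]
        summary = summarize(rows, estimates, ivw_variant=cfg.ivw_variant, alpha=cfg.alpha)
        _write_json(_sanitize(summary.as_dict()), out / "summary.json")
        _register(out / "summary.json", manifest)

        log_pairs = [(math.log(o.point), math.log(r.point)) for o, r in estimates]
        ba = bland_altman(log_pairs, [r.study_id for r in rows])
        pd.DataFrame(
            {
                "study_id": ba.study_ids,
                "mean_log_effect": ba.means,
                "diff_log_effect": ba.diffs,
                "outside_limits": [sid in set(ba.outside_limits) for sid in ba.study_ids],
            }
        ).to_csv(out / "blandaltman.csv", index=False)
        _register(out / "blandaltman.csv", manifest)

        k = min(cfg.outlier_k, len(rows))
        outlier_ids = top_outliers(rows, k)
        by_row = {r.study_id: r for r in rows}
        pd.DataFrame(
            {
                "rank": range(1, k + 1),
                "study_id": outlier_ids,
                "abs_log_diff": [by_row[s].abs_log_diff for s in outlier_ids],
            }
        ).to_csv(out / "outliers.csv", index=False)
        _register(out / "outliers.csv", manifest)
        _log_stage(manifest, "agreement_summary", studies=summary.n_studies, outliers=k)

        _write_subgroups(rows, pairs, out, manifest)
    else:
        _log_stage(manifest, "agreement_summary", skipped=True, reason="fewer than 3 comparative rows")

    if checklist_path is not None:
        checklist = read_checklist(checklist_path)
        _register_rejections(checklist, out, "rejections_checklist.csv", manifest)
        cs = clarity_summary(checklist.records, cfg.partial_counts_as_reported)
        _write_json(_sanitize(cs.as_dict()), out / "clarity_summary.json")
        _register(out / "clarity_summary.json", manifest)
        _log_stage(manifest, "reporting_clarity", studies=len(checklist.records))

    fig_paths = make_figures(pairs, rows, cohort_rows, ba, outlier_ids, out)
    for p in fig_paths:
        _register(p, manifest)
    _log_stage(manifest, "figures", files=len(fig_paths))


def _register(path: Path, manifest) -> None:
    manifest["outputs"][path.name] = _sha256(path)


def _register_rejections(result: TableReadResult, out: Path, name: str, manifest) -> None:
    if result.rejections:
        df = pd.DataFrame([asdict(r) for r in result.rejections])
        df.to_csv(out / name, index=False)
        _register(out / name, manifest)
        logger.warning("%d rejected rows written to %s", len(result.rejections), name)


def _write_cohort_rows(rows, path: Path) -> None:
    """Long-format cohort concordance: one 'size' row per study plus one row
    per covariate/risk/rate difference."""
    records = []
    for r in rows:
        base = {
            "study_id": r.study_id,
            "design": r.design,
            "rel_sample_size": r.rel_sample_size,
            "size_extreme": r.size_extreme,
        }
        records.append({**base, "metric": "sample_size", "label": "", "arm_id": "", "diff": "", "large_flag": ""})
        for d in r.covariate_diffs:
            records.append(
                {**base, "metric": "covariate", "label": d.covariate, "arm_id": d.arm_id, "diff": d.diff_pct, "large_flag": d.large}
            )
        for d in r.risk_diffs:
            records.append({**base, "metric": "risk", "label": "", "arm_id": d.arm_id, "diff": d.diff, "large_flag": d.large})
        for d in r.rate_diffs:
            records.append({**base, "metric": "rate", "label": "", "arm_id": d.arm_id, "diff": d.diff, "large_flag": d.large})
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def _write_subgroups(rows, pairs, out: Path, manifest) -> None:
    attr_keys = sorted({k for p in pairs for k in p.attributes})
    records = []
    for key in attr_keys:
        groups = {
            p.study_id: p.attributes[key]
            for p in pairs
            if p.design is Design.comparative and key in p.attributes
        }
        try:
            table, f_stat, p_val, degenerate = subgroup_variation(rows, groups)
        except ValueError:
            continue
        for g, n, mean, sd in table:
            records.append(
                {
                    "attribute": key,
                    "group": g,
                    "n": n,
                    "mean_abs_log_diff": mean,
                    "sd_abs_log_diff": sd,
                    "anova_f": f_stat,
                    "anova_p": p_val,
                    "degenerate": degenerate,
                }
            )
    if records:
        pd.DataFrame.from_records(records).to_csv(out / "subgroup_variation.csv", index=False)
        _register(out / "subgroup_variation.csv", manifest)
        _log_stage(manifest, "subgroup_variation", attributes=len(attr_keys))
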