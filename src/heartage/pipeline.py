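"""End-to-end pipeline: simulate -> metrics -> derive -> predict -> validate.

Every stage writes CSV/JSON artifacts into one output directory plus a
manifest (seed, per-stage row counts, SHA-256 checksums), so a rerun with
the same configuration is bit-identical and the subject flow can be
reconstructed stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import derivation, metrics, model, simulate, stats

__all__ = ["PipelineConfig", "run_pipeline", "exclusion_filter"]

log = logging.getLogger("heartage")

#: machine-readable exclusion reason codes
REASON_LVEF = "lvef_lt_50"
REASON_MISSING = "missing_metric"
REASON_QUALITY = "quality_fail"


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    n_healthy: int = 191
    n_unhealthy: int = 366
    simulate: bool = True
    cohort_path: Path | None = None  # used when simulate is off
    run_metrics_stage: bool = True
    metrics_subjects: int = 25  # contour round-trip audit size
    contour_phases: int = 32


def exclusion_filter(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into retained and excluded rows with reason codes.

    Exclusions: LV EF < 50 %, missing LA ESV / LA EF / LV EF, or an optional
    ``quality_ok`` column set false.  Filtering is total: retained and
    excluded partition the input.
    """
    reasons = pd.Series([""] * len(cohort), index=cohort.index, dtype=object)
    required = ["la_esv_ml", "la_ef_pct", "lv_ef_pct"]
    missing_mask = cohort[required].isna().any(axis=1)
    reasons[missing_mask] = REASON_MISSING
    lvef_mask = ~missing_mask & (cohort["lv_ef_pct"] < 50.0)
    reasons[lvef_mask] = REASON_LVEF
    if "quality_ok" in cohort.columns:
        q = ~cohort["quality_ok"].astype(bool) & (reasons == "")
        reasons[q] = REASON_QUALITY
    excluded_mask = reasons != ""
    retained = cohort[~excluded_mask].copy()
    excluded = cohort[excluded_mask].copy()
    excluded["exclusion_reason"] = reasons[excluded_mask]
    log.info(
        "exclusion filter: %d retained, %d excluded (%s)",
        len(retained),
        len(excluded),
        dict(excluded["exclusion_reason"].value_counts()) if len(excluded) else {},
    )
    return retained, excluded


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _metrics_audit(records, phases: int) -> pd.DataFrame:
    """Rebuild chamber metrics from generated contours and compare."""
    rows = []
    for rec in records:
        contours = simulate.generate_contours(rec, phases=phases)
        lv = metrics.volumes_from_contours(contours["LV"])
        m = metrics.basic_metrics(lv, rec.heart_rate_bpm)
        per, pfr = metrics.peak_rates(lv)
        epi = metrics.volumes_from_contours(contours["LV_epi"])
        rows.append(
            {
                "subject_id": rec.subject_id,
                "lv_edv_ml": m.edv,
                "lv_esv_ml": m.esv,
                "lv_ef_pct": m.ef,
                "lv_co_ml_per_min": m.co,
                "lv_per_ml_per_s": per,
                "lv_pfr_ml_per_s": pfr,
                "lv_gls_pct": metrics.gls(contours["LV"].lengths),
                "lv_mass_g": metrics.lv_mass(epi, lv),
                "edv_error_ml": m.edv - rec.lv_edv_ml,
                "esv_error_ml": m.esv - rec.lv_esv_ml,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    def record_stage(name: str, n_rows: int, files: list[Path]):
        manifest["stages"].append(
            {
                "stage": name,
                "rows": n_rows,
                "outputs": {f.name: _sha256(f) for f in files},
            }
        )
        log.info("stage %s: %d rows", name, n_rows)

    # 1. simulate (or load)
    if config.simulate:
        healthy = simulate.generate_healthy(
            simulate.CohortConfig(n=config.n_healthy, seed=config.seed)
        )
        unhealthy = simulate.generate_unhealthy(
            simulate.CohortConfig(n=config.n_unhealthy, seed=config.seed)
        )
        cohort = pd.concat(
            [simulate.cohort_frame(healthy), simulate.cohort_frame(unhealthy)],
            ignore_index=True,
        )
        cohort["subject_id"] = [f"S{i:05d}" for i in range(len(cohort))]
        cohort_path = out / "cohort.csv"
        simulate.write_cohort(cohort, cohort_path)
    else:
        if config.cohort_path is None or not Path(config.cohort_path).exists():
            raise FileNotFoundError(
                "simulate stage disabled and no existing cohort_path given"
            )
        cohort_path = Path(config.cohort_path)
        cohort = simulate.read_cohort(cohort_path)
        healthy = None
    record_stage("simulate", len(cohort), [cohort_path])

    # 2. chamber-metrics audit on generated contours
    if config.run_metrics_stage and config.simulate:
        audit = _metrics_audit(
            healthy[: config.metrics_subjects], config.contour_phases
        )
        audit_path = out / "metrics_audit.csv"
        audit.to_csv(audit_path, index=False)
        record_stage("metrics", len(audit), [audit_path])

    # 3. exclusion filter + derive on healthy subset
    retained, excluded = exclusion_filter(cohort)
    excl_path = out / "excluded.csv"
    excluded.to_csv(excl_path, index=False)
    healthy_frame = retained[retained["health_status"] == "healthy"]
    params, report = derivation.derive_model(healthy_frame.reset_index(drop=True))
    model_path = out / "model.yaml"
    model.save_params(params, model_path)
    record_stage("derive", len(healthy_frame), [model_path, excl_path])

    # 4. predict the full retained cohort with the shipped (published) model
    preds = model.predict_cohort(retained, model.DEFAULT_PARAMS)
    pred_frame = model.predictions_frame(preds)
    pred_frame["age_yr"] = retained["age_yr"].to_numpy()
    pred_path = out / "predictions.csv"
    pred_frame.to_csv(pred_path, index=False)
    record_stage("predict", len(pred_frame), [pred_path])

    # 5. validate
    h_mask = (retained["health_status"] == "healthy").to_numpy()
    fage = pred_frame["functional_heart_age_yr"].to_numpy()
    age = pred_frame["age_yr"].to_numpy()
    validation = {
        "healthy_bland_altman_pct": vars(
            stats.bland_altman(fage[h_mask], age[h_mask], mode="percent")
        ),
        "unhealthy_gap_yr": vars(
            stats.bland_altman(fage[~h_mask], age[~h_mask], mode="absolute")
        ),
        "healthy_spearman": vars(stats.spearman_ci(fage[h_mask], age[h_mask])),
        "unhealthy_spearman": vars(stats.spearman_ci(fage[~h_mask], age[~h_mask])),
    }
    gap_tables = stats.age_gap_by_group(
        retained.reset_index(drop=True), fage, "bmi_class"
    )
    gap_path = out / "age_gap_by_bmi_class.csv"
    gap_tables.to_csv(gap_path, index=False)
    val_path = out / "validation.json"
    val_path.write_text(json.dumps(validation, indent=2, default=float))
    record_stage("validate", len(retained), [val_path, gap_path])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
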