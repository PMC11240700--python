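"""End-to-end orchestration: simulate/load -> aggregate -> screen -> benchmark.

The table path (per-lesion feature CSV + patient covariates + outcomes) is
the primary entry point; the image path (NIfTI volumes/masks through the
extractor) feeds the same tables.  Every stage persists its artifacts as
CSV/JSON so runs are resumable and reproducible: identical config + seed
give identical reports.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate, filters, screening, simulate
from .evaluation import (
    CVPlan,
    repeated_stratified_cv,
    rep_means,
    summarize_cv,
    permutation_importance,
)
from .models import MODEL_LABELS, ModelSpec, one_hot_encode

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

CLINICAL_CATEGORICAL = ["who_ps", "pdl1", "n_met_sites"]


@dataclass
class PipelineConfig:
    outdir: str = "radsurv_run"
    cohort_dir: str | None = None  # directory with lesions/patients/outcomes CSVs
    seed: int = 0
    n_patients: int = 140
    n_features: int = 68
    heterogeneity_scale: float = 1.0
    beta_feature: float = 0.0
    beta_ipith: float = 0.0
    screen_threshold: float = 0.100
    correlation_alpha: float = 0.05
    repetitions: int = 10
    folds: int = 5
    models: tuple[str, ...] = MODEL_LABELS
    model_hyperparams: dict = field(default_factory=dict)
    minkowski_p: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.screen_threshold < 1 or not 0 < self.correlation_alpha < 1:
            raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def validate_inputs(
    lesions: pd.DataFrame, patients: pd.DataFrame, outcomes: pd.DataFrame
) -> list[dict]:
    """Schema and consistency checks; returns a machine-readable violation
    list (never silently drops rows)."""
    violations: list[dict] = []
    need_lesion = {"patient_id", "lesion_id", "location", "volume_mm3"}
    missing = need_lesion - set(lesions.columns)
    if missing:
        violations.append({"rule": "lesion-columns", "detail": sorted(missing)})
    need_out = {"patient_id", "time_months", "event"}
    missing = need_out - set(outcomes.columns)
    if missing:
        violations.append({"rule": "outcome-columns", "detail": sorted(missing)})
        return violations
    counts = lesions.groupby("patient_id").size() if "patient_id" in lesions else pd.Series(dtype=int)
    solo = counts[counts < 2]
    for pid in solo.index:
        violations.append({"rule": "min-two-lesions", "detail": str(pid)})
    if "volume_mm3" in lesions:
        small = lesions.loc[lesions.volume_mm3 < simulate.RTL_MIN_VOLUME_MM3, "lesion_id"]
        for lid in small:
            violations.append({"rule": "below-rtl-volume", "detail": str(lid)})
    bad_t = outcomes.loc[
        ~np.isfinite(outcomes.time_months) | (outcomes.time_months <= 0), "patient_id"
    ]
    for pid in bad_t:
        violations.append({"rule": "nonpositive-time", "detail": str(pid)})
    if not set(outcomes.patient_id) <= set(patients.patient_id):
        violations.append({"rule": "unknown-patient-in-outcomes", "detail": ""})
    return violations


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.cohort_dir is not None:
        lesions, patients, outcomes = simulate.read_cohort(cfg.cohort_dir)
        return lesions, patients, outcomes, None
    sim = simulate.CohortSimConfig(
        n_patients=cfg.n_patients,
        n_features=cfg.n_features,
        heterogeneity_scale=cfg.heterogeneity_scale,
        beta_feature=cfg.beta_feature,
        beta_ipith=cfg.beta_ipith,
        seed=cfg.seed,
    )
    return simulate.generate_cohort(sim)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also persisted)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    lesions, patients, outcomes, truth = _load_or_simulate(cfg)
    violations = validate_inputs(lesions, patients, outcomes)
    if violations:
        raise ValueError(f"input validation failed: {violations[:5]}")
    simulate.write_cohort(out / "cohort", lesions, patients, outcomes, truth)

    feat_cols = [c for c in lesions.columns if c.startswith("f")]
    kept, dropped = filters.near_zero_variance_filter(lesions[feat_cols])
    scaled, _ = filters.center_scale(lesions[kept])
    lesions_scaled = pd.concat(
        [lesions[["patient_id", "lesion_id", "location", "volume_mm3"]], scaled], axis=1
    )

    predictors = aggregate.compute_patient_predictors(
        lesions_scaled, kept, minkowski_p=cfg.minkowski_p
    )
    predictors = predictors.loc[outcomes.patient_id]
    predictors.to_csv(out / "patient_predictors.csv")

    time = outcomes.time_months.to_numpy()
    event = outcomes.event.to_numpy()

    clin = patients.set_index("patient_id").loc[outcomes.patient_id]
    screen_df = pd.concat([clin, predictors], axis=1)
    provenance = {c: "clinicopathological" for c in clin.columns}
    provenance.update({c: "radiomics" for c in predictors.columns})
    results, full, clin_set = screening.screen_variables(
        screen_df,
        time,
        event,
        provenance,
        categorical=[c for c in CLINICAL_CATEGORICAL if c in clin.columns],
        threshold=cfg.screen_threshold,
    )
    uncorr = screening.prune_correlated(full, screen_df, results, alpha=cfg.correlation_alpha)
    screening.results_to_frame(results).to_csv(out / "univariable_results.csv", index=False)
    for s in (full, clin_set, uncorr):
        s.to_json(out / f"input_{s.label}.json")

    inputs = {"clinicopathological": clin_set, "full": full, "uncorrelated": uncorr}
    plan = CVPlan(repetitions=cfg.repetitions, folds=cfg.folds, base_seed=cfg.seed)
    bench_rows = []
    for input_label, iset in inputs.items():
        if not iset.variables:
            warnings.warn(f"input set {input_label!r} is empty; skipped", stacklevel=2)
            continue
        design, _ = one_hot_encode(screen_df[iset.variables])
        for label in cfg.models:
            hp = cfg.model_hyperparams.get(label, {})
            cv = repeated_stratified_cv(design, time, event, ModelSpec(label, hp), plan)
            summ = summarize_cv(cv)
            bench_rows.append({"input": input_label, "model": label, **summ})
    bench = pd.DataFrame(bench_rows)
    bench.to_csv(out / "benchmark.csv", index=False)

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_patients": int(len(outcomes)),
        "n_lesions": int(len(lesions)),
        "kept_features": len(kept),
        "dropped_features": dropped,
        "inputs": {k: v.variables for k, v in inputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"manifest": manifest, "benchmark": bench, "univariable": results}
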