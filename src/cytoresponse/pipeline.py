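"""End-to-end orchestration: simulate/load -> standardize -> cluster ->
features -> survival, with provenance and a machine-readable report.

All stochastic stages derive their seeds from one master seed via
``numpy.random.SeedSequence(master).generate_state`` (cohort, SOM training,
consensus metaclustering, in that order), so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .cluster import assign_cells, metacluster
from .core import PanelConfig, ValidationError, default_panel
from .features import build_feature_matrix, extract_sample_features
from .preprocess import normalize_cohort
from .som import SOMConfig, pool_cells, train_som
from .survival import (
    apply_horizon,
    logrank_test,
    median_split,
    nested_loocv_select,
)
from .synth import CohortSpec, generate_cohort

log = logging.getLogger("cytoresponse")


@dataclass
class RunConfig:
    """One config drives the whole pipeline.

    Either ``cohort_spec`` (synthetic) or ``manifest``/``clinical`` paths
    (real data) supplies the cohort.  Stage parameters default to the study
    setup: 101 quantiles, cofactor 5, 5x5 grid, 10 metaclusters, 90th
    percentile, 5-year horizon.
    """

    cohort_spec: CohortSpec | None = None
    manifest: str | None = None
    clinical: str | None = None
    data_root: str | None = None
    target_batch: str | None = None      # required for file input; defaults to
                                         # the last batch for synthetic cohorts
    quantiles: int = 101
    grid: tuple = (5, 5)
    metaclusters: int = 10
    som_epochs: int = 10
    max_training_cells: int | None = None
    percentile: float = 0.90
    min_cells: int = 10
    horizon: str = "5y"
    n_lambdas: int = 15
    lambda_min_ratio: float = 0.1
    seed: int = 0
    out_dir: str | None = None
    write_intermediates: bool = False
    panel: PanelConfig = field(default_factory=default_panel)


@dataclass
class PipelineResult:
    cohort: object
    normalized: dict
    quantile_maps: dict
    model: object
    assignments: dict
    features: object
    selection: object
    groups: np.ndarray
    logrank: object
    report: dict


def _derived_seeds(master: int, n: int = 3):
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(manifest: pd.DataFrame, panel: PanelConfig, clinical: pd.DataFrame) -> dict:
    """Cross-check cohort layout before any stage runs.

    Fatal: bad sample roles, missing 0 h / 24 h samples, patients present in
    only one of manifest/clinical.  Warning: patients missing the 4 h sample.
    """
    errors, warnings_ = [], []
    bad_roles = set(manifest["sample_role"]) - {"patient", "healthy_donor", "batch_reference"}
    if bad_roles:
        errors.append(f"unknown sample roles: {sorted(bad_roles)}")
    pm = manifest[manifest["sample_role"] == "patient"]
    man_patients = set(pm["patient_id"].dropna())
    clin_patients = set(clinical["patient_id"])
    for pid in sorted(clin_patients - man_patients):
        errors.append(f"patient {pid} in clinical table but not in manifest")
    for pid in sorted(man_patients - clin_patients):
        errors.append(f"patient {pid} in manifest but not in clinical table")
    for pid in sorted(man_patients):
        tps = set(pm.loc[pm["patient_id"] == pid, "timepoint_h"].astype(float))
        for must in (0.0, 24.0):
            if must not in tps:
                errors.append(f"patient {pid} lacks the {must:g} h sample")
        if 4.0 not in tps:
            warnings_.append(f"patient {pid} lacks the 4 h sample (allowed)")
    batches_with_ref = set(
        manifest.loc[manifest["sample_role"] == "batch_reference", "batch_id"]
    )
    for b in sorted(set(manifest["batch_id"]) - batches_with_ref):
        errors.append(f"batch {b} has no reference aliquot")
    return {"errors": errors, "warnings": warnings_, "ok": not errors}


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute simulate/load -> normalize -> cluster -> features -> survive."""
    seeds = _derived_seeds(config.seed, 3)
    panel = config.panel

    # ---- stage 0: cohort ---------------------------------------------------
    if config.cohort_spec is not None:
        spec = config.cohort_spec
        if spec.seed != seeds[0]:
            spec = CohortSpec(**{**spec.__dict__, "seed": seeds[0]})
        log.info("generating synthetic cohort: %d patients, seed %d", spec.n_patients, spec.seed)
        cohort = generate_cohort(spec)
    else:
        if not config.manifest or not config.clinical:
            raise ValidationError("either cohort_spec or manifest+clinical paths are required")
        manifest = cio.read_manifest(config.manifest)
        clinical = cio.read_clinical(config.clinical)
        root = config.data_root or Path(config.manifest).parent
        tables = cio.load_cohort_tables(manifest, root)
        from .synth import SyntheticCohort  # container reuse; truth absent

        cohort = SyntheticCohort(
            samples=tables, manifest=manifest, clinical=clinical, truth=None, spec=None
        )
    report_validate = validate_inputs(cohort.manifest, panel, cohort.clinical)
    if not report_validate["ok"]:
        raise ValidationError("input validation failed: " + "; ".join(report_validate["errors"]))

    # ---- stage 1: standardization -----------------------------------------
    references = cohort.references()
    target_batch = config.target_batch
    if target_batch is None:
        if config.cohort_spec is None:
            raise ValidationError("target_batch must be set explicitly for file input")
        target_batch = sorted(references)[-1]
    order = list(cohort.manifest["sample_id"])
    normalized_list, qmaps = normalize_cohort(
        [cohort.samples[s] for s in order],
        references,
        target_batch,
        panel,
        grid_size=config.quantiles,
    )
    normalized = dict(zip(order, normalized_list))
    log.info("standardized %d samples onto batch %s", len(normalized), target_batch)

    # ---- stage 2: clustering ----------------------------------------------
    training_tables = [
        t
        for s, t in normalized.items()
        if (t.sample_role == "patient" and t.timepoint_h == 0.0)
        or t.sample_role == "healthy_donor"
    ]
    X = pool_cells(
        training_tables,
        panel.clustering,
        max_cells_per_sample=config.max_training_cells,
        seed=seeds[1],
    )
    som_cfg = SOMConfig(
        rows=config.grid[0], cols=config.grid[1], epochs=config.som_epochs, seed=seeds[1]
    )
    model = train_som(X, panel, som_cfg)
    model = metacluster(model, k=config.metaclusters, seed=seeds[2])
    assignments = {
        s: assign_cells(model, t)
        for s, t in normalized.items()
        if t.sample_role == "patient"
    }
    log.info(
        "trained %dx%d SOM on %d cells (quantization error %.3f), %d metaclusters",
        som_cfg.rows, som_cfg.cols, len(X), model.quantization_error, config.metaclusters,
    )

    # ---- stage 3: features -------------------------------------------------
    mcs = list(range(1, config.metaclusters + 1))
    sample_features = {
        s: extract_sample_features(
            normalized[s], a, panel, mcs, q=config.percentile, min_cells=config.min_cells
        )
        for s, a in assignments.items()
    }
    timepoints = (
        tuple(float(t) for t in cohort.spec.timepoints)
        if cohort.spec is not None
        else (0.0, 4.0, 24.0)
    )
    fm = build_feature_matrix(
        sample_features, cohort.manifest, cohort.clinical, panel, mcs, timepoints=timepoints
    )

    # ---- stage 4: survival -------------------------------------------------
    clin = cohort.clinical.set_index("patient_id").loc[fm.patients]
    time, event = apply_horizon(clin["os_days"], clin["os_event"], config.horizon)
    selection = nested_loocv_select(
        fm.X, time, event, n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio, seed=config.seed,
    )
    top_feature = selection.selection_frequency.index[0]
    groups = median_split(fm.X[top_feature])
    lr = logrank_test(time, event, groups, group_order=("low", "high"))

    report = {
        "seed": config.seed,
        "derived_seeds": seeds,
        "n_patients": len(fm.patients),
        "target_batch": target_batch,
        "validation": report_validate,
        "quantization_error": model.quantization_error,
        "top_feature": top_feature,
        "selection_frequency_top10": selection.selection_frequency.head(10).to_dict(),
        "chosen_lambda": selection.chosen_lambda,
        "selected_features": selection.selected_features,
        "refit": selection.refit.to_dict(orient="index"),
        "median_split": {
            "low": int((groups == "low").sum()),
            "high": int((groups == "high").sum()),
        },
        "logrank": {
            "chi2": lr.chi2,
            "p": lr.p,
            "hazard_ratio_low_high": lr.hazard_ratio,
            "hr_ci": list(lr.hr_ci),
        },
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        checksums = {}
        if config.write_intermediates:
            cio.write_cohort(cohort, out / "cohort") if cohort.truth is not None else None
            cio.quantile_maps_to_json(qmaps, out / "quantile_maps.json")
            cio.som_model_to_json(model, out / "som_model.json")
            for s, a in assignments.items():
                cio.write_assignment(a, out / "assignments" / f"{s}.csv")
            cio.write_feature_matrix(fm, out / "features.tsv")
            selection.selection_frequency.rename("selection_frequency").to_csv(
                out / "selection.tsv", sep="\t"
            )
            for name in ("quantile_maps.json", "som_model.json", "features.tsv", "selection.tsv"):
                checksums[name] = _sha256(out / name)
        report["checksums"] = checksums
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))

    return PipelineResult(
        cohort=cohort,
        normalized=normalized,
        quantile_maps=qmaps,
        model=model,
        assignments=assignments,
        features=fm,
        selection=selection,
        groups=groups,
        logrank=lr,
        report=report,
    )
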