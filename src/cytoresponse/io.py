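"""Plain-text serialization: cell tables as CSV, manifest/clinical/features
as TSV, quantile maps and SOM models as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .core import CellTable, ValidationError
from .features import FeatureMatrix
from .preprocess import ChannelMap, QuantileMap
from .som import SOMConfig, SOMModel


def write_cell_table(table: CellTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=False)
    return path


def read_cell_table(path, sample_id=None, scale="raw", **metadata) -> CellTable:
    data = pd.read_csv(path)
    return CellTable(
        sample_id=sample_id or Path(path).stem, data=data, scale=scale, **metadata
    )


def write_cohort(cohort, outdir) -> dict:
    """Write a synthetic cohort: per-sample CSVs, manifest.tsv, clinical.tsv,
    per-sample ground-truth label CSVs and ground_truth.json.  Returns a map
    of artifact names to paths."""
    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    (outdir / "labels").mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for sid in manifest["sample_id"]:
        p = write_cell_table(cohort.samples[sid], outdir / "cells" / f"{sid}.csv")
        paths.append(str(p.relative_to(outdir)))
        pd.DataFrame({"population": cohort.truth.cell_labels[sid]}).to_csv(
            outdir / "labels" / f"{sid}.csv", index=False
        )
    manifest["path"] = paths
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    truth = {
        "beta": cohort.truth.beta,
        "target_population": cohort.truth.target_population,
        "target_marker": cohort.truth.target_marker,
        "batch_params": cohort.truth.batch_params,
        "patients": cohort.truth.patients.to_dict(orient="records"),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1, default=float))
    return {
        "manifest": outdir / "manifest.tsv",
        "clinical": outdir / "clinical.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }


def read_manifest(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t")
    required = {"sample_id", "patient_id", "timepoint_h", "batch_id", "sample_role"}
    missing = required - set(m.columns)
    if missing:
        raise ValidationError(f"manifest lacks columns: {sorted(missing)}")
    return m


def read_clinical(path) -> pd.DataFrame:
    c = pd.read_csv(path, sep="\t")
    required = {"patient_id", "os_days", "os_event"}
    missing = required - set(c.columns)
    if missing:
        raise ValidationError(f"clinical table lacks columns: {sorted(missing)}")
    return c


def load_cohort_tables(manifest: pd.DataFrame, root) -> dict:
    root = Path(root)
    out = {}
    for r in manifest.itertuples(index=False):
        out[r.sample_id] = read_cell_table(
            root / r.path,
            sample_id=r.sample_id,
            scale="raw",
            patient_id=None if pd.isna(r.patient_id) else r.patient_id,
            timepoint_h=None if pd.isna(r.timepoint_h) else float(r.timepoint_h),
            batch_id=r.batch_id,
            sample_role=r.sample_role,
        )
    return out


# ---- quantile maps ---------------------------------------------------------

def quantile_maps_to_json(maps: dict, path) -> Path:
    obj = {}
    for b, qm in maps.items():
        obj[b] = {
            "target_batch": qm.target_batch,
            "grid_size": qm.grid_size,
            "quantile_method": qm.quantile_method,
            "channels": {
                ch: {
                    "source": cm.source.tolist(),
                    "target": cm.target.tolist(),
                    "passthrough": cm.passthrough,
                }
                for ch, cm in qm.channels.items()
            },
        }
    path = Path(path)
    path.write_text(json.dumps(obj))
    return path


def quantile_maps_from_json(path) -> dict:
    obj = json.loads(Path(path).read_text())
    maps = {}
    for b, rec in obj.items():
        qm = QuantileMap(
            batch_id=b,
            target_batch=rec["target_batch"],
            grid_size=rec["grid_size"],
            quantile_method=rec["quantile_method"],
        )
        for ch, cm in rec["channels"].items():
            qm.channels[ch] = ChannelMap(
                np.array(cm["source"]), np.array(cm["target"]), cm["passthrough"]
            )
        maps[b] = qm
    return maps


# ---- SOM models ------------------------------------------------------------

def som_model_to_json(model: SOMModel, path) -> Path:
    obj = {
        "weights": model.weights.tolist(),
        "channels": list(model.channels),
        "quantization_error": model.quantization_error,
        "node_mc": model.node_mc.tolist() if model.node_mc is not None else None,
        "config": {
            "rows": model.config.rows,
            "cols": model.config.cols,
            "epochs": model.config.epochs,
            "alpha": list(model.config.alpha),
            "sigma": list(model.config.radii),
            "seed": model.config.seed,
        },
    }
    path = Path(path)
    path.write_text(json.dumps(obj))
    return path


def som_model_from_json(path) -> SOMModel:
    obj = json.loads(Path(path).read_text())
    cfg = obj["config"]
    return SOMModel(
        weights=np.array(obj["weights"]),
        channels=tuple(obj["channels"]),
        config=SOMConfig(
            rows=cfg["rows"],
            cols=cfg["cols"],
            epochs=cfg["epochs"],
            alpha=tuple(cfg["alpha"]),
            sigma=tuple(cfg["sigma"]),
            seed=cfg["seed"],
        ),
        quantization_error=obj["quantization_error"],
        node_mc=np.array(obj["node_mc"]) if obj["node_mc"] is not None else None,
    )


# ---- assignments and features ---------------------------------------------

def write_assignment(a: ClusterAssignment, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"cell_index": np.arange(a.n_cells), "node": a.node, "metacluster": a.metacluster}
    ).to_csv(path, index=False)
    return path


def read_assignment(path, sample_id=None) -> ClusterAssignment:
    df = pd.read_csv(path)
    return ClusterAssignment(
        sample_id=sample_id or Path(path).stem,
        node=df["node"].to_numpy(),
        metacluster=df["metacluster"].to_numpy(),
    )


def write_feature_matrix(fm: FeatureMatrix, path_tsv, path_json=None) -> Path:
    path_tsv = Path(path_tsv)
    fm.X.rename_axis("patient_id").to_csv(path_tsv, sep="\t")
    if path_json is None:
        path_json = path_tsv.with_suffix(".json")
    sidecar = {
        "provenance": {
            col: {"metacluster": mc, "marker": marker, "timepoint_h": tp, "transform": tr}
            for col, (mc, marker, tp, tr) in fm.provenance.items()
        },
        "imputation_log": fm.imputation_log,
        "missing": {
            col: fm.missing.index[fm.missing[col]].tolist()
            for col in fm.missing.columns
            if fm.missing[col].any()
        },
    }
    Path(path_json).write_text(json.dumps(sidecar, default=float))
    return path_tsv


def read_feature_matrix(path_tsv) -> pd.DataFrame:
    return pd.read_csv(path_tsv, sep="\t", index_col="patient_id")
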