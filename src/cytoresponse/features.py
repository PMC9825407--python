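"""Patient x feature matrix construction.

For every metacluster and functional marker, the signaling feature is the
90th percentile of the arcsinh-transformed intensity among that sample's
cells of that metacluster (linear interpolation of order statistics).  Per
patient the matrix holds those levels at each timepoint, the 24 h / 0 h
ratio per metacluster x marker, metacluster sizes (% of cells at baseline),
and the clinical covariates age and sex.  The 24 h - 0 h difference (delta)
is available behind a flag.

Features with too few cells (default < 10) are flagged missing and, for the
complete-matrix consumers (penalized Cox), imputed with the cohort column
mean; every imputation is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .core import CellTable, PanelConfig, ValidationError

RATIO_FLOOR = 1e-6  # transformed-scale denominator floor for ratio24h


def cluster_abundance(assignment: ClusterAssignment, metaclusters) -> pd.Series:
    """Percentage of the sample's cells in each metacluster (sums to 100)."""
    if assignment.n_cells == 0:
        raise ValidationError(f"sample {assignment.sample_id}: empty assignment")
    counts = pd.Series(0.0, index=list(metaclusters))
    got = pd.Series(assignment.metacluster).value_counts()
    for mc, c in got.items():
        counts.loc[mc] = c
    return counts / assignment.n_cells * 100.0


def percentile_feature(values, q: float = 0.90, min_cells: int = 10):
    """q-th empirical quantile (type 7) of one marker in one metacluster of
    one sample, or NaN when fewer than ``min_cells`` cells support it."""
    if not 0.0 < q < 1.0:
        raise ValidationError(f"q must be in (0,1), got {q}")
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("percentile input contains non-finite values")
    if values.size < min_cells:
        return np.nan
    return float(np.quantile(values, q, method="linear"))


def extract_sample_features(
    table: CellTable,
    assignment: ClusterAssignment,
    panel: PanelConfig,
    metaclusters,
    q: float = 0.90,
    min_cells: int = 10,
) -> dict:
    """Per-metacluster per-functional-marker percentile levels plus
    metacluster percentages for one sample."""
    if table.n_cells != assignment.n_cells:
        raise ValidationError(
            f"sample {table.sample_id}: {table.n_cells} cells but "
            f"{assignment.n_cells} assignments"
        )
    X = table.values(panel.functional)
    levels = {}
    for mc in metaclusters:
        mask = assignment.metacluster == mc
        sub = X[mask]
        for j, marker in enumerate(panel.functional):
            levels[(mc, marker)] = percentile_feature(sub[:, j], q=q, min_cells=min_cells)
    return {
        "levels": levels,
        "abundance": cluster_abundance(assignment, metaclusters),
    }


@dataclass
class FeatureMatrix:
    """Complete patients x features matrix with provenance.

    ``X`` has unique, named columns and no non-finite entries; ``missing``
    marks entries that were imputed (cohort column mean); ``provenance``
    maps each column to (metacluster, marker, timepoint, transform).
    """

    X: pd.DataFrame
    missing: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    imputation_log: list = field(default_factory=list)

    @property
    def patients(self):
        return list(self.X.index)

    @property
    def columns(self):
        return list(self.X.columns)


def _level_name(mc, marker, tp):
    return f"MC{mc}|{marker}|{tp:g}h"


def build_feature_matrix(
    sample_features: dict,
    manifest: pd.DataFrame,
    clinical: pd.DataFrame,
    panel: PanelConfig,
    metaclusters,
    timepoints=(0.0, 4.0, 24.0),
    include_ratio: bool = True,
    include_delta: bool = False,
    size_timepoint: float = 0.0,
) -> FeatureMatrix:
    """Assemble the patient x feature matrix.

    Parameters
    ----------
    sample_features : dict
        sample_id -> output of :func:`extract_sample_features`.
    manifest, clinical : DataFrame
        Cohort layout and per-patient covariates (age, sex) and survival.
    include_ratio, include_delta : bool
        Whether to add the 24 h / 0 h ratio (default) and 24 h - 0 h delta
        columns per metacluster x marker.
    size_timepoint : float
        Timepoint whose metacluster percentages serve as the size features
        (baseline by default).

    Every patient must have a 0 h and a 24 h sample; intermediate timepoints
    are optional (missing entries are flagged and mean-imputed).
    """
    pm = manifest[manifest["sample_role"] == "patient"]
    patients = list(dict.fromkeys(pm["patient_id"]))
    sample_of = {
        (r.patient_id, float(r.timepoint_h)): r.sample_id
        for r in pm.itertuples(index=False)
    }
    for pid in patients:
        for tp in (0.0, 24.0):
            if (pid, tp) not in sample_of:
                raise ValidationError(f"patient {pid} is missing the {tp:g} h sample")

    timepoints = [float(t) for t in timepoints]
    cols, rows = [], {}
    for mc in metaclusters:
        for marker in panel.functional:
            for tp in timepoints:
                cols.append((_level_name(mc, marker, tp), (mc, marker, tp, "level")))
    if include_ratio:
        for mc in metaclusters:
            for marker in panel.functional:
                cols.append((f"MC{mc}|{marker}|ratio24h", (mc, marker, None, "ratio24h")))
    if include_delta:
        for mc in metaclusters:
            for marker in panel.functional:
                cols.append((f"MC{mc}|{marker}|delta24h", (mc, marker, None, "delta24h")))
    for mc in metaclusters:
        cols.append((f"MC{mc}|size", (mc, None, size_timepoint, "size")))
    cols.append(("age", (None, None, None, "clinical")))
    cols.append(("sex", (None, None, None, "clinical")))

    clin = clinical.set_index("patient_id")
    sex_code = {"F": 0.0, "M": 1.0}
    for pid in patients:
        row = {}
        feats = {
            tp: sample_features.get(sample_of.get((pid, tp)))
            for tp in timepoints
        }
        for mc in metaclusters:
            for marker in panel.functional:
                for tp in timepoints:
                    f = feats[tp]
                    row[_level_name(mc, marker, tp)] = (
                        f["levels"][(mc, marker)] if f is not None else np.nan
                    )
                v0 = row[_level_name(mc, marker, 0.0)]
                v24 = row[_level_name(mc, marker, 24.0)]
                if include_ratio:
                    ok = np.isfinite(v0) and np.isfinite(v24) and abs(v0) > RATIO_FLOOR
                    row[f"MC{mc}|{marker}|ratio24h"] = v24 / v0 if ok else np.nan
                if include_delta:
                    ok = np.isfinite(v0) and np.isfinite(v24)
                    row[f"MC{mc}|{marker}|delta24h"] = v24 - v0 if ok else np.nan
        size_f = feats.get(size_timepoint)
        for mc in metaclusters:
            row[f"MC{mc}|size"] = (
                float(size_f["abundance"].loc[mc]) if size_f is not None else np.nan
            )
        row["age"] = float(clin.loc[pid, "age"])
        row["sex"] = sex_code.get(str(clin.loc[pid, "sex"]), np.nan)
        rows[pid] = row

    names = [c for c, _ in cols]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate feature column names")
    X = pd.DataFrame.from_dict(rows, orient="index")[names]
    missing = X.isna()
    log = []
    col_means = X.mean(axis=0, skipna=True)
    for col in X.columns:
        if missing[col].any():
            fill = col_means[col] if np.isfinite(col_means[col]) else 0.0
            for pid in X.index[missing[col]]:
                log.append({"patient_id": pid, "feature": col, "imputed": float(fill)})
            X[col] = X[col].fillna(fill)
    return FeatureMatrix(
        X=X, missing=missing, provenance=dict(cols), imputation_log=log
    )
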