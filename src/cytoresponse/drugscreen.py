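"""Ex vivo drug-sensitivity scoring.

Plates carry a 5-point, 10-fold dose series per drug (1 nM to 10 uM in the
reference design) with positive (total-kill) and negative (vehicle) control
wells.  Readouts are normalized per plate to percent inhibition between the
control medians; the drug sensitivity score (DSS) is the normalized area
under the inhibition vs log10-concentration curve above an activity
threshold (a DSS1-style convention, threshold 10% by default, isotonic
monotone smoothing before trapezoidal integration); the selective score
(sDSS) subtracts the mean DSS of healthy-donor samples per drug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .core import ValidationError

CLIP_RANGE = (-10.0, 110.0)

PLATE_COLUMNS = ("plate_id", "well", "drug", "conc_nM", "readout", "control_type")


@dataclass
class PlateQC:
    plate_id: str
    neg_median: float
    pos_median: float
    n_clipped: int = 0


def normalize_plate(plate: pd.DataFrame) -> tuple:
    """Percent inhibition per drug well, anchored at the plate's control
    medians: 0% at the negative (DMSO) median, 100% at the positive (BzCl)
    median.  Invariant to affine rescaling of the raw readout."""
    for col in ("drug", "conc_nM", "readout", "control_type"):
        if col not in plate.columns:
            raise ValidationError(f"plate table lacks column {col!r}")
    neg = plate.loc[plate["control_type"] == "negative", "readout"]
    pos = plate.loc[plate["control_type"] == "positive", "readout"]
    if neg.empty or pos.empty:
        raise ValidationError("plate needs at least one positive and one negative control")
    neg_med, pos_med = float(neg.median()), float(pos.median())
    if neg_med <= pos_med:
        raise ValidationError(
            f"plate quality failure: negative-control median {neg_med} <= "
            f"positive-control median {pos_med}"
        )
    wells = plate[plate["control_type"].isna() | (plate["control_type"] == "")].copy()
    if (wells["conc_nM"] <= 0).any():
        raise ValidationError("drug concentrations must be positive")
    wells["inhibition"] = 100.0 * (neg_med - wells["readout"]) / (neg_med - pos_med)
    plate_id = str(plate["plate_id"].iloc[0]) if "plate_id" in plate.columns else ""
    return wells, PlateQC(plate_id, neg_med, pos_med)


def compute_dss(
    inhibition, conc_nM, activity_threshold: float = 10.0, smooth: bool = True
) -> float:
    """DSS in [0, 100]: thresholded normalized area under the monotone
    (isotonic) inhibition curve over log10 concentration."""
    y = np.asarray(inhibition, dtype=float)
    x = np.asarray(conc_nM, dtype=float)
    if y.size < 2:
        raise ValidationError("DSS needs at least 2 dose points")
    if np.any(x <= 0):
        raise ValidationError("concentrations must be positive")
    order = np.argsort(x)
    x, y = np.log10(x[order]), y[order]
    n_clip = int(np.sum((y < CLIP_RANGE[0]) | (y > CLIP_RANGE[1])))
    if n_clip:
        warnings.warn(f"{n_clip} inhibition values clipped to {CLIP_RANGE}")
    y = np.clip(y, *CLIP_RANGE)
    if smooth:
        y = IsotonicRegression(increasing=True).fit_transform(x, y)
    t = activity_threshold
    area = np.trapezoid(np.maximum(y - t, 0.0), x)
    norm = (100.0 - t) * (x[-1] - x[0])
    return float(np.clip(100.0 * area / norm, 0.0, 100.0))


def score_sample(
    wells: pd.DataFrame, activity_threshold: float = 10.0, smooth: bool = True
) -> pd.DataFrame:
    """Per-drug DSS from normalized wells (columns drug, conc_nM, inhibition)."""
    rows = []
    for drug, g in wells.groupby("drug", sort=True):
        rows.append(
            {
                "drug": drug,
                "dss": compute_dss(
                    g["inhibition"].to_numpy(), g["conc_nM"].to_numpy(),
                    activity_threshold, smooth,
                ),
            }
        )
    return pd.DataFrame(rows)


def compute_sdss(patient_dss: pd.DataFrame, healthy_dss: list) -> pd.DataFrame:
    """sDSS = patient DSS minus the mean healthy-donor DSS per drug.

    Drugs absent from every healthy table get a warning and a missing sDSS.
    """
    healthy = pd.concat(healthy_dss, ignore_index=True)
    healthy_mean = healthy.groupby("drug")["dss"].mean()
    out = patient_dss.copy()
    out["healthy_mean_dss"] = out["drug"].map(healthy_mean)
    missing = out.loc[out["healthy_mean_dss"].isna(), "drug"].tolist()
    if missing:
        warnings.warn(f"no healthy-control DSS for drugs: {missing}; sDSS left missing")
    out["sdss"] = out["dss"] - out["healthy_mean_dss"]
    return out


def top_targets(
    sdss_tables: dict, drug_targets: dict, n: int = 10
) -> pd.DataFrame:
    """Tally drug targets among each sample's top-n drugs by sDSS.

    ``sdss_tables`` maps sample_id -> sDSS table; ``drug_targets`` maps drug
    -> target label.  Ties at the cutoff break lexicographically by drug
    name; samples with fewer than n scored drugs use all of them (with a
    warning).  Returns a target x count tally across samples (a target
    counts once per sample).
    """
    if not drug_targets:
        raise ValidationError("empty drug -> target map")
    counts: dict = {}
    for sid, tab in sdss_tables.items():
        scored = tab.dropna(subset=["sdss"]).sort_values(
            ["sdss", "drug"], ascending=[False, True]
        )
        if len(scored) < n:
            warnings.warn(f"sample {sid}: only {len(scored)} scored drugs (< {n})")
        top = scored.head(n)
        targets = {drug_targets.get(d) for d in top["drug"] if d in drug_targets}
        for t in targets:
            counts[t] = counts.get(t, 0) + 1
    out = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0]))),
        columns=["target", "n_patients"],
    )
    return out


def simulate_plate(
    drugs: dict,
    plate_id: str = "PL1",
    conc_nM=(1.0, 10.0, 100.0, 1000.0, 10000.0),
    n_controls: int = 8,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic viability plate for testing the scoring path.

    ``drugs`` maps drug name -> (ec50_nM, max_inhibition); wells follow a
    Hill curve (slope 1) plus Gaussian noise, on a luminescence-like raw
    scale where the negative-control median is 10000 and the positive 200.
    """
    rng = np.random.default_rng(seed)
    neg_level, pos_level = 10000.0, 200.0
    rows = []
    w = 1
    for drug, (ec50, maxinh) in sorted(drugs.items()):
        for c in conc_nM:
            inh = maxinh * c / (c + ec50)
            frac = 1.0 - inh / 100.0
            readout = pos_level + (neg_level - pos_level) * frac + rng.normal(0, noise_sd * 100)
            rows.append((plate_id, f"W{w:03d}", drug, c, max(readout, 0.0), ""))
            w += 1
    for _ in range(n_controls):
        rows.append((plate_id, f"W{w:03d}", "DMSO", 1.0, neg_level + rng.normal(0, noise_sd * 100), "negative"))
        w += 1
    for _ in range(n_controls):
        rows.append((plate_id, f"W{w:03d}", "BzCl", 1.0, pos_level + rng.normal(0, noise_sd * 100), "positive"))
        w += 1
    return pd.DataFrame(rows, columns=list(PLATE_COLUMNS))
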