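"""Manual bi-axial gating of blasts (CD45-low / CD66b-low) as a validation
path alongside the clustering pipeline.

Analyst-set gates are accepted verbatim; a reproducible default derives each
threshold from a quantile of a healthy reference sample (granulocytes are
CD66b-high, mature lymphocytes CD45-high, so immature cells sit below both
thresholds).  Gated signaling features follow the bi-axial convention of
taking the 90th percentile on the *raw* dual counts of the gated cells and
arcsinh-transforming that single number — deliberately the reverse order of
the clustering pipeline (transform, then percentile); with a strictly
increasing transform the two orders rank patients identically up to
interpolation effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RAW, TRANSFORMED, CellTable, ValidationError
from .features import percentile_feature

#: The CD45 cut must land *above* the granulocyte CD45 mode (granulocytes
#: are ~60% of a healthy sample and CD45-low themselves) but below the
#: mature lymphoid/monocyte range, so immature cells are captured whole and
#: mature mononuclear cells excluded; granulocytes are removed by the CD66b
#: cut instead.
DEFAULT_GATE_QUANTILES = {"CD45": 0.65, "CD66b": 0.90}

#: CD45 quantile above which healthy cells are treated as the lymphoid
#: subset when deriving the CD66b threshold (granulocytes dominate a healthy
#: sample, so the CD66b cut must come from the CD66b-low lineages; the top
#: 20% by CD45 is safely beyond the granulocyte mode)
LYMPHOID_CD45_QUANTILE = 0.8


@dataclass(frozen=True)
class BiaxialGate:
    """Upper thresholds on the transformed scale for two channels; cells
    strictly below both are retained."""

    channel_x: str
    channel_y: str
    threshold_x: float
    threshold_y: float
    provenance: str = "manual"

    def __post_init__(self):
        if not (np.isfinite(self.threshold_x) and np.isfinite(self.threshold_y)):
            raise ValidationError("gate thresholds must be finite")


def derive_thresholds(
    reference: CellTable,
    channel_x: str = "CD45",
    channel_y: str = "CD66b",
    q: dict | None = None,
    lymphoid_quantile: float = LYMPHOID_CD45_QUANTILE,
) -> BiaxialGate:
    """Derive gate thresholds from quantiles of a healthy reference sample.

    The x (CD45) threshold is a straight quantile of the whole reference.
    The y (CD66b) threshold is a quantile of the *lymphoid* cells only —
    those above the ``lymphoid_quantile`` of channel x — because the
    reference is dominated by CD66b-high granulocytes and a whole-sample
    quantile would sit inside the granulocyte mode, excluding nothing.
    """
    if reference.n_cells == 0:
        raise ValidationError("empty reference sample")
    if reference.scale != TRANSFORMED:
        raise ValidationError("reference must be on the transformed scale")
    q = {**DEFAULT_GATE_QUANTILES, **(q or {})}
    x = reference.values([channel_x])[:, 0]
    y = reference.values([channel_y])[:, 0]
    tx = float(np.quantile(x, q.get(channel_x, 0.5)))
    lymphoid = y[x >= np.quantile(x, lymphoid_quantile)]
    if lymphoid.size == 0:
        lymphoid = y
    ty = float(np.quantile(lymphoid, q.get(channel_y, 0.5)))
    return BiaxialGate(channel_x, channel_y, tx, ty, provenance="reference-derived")


def apply_gate(sample: CellTable, gate: BiaxialGate) -> CellTable:
    """Retain cells with value_x < threshold_x and value_y < threshold_y."""
    x = sample.values([gate.channel_x])[:, 0]
    y = sample.values([gate.channel_y])[:, 0]
    keep = (x < gate.threshold_x) & (y < gate.threshold_y)
    return sample.with_data(sample.data.loc[keep].reset_index(drop=True))


def gated_percentile_feature(
    sample: CellTable,
    gate: BiaxialGate,
    marker: str,
    q: float = 0.90,
    min_cells: int = 10,
    cofactor: float = 5.0,
    raw_data: CellTable | None = None,
):
    """90th-percentile signaling of the gated population.

    Gating happens on the (normalized) transformed sample; the percentile is
    taken on the corresponding raw dual counts and then arcsinh-transformed
    (``raw_data`` supplies raw values matching ``sample`` row-for-row;
    without it the transformed values are inverted with sinh).
    """
    x = sample.values([gate.channel_x])[:, 0]
    y = sample.values([gate.channel_y])[:, 0]
    keep = (x < gate.threshold_x) & (y < gate.threshold_y)
    if raw_data is not None:
        if raw_data.scale != RAW or raw_data.n_cells != sample.n_cells:
            raise ValidationError("raw_data must be a raw-scale table matching the sample")
        vals = raw_data.values([marker])[:, 0][keep]
    else:
        vals = cofactor * np.sinh(sample.values([marker])[:, 0][keep])
    p90_raw = percentile_feature(vals, q=q, min_cells=min_cells)
    return float(np.arcsinh(p90_raw / cofactor)) if np.isfinite(p90_raw) else np.nan


def gated_blast_fraction(sample: CellTable, gate: BiaxialGate) -> float:
    """Fraction of the sample's cells inside the blast gate."""
    if sample.n_cells == 0:
        raise ValidationError("empty sample")
    return apply_gate(sample, gate).n_cells / sample.n_cells
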