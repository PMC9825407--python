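"""Variance-stabilizing transform and reference-anchored batch standardization.

Every batch carries an aliquot of the same reference material.  For each
channel we compute the empirical quantiles of each batch's reference at a
fixed grid (0%, 1%, ..., 100% by default), and correct a batch by the
piecewise-linear map sending its reference quantiles onto the quantiles of a
chosen target batch's reference — quantile normalization against anchors,
without any clustering step.  Because the map is monotone, within-channel
cell rankings (and hence which cell attains a given percentile) are
preserved.

Quantiles use linear interpolation of order statistics (the "type 7"
convention, numpy's default); this choice is recorded in the serialized map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import RAW, TRANSFORMED, CellTable, PanelConfig, ValidationError


def arcsinh_transform(table: CellTable, cofactor: float = 5.0) -> CellTable:
    """Replace every value x by asinh(x / cofactor); strictly monotone."""
    if cofactor <= 0:
        raise ValidationError(f"cofactor must be > 0, got {cofactor}")
    if table.scale != RAW:
        raise ValidationError(f"sample {table.sample_id} is already transformed")
    data = np.arcsinh(table.data / cofactor)
    return table.with_data(data, scale=TRANSFORMED)


def inverse_arcsinh(table: CellTable, cofactor: float = 5.0) -> CellTable:
    """Back-transform to the raw scale: x = cofactor * sinh(v)."""
    if cofactor <= 0:
        raise ValidationError(f"cofactor must be > 0, got {cofactor}")
    if table.scale != TRANSFORMED:
        raise ValidationError(f"sample {table.sample_id} is not on the transformed scale")
    data = cofactor * np.sinh(table.data)
    return table.with_data(data, scale=RAW)


@dataclass
class ChannelMap:
    """Piecewise-linear correction for one channel of one batch.

    ``source``/``target`` are matched knot vectors (non-decreasing).  Outside
    the knot range the terminal segments extend linearly; the terminal slope
    is a secant over the outermost few knots (the ~5% tail window) rather
    than the outermost pair, because with finite references the spacing of
    the two extreme order statistics is far too noisy to extrapolate from —
    cells beyond the reference's support (e.g. a population absent from the
    reference material) would otherwise be mapped to wild values.
    ``passthrough`` marks degenerate channels (constant reference) left
    uncorrected.
    """

    source: np.ndarray
    target: np.ndarray
    passthrough: bool = False
    tail_window: int = 5

    def _tail_slopes(self):
        s, t = self.source, self.target
        w = min(self.tail_window, len(s) - 1)
        lo = (t[w] - t[0]) / (s[w] - s[0]) if s[w] > s[0] else 1.0
        hi = (t[-1] - t[-1 - w]) / (s[-1] - s[-1 - w]) if s[-1] > s[-1 - w] else 1.0
        return lo, hi

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.passthrough:
            return x.copy()
        s, t = self.source, self.target
        y = np.interp(x, s, t)
        lo_slope, hi_slope = self._tail_slopes()
        below = x < s[0]
        above = x > s[-1]
        y[below] = t[0] + (x[below] - s[0]) * lo_slope
        y[above] = t[-1] + (x[above] - s[-1]) * hi_slope
        return y


@dataclass
class QuantileMap:
    """Per-channel piecewise-linear corrections anchoring one batch onto the
    target batch's reference quantiles."""

    batch_id: str
    target_batch: str
    channels: dict = field(default_factory=dict)  # channel -> ChannelMap
    grid_size: int = 101
    quantile_method: str = "linear"  # type 7

    @property
    def is_identity(self) -> bool:
        return self.batch_id == self.target_batch


def _dedup_knots(source: np.ndarray, target: np.ndarray):
    """Collapse duplicate source knots (zero-inflated channels).

    Consecutive identical source knots become one knot whose target is the
    *median* of their targets, so tied inputs map to a single well-defined
    value.  The median (not the mean) is essential for atoms: both
    references carry an atom at the same point of the distribution whose
    masses differ only by sampling noise, so the majority of the tied
    knots' targets equal the target's own atom value and the median maps
    atom onto atom exactly; a mean would be dragged off the atom by the few
    above-atom knots, displacing the full atom mass in distribution
    distance.  Returns None if fewer than 2 distinct knots remain
    (degenerate channel).
    """
    uniq, inverse = np.unique(source, return_inverse=True)
    if uniq.size < 2:
        return None
    tgt = np.array(
        [np.median(target[inverse == g]) for g in range(uniq.size)]
    )
    # clamp float noise so the target knots stay non-decreasing
    tgt = np.maximum.accumulate(tgt)
    return uniq, tgt


def fit_quantile_maps(
    references: dict,
    target_batch: str,
    grid_size: int = 101,
    channels=None,
) -> dict:
    """Fit one QuantileMap per batch from its reference aliquot.

    Parameters
    ----------
    references : dict
        batch_id -> CellTable of that batch's reference aliquot, on the
        transformed scale.
    target_batch : str
        Batch whose reference defines the common frame (its own map is the
        identity).  The choice of standard is a study decision and must be
        explicit.
    grid_size : int
        Number of quantile knots; the default 101 anchors at 0%, 1%, ..., 100%.
    channels : sequence of str, optional
        Channels to correct; defaults to all channels of the target reference.
    """
    if target_batch not in references:
        raise ValidationError(f"no reference aliquot for target batch {target_batch!r}")
    for b, t in references.items():
        if t.scale != TRANSFORMED:
            raise ValidationError(f"reference for batch {b} must be on the transformed scale")
    grid = np.linspace(0.0, 1.0, grid_size)
    ref_t = references[target_batch]
    if channels is None:
        channels = ref_t.channels
    target_q = {}
    for ch in channels:
        target_q[ch] = np.quantile(ref_t.values([ch])[:, 0], grid, method="linear")

    maps = {}
    for b, ref in sorted(references.items()):
        qm = QuantileMap(batch_id=b, target_batch=target_batch, grid_size=grid_size)
        if ref.n_cells < grid_size:
            warnings.warn(
                f"reference for batch {b} has {ref.n_cells} < {grid_size} cells; "
                "effective grid reduced to the sample size"
            )
        for ch in channels:
            if b == target_batch:
                q = target_q[ch]
                knots = _dedup_knots(q, q)
            else:
                src = np.quantile(ref.values([ch])[:, 0], grid, method="linear")
                knots = _dedup_knots(src, target_q[ch])
            if knots is None:
                warnings.warn(
                    f"batch {b} channel {ch}: constant reference, leaving channel uncorrected"
                )
                qm.channels[ch] = ChannelMap(
                    np.array([0.0, 1.0]), np.array([0.0, 1.0]), passthrough=True
                )
            else:
                qm.channels[ch] = ChannelMap(*knots)
        maps[b] = qm
    return maps


def apply_quantile_maps(
    table: CellTable, qmap: QuantileMap, passthrough_channels=()
) -> CellTable:
    """Correct a transformed-scale sample with its batch's quantile map.

    Channels covered by the map are interpolated between knots (terminal
    segments extend linearly); channels listed in ``passthrough_channels``
    are left untouched; any other channel raises.
    """
    if table.scale != TRANSFORMED:
        raise ValidationError(f"sample {table.sample_id} must be on the transformed scale")
    if table.batch_id is not None and table.batch_id != qmap.batch_id:
        raise ValidationError(
            f"sample {table.sample_id} is from batch {table.batch_id}, "
            f"map is for batch {qmap.batch_id}"
        )
    df = table.data.copy()
    for ch in df.columns:
        if ch in qmap.channels:
            df[ch] = qmap.channels[ch](df[ch].to_numpy(dtype=float))
        elif ch in passthrough_channels:
            continue
        else:
            raise ValidationError(
                f"channel {ch!r} missing from quantile map for batch {qmap.batch_id} "
                "and not declared pass-through"
            )
    return table.with_data(df)


def normalize_cohort(
    tables,
    references: dict,
    target_batch: str,
    panel: PanelConfig,
    grid_size: int = 101,
):
    """End-to-end standardization: arcsinh-transform everything, fit the
    quantile maps on the reference aliquots, and correct every sample by its
    batch's map.  Clustering and functional channels are corrected; excluded
    channels pass through untouched.

    Returns (normalized tables in input order, fitted maps).
    """
    refs_t = {
        b: arcsinh_transform(t, panel.cofactor) if t.scale == RAW else t
        for b, t in references.items()
    }
    maps = fit_quantile_maps(
        refs_t, target_batch, grid_size=grid_size, channels=panel.normalized_channels
    )
    out = []
    for t in tables:
        tt = arcsinh_transform(t, panel.cofactor) if t.scale == RAW else t
        if tt.batch_id not in maps:
            raise ValidationError(f"sample {t.sample_id}: no reference for batch {tt.batch_id}")
        out.append(
            apply_quantile_maps(tt, maps[tt.batch_id], passthrough_channels=panel.excluded)
        )
    return out, maps
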