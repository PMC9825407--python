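"""Core containers: cell tables and panel configuration.

A mass cytometry sample is a cells x channels matrix of non-negative "dual
count" intensities.  Channels play one of three roles: *clustering* (surface
markers used to define cell populations), *functional* (intracellular
phospho-protein / signaling readouts), or *excluded* (measured but kept out of
clustering, e.g. channels with batch-variable staining).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RAW = "raw"
TRANSFORMED = "transformed"

SAMPLE_ROLES = ("patient", "healthy_donor", "batch_reference")

#: Surface markers used for clustering (19 channels).
CLUSTERING_CHANNELS = (
    "AXL", "CD117", "CD123", "CD14", "CD16", "CD20", "CD3", "CD33", "CD34",
    "CD38", "CD4", "CD45", "CD56", "CD64", "CD66b", "CD7", "CD8a", "CD90",
    "HLA-DR",
)

#: Surface markers measured but excluded from top-level clustering.
EXCLUDED_CHANNELS = ("CD25", "CD11b")

#: Intracellular signaling readouts (15 channels).
FUNCTIONAL_CHANNELS = (
    "cCaspase3", "CyclinB1", "p-4E-BP1", "p-AKT", "p-AXL", "p-CREB",
    "p-ERK1/2", "p-Histone3", "p-NF-kB-p65", "p-p38", "p-Rb", "p-S6",
    "p-STAT1", "p-STAT3", "p-STAT5",
)


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class PanelConfig:
    """Channel roles and the arcsinh cofactor.

    Parameters
    ----------
    clustering : tuple of str
        Surface channels used for clustering.
    functional : tuple of str
        Signaling channels summarized into features.
    excluded : tuple of str
        Measured channels excluded from clustering (still normalized and
        available for sub-clustering on "all surface markers").
    cofactor : float
        Divisor ``c`` of the variance-stabilizing transform ``asinh(x / c)``.
        The mass cytometry convention is 5.
    """

    clustering: tuple = CLUSTERING_CHANNELS
    functional: tuple = FUNCTIONAL_CHANNELS
    excluded: tuple = EXCLUDED_CHANNELS
    cofactor: float = 5.0

    def __post_init__(self):
        if self.cofactor <= 0:
            raise ValidationError(f"cofactor must be > 0, got {self.cofactor}")
        overlap = set(self.clustering) & set(self.functional)
        if overlap:
            raise ValidationError(
                f"channels cannot be both clustering and functional: {sorted(overlap)}"
            )
        dup = [c for c in self.all_channels if list(self.all_channels).count(c) > 1]
        if dup:
            raise ValidationError(f"duplicate channel names: {sorted(set(dup))}")

    @property
    def all_channels(self) -> tuple:
        return tuple(self.clustering) + tuple(self.excluded) + tuple(self.functional)

    @property
    def surface_channels(self) -> tuple:
        """All surface markers (clustering + excluded), used for sub-clustering."""
        return tuple(self.clustering) + tuple(self.excluded)

    @property
    def normalized_channels(self) -> tuple:
        """Channels that batch standardization corrects (clustering + functional)."""
        return tuple(self.clustering) + tuple(self.functional)


def default_panel() -> PanelConfig:
    """The default 19-clustering / 15-functional panel with cofactor 5."""
    return PanelConfig()


@dataclass
class CellTable:
    """One sample's cells x channels intensities plus sample metadata.

    ``scale`` tracks whether values are raw dual counts (non-negative) or
    arcsinh-transformed.  Operations that require one scale refuse the other.
    """

    sample_id: str
    data: pd.DataFrame
    scale: str = RAW
    patient_id: str | None = None
    timepoint_h: float | None = None
    batch_id: str | None = None
    sample_role: str = "patient"

    def __post_init__(self):
        if self.scale not in (RAW, TRANSFORMED):
            raise ValidationError(f"scale must be 'raw' or 'transformed', got {self.scale!r}")
        if self.sample_role not in SAMPLE_ROLES:
            raise ValidationError(
                f"sample_role must be one of {SAMPLE_ROLES}, got {self.sample_role!r}"
            )
        if self.scale == RAW and len(self.data) and (self.data.to_numpy() < 0).any():
            raise ValidationError(f"sample {self.sample_id}: negative raw intensities")

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> tuple:
        return tuple(self.data.columns)

    def values(self, channels=None) -> np.ndarray:
        cols = list(channels) if channels is not None else list(self.data.columns)
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValidationError(f"sample {self.sample_id}: missing channels {missing}")
        return self.data[cols].to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "CellTable":
        return replace(self, data=data, scale=scale if scale is not None else self.scale)

    def metadata(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "patient_id": self.patient_id,
            "timepoint_h": self.timepoint_h,
            "batch_id": self.batch_id,
            "sample_role": self.sample_role,
        }
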