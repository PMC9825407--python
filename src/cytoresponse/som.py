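"""Self-organizing map: online training on a rectangular grid.

The SOM is trained with the classic sequential rule: for each presented cell
the best-matching unit (BMU) is found by Euclidean distance and all node
weights are pulled toward the cell with a Gaussian neighborhood kernel on
the grid.  Learning rate and neighborhood radius decay linearly over
training.  Training order is shuffled per epoch from the seed, so a given
data + config + seed always yields identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .core import CellTable, PanelConfig, ValidationError


@dataclass(frozen=True)
class SOMConfig:
    rows: int = 5
    cols: int = 5
    epochs: int = 10
    alpha: tuple = (0.05, 0.01)       # initial, final learning rate
    sigma: tuple | None = None        # initial, final radius; default (max(grid)/2, 0.5)
    refine_epochs: int = 10           # zero-radius convergence passes (centroid snap)
    seed: int = 0

    def validate(self):
        if self.rows < 1 or self.cols < 1:
            raise ValidationError("grid dimensions must be >= 1")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        a0, a1 = self.alpha
        if a0 <= 0 or a1 <= 0 or a1 > a0:
            raise ValidationError("learning rate must be positive and non-increasing")
        s0, s1 = self.radii
        if s0 <= 0 or s1 <= 0 or s1 > s0:
            raise ValidationError("neighborhood radius must be positive and non-increasing")

    @property
    def radii(self) -> tuple:
        if self.sigma is not None:
            return self.sigma
        return (max(self.rows, self.cols) / 2.0, 0.5)

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols


@dataclass
class SOMModel:
    """Trained node weights plus (after metaclustering) node labels."""

    weights: np.ndarray               # (n_nodes, n_channels)
    channels: tuple
    config: SOMConfig
    quantization_error: float
    node_counts: np.ndarray | None = None  # training cells per node (BMU counts)
    node_mc: np.ndarray | None = None  # node -> metacluster label in 1..k

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def nearest_nodes(self, X: np.ndarray) -> np.ndarray:
        """Index of the Euclidean-nearest node per row (ties -> lowest index)."""
        if X.shape[0] == 0:
            return np.empty(0, dtype=int)
        d = cdist(np.asarray(X, dtype=float), self.weights, metric="sqeuclidean")
        return np.argmin(d, axis=1)


def _grid_positions(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


@njit(cache=False)
def _som_train_kernel(data, weights, grid_d2, order, alpha0, alpha1, sigma0, sigma1):
    n, d = data.shape
    m = weights.shape[0]
    total = order.shape[0]
    for step in range(total):
        frac = step / total
        alpha = alpha0 + (alpha1 - alpha0) * frac
        sigma = sigma0 + (sigma1 - sigma0) * frac
        x = data[order[step]]
        best = 0
        best_d = np.inf
        for j in range(m):
            dist = 0.0
            for k in range(d):
                diff = x[k] - weights[j, k]
                dist += diff * diff
            if dist < best_d:
                best_d = dist
                best = j
        denom = 2.0 * sigma * sigma
        for j in range(m):
            h = alpha * np.exp(-grid_d2[best, j] / denom)
            if h > 1e-7:
                for k in range(d):
                    weights[j, k] += h * (x[k] - weights[j, k])


def _as_matrix(cells, channels):
    if isinstance(cells, np.ndarray):
        return np.asarray(cells, dtype=float)
    if isinstance(cells, CellTable):
        return cells.values(channels)
    # sequence of CellTables: pool
    return np.vstack([t.values(channels) for t in cells])


def pool_cells(tables, channels, max_cells_per_sample=None, seed=0):
    """Pool cells from several samples into one matrix, optionally capping
    each sample at ``max_cells_per_sample`` seeded random cells."""
    rng = np.random.default_rng(seed)
    blocks = []
    for t in tables:
        X = t.values(channels)
        if max_cells_per_sample is not None and len(X) > max_cells_per_sample:
            idx = np.sort(rng.choice(len(X), size=max_cells_per_sample, replace=False))
            X = X[idx]
        blocks.append(X)
    return np.vstack(blocks)


def train_som(cells, panel_or_channels, config: SOMConfig | None = None) -> SOMModel:
    """Train a SOM on pooled cells.

    ``cells`` may be a matrix, a CellTable, or a sequence of CellTables
    (pooled); ``panel_or_channels`` selects the clustering channels (a
    PanelConfig, or an explicit channel sequence; ignored for a bare matrix
    with channel names attached later).
    """
    config = config or SOMConfig()
    config.validate()
    if isinstance(panel_or_channels, PanelConfig):
        channels = tuple(panel_or_channels.clustering)
    else:
        channels = tuple(panel_or_channels)
    X = _as_matrix(cells, channels)
    if not np.all(np.isfinite(X)):
        raise ValidationError("training data contains non-finite values")
    m = config.n_nodes
    if X.shape[0] < m:
        raise ValidationError(f"need at least {m} cells to train a {config.rows}x{config.cols} SOM")
    rng = np.random.default_rng(config.seed)
    init_idx = rng.choice(X.shape[0], size=m, replace=False)
    weights = X[init_idx].copy()
    order = np.concatenate(
        [rng.permutation(X.shape[0]) for _ in range(config.epochs)]
    ).astype(np.int64)
    grid_d2 = cdist(
        _grid_positions(config.rows, config.cols),
        _grid_positions(config.rows, config.cols),
        metric="sqeuclidean",
    )
    a0, a1 = config.alpha
    s0, s1 = config.radii
    _som_train_kernel(X, weights, grid_d2, order, a0, a1, s0, s1)
    # convergence phase: zero-radius passes snap each node to the centroid of
    # its best-matching cells, so node weights are true local centers
    for _ in range(config.refine_epochs):
        bmu = np.argmin(cdist(X, weights, metric="sqeuclidean"), axis=1)
        for j in range(m):
            mask = bmu == j
            if mask.any():
                weights[j] = X[mask].mean(axis=0)
    d = cdist(X, weights, metric="sqeuclidean")
    bmu = np.argmin(d, axis=1)
    qe = float(np.sqrt(d[np.arange(len(X)), bmu]).mean())
    counts = np.bincount(bmu, minlength=m)
    return SOMModel(
        weights=weights, channels=channels, config=config,
        quantization_error=qe, node_counts=counts,
    )
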