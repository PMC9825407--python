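"""Consensus metaclustering of SOM nodes and cell-to-cluster assignment.

Nodes are grouped into k metaclusters by consensus hierarchical clustering:
the node weights are repeatedly subsampled and cut into k groups by
average-linkage hierarchical clustering; the frequency with which two nodes
land in the same group over the resamples forms a consensus matrix, and the
final node labels come from average-linkage clustering of 1 - consensus.

Post-treatment cells are assigned to the Euclidean-nearest trained node
("closest cluster center") and inherit that node's metacluster label; a flag
switches to nearest-metacluster-centroid assignment instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .core import CellTable, PanelConfig, ValidationError
from .som import SOMConfig, SOMModel, train_som


@dataclass
class ClusterAssignment:
    sample_id: str
    node: np.ndarray          # per-cell node index
    metacluster: np.ndarray   # per-cell metacluster label (1..k)

    @property
    def n_cells(self) -> int:
        return len(self.node)


def _relabel_first_seen(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary cluster ids to 1..k in order of first appearance."""
    mapping, out = {}, np.empty_like(labels)
    nxt = 1
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def consensus_matrix(
    weights: np.ndarray,
    k: int,
    n_resamples: int = 100,
    subsample: float = 0.9,
    seed: int = 0,
    linkage_method: str = "ward",
) -> np.ndarray:
    """Co-assignment frequency of node pairs over resampled clusterings."""
    m = weights.shape[0]
    rng = np.random.default_rng(seed)
    size = max(2, int(np.ceil(subsample * m)))
    co = np.zeros((m, m))
    cnt = np.zeros((m, m))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(m, size=size, replace=False))
        Z = linkage(weights[idx], method=linkage_method, metric="euclidean")
        labs = fcluster(Z, t=min(k, size), criterion="maxclust")
        same = labs[:, None] == labs[None, :]
        cnt[np.ix_(idx, idx)] += 1.0
        co[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore"):
        cons = np.where(cnt > 0, co / np.maximum(cnt, 1), 0.5)
    np.fill_diagonal(cons, 1.0)
    return cons


def metacluster(
    model: SOMModel,
    k: int = 10,
    n_resamples: int = 100,
    subsample: float = 0.9,
    seed: int = 0,
    min_occupancy: float = 0.005,
    linkage_method: str = "ward",
) -> SOMModel:
    """Attach a node -> metacluster label map (1..k) to a trained SOM.

    Nodes holding fewer than ``min_occupancy`` of the training cells
    represent essentially no population; they are excluded from the
    consensus (where they would otherwise survive as outlier singletons and
    consume clusters) and afterwards inherit the label of the nearest
    retained node in weight space.
    """
    m = model.n_nodes
    if not 1 <= k <= m:
        raise ValidationError(f"k must be in [1, {m}], got {k}")
    if k == m:
        labels = np.arange(1, m + 1)
    elif k == 1:
        labels = np.ones(m, dtype=int)
    else:
        if model.node_counts is not None:
            frac = model.node_counts / max(model.node_counts.sum(), 1)
            keep = frac >= min_occupancy
            if keep.sum() < k:
                keep = np.argsort(-frac) < k  # top-k occupied nodes at minimum
                keep = np.isin(np.arange(m), np.flatnonzero(keep))
        else:
            keep = np.ones(m, dtype=bool)
        kept = np.flatnonzero(keep)
        cons = consensus_matrix(
            model.weights[kept], k, n_resamples, subsample, seed, linkage_method
        )
        dist = squareform(1.0 - cons, checks=False)
        Z = linkage(dist, method="average")
        kept_labels = _relabel_first_seen(fcluster(Z, t=k, criterion="maxclust"))
        labels = np.empty(m, dtype=int)
        labels[kept] = kept_labels
        dropped = np.flatnonzero(~keep)
        if dropped.size:
            d = cdist(model.weights[dropped], model.weights[kept], metric="sqeuclidean")
            labels[dropped] = kept_labels[np.argmin(d, axis=1)]
    return dc_replace(model, node_mc=np.asarray(labels, dtype=int))


def consensus_dispersion(cons: np.ndarray) -> float:
    """Mean distance of off-diagonal consensus entries from {0, 1}.

    Near 0 for stable clusterings (pairs always or never together), large
    when resampled clusterings disagree — a red flag for over-clustering a
    homogeneous population.
    """
    off = cons[~np.eye(cons.shape[0], dtype=bool)]
    return float(np.minimum(off, 1.0 - off).mean()) if off.size else 0.0


def assign_cells(
    model: SOMModel, sample: CellTable, by_centroid: bool = False
) -> ClusterAssignment:
    """Assign each cell to the closest trained cluster center.

    Default: nearest SOM node (ties -> lowest node index), inheriting the
    node's metacluster label.  ``by_centroid=True`` assigns to the nearest
    metacluster centroid (mean of that metacluster's node weights) instead.
    """
    if model.node_mc is None:
        raise ValidationError("model has no metacluster labels; run metacluster() first")
    missing = [c for c in model.channels if c not in sample.channels]
    if missing:
        raise ValidationError(f"sample {sample.sample_id}: missing channels {missing}")
    X = sample.values(model.channels)
    if X.shape[0] == 0:
        return ClusterAssignment(sample.sample_id, np.empty(0, dtype=int), np.empty(0, dtype=int))
    if by_centroid:
        ks = np.unique(model.node_mc)
        centroids = np.vstack([model.weights[model.node_mc == kk].mean(axis=0) for kk in ks])
        nearest = np.argmin(cdist(X, centroids, metric="sqeuclidean"), axis=1)
        mc = ks[nearest]
        # report the nearest node within the winning metacluster
        node = np.empty(len(X), dtype=int)
        for kk in ks:
            mask = mc == kk
            if mask.any():
                sub_nodes = np.flatnonzero(model.node_mc == kk)
                d = cdist(X[mask], model.weights[sub_nodes], metric="sqeuclidean")
                node[mask] = sub_nodes[np.argmin(d, axis=1)]
    else:
        node = model.nearest_nodes(X)
        mc = model.node_mc[node]
    return ClusterAssignment(sample.sample_id, node, mc)


def subcluster(
    tables,
    panel: PanelConfig,
    config: SOMConfig | None = None,
    k: int = 10,
    n_resamples: int = 100,
    subsample: float = 0.9,
):
    """Re-cluster the cells of one metacluster, using *all* surface markers
    (including channels excluded from the top-level clustering).

    ``tables`` are CellTables already restricted to the metacluster of
    interest.  Returns the sub-clustering model and one assignment per table.
    """
    config = config or SOMConfig()
    total = sum(t.n_cells for t in tables)
    if total == 0:
        raise ValidationError("no cells to sub-cluster")
    channels = panel.surface_channels
    model = train_som(list(tables), channels, config)
    model = metacluster(model, k=k, n_resamples=n_resamples, subsample=subsample, seed=config.seed)
    assignments = [assign_cells(model, t) for t in tables]
    return model, assignments
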