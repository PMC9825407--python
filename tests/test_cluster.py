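"""SOM training, consensus metaclustering and nearest-center assignment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import cytoresponse as cr
from cytoresponse.cluster import consensus_dispersion, consensus_matrix
from cytoresponse.core import CellTable, ValidationError
from cytoresponse.som import SOMConfig, train_som


def _gaussians(rng, centers, n_per, sd=1.0):
    X = np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return X, labels


class TestTrainSOM:
    def test_single_population_quantization(self):
        rng = np.random.default_rng(0)
        sd = 0.5
        X = rng.normal(2.0, sd, size=(2000, 3))
        model = train_som(X, [f"c{i}" for i in range(3)], SOMConfig(seed=0))
        assert model.quantization_error <= 2 * sd
        assert np.all(np.abs(model.weights - 2.0) <= 3 * sd)

    def test_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 4))
        cfg = SOMConfig(seed=3)
        w1 = train_som(X, list("abcd"), cfg).weights
        w2 = train_som(X, list("abcd"), cfg).weights
        np.testing.assert_array_equal(w1, w2)

    def test_three_separated_gaussians_occupy_pure_nodes(self):
        rng = np.random.default_rng(2)
        centers = [(0, 0), (10, 0), (0, 10)]
        X, labels = _gaussians(rng, centers, 300, sd=1.0)
        model = train_som(X, ["a", "b"], SOMConfig(rows=2, cols=2, seed=0))
        bmu = model.nearest_nodes(X)
        occupied = np.unique(bmu)
        assert len(occupied) >= 3
        # each occupied node is pure for the brute-force nearest-mean label
        means = np.array(centers)
        oracle = np.argmin(
            ((X[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1
        )
        for node in occupied:
            mask = bmu == node
            assert pd.Series(oracle[mask]).value_counts(normalize=True).iloc[0] == 1.0

    def test_errors(self):
        with pytest.raises(ValidationError, match="cells"):
            train_som(np.zeros((10, 2)), ["a", "b"], SOMConfig(rows=5, cols=5))
        X = np.random.default_rng(0).normal(size=(100, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError, match="finite"):
            train_som(X, ["a", "b"], SOMConfig())
        with pytest.raises(ValidationError, match="rate"):
            SOMConfig(alpha=(0.01, 0.05)).validate()


class TestMetacluster:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(800, 3))
        return train_som(X, list("abc"), SOMConfig(seed=0))

    def test_k_equals_nodes(self, model):
        out = cr.metacluster(model, k=model.n_nodes)
        assert sorted(out.node_mc) == list(range(1, model.n_nodes + 1))

    def test_k_one(self, model):
        out = cr.metacluster(model, k=1)
        assert (out.node_mc == 1).all()

    def test_k_too_large(self, model):
        with pytest.raises(ValidationError, match="k must be"):
            cr.metacluster(model, k=model.n_nodes + 1)

    def test_three_gaussians_perfect_recovery(self):
        rng = np.random.default_rng(4)
        centers = [(0, 0, 0), (12, 0, 0), (0, 12, 0)]
        X, labels = _gaussians(rng, centers, 400, sd=1.0)
        model = train_som(X, list("abc"), SOMConfig(rows=4, cols=4, seed=0))
        model = cr.metacluster(model, k=3, seed=0)
        pred = model.node_mc[model.nearest_nodes(X)]
        assert adjusted_rand_score(labels, pred) == 1.0


class TestAssignCells:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(600, 4))
        m = train_som(X, list("wxyz"), SOMConfig(seed=1))
        return cr.metacluster(m, k=5, seed=1)

    def _table(self, X, channels):
        return CellTable(
            sample_id="S", data=pd.DataFrame(X, columns=list(channels)), scale="transformed"
        )

    def test_cell_at_node_weight_assigned_to_it(self, model):
        X = model.weights[[3, 17]]
        a = cr.assign_cells(model, self._table(X, model.channels))
        assert a.node.tolist() == [3, 17]
        assert (a.metacluster == model.node_mc[[3, 17]]).all()

    def test_matches_exhaustive_nearest_neighbor(self, model):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(1000, 4))
        a = cr.assign_cells(model, self._table(X, model.channels))
        oracle = np.empty(len(X), dtype=int)
        for i, x in enumerate(X):
            d = ((model.weights - x) ** 2).sum(axis=1)
            oracle[i] = int(np.argmin(d))
        np.testing.assert_array_equal(a.node, oracle)

    def test_empty_sample(self, model):
        a = cr.assign_cells(model, self._table(np.empty((0, 4)), model.channels))
        assert a.n_cells == 0

    def test_channel_mismatch_lists_missing(self, model):
        t = CellTable(sample_id="S", data=pd.DataFrame({"w": [1.0]}), scale="transformed")
        with pytest.raises(ValidationError, match="missing channels"):
            cr.assign_cells(model, t)

    def test_unmetaclustered_model_rejected(self):
        rng = np.random.default_rng(7)
        m = train_som(rng.normal(size=(200, 2)), ["a", "b"], SOMConfig(seed=0))
        with pytest.raises(ValidationError, match="metacluster"):
            cr.assign_cells(m, CellTable("S", pd.DataFrame({"a": [0.0], "b": [0.0]}),
                                         scale="transformed"))


def test_assignment_idempotence_and_conservation(trained_model, normalized_small):
    model, training, X = trained_model
    bmu_train = model.nearest_nodes(X)
    # assigning the training cells reproduces their BMU labels
    again = model.nearest_nodes(X)
    np.testing.assert_array_equal(bmu_train, again)
    tables, _ = normalized_small
    for t in tables.values():
        if t.sample_role != "patient":
            continue
        a = cr.assign_cells(model, t)
        assert a.n_cells == t.n_cells
        counts = pd.Series(a.metacluster).value_counts()
        assert counts.sum() == t.n_cells


def test_stability_across_seeds(trained_model, normalized_small, small_spec):
    _, training, X = trained_model
    panel = small_spec.panel
    labels = []
    for seed in range(5):
        m = train_som(X, panel, SOMConfig(seed=seed))
        m = cr.metacluster(m, k=10, seed=seed)
        labels.append(m.node_mc[m.nearest_nodes(X)])
    for i in range(5):
        for j in range(i + 1, 5):
            assert adjusted_rand_score(labels[i], labels[j]) >= 0.8


class TestSubcluster:
    def test_two_separated_gaussians(self, small_spec):
        rng = np.random.default_rng(8)
        panel = small_spec.panel
        nch = len(panel.surface_channels)
        c1, c2 = np.zeros(nch), np.full(nch, 8.0)
        X = np.vstack([rng.normal(c1, 1, (300, nch)), rng.normal(c2, 1, (300, nch))])
        labels = np.repeat([0, 1], 300)
        t = CellTable("S", pd.DataFrame(X, columns=list(panel.surface_channels)),
                      scale="transformed")
        model, assigns = cr.subcluster([t], panel, cr.SOMConfig(rows=3, cols=3, seed=0), k=2)
        assert adjusted_rand_score(labels, assigns[0].metacluster) == 1.0

    def test_determinism(self, small_spec):
        rng = np.random.default_rng(9)
        panel = small_spec.panel
        X = rng.normal(size=(400, len(panel.surface_channels)))
        t = CellTable("S", pd.DataFrame(X, columns=list(panel.surface_channels)),
                      scale="transformed")
        cfg = cr.SOMConfig(rows=3, cols=3, seed=5)
        m1, a1 = cr.subcluster([t], panel, cfg, k=4)
        m2, a2 = cr.subcluster([t], panel, cfg, k=4)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(a1[0].metacluster, a2[0].metacluster)

    def test_homogeneous_subset_flagged_by_consensus_dispersion(self):
        rng = np.random.default_rng(10)
        homog = rng.normal(size=(25, 6))
        sep = np.vstack([rng.normal(0, 1, (12, 6)), rng.normal(10, 1, (13, 6))])
        d_h = consensus_dispersion(consensus_matrix(homog, k=2, seed=0))
        d_s = consensus_dispersion(consensus_matrix(sep, k=2, seed=0))
        assert d_s < 0.01
        assert d_h > d_s

    def test_empty_subset_errors(self, small_spec):
        t = CellTable(
            "S",
            pd.DataFrame(columns=list(small_spec.panel.surface_channels), dtype=float),
            scale="transformed",
        )
        with pytest.raises(ValidationError, match="cell"):
            cr.subcluster([t], small_spec.panel, cr.SOMConfig(rows=2, cols=2, seed=0), k=2)
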