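import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import midmap as mm
from midmap.preprocess import FeatureSet


def _norm_adata(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=genes),
    )


def _simplex_rows(draw_rows):
    rows = np.asarray(draw_rows, dtype=float) + 1e-6
    return rows / rows.sum(axis=1, keepdims=True)


class TestFitClassifier:
    def test_separable_toy_has_boundary_at_zero(self):
        X = np.array([[-1.0], [-1.0], [-1.0], [1.0], [1.0], [1.0]])
        a = _norm_adata(X)
        model = mm.fit_classifier(
            a, ["neg"] * 3 + ["pos"] * 3, FeatureSet(("g0",), "manual")
        )
        probs = mm.predict_probabilities(model, a)
        assert (probs.idxmax(axis=1) == ["neg"] * 3 + ["pos"] * 3).all()
        # symmetric classes: the decision scores cross at feature value 0
        mid = mm.predict_probabilities(model, _norm_adata([[0.0]]))
        assert mid.iloc[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_permuted_labels_give_prior_probabilities(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 5))
        labels = np.array(["a"] * 100 + ["b"] * 200)
        rng.shuffle(labels)
        a = _norm_adata(X)
        model = mm.fit_classifier(a, labels, FeatureSet(tuple(a.var_names), "manual"))
        held = mm.predict_probabilities(model, _norm_adata(rng.normal(size=(200, 5))))
        assert held["a"].mean() == pytest.approx(1 / 3, abs=0.1)
        assert held["b"].mean() == pytest.approx(2 / 3, abs=0.1)

    def test_rare_type_error_names_it(self):
        a = _norm_adata(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="rare"):
            mm.fit_classifier(a, ["x", "x", "rare"], FeatureSet(("g0", "g1"), "manual"))

    def test_single_type_rejected(self):
        a = _norm_adata(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="2 reference types"):
            mm.fit_classifier(a, ["x"] * 4, FeatureSet(("g0",), "manual"))

    def test_non_finite_rejected(self):
        a = _norm_adata([[np.nan, 1.0], [0.0, 1.0], [1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            mm.fit_classifier(a, ["x", "x", "y", "y"], FeatureSet(("g0", "g1"), "manual"))

    def test_model_roundtrip(self, tmp_path, small_model):
        _, model = small_model
        path = tmp_path / "model.json"
        model.save(path)
        back = mm.ClassifierModel.load(path)
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.classes == model.classes and back.scheme == model.scheme


class TestPredictProbabilities:
    def test_rows_are_on_the_simplex(self, small_model, small_query, small_atlas):
        fs, model = small_model
        q, _ = small_query
        probs = mm.predict_probabilities(model, mm.normalize_log_library(q))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs.values >= 0).all() and (probs.values <= 1).all()

    def test_training_cells_recover_their_type(self, small_model, small_atlas_norm, small_atlas):
        _, model = small_model
        _, adata, _ = small_atlas
        probs = mm.predict_probabilities(model, small_atlas_norm)
        assigned = probs.idxmax(axis=1).to_numpy()
        assert (assigned == adata.obs["cell_type"].to_numpy()).mean() > 0.99
        assert probs.to_numpy().max(axis=1).mean() > 0.9

    def test_zero_model_gives_uniform_row(self):
        model = mm.ClassifierModel(
            weights=np.zeros((4, 2)), intercepts=np.zeros(4),
            features=("g0", "g1"), classes=("a", "b", "c", "d"), l2_strength=1.0,
        )
        probs = mm.predict_probabilities(model, _norm_adata(np.zeros((3, 2))))
        np.testing.assert_allclose(probs.values, 0.25, atol=1e-12)

    def test_missing_features_listed(self, small_model):
        _, model = small_model
        with pytest.raises(ValueError, match="missing from query"):
            mm.predict_probabilities(model, _norm_adata(np.zeros((2, 2))))

    def test_empty_query(self, small_model):
        _, model = small_model
        probs = mm.predict_probabilities(
            model, _norm_adata(np.zeros((0, len(model.features))), genes=list(model.features))
        )
        assert probs.shape == (0, len(model.classes))

    def test_sigmoid_oracle_on_two_feature_toy(self):
        W = np.array([[1.5, -2.0], [-0.5, 1.0]])
        b = np.array([0.25, -1.0])
        model = mm.ClassifierModel(
            weights=W, intercepts=b, features=("g0", "g1"),
            classes=("a", "b"), l2_strength=1.0,
        )
        X = np.array([[0.3, 1.2], [2.0, 0.0]])
        probs = mm.predict_probabilities(model, _norm_adata(X))
        for i in range(2):
            s = 1.0 / (1.0 + np.exp(-(X[i] @ W.T + b)))
            np.testing.assert_allclose(probs.values[i], s / s.sum(), atol=1e-9)


class TestScoreClusters:
    def _probs(self, rows, types=("DA", "OMTN", "Sert")):
        return pd.DataFrame(rows, columns=list(types))

    def test_one_hot_cluster_is_perfect(self):
        probs = self._probs([[1.0, 0, 0]] * 4)
        sim = mm.score_clusters(probs, np.zeros(4, dtype=int))
        row = sim.summary.iloc[0]
        assert row["assigned_type"] == "DA"
        assert row["similarity"] == 1.0 and row["band"] == "high" and row["frac_high"] == 1.0

    @pytest.mark.parametrize(
        "score,band", [(0.85, "high"), (0.8, "high"), (0.6, "moderate"),
                       (0.5, "moderate"), (0.49, "below")]
    )
    def test_band_boundaries(self, score, band):
        rest = (1.0 - score) / 2
        probs = self._probs([[score, rest, rest]] * 3)
        sim = mm.score_clusters(probs, np.zeros(3, dtype=int))
        assert sim.summary.iloc[0]["band"] == band

    def test_fraction_of_high_cells(self):
        probs = self._probs([[0.95, 0.05, 0], [0.85, 0.15, 0], [0.5, 0.5, 0], [0.7, 0.3, 0]])
        sim = mm.score_clusters(probs, np.zeros(4, dtype=int))
        assert sim.summary.iloc[0]["frac_high"] == 0.5

    def test_shown_hides_below_band(self):
        probs = self._probs([[0.9, 0.1, 0]] * 2 + [[0.4, 0.3, 0.3]] * 2)
        sim = mm.score_clusters(probs, np.array([0, 0, 1, 1]))
        assert list(sim.shown()["cluster"]) == [0]

    def test_misaligned_partition_raises(self):
        with pytest.raises(ValueError, match="aligned"):
            mm.score_clusters(self._probs([[1, 0, 0]]), np.zeros(2, dtype=int))


class TestWheel:
    def test_one_hot_rows_hit_vertices(self):
        probs = pd.DataFrame(np.eye(5), columns=list("abcde"))
        layout = mm.wheel_coordinates(probs)
        for i, t in enumerate("abcde"):
            np.testing.assert_allclose(
                layout.cells.iloc[i].to_numpy(), layout.vertex(t), atol=1e-12
            )

    def test_uniform_row_is_origin(self):
        probs = pd.DataFrame(np.full((1, 7), 1 / 7), columns=[f"t{i}" for i in range(7)])
        layout = mm.wheel_coordinates(probs)
        np.testing.assert_allclose(layout.cells.iloc[0].to_numpy(), 0.0, atol=1e-12)

    def test_adjacent_half_mix_is_midpoint(self):
        probs = pd.DataFrame([[0.5, 0.5, 0.0, 0.0]], columns=list("abcd"))
        layout = mm.wheel_coordinates(probs)
        mid = (layout.vertex("a") + layout.vertex("b")) / 2
        np.testing.assert_allclose(layout.cells.iloc[0].to_numpy(), mid, atol=1e-12)

    def test_vertex_order_must_be_permutation(self):
        probs = pd.DataFrame([[1.0, 0.0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="permutation"):
            mm.wheel_coordinates(probs, vertex_order=["a", "z"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6),
            min_size=1, max_size=8,
        )
    )
    def test_cells_stay_inside_the_polygon(self, raw):
        P = _simplex_rows(raw)
        probs = pd.DataFrame(P, columns=[f"t{i}" for i in range(6)])
        layout = mm.wheel_coordinates(probs)
        # a convex combination of unit-circle points has norm <= 1, and
        # more tightly stays within the polygon's circumradius
        norms = np.linalg.norm(layout.cells.to_numpy(), axis=1)
        assert (norms <= 1.0 + 1e-12).all()
        # hull check: every point is inside the hexagon (distance to
        # every edge's outward half-plane <= 0)
        V = layout.vertices.to_numpy()
        for i in range(6):
            a, b = V[i], V[(i + 1) % 6]
            edge = b - a
            normal = np.array([edge[1], -edge[0]])  # outward for CCW polygon
            side = (layout.cells.to_numpy() - a) @ normal
            assert (side <= 1e-9).all()


def test_accuracy_monotone_in_marker_effect_size():
    """Held-out classification accuracy should not decrease as marker
    fold-change grows."""
    accs = []
    for fc in (0.5, 1.5, 3.0):
        spec = mm.AtlasSpec(
            n_types=4, n_cells_per_type=60, n_genes=300, n_markers_per_type=15,
            marker_log2fc=fc, seed=9,
        )
        adata, truth = mm.generate_atlas(spec)
        norm = mm.normalize_log_library(adata)
        rng = np.random.default_rng(10)
        idx = rng.permutation(adata.n_obs)
        train, test = idx[:180], idx[180:]
        fs = mm.select_features(norm.var_names, norm.var_names)
        model = mm.fit_classifier(
            norm[train].copy(), adata.obs["cell_type"].to_numpy()[train], fs
        )
        probs = mm.predict_probabilities(model, norm[test].copy())
        acc = (probs.idxmax(axis=1).to_numpy() == adata.obs["cell_type"].to_numpy()[test]).mean()
        accs.append(acc)
    assert accs[0] <= accs[1] + 0.02 and accs[1] <= accs[2] + 0.02


def test_top_coefficient_genes_recover_markers(small_atlas, small_model):
    _, _, truth = small_atlas
    _, model = small_model
    for t in truth.type_names:
        top = mm.top_coefficient_genes(model, t, k=10)
        markers = set(truth.markers_of(t))
        assert len(markers.intersection(top)) >= 7
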