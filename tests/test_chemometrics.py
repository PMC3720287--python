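"""Ratio features, PCA, k-means grouping and loading interpretation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbomirror.chemometrics import (
    ClusterResult,
    FeatureMatrix,
    PCAModel,
    adjusted_rand,
    cluster_scores,
    pca,
    ratio_transform,
    top_loading_features,
)
from herbomirror.chrom import AlignedPeakMatrix


def make_matrix(heights, rts=None, ids=None):
    heights = np.asarray(heights, dtype=float)
    n = heights.shape[1]
    if rts is None:
        rts = np.arange(1.0, n + 1)
    if ids is None:
        ids = [f"s{i}" for i in range(heights.shape[0])]
    return AlignedPeakMatrix(heights, np.asarray(rts, float), ids)


class TestRatioTransform:
    def test_107_peaks_give_5671_features(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(1, 100, size=(4, 107)))
        fm = ratio_transform(m)
        assert len(fm.feature_ids) == 107 * 106 // 2 == 5671
        assert fm.values.shape == (4, 5671)

    def test_equal_heights_give_unit_ratios(self):
        m = make_matrix(np.full((3, 5), 42.0))
        assert np.all(ratio_transform(m, log_scale=False).values == 1.0)
        assert np.all(ratio_transform(m, log_scale=True).values == 0.0)

    def test_hand_enumerated_pairs(self):
        # heights (1,2,4): pairs (1/2, 1/4, 2/4), earlier rt as numerator
        m = make_matrix([[1.0, 2.0, 4.0]], ids=["s"])
        fm = ratio_transform(m, log_scale=False)
        np.testing.assert_allclose(fm.values[0], [0.5, 0.25, 0.5])

    def test_undetected_peaks_floored(self):
        m = make_matrix([[10.0, 0.0], [10.0, 4.0]])
        fm = ratio_transform(m, log_scale=False)
        # floor = half smallest nonzero = 2; 0 lifted to 2
        np.testing.assert_allclose(fm.values[:, 0], [10 / 2.0, 10 / 4.0])

    def test_single_column_fails(self):
        with pytest.raises(ValueError):
            ratio_transform(make_matrix([[1.0], [2.0]]))

    def test_nonpositive_floor_fails(self):
        with pytest.raises(ValueError):
            ratio_transform(make_matrix([[1.0, 2.0]], ids=["s"]), floor=0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance_per_sample(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.uniform(1, 100, size=(5, 8))
        factors = rng.uniform(0.2, 5.0, size=5)
        base = ratio_transform(make_matrix(h), floor=0.5)
        scaled = ratio_transform(make_matrix(h * factors[:, None]), floor=0.5)
        # dilution changes no ratio as long as heights stay above the floor
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-10)


class TestPCA:
    def feature_matrix(self, values):
        values = np.asarray(values, dtype=float)
        return FeatureMatrix(
            values,
            [f"f{j}" for j in range(values.shape[1])],
            [f"s{i}" for i in range(values.shape[0])],
        )

    def test_matches_covariance_eigendecomposition(self, rng):
        x = self.feature_matrix(rng.normal(size=(5, 4)))
        model = pca(x)
        v = (x.values - x.values.mean(0)) / x.values.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(v.T @ v)
        evals = evals[::-1]
        np.testing.assert_allclose(
            model.explained_fraction, evals / evals.sum(), atol=1e-8
        )
        scores_oracle = v @ evecs[:, ::-1]
        np.testing.assert_allclose(
            np.abs(model.scores), np.abs(scores_oracle), atol=1e-8
        )

    def test_duplicated_samples_get_identical_scores(self, rng):
        row = rng.normal(size=6)
        base = rng.normal(size=(3, 6))
        x = self.feature_matrix(np.vstack([base, row, row]))
        model = pca(x)
        np.testing.assert_allclose(model.scores[-1], model.scores[-2], atol=1e-10)

    def test_collinear_samples_explained_one(self):
        t = np.array([0.0, 1.0, 2.0, 5.0])
        x = self.feature_matrix(np.outer(t, [1.0, -2.0, 0.5]))
        model = pca(x, scale=False)
        assert model.explained_fraction[0] == pytest.approx(1.0)

    def test_explained_sums_to_one(self, rng):
        model = pca(self.feature_matrix(rng.normal(size=(8, 20))))
        assert model.explained_fraction.sum() == pytest.approx(1.0)

    def test_constant_feature_dropped_without_changing_scores(self, rng):
        v = rng.normal(size=(6, 5))
        with_const = np.hstack([v, np.full((6, 1), 3.0)])
        m1 = pca(self.feature_matrix(v))
        m2 = pca(self.feature_matrix(with_const))
        assert m2.dropped_features == ["f5"]
        np.testing.assert_allclose(np.abs(m1.scores), np.abs(m2.scores), atol=1e-8)

    def test_too_few_features_fails(self):
        x = self.feature_matrix(np.array([[1.0, 2.0], [1.0, 3.0]]))
        # first column constant -> dropped -> one feature left
        with pytest.raises(ValueError):
            pca(x)

    def test_transform_reproduces_scores(self, rng):
        x = self.feature_matrix(rng.normal(size=(6, 8)))
        model = pca(x)
        np.testing.assert_allclose(model.transform(x.values), model.scores, atol=1e-10)


class TestClusterScores:
    def separated_clouds(self, rng, sizes=(5, 5, 5), spread=0.05):
        centers = np.array([[0, 0], [10, 0], [0, 10.0]])
        pts, labels = [], []
        for g, n in enumerate(sizes):
            pts.append(centers[g] + rng.normal(0, spread, size=(n, 2)))
            labels += [g] * n
        scores = np.vstack(pts)
        model = PCAModel(
            scores=scores,
            loadings=np.eye(2),
            explained_fraction=np.array([0.5, 0.5]),
            centered=True,
            scaled=True,
            sample_ids=[str(i) for i in range(scores.shape[0])],
            feature_ids=["f0", "f1"],
            dropped_features=[],
        )
        return model, np.array(labels)

    def test_k1_single_label(self, rng):
        model, _ = self.separated_clouds(rng)
        out = cluster_scores(model, k=1)
        assert set(out.labels) == {0}

    def test_k_equals_samples_zero_inertia(self, rng):
        model, _ = self.separated_clouds(rng, sizes=(2, 2, 2))
        out = cluster_scores(model, k=6)
        assert len(set(out.labels)) == 6
        assert out.inertia == pytest.approx(0.0, abs=1e-12)

    def test_separated_clouds_recovered(self, rng):
        model, truth = self.separated_clouds(rng)
        out = cluster_scores(model, k=3, seed=0)
        assert adjusted_rand(truth, out.labels) == 1.0

    def test_k_exceeding_samples_fails(self, rng):
        model, _ = self.separated_clouds(rng, sizes=(1, 1, 1))
        with pytest.raises(ValueError):
            cluster_scores(model, k=10)

    def test_deterministic_given_seed(self, rng):
        model, _ = self.separated_clouds(rng)
        a = cluster_scores(model, k=3, seed=5)
        b = cluster_scores(model, k=3, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestAdjustedRand:
    def test_identical_labelings(self):
        assert adjusted_rand([0, 0, 1, 1, 2], [0, 0, 1, 1, 2]) == 1.0

    def test_constant_vs_balanced_split_is_zero(self):
        # hand contingency: expected index equals observed index
        assert adjusted_rand([0, 0, 0, 0], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_invariant_to_label_names(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [1, 1, 0, 0, 2, 2]
        c = ["x", "x", "y", "y", "z", "z"]
        assert adjusted_rand(a, b) == adjusted_rand(a, c) == 1.0

    def test_length_mismatch_fails(self):
        with pytest.raises(ValueError):
            adjusted_rand([0, 1], [0, 1, 2])


class TestTopLoadingFeatures:
    def marker_setup(self, rng):
        # feature j elevated only in group j's samples
        n_per = 4
        base = rng.normal(0, 0.3, size=(3 * n_per, 6))
        for g in range(3):
            base[g * n_per : (g + 1) * n_per, g] += 8.0
        fm = FeatureMatrix(
            base,
            [f"f{j}" for j in range(6)],
            [f"s{i}" for i in range(12)],
        )
        model = pca(fm)
        clusters = cluster_scores(model, k=3, seed=0)
        truth = np.repeat(np.arange(3), n_per)
        return model, clusters, truth

    def test_marker_ranks_first_for_its_group(self, rng):
        model, clusters, truth = self.marker_setup(rng)
        for g in range(3):
            cluster_of_g = int(np.bincount(clusters.labels[truth == g]).argmax())
            ranking = top_loading_features(model, clusters, cluster_of_g)
            assert ranking.feature_ids[0] == f"f{g}"

    def test_degenerate_flag_on_flat_loadings(self):
        model = PCAModel(
            scores=np.zeros((4, 2)),
            loadings=np.full((5, 2), 0.3),
            explained_fraction=np.array([0.5, 0.5]),
            centered=True,
            scaled=True,
            sample_ids=list("abcd"),
            feature_ids=[f"f{j}" for j in range(5)],
            dropped_features=[],
        )
        clusters = ClusterResult(np.zeros(4, int), np.array([[1.0, 0.0]]), 1, 0.0, 0)
        assert top_loading_features(model, clusters, 0).degenerate

    def test_top_n_larger_than_features_returns_all(self, rng):
        model, clusters, _ = self.marker_setup(rng)
        ranking = top_loading_features(model, clusters, 0, top_n=100)
        assert len(ranking.feature_ids) == 6

    def test_unknown_group_fails(self, rng):
        model, clusters, _ = self.marker_setup(rng)
        with pytest.raises(ValueError):
            top_loading_features(model, clusters, 7)
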