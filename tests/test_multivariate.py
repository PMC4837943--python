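"""Preprocessing, PCA, PLS-DA/OPLS-DA and the Welch marker test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.decomposition import PCA as SkPCA
from sklearn.metrics import silhouette_score

from dinolipid.multivariate import (
    OPLSDA,
    PCAModel,
    PLSDA,
    ParetoScaler,
    select_markers,
    welch_test,
)

from conftest import SUITE_SEED


class TestParetoScaler:
    def test_columns_centred_and_pareto_scaled(self):
        rng = np.random.default_rng(SUITE_SEED)
        X = rng.dirichlet(np.ones(5), size=12)
        sc = ParetoScaler().fit(X)
        Xt = sc.transform(X)
        assert np.allclose(Xt.mean(axis=0), 0.0, atol=1e-9)
        Xl = np.log10(100 * X + 1)
        assert np.allclose(sc.scale_, np.sqrt(Xl.std(axis=0, ddof=1)))

    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.full(8, 0.3), np.linspace(0.1, 0.9, 8)])
        with pytest.warns(UserWarning, match="zero-variance"):
            sc = ParetoScaler().fit(X)
        assert sc.transform(X).shape[1] == 1

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            ParetoScaler().fit(np.zeros((5, 3)))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            ParetoScaler().fit(np.array([[0.1, -0.2], [0.3, 0.4]]))

    def test_inverse_transform_round_trip(self):
        rng = np.random.default_rng(SUITE_SEED)
        X = rng.uniform(0.0, 1.0, size=(6, 4))
        sc = ParetoScaler(drop_zero_variance=False).fit(X)
        assert np.allclose(sc.inverse_transform(sc.transform(X)), X, atol=1e-10)


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.arange(6, dtype=float)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        m = PCAModel(n_components=1).fit(u @ v)
        assert m.r2x_[0] == pytest.approx(1.0)

    def test_loadings_match_analytic_eigenvectors(self):
        """2-variable Gaussian: loadings equal the covariance eigenvectors."""
        rng = np.random.default_rng(SUITE_SEED)
        cov = np.array([[2.0, 1.2], [1.2, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=4000)
        m = PCAModel(n_components=2).fit(X)
        S = np.cov((X - X.mean(axis=0)).T)
        vals, vecs = np.linalg.eigh(S)
        for a, j in enumerate(np.argsort(vals)[::-1]):
            v = vecs[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.allclose(m.loadings_[:, a], v, atol=1e-6)

    def test_scores_orthogonal(self, preprocessed):
        X, *_ = preprocessed
        m = PCAModel(n_components=3).fit(X)
        g = m.scores_.T @ m.scores_
        assert np.all(np.abs(g - np.diag(np.diag(g))) < 1e-8)

    def test_agrees_with_reference_svd_implementation(self, preprocessed):
        X, *_ = preprocessed
        ours = PCAModel(n_components=2).fit(X)
        ref = SkPCA(n_components=2).fit(X)
        assert np.allclose(
            np.abs(ours.loadings_), np.abs(ref.components_.T), atol=1e-8
        )
        assert np.allclose(
            ours.r2x_, ref.explained_variance_ratio_, atol=1e-10
        )

    def test_component_one_separates_planted_groups(self, preprocessed):
        X, groups, *_ = preprocessed
        m = PCAModel(n_components=2).fit(X)
        assert silhouette_score(m.scores_[:, :1], groups.to_numpy()) > 0.5

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            PCAModel(n_components=5).fit(np.random.default_rng(0).normal(size=(4, 10)))


class TestPLSDA:
    def test_label_column_gives_high_q2(self):
        rng = np.random.default_rng(SUITE_SEED)
        y = np.array(["a"] * 5 + ["b"] * 5)
        X = np.column_stack(
            [(y == "b").astype(float), 0.05 * rng.normal(size=(10, 4))]
        )
        m = PLSDA(n_permutations=0).fit(X, y)
        assert m.q2_ > 0.9
        assert (m.predict(X) == y).all()

    def test_planted_structure_significant(self, preprocessed):
        """Mirrors the published Q² ≈ 0.8, P < 0.05 on planted groups."""
        X, groups, *_ = preprocessed
        m = PLSDA(n_permutations=200, random_state=SUITE_SEED).fit(X, groups.to_numpy())
        assert m.q2_ >= 0.8
        assert m.permutation_p_ < 0.05
        assert m.permutation_p_ >= 1 / 201

    def test_fixed_seed_reproduces_exactly(self, preprocessed):
        X, groups, *_ = preprocessed
        a = PLSDA(n_permutations=30, random_state=7).fit(X, groups.to_numpy())
        b = PLSDA(n_permutations=30, random_state=7).fit(X, groups.to_numpy())
        assert a.q2_ == b.q2_ and a.permutation_p_ == b.permutation_p_
        assert np.array_equal(a.scores_, b.scores_)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError):
            PLSDA().fit(X, np.array(["a"] * 6))

    def test_r2x_fractions_valid(self, preprocessed):
        X, groups, *_ = preprocessed
        m = PLSDA(n_permutations=0).fit(X, groups.to_numpy())
        assert np.all(m.r2x_ >= 0) and np.all(m.r2x_ <= 1)
        assert m.r2x_.sum() <= 1 + 1e-9

    def test_permuted_labels_degrade_q2(self, preprocessed):
        """Observed Q² stochastically dominates the permutation null."""
        X, groups, *_ = preprocessed
        y = groups.to_numpy()
        obs = PLSDA(n_permutations=0).fit(X, y).q2_
        rng = np.random.default_rng(SUITE_SEED)
        null = [
            PLSDA(n_permutations=0).fit(X, rng.permutation(y)).q2_ for _ in range(100)
        ]
        assert np.mean(np.asarray(null) < obs) > 0.95


class TestOPLSDA:
    def test_dummy_code_column_p_corr_one(self):
        rng = np.random.default_rng(SUITE_SEED)
        y = np.array(["a"] * 5 + ["b"] * 5)
        dummy = (y == "b").astype(float)
        yc = dummy - dummy.mean()
        noise = rng.normal(size=(10, 3))
        noise -= np.outer(yc, yc @ noise / (yc @ yc))  # keep the contrast clean
        m = OPLSDA(n_orthogonal=0).fit(np.column_stack([dummy, noise]), y)
        assert abs(m.p_corr_[0]) == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_rotation_leaves_p_corr_stable(self):
        """Rotating orthogonal-subspace columns must not move predictive p(corr)."""
        rng = np.random.default_rng(SUITE_SEED)
        y = np.array(["a"] * 5 + ["b"] * 5)
        signal = (y == "b").astype(float) - 0.5
        ortho = rng.normal(size=(10, 2))
        ortho -= np.outer(signal, signal @ ortho / (signal @ signal))
        X = np.column_stack([signal + 0.05 * rng.normal(size=10), ortho])
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        X_rot = X.copy()
        X_rot[:, 1:] = ortho @ R
        p1 = OPLSDA().fit(X, y).p_corr_[0]
        p2 = OPLSDA().fit(X_rot, y).p_corr_[0]
        assert p1 == pytest.approx(p2, abs=1e-6)

    def test_scores_orthogonal_to_orthogonal_scores(self, preprocessed):
        X, groups, *_ = preprocessed
        m = OPLSDA().fit(X, groups.to_numpy())
        assert abs(m.scores_ @ m.orthogonal_scores_[:, 0]) < 1e-6


class TestWelch:
    def test_identical_groups_p_one(self):
        assert welch_test([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_symmetry(self):
        g1, g2 = [79.1, 82.3, 81.1, 77.4], [1.4, 17.9, 0.0, 1.7, 13.0, 10.8]
        assert welch_test(g1, g2) == welch_test(g2, g1)

    @pytest.mark.parametrize(
        "g1, g2",
        [
            ([1.0, 2.0, 3.0], [2.5, 3.5, 4.5, 5.5]),
            ([79.1, 82.3, 81.1, 77.4], [1.4, 17.9, 0.0, 1.7, 13.0, 10.8]),
            ([0.0, 0.1, 0.2, 0.15], [10.0, 11.0, 9.0]),
        ],
    )
    def test_against_closed_form(self, g1, g2):
        """t statistic + Satterthwaite df reproduce the p to 1e-10 relative."""
        a, b = np.asarray(g1), np.asarray(g2)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        expected = 2 * stats.t.sf(abs(t), df)
        assert welch_test(g1, g2) == pytest.approx(expected, rel=1e-10)

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [2.0, 3.0])


class TestSelectMarkers:
    def _fit(self, preprocessed):
        X, groups, scaler, table = preprocessed
        kept = list(scaler.kept_feature_names())
        model = OPLSDA().fit(X, groups.to_numpy())
        return model, table.data[kept] * 100, groups.to_numpy()

    def test_planted_markers_selected_with_correct_group(self, preprocessed):
        model, percent, y = self._fit(preprocessed)
        mk = select_markers(model, percent, y)
        assert mk.loc["DGDG 36:9", "marker"]
        assert mk.loc["DGDG 36:9", "characterizes"] == "group1"
        assert mk.loc["SQDG 34:1", "marker"]
        assert mk.loc["SQDG 34:1", "characterizes"] == "group2"

    def test_threshold_is_strict(self, preprocessed):
        model, percent, y = self._fit(preprocessed)
        mk = select_markers(model, percent, y, p_corr_threshold=0.75)
        sub = mk[np.abs(mk["p_corr"]) < 0.75]
        assert not sub["marker"].any()

    def test_impossible_threshold_gives_empty_selection(self, preprocessed):
        model, percent, y = self._fit(preprocessed)
        mk = select_markers(model, percent, y, p_corr_threshold=1.01)
        assert not mk["marker"].any()
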