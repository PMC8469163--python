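import numpy as np
import pytest

from pairedmetab.multivariate import (
    PlsdaModel,
    autoscale,
    cross_validate_q2,
    encode_response,
    fit_pca,
    fit_plsda,
    permutation_test,
    scale_matrix,
    vip_scores,
)



def scaled_from(X, **kw):
    return scale_matrix(np.asarray(X, float), [f"v{j}" for j in range(np.shape(X)[1])], **kw)


def labels(n_before, n_after):
    return np.array(["before"] * n_before + ["after"] * n_after)


def separated_toy(seed=0, n_per=5, j=4, shift=6.0):
    """Two classes with means +-shift/2 sd apart on the first variable.

    For a binary response the population point-biserial R^2 of the first
    variable alone is shift^2 / (shift^2 + 4) — 0.9 at shift 6 — so a
    one-component fit must reach at least that level.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per, j))
    X[n_per:, 0] += shift
    return X, labels(n_per, n_per)


class TestAutoscale:
    def test_hand_column_with_sample_sd(self):
        sm = scaled_from([[1.0], [2.0], [3.0]])
        np.testing.assert_allclose(sm.X.ravel(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_column_centred_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            sm = scaled_from([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        np.testing.assert_allclose(sm.X[:, 0], 0.0)
        assert sm.column_sds[0] == 1.0

    def test_idempotent_on_scaled_data(self):
        rng = np.random.default_rng(1)
        sm = scaled_from(rng.standard_normal((8, 3)))
        again = scale_matrix(sm.X, sm.columns)
        np.testing.assert_allclose(again.X, sm.X, atol=1e-10)

    def test_table_interface_and_minimum_size(self, small_table):
        sm = autoscale(small_table)
        assert np.allclose(sm.X.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(sm.X.std(axis=0, ddof=1), 1, atol=1e-10)


class TestPca:
    def test_duplicated_columns_share_pc1_loading(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        sm = scaled_from(np.column_stack([a, a, b]))
        model = fit_pca(sm, 2)
        # the duplicated pair dominates PC1 with equal weight
        assert model.loadings[0, 0] == pytest.approx(model.loadings[1, 0], abs=1e-10)
        assert abs(model.loadings[0, 0]) > abs(model.loadings[2, 0])

    def test_rank_one_matrix_fully_explained_by_pc1(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.outer(v, [1.0, -2.0, 0.5])
        sm = scaled_from(X)
        assert fit_pca(sm, 1).explained_fraction[0] == pytest.approx(1.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(3)
        sm = scaled_from(rng.standard_normal((10, 6)))
        k = min(sm.X.shape[0] - 1, sm.X.shape[1])
        model = fit_pca(sm, k)
        np.testing.assert_allclose(
            model.scores @ model.loadings.T, sm.X - sm.X.mean(axis=0), atol=1e-8
        )

    def test_agrees_with_sklearn_svd_oracle(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(4)
        sm = scaled_from(rng.standard_normal((15, 7)))
        mine = fit_pca(sm, 3)
        ref = PCA(n_components=3).fit(sm.X)
        np.testing.assert_allclose(
            np.abs(mine.scores), np.abs(ref.transform(sm.X)), atol=1e-6
        )
        np.testing.assert_allclose(
            mine.explained_fraction, ref.explained_variance_ratio_, atol=1e-10
        )

    def test_k_too_large_rejected(self):
        sm = scaled_from(np.random.default_rng(0).standard_normal((5, 3)))
        with pytest.raises(ValueError, match="k must be"):
            fit_pca(sm, 5)


class TestPlsda:
    def test_separated_toy_r2y_matches_univariate_regression(self):
        # single discriminating metabolite: one PLS component IS simple
        # regression, so R2Y must equal the squared point-biserial
        # correlation and clear 0.9 for class means +-3 sd apart
        from scipy.stats import pearsonr

        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-3, 1, 5), rng.normal(3, 1, 5)])
        y = labels(5, 5)
        model = fit_plsda(scaled_from(x[:, None]), y, n_components=1)
        r_closed_form = pearsonr(x, encode_response(y)).statistic
        assert model.r2y[0] == pytest.approx(r_closed_form**2, abs=1e-10)
        assert model.r2y[0] >= 0.9

    def test_label_flip_negates_scores_keeps_r2y(self):
        X, y = separated_toy(seed=5)
        flipped = np.where(y == "before", "after", "before")
        m1 = fit_plsda(scaled_from(X), y, n_components=2)
        m2 = fit_plsda(scaled_from(X), flipped, n_components=2)
        np.testing.assert_allclose(m2.scores, -m1.scores, atol=1e-10)
        np.testing.assert_allclose(m2.r2y, m1.r2y, atol=1e-10)

    def test_scores_orthogonal_and_r2y_monotone(self):
        rng = np.random.default_rng(6)
        model = fit_plsda(
            scaled_from(rng.standard_normal((16, 10))), labels(8, 8), n_components=5
        )
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8
        assert (np.diff(model.r2y) >= -1e-12).all()
        assert ((model.r2y >= 0) & (model.r2y <= 1 + 1e-12)).all()

    def test_weights_match_sklearn_nipals(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(7)
        X = rng.standard_normal((14, 9))
        y = labels(7, 7)
        sm = scaled_from(X)
        mine = fit_plsda(sm, y, n_components=4)
        yc = encode_response(y)
        ref = PLSRegression(n_components=4, scale=False).fit(sm.X, yc)
        np.testing.assert_allclose(
            np.abs(mine.weights), np.abs(ref.x_weights_), atol=1e-8
        )
        np.testing.assert_allclose(
            mine.predict(sm.X) - mine.y_mean, ref.predict(sm.X).ravel(), atol=1e-8
        )

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((6, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_plsda(scaled_from(X), ["before"] * 6, n_components=1)

    def test_components_truncated_at_rank_with_warning(self):
        X, y = separated_toy(n_per=3, j=2)
        with pytest.warns(UserWarning, match="truncated"):
            model = fit_plsda(scaled_from(X), y, n_components=5)
        assert model.n_components <= 2

    def test_overfitting_signature_on_pure_noise(self):
        # n=20, J=28, 5 components: apparent fit is high, predictivity absent
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 28))
        y = labels(10, 10)
        model = fit_plsda(scaled_from(X), y, n_components=5)
        q2 = cross_validate_q2(X, y, n_components=5, folds=10, seed=8)
        assert model.r2y[-1] > 0.8
        assert q2 < model.r2y[-1] - 0.5  # R2Y >> Q2Y


class TestCrossValidation:
    def test_separated_toy_predictive(self):
        X, y = separated_toy(seed=9, n_per=8)
        assert cross_validate_q2(X, y, n_components=1, folds=8, seed=0) > 0.5

    def test_noise_q2_nonpositive_in_majority(self):
        rng = np.random.default_rng(10)
        y = labels(8, 8)
        nonpos = sum(
            cross_validate_q2(
                rng.standard_normal((16, 12)), y, n_components=3, folds=8,
                seed=int(rng.integers(2**31 - 1)),
            ) <= 0
            for _ in range(100)
        )
        assert nonpos > 80

    def test_q2_below_r2y(self, preset_cohort):
        table, _ = preset_cohort
        y = table.class_labels()
        model = fit_plsda(autoscale(table), y, n_components=5)
        q2 = cross_validate_q2(table.data.to_numpy(), y, n_components=5, seed=0)
        assert q2 <= model.r2y[-1] + 1e-12

    def test_impossible_stratification_rejected(self):
        X, y = separated_toy(n_per=3)
        with pytest.raises(ValueError, match="stratif"):
            cross_validate_q2(X, y, folds=5, n_components=1)


class TestPermutationTest:
    def test_strong_signal_gives_minimal_p(self):
        X, y = separated_toy(seed=11, n_per=6)
        p, null = permutation_test(X, y, n_components=1, B=99, seed=1)
        assert p == pytest.approx(1 / 100)
        assert len(null) == 99

    def test_addone_formula_consistency_and_nonzero(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((12, 6))
        y = labels(6, 6)
        sm = scaled_from(X)
        observed = fit_plsda(sm, y, n_components=2).r2y[-1]
        p, null = permutation_test(X, y, n_components=2, B=50, seed=2)
        assert p == pytest.approx((int((null >= observed).sum()) + 1) / 51)
        assert p >= 1 / 51

    def test_reproducible_given_seed(self):
        X, y = separated_toy(seed=13)
        r1 = permutation_test(X, y, n_components=2, B=30, seed=7)
        r2 = permutation_test(X, y, n_components=2, B=30, seed=7)
        assert r1[0] == r2[0]
        np.testing.assert_array_equal(r1[1], r2[1])

    def test_within_pair_sign_flip_mode(self):
        X, y = separated_toy(seed=14, n_per=6)
        pairs = np.array(list(range(6)) + list(range(6)))
        p, null = permutation_test(X, y, n_components=1, B=40, seed=3, pairs=pairs)
        assert 0 < p <= 1 and len(null) == 40


class TestVip:
    def test_equal_weights_force_unit_vip(self):
        J = 5
        model = PlsdaModel(
            n_components=1,
            weights=np.full((J, 1), 1 / np.sqrt(J)),
            x_loadings=np.zeros((J, 1)),
            y_loadings=np.array([0.8]),
            scores=np.arange(4.0).reshape(4, 1),
            r2x=np.array([0.5]),
            r2y=np.array([0.6]),
            columns=[f"v{j}" for j in range(J)],
            y_mean=0.5,
        )
        np.testing.assert_allclose(vip_scores(model).to_numpy(), 1.0, atol=1e-12)

    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(15)
        for seed in range(5):
            X = rng.standard_normal((12, 7))
            model = fit_plsda(scaled_from(X), labels(6, 6), n_components=3)
            vip = vip_scores(model)
            assert float((vip**2).sum()) == pytest.approx(7.0, abs=1e-8)

    def test_hand_toy_matches_stepwise_formula(self):
        # independent spreadsheet-style evaluation: explicit NIPALS passes
        # and the VIP formula written out term by term
        X = np.array(
            [[1.0, 2.0, 0.5], [1.2, 1.8, 0.4], [2.0, 1.0, 0.9], [2.2, 0.8, 1.0]]
        )
        y = labels(2, 2)
        sm = scaled_from(X)
        yc = np.array([0.0, 0.0, 1.0, 1.0]) - 0.5

        Xd = sm.X.copy()
        W, T, Q = [], [], []
        for _ in range(2):
            w = np.array([sum(Xd[i, j] * yc[i] for i in range(4)) for j in range(3)])
            w = w / np.sqrt(sum(v * v for v in w))
            t = np.array([sum(Xd[i, j] * w[j] for j in range(3)) for i in range(4)])
            tt = sum(v * v for v in t)
            p = np.array([sum(Xd[i, j] * t[i] for i in range(4)) / tt for j in range(3)])
            q = sum(yc[i] * t[i] for i in range(4)) / tt
            Xd = Xd - np.outer(t, p)
            W.append(w), T.append(t), Q.append(q)
        ssy = [Q[a] ** 2 * sum(v * v for v in T[a]) for a in range(2)]
        expected = np.array(
            [
                np.sqrt(
                    3
                    * sum(ssy[a] * W[a][j] ** 2 for a in range(2))
                    / sum(ssy)
                )
                for j in range(3)
            ]
        )

        model = fit_plsda(sm, y, n_components=2)
        np.testing.assert_allclose(vip_scores(model).to_numpy(), expected, atol=1e-10)

    def test_zero_response_variance_rejected(self):
        model = PlsdaModel(
            n_components=1,
            weights=np.ones((2, 1)),
            x_loadings=np.ones((2, 1)),
            y_loadings=np.array([0.0]),
            scores=np.ones((3, 1)),
            r2x=np.array([0.1]),
            r2y=np.array([0.0]),
            columns=["a", "b"],
            y_mean=0.5,
        )
        with pytest.raises(ValueError, match="no response variance"):
            vip_scores(model)
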