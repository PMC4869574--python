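"""PCA, OPLS/OPLS-DA, age regression and MANOVA behavior."""

import numpy as np
import pytest

from flyaging import multivariate as mv


def _nipals_pls1_weight(X, y, tol=1e-12, iters=1000):
    """Independent reference: first PLS1 weight vector by classic NIPALS."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    u = yc.copy()
    w_old = None
    for _ in range(iters):
        w = Xc.T @ u / (u @ u)
        w = w / np.linalg.norm(w)
        t = Xc @ w
        q = yc @ t / (t @ t)
        u = yc * q
        if w_old is not None and np.linalg.norm(w - w_old) < tol:
            break
        w_old = w
    return w


class TestPCA:
    def test_rank_one_matrix_explained_by_first_component(self, rng):
        x = np.outer(rng.normal(size=12), rng.normal(size=30))
        model = mv.fit_pca(x, n_components=3)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_column_permutation_leaves_explained_fractions(self, rng):
        x = rng.normal(size=(15, 20))
        x -= x.mean(axis=0)
        a = mv.fit_pca(x, 5).explained_variance_fraction
        b = mv.fit_pca(x[:, rng.permutation(20)], 5).explained_variance_fraction
        assert np.allclose(a, b)

    def test_full_reconstruction_machine_precision(self, rng):
        x = rng.normal(size=(10, 8))
        x -= x.mean(axis=0)
        model = mv.fit_pca(x)
        assert np.allclose(model.reconstruct(), x, atol=1e-10)

    def test_explained_fractions_non_increasing_and_sum_le_one(self, rng):
        x = rng.normal(size=(20, 12))
        x -= x.mean(axis=0)
        f = mv.fit_pca(x, 6).explained_variance_fraction
        assert np.all(np.diff(f) <= 1e-12)
        assert f.sum() <= 1 + 1e-12

    def test_too_many_components_raises(self, rng):
        with pytest.raises(ValueError):
            mv.fit_pca(rng.normal(size=(5, 10)), n_components=5)

    def test_pc23_plane_separates_control_from_abeta(self, head_processed):
        from sklearn.metrics import silhouette_score

        pca = mv.fit_pca(head_processed.intensities, n_components=4)
        labels = (head_processed.sample_meta["genotype"] != "control").to_numpy()
        score = silhouette_score(pca.scores[:, [1, 2]], labels)
        assert score > 0


class TestOPLS:
    def test_two_factor_data_split_into_predictive_and_orthogonal(self, rng):
        n = 40
        y = np.repeat([0.0, 1.0], n // 2)
        ortho = rng.normal(size=n)
        ortho -= ortho.mean()
        ortho -= (ortho @ (y - y.mean())) / ((y - y.mean()) @ (y - y.mean())) * (
            y - y.mean()
        )  # exactly uncorrelated with y
        X = np.zeros((n, 4))
        X[:, 0] = y + rng.normal(scale=1e-3, size=n)
        X[:, 1] = ortho
        X[:, 2] = 0.8 * ortho + rng.normal(scale=1e-3, size=n)
        X[:, 3] = rng.normal(scale=1e-3, size=n)
        model = mv.fit_opls(X, y[:, None], n_predictive=1, n_orthogonal=1)
        assert abs(model.correlation[0, 0]) > 0.99
        # the orthogonal weight loads on the structured-noise variables
        w_o = np.abs(model.w_orth[:, 0])
        assert w_o[1] + w_o[2] > 0.9
        # orthogonal score uncorrelated with response
        r = np.corrcoef(model.orth_scores[:, 0], y)[0, 1]
        assert abs(r) < 1e-8

    def test_three_classes_give_two_predictive_components(self, rng):
        X = rng.normal(size=(18, 10))
        classes = np.repeat(["a", "b", "c"], 6)
        X[:6, 0] += 3
        X[6:12, 1] += 3
        model = mv.fit_oplsda(X, classes, n_orthogonal=1)
        assert model.n_predictive == 2
        assert model.n_orthogonal == 1

    def test_orthogonal_scores_exactly_y_uncorrelated(self, rng):
        X = rng.normal(size=(30, 50))
        y = rng.normal(size=30)
        model = mv.fit_opls(X, y[:, None], n_predictive=1, n_orthogonal=3)
        yc = y - y.mean()
        for j in range(model.n_orthogonal):
            t = model.orth_scores[:, j]
            assert abs(np.corrcoef(t, yc)[0, 1]) < 1e-8

    def test_zero_orthogonal_equals_independent_pls1(self, rng):
        for _ in range(5):
            X = rng.normal(size=(25, 40))
            y = rng.normal(size=25)
            model = mv.fit_opls(X, y[:, None], n_predictive=1, n_orthogonal=0)
            w_ref = _nipals_pls1_weight(X, y)
            cos = abs(model.weights[:, 0] @ w_ref)
            assert cos > 0.999

    def test_degenerate_constant_x_raises(self):
        X = np.ones((10, 5))
        y = np.arange(10.0)
        with pytest.raises(ValueError):
            mv.fit_opls(X, y[:, None], n_predictive=1)


class TestClassPrediction:
    @pytest.fixture()
    def separable(self, rng):
        X = rng.normal(scale=0.2, size=(24, 12))
        classes = np.repeat(["a", "b", "c"], 8)
        X[:8, 0] += 3
        X[8:16, 1] += 3
        X[16:, 2] += 3
        return X, classes

    def test_training_samples_re_predicted_to_own_class(self, separable):
        X, classes = separable
        model = mv.fit_oplsda(X, classes, n_orthogonal=0)
        pred = mv.predict_class(model, X, is_training=np.ones(len(X), bool))
        assert (pred.assigned == classes).all()
        assert pred.is_training.all()

    def test_centroid_input_assigned_to_its_class(self, separable):
        X, classes = separable
        model = mv.fit_oplsda(X, classes, n_orthogonal=0)
        for c in model.classes_:
            centroid_x = X[classes == c].mean(axis=0, keepdims=True)
            pred = mv.predict_class(model, centroid_x)
            assert pred.assigned[0] == c

    def test_variable_mismatch_raises(self, separable):
        X, classes = separable
        model = mv.fit_oplsda(X, classes, n_orthogonal=0)
        with pytest.raises(ValueError):
            mv.predict_class(model, X[:, :5])

    def test_single_sample_class_raises(self, rng):
        X = rng.normal(size=(5, 4))
        with pytest.raises(ValueError):
            mv.fit_oplsda(X, ["a", "a", "a", "a", "b"])


class TestAgeModel:
    def test_noiseless_linear_gradient_recovered_exactly(self):
        ages = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        X = np.zeros((5, 3))
        X[:, 0] = 0.1 * ages
        model = mv.fit_opls_age(X, ages)
        pred = mv.predict_age(model, X, ages)
        assert np.allclose(pred.predicted_age, ages, atol=1e-9)
        assert np.allclose(pred.residual, 0.0, atol=1e-9)

    def test_affine_equivariance_of_predictions(self, rng):
        X = rng.normal(size=(20, 15))
        ages = rng.uniform(10, 40, size=20)
        m0 = mv.fit_opls_age(X, ages, n_orthogonal=1)
        m1 = mv.fit_opls_age(X, ages + 7.5, n_orthogonal=1)
        Xn = rng.normal(size=(6, 15))
        p0 = mv.predict_age(m0, Xn).predicted_age
        p1 = mv.predict_age(m1, Xn).predicted_age
        assert np.allclose(p1, p0 + 7.5, atol=1e-8)

    def test_training_prediction_matches_fitted_values(self, rng):
        X = rng.normal(size=(15, 10))
        ages = rng.uniform(0, 30, size=15)
        model = mv.fit_opls_age(X, ages, n_orthogonal=0)
        fitted = model.scores @ model.c_loadings.T + model.y_mean
        pred = mv.predict_age(model, X)
        assert np.allclose(pred.predicted_age, fitted[:, 0], atol=1e-10)

    def test_constant_ages_raise(self, rng):
        with pytest.raises(ValueError):
            mv.fit_opls_age(rng.normal(size=(6, 4)), [5, 5, 5, 5, 5, 5])


class TestManova:
    def test_identical_group_means_gives_lambda_near_one(self, rng):
        scores = rng.normal(size=(48, 3))
        geno = np.tile(np.repeat(["a", "b"], 6), 4)
        age = np.repeat([1, 2, 3, 4], 12)
        res = mv.two_way_manova(scores, geno, age)
        for eff in ("genotype", "age"):
            assert 0 < res[eff]["wilks_lambda"] <= 1
        assert res["genotype"]["p_value"] > 0.1

    def test_injected_separation_detected(self, rng):
        scores = rng.normal(scale=0.3, size=(18, 2))
        geno = np.repeat(["a", "b", "c"], 6)
        age = np.tile([1, 1, 2, 2, 3, 3], 3)
        scores[geno == "b", 0] += 5
        scores[geno == "c", 1] += 5
        res = mv.two_way_manova(scores, geno, age)
        assert res["genotype"]["p_value"] < 0.001
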