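import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import silhouette_score

from crcmet.latent_models import (
    NipalsPCA,
    OPLSDA,
    PLSDA,
    hotelling_outliers,
    opls_predict,
    vip,
)


def centered(rng, n, p):
    X = rng.standard_normal((n, p))
    return X - X.mean(axis=0)


class TestNipalsPCA:
    def test_matches_eigendecomposition_on_complete_data(self):
        rng = np.random.default_rng(0)
        X = centered(rng, 10, 6)
        model = NipalsPCA(n_components=3).fit(X)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        for a in range(3):
            sign = np.sign(Vt[a] @ model.loadings_[:, a])
            assert np.abs(model.loadings_[:, a] - sign * Vt[a]).max() < 1e-6
            assert np.abs(model.scores_[:, a] - sign * U[:, a] * S[a]).max() < 1e-6

    def test_rank_one_matrix_fully_explained(self):
        t = np.array([1.0, -2.0, 0.5, 0.5])
        p = np.array([0.3, 0.9, -0.2])
        model = NipalsPCA(n_components=1).fit(np.outer(t - t.mean(), p))
        assert model.explained_r2x_[0] == pytest.approx(1.0, abs=1e-12)

    def test_missing_cells_recover_generating_direction(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(40)
        p = rng.standard_normal(8)
        p /= np.linalg.norm(p)
        X = np.outer(t - t.mean(), p)
        mask = rng.random(X.shape) < 0.10
        Xm = X.copy()
        Xm[mask] = np.nan
        model = NipalsPCA(n_components=1, missing_allowed=True).fit(Xm)
        cosine = abs(model.loadings_[:, 0] @ p)
        assert cosine >= 0.999

    def test_missing_rejected_without_flag(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            NipalsPCA(n_components=1).fit(X)

    def test_score_columns_orthogonal_and_r2x_nondecreasing(self):
        rng = np.random.default_rng(2)
        model = NipalsPCA(n_components=3).fit(centered(rng, 20, 8))
        T = model.scores_
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.abs(off).max() < 1e-8
        assert (np.diff(model.explained_r2x_) >= -1e-12).all()


class TestHotellingOutliers:
    def test_displaced_sample_flagged(self):
        rng = np.random.default_rng(3)
        X = centered(rng, 60, 5)
        X[0] += 10.0 * X.std(axis=0)
        model = NipalsPCA(n_components=2).fit(X - X.mean(axis=0))
        assert 0 in hotelling_outliers(model, level=0.99)

    def test_null_flag_rate_near_one_percent(self):
        rng = np.random.default_rng(4)
        X = centered(rng, 500, 8)
        model = NipalsPCA(n_components=3).fit(X)
        rate = len(hotelling_outliers(model, level=0.99)) / 500
        # 99% binomial interval around 0.01 at n=500
        assert rate < 0.01 + 2.576 * np.sqrt(0.01 * 0.99 / 500) + 1e-9

    def test_tiny_sample_limit_finite(self):
        X = np.array([[1.0, 0.0, 0.5], [-0.5, 1.0, -1.0], [-0.5, -1.0, 0.5]])
        model = NipalsPCA(n_components=2).fit(X - X.mean(axis=0))
        assert np.isfinite(model.t2_critical(0.99))

    def test_invalid_level_rejected(self):
        rng = np.random.default_rng(5)
        model = NipalsPCA(n_components=2).fit(centered(rng, 10, 4))
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            model.t2_critical(1.0)


class TestOPLSDA:
    def test_zero_orthogonal_components_match_pls1_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((24, 7))
        y = np.r_[np.zeros(12), np.ones(12)].astype(int)
        model = OPLSDA(n_orth=0).fit(X, y)
        pls = PLSRegression(n_components=1, scale=False).fit(
            X - X.mean(axis=0), y - y.mean()
        )
        w = pls.x_weights_[:, 0]
        w /= np.linalg.norm(w)
        sign = np.sign(w @ model.weights_)
        assert np.abs(model.weights_ - sign * w).max() < 1e-8
        assert np.abs(model.scores_ - sign * pls.x_scores_[:, 0]).max() < 1e-8

    def test_constructed_geometry_separates_predictive_and_orthogonal(self):
        # X carries the label direction along `a` plus label-orthogonal
        # structured variation (z _|_ y) along a direction overlapping `a`,
        # so it confounds the predictive loading: the extracted orthogonal
        # score must be exactly the z direction (zero correlation with y)
        # and the cleaned predictive score must track y
        n = 20
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        yc = y - y.mean()
        rng = np.random.default_rng(7)
        z = rng.standard_normal(n)
        z -= z.mean()
        z -= (z @ yc) / (yc @ yc) * yc  # enforce z _|_ yc
        a = np.array([1.0, 0, 0, 0, 0])
        b = np.array([0, 1.0, 0, 0, 0])
        confounder = (a + b) / np.sqrt(2)
        X = np.outer(yc, a) + 3.0 * np.outer(z, confounder)
        model = OPLSDA(n_orth=1).fit(X, y.astype(int))
        assert model.orth_scores_.shape[1] == 1
        r_orth = np.corrcoef(model.orth_scores_[:, 0], yc)[0, 1]
        r_pred = np.corrcoef(model.scores_, yc)[0, 1]
        assert abs(r_orth) <= 1e-6
        assert abs(r_pred) >= 0.999

    def test_sample_duplication_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((16, 5))
        y = np.r_[np.zeros(8), np.ones(8)].astype(int)
        m1 = OPLSDA(n_orth=1).fit(X, y)
        m2 = OPLSDA(n_orth=1).fit(np.vstack([X, X]), np.r_[y, y])
        assert np.allclose(m1.weights_, m2.weights_, atol=1e-10)
        assert np.allclose(m1.loadings_, m2.loadings_, atol=1e-10)
        assert np.allclose(m1.vip_, m2.vip_, atol=1e-10)

    def test_single_class_and_excess_orth_rejected(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="two classes"):
            OPLSDA().fit(X, np.zeros(10, dtype=int))
        y = np.r_[np.zeros(5), np.ones(5)].astype(int)
        with pytest.raises(ValueError, match="rank"):
            OPLSDA(n_orth=4).fit(X, y)

    def test_predict_training_self_consistency(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((18, 6))
        y = np.r_[np.zeros(9), np.ones(9)].astype(int)
        model = OPLSDA(n_orth=2).fit(X, y)
        y_hat_train = model.scores_ * model.y_loading_ + model.y_mean_
        _, y_hat, _ = opls_predict(model, X)
        assert np.abs(y_hat - y_hat_train).max() < 1e-10

    def test_mean_sample_predicts_class_rate(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((15, 6))
        y = np.r_[np.zeros(9), np.ones(6)].astype(int)
        model = OPLSDA(n_orth=1).fit(X, y)
        y_hat = model.decision_function(X.mean(axis=0)[None, :])
        assert y_hat[0] == pytest.approx(6 / 15, abs=1e-10)

    def test_noiseless_separable_validation_is_perfect(self):
        rng = np.random.default_rng(12)
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        direction = rng.standard_normal(6)
        X = np.outer(y - y.mean(), direction) + 0.01 * rng.standard_normal((40, 6))
        model = OPLSDA(n_orth=0).fit(X[:30], y[:30])
        assert (model.predict(X[30:]) == y[30:]).all()

    def test_metabolite_mismatch_listed(self):
        X = pd.DataFrame(
            np.random.default_rng(13).standard_normal((12, 3)), columns=["a", "b", "c"]
        )
        y = np.r_[np.zeros(6), np.ones(6)].astype(int)
        model = OPLSDA(n_orth=0).fit(X, y)
        with pytest.raises(ValueError, match="'b'"):
            model.decision_function(X[["a", "c"]])

    def test_auto_orthogonal_component_selection_bounded(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((30, 10))
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        model = OPLSDA(n_orth="auto", max_orth=3).fit(X, y)
        assert 0 <= model.n_orth_ <= 3


class TestVip:
    def test_single_direction_weight(self):
        model = OPLSDA(n_orth=0)
        model.weights_ = np.array([1.0, 0.0, 0.0])
        model.vip_ = np.sqrt(3) * np.abs(model.weights_)
        assert np.allclose(vip(model), [np.sqrt(3), 0.0, 0.0])

    def test_equal_weights_give_unit_vip(self):
        rng = np.random.default_rng(15)
        n, p = 20, 4
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        # equal-magnitude weights arise when every column carries the signal equally
        X = np.outer(y - y.mean(), np.ones(p)) + 1e-6 * rng.standard_normal((n, p))
        model = OPLSDA(n_orth=0).fit(X, y)
        assert np.allclose(model.vip_, 1.0, atol=1e-3)

    def test_mean_square_vip_is_one(self, fitted_pipeline):
        v = fitted_pipeline.model_.vip_
        assert np.mean(v**2) == pytest.approx(1.0, abs=1e-12)


class TestPLSDA:
    @staticmethod
    def gaussians(rng, centers, n=15, sd=0.3):
        X = np.vstack([c + sd * rng.standard_normal((n, len(c))) for c in centers])
        labels = np.repeat([f"g{i}" for i in range(len(centers))], n)
        return X, labels

    def test_separated_classes_resolved_in_score_space(self):
        rng = np.random.default_rng(16)
        X, labels = self.gaussians(rng, [np.r_[0, 0, 0.0], np.r_[4, 0, 0.0], np.r_[0, 4, 0.0]])
        model = PLSDA(n_components=2).fit(X, labels)
        assert silhouette_score(model.scores_, labels) > 0.5

    def test_identical_classes_share_centroid(self):
        rng = np.random.default_rng(17)
        base = rng.standard_normal((20, 4))
        X = np.vstack([base, base, base + np.r_[5.0, 0, 0, 0]])
        labels = np.repeat(["a", "b", "c"], 20)
        model = PLSDA(n_components=2).fit(X, labels)
        cen = {g: model.scores_[labels == g].mean(axis=0) for g in "abc"}
        pooled_sd = model.scores_.std()
        assert np.linalg.norm(cen["a"] - cen["b"]) <= 0.05 * pooled_sd

    def test_small_class_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match="< 2 samples"):
            PLSDA().fit(X, np.array(["a", "a", "b", "b", "c"]))

    def test_predictions_hit_dominant_class(self):
        rng = np.random.default_rng(18)
        X, labels = self.gaussians(rng, [np.r_[0, 0.0], np.r_[5, 0.0]], n=10)
        model = PLSDA(n_components=2).fit(X, labels)
        assert (model.predict(X) == labels).mean() == 1.0
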