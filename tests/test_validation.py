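import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from crcmet.latent_models import OPLSDA
from crcmet.validation import (
    CvResult,
    auroc,
    confusion_metrics,
    cv_anova,
    label_permutation_test,
    permutation_q2_intercept,
    q2_cv,
    q2_intercept_line,
    stratified_folds,
)


def signal_data(rng, n=70, p=5, noise=0.0):
    y = (np.arange(n) % 2).astype(int)
    beta = rng.standard_normal(p)
    X = np.outer(y - y.mean(), beta) + noise * rng.standard_normal((n, p))
    return pd.DataFrame(X), y


class TestQ2Cv:
    def test_noiseless_construction_predicts_almost_perfectly(self):
        rng = np.random.default_rng(0)
        X, y = signal_data(rng, noise=1e-4)
        cv = q2_cv(OPLSDA(n_orth=0), X, y, folds=7, seed=0)
        assert cv.q2y >= 0.99

    def test_permuted_labels_give_nonpositive_q2(self):
        # with the study's model structure (one orthogonal + one predictive
        # component) at signature-scale width, a label permutation leaves the
        # cross-validated Q2 non-positive almost always; narrower or
        # orthogonal-free models overfit less and their null Q2 distribution
        # straddles zero more
        rng = np.random.default_rng(1)
        bad = 0
        n_rep = 200
        for i in range(n_rep):
            X = pd.DataFrame(rng.standard_normal((70, 48)))
            y_perm = rng.permutation((np.arange(70) % 2).astype(int))
            if q2_cv(OPLSDA(n_orth=1), X, y_perm, folds=7, seed=i).q2y > 0:
                bad += 1
        assert bad <= 0.05 * n_rep

    def test_leave_one_out_matches_brute_force(self):
        rng = np.random.default_rng(2)
        n = 8
        X = pd.DataFrame(rng.standard_normal((n, 3)))
        y = (np.arange(n) % 2).astype(int)
        cv = q2_cv(OPLSDA(n_orth=0), X, y, folds=n, seed=3)
        press = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            model = OPLSDA(n_orth=0).fit(X.loc[keep], y[keep])
            y_hat = model.decision_function(X.loc[[i]])[0]
            press += (y[i] - y_hat) ** 2
        assert cv.press == pytest.approx(press, rel=1e-12)

    def test_fold_assignment_is_stratified_partition(self):
        y = np.r_[np.zeros(21), np.ones(32)].astype(int)
        folds = stratified_folds(y, 7, seed=5)
        assert sorted(np.unique(folds)) == list(range(7))
        for k in range(7):
            # every fold keeps both classes when class counts allow it
            assert len(np.unique(y[folds == k])) == 2

    def test_lost_class_in_training_split_rejected(self):
        X = pd.DataFrame(np.random.default_rng(4).standard_normal((6, 3)))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="fewer folds|lost a class"):
            q2_cv(OPLSDA(n_orth=0), X, y, folds=6, seed=0)


class TestCvAnova:
    @staticmethod
    def result(press, ss_tot, n):
        return CvResult(7, press, ss_tot, 1 - press / ss_tot,
                        np.zeros(n), np.zeros(n, dtype=int), np.zeros(7))

    def test_no_improvement_gives_f_zero_p_one(self):
        f, _, _, p = cv_anova(self.result(10.0, 10.0, 30), 2)
        assert f == 0.0
        assert p == 1.0

    def test_worked_arithmetic(self):
        f, df1, df2, p = cv_anova(self.result(2.0, 10.0, 53), 2)
        assert f == pytest.approx(100.0)
        assert (df1, df2) == (2, 50)
        assert p == pytest.approx(stats.f.sf(100.0, 2, 50), rel=1e-12)

    def test_p_decreases_as_press_shrinks(self):
        ps = [cv_anova(self.result(press, 10.0, 53), 2)[3] for press in (5.0, 2.0, 0.5)]
        assert ps[0] > ps[1] > ps[2]

    def test_nonpositive_df2_rejected(self):
        with pytest.raises(ValueError, match="df2"):
            cv_anova(self.result(1.0, 2.0, 3), 5)


class TestPermutationIntercept:
    def test_flat_points_recover_constant(self):
        slope, intercept = q2_intercept_line([0.1, 0.4, 0.9, 1.0], [0.3, 0.3, 0.3, 0.3])
        assert intercept == pytest.approx(0.3, abs=1e-12)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        rs = np.array([0.05, 0.2, 0.55, 0.8, 1.0])
        q2s = 0.7 * rs - 0.25
        slope, intercept = q2_intercept_line(rs, q2s)
        assert intercept == pytest.approx(-0.25, abs=1e-10)
        assert slope == pytest.approx(0.7, abs=1e-10)

    def test_informative_data_validates(self):
        rng = np.random.default_rng(6)
        X, y = signal_data(rng, n=40, p=6, noise=0.5)
        res = permutation_q2_intercept(OPLSDA(n_orth=0), X, y, n=49, seed=0)
        assert res.q2_intercept <= 0
        assert res.valid
        assert res.p_q2 == pytest.approx(1 / 50)

    def test_too_few_iterations_rejected(self):
        rng = np.random.default_rng(7)
        X, y = signal_data(rng, n=20, p=3, noise=0.5)
        with pytest.raises(ValueError, match="unstable"):
            permutation_q2_intercept(OPLSDA(n_orth=0), X, y, n=10)


class TestLabelPermutation:
    @staticmethod
    def scorer(X, y):
        cv = q2_cv(OPLSDA(n_orth=0), X, y, folds=4, seed=0)
        return cv.q2y, float(np.sqrt(cv.press / len(y)))

    def test_separated_classes_reach_minimum_p(self):
        rng = np.random.default_rng(8)
        X, y = signal_data(rng, n=24, p=4, noise=0.2)
        res = label_permutation_test(self.scorer, X, y, n=200, seed=0)
        assert res.p_q2 == pytest.approx(1 / 201)
        assert res.p_rmsep == pytest.approx(1 / 201)

    def test_null_p_values_super_uniform(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 20
        alpha = 0.25
        for i in range(n_rep):
            X = pd.DataFrame(rng.standard_normal((16, 5)))
            y = (np.arange(16) % 2).astype(int)
            res = label_permutation_test(self.scorer, X, y, n=39, seed=i)
            hits += res.p_q2 <= alpha
        # P(p <= alpha) <= alpha under the null; 99% binomial slack at n=20
        assert hits <= n_rep * alpha + 2.576 * np.sqrt(n_rep * alpha * (1 - alpha))

    def test_small_sample_matches_enumeration(self):
        # 2+2 samples: only 6 distinct label assignments; sampled permutation
        # p must approach the exact enumeration p
        rng = np.random.default_rng(10)
        X = pd.DataFrame(
            [[0.0, 0.1], [0.2, -0.1], [1.0, 1.2], [0.9, 1.1]], columns=["a", "b"]
        )
        y = np.array([0, 0, 1, 1])

        def scorer(Xm, ym):
            if len(np.unique(ym)) < 2:
                return -1.0, 1.0
            model = OPLSDA(n_orth=0).fit(Xm, ym)
            y_hat = model.decision_function(Xm)
            press = float(np.sum((ym - y_hat) ** 2))
            ss = float(np.sum((ym - ym.mean()) ** 2))
            return 1 - press / ss, np.sqrt(press / len(ym))

        obs = scorer(X, y)[0]
        exact_hits = 0
        perms = list(itertools.permutations(range(4)))
        for perm in perms:
            if scorer(X, y[list(perm)])[0] >= obs:
                exact_hits += 1
        exact_fraction = exact_hits / len(perms)
        res = label_permutation_test(scorer, X, y, n=999, seed=0)
        sampled_fraction = (res.p_q2 * (999 + 1) - 1) / 999
        assert sampled_fraction == pytest.approx(exact_fraction, abs=0.05)


class TestConfusionMetrics:
    def test_reconstructed_validation_counts_reproduce_printed_rates(self):
        cm = confusion_metrics(
            np.r_[np.ones(28), np.zeros(20)],
            np.r_[np.ones(26), np.zeros(2), np.ones(1), np.zeros(19)],
            positive_label=1,
        )
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (26, 2, 1, 19)
        assert cm.percentages == {
            "sensitivity": 93, "specificity": 95, "accuracy": 94, "precision": 96
        }

    def test_perfect_prediction(self):
        cm = confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert all(v == 100 for v in cm.percentages.values())

    def test_all_predicted_positive(self):
        cm = confusion_metrics([0, 0, 1, 1], [1, 1, 1, 1])
        assert cm.percentages["sensitivity"] == 100
        assert cm.percentages["specificity"] == 0

    def test_empty_class_flags_undefined(self):
        cm = confusion_metrics([1, 1, 1], [0, 0, 0], positive_label=1)
        assert cm.specificity is None
        assert "specificity" in cm.undefined
        assert cm.percentages["specificity"] is None


class TestAuroc:
    def test_worked_examples(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1])[0] == 1.0
        assert auroc([1, 2, 3, 4], [0, 1, 0, 1])[0] == 0.75
        assert auroc([5.0] * 6, [0, 0, 0, 1, 1, 1])[0] == 0.5

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        s = rng.normal(size=30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[:2] = [0, 1]
        a1 = auroc(s, labels)
        a2 = auroc(np.exp(s) + 3, labels)
        assert a1 == pytest.approx(a2)

    def test_matches_sklearn_point_estimate(self):
        rng = np.random.default_rng(12)
        s = rng.normal(size=50)
        labels = (rng.random(50) < 0.4).astype(int)
        labels[:2] = [0, 1]
        assert auroc(s, labels)[0] == pytest.approx(roc_auc_score(labels, s), rel=1e-12)

    def test_delong_ci_matches_independent_reference(self):
        # expected values computed with the standard DeLong implementation in
        # the pROC R package on this exact input
        scores = [0.1, 0.4, 0.35, 0.8, 0.45, 0.9, 0.2, 0.6, 0.3, 0.52, 0.15, 0.65]
        labels = [0, 0, 1, 1, 0, 1, 0, 1, 0, 1, 0, 0]
        auc, lo, hi = auroc(scores, labels)
        assert auc == pytest.approx(0.857142857143, abs=1e-10)
        assert lo == pytest.approx(0.631983350384, abs=1e-10)
        assert hi == pytest.approx(1.0, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([1.0, 2.0], [1, 1])
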