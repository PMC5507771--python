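"""O-PLS core: PLS1 substrate, orthogonal filtering, prediction, CV."""

import numpy as np
import pytest

from metabopredict.opls import OPLS, OPLSDA, encode_classes, fit_pls1, kfold_cv
from _oracles import loo_cv_oracle, nipals_pls1


def random_problem(rng, n=20, p=10, noise=1.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestFitPls1:
    def test_rank_one_exact_fit(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=12)
        X = np.zeros((12, 5))
        X[:, 2] = col
        y = 3.0 * col
        res = fit_pls1(X, y, scaling="none")
        np.testing.assert_allclose(res.fittedvalues, y, atol=1e-10)

    def test_matches_nipals_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = random_problem(rng)
            res = fit_pls1(X, y)
            np.testing.assert_allclose(res.fittedvalues, nipals_pls1(X, y, 1),
                                       atol=1e-8)

    def test_tiny_printed_fixture(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([1.0, 2.0, 3.0])
        res = fit_pls1(X, y)
        np.testing.assert_allclose(res.fittedvalues, y, atol=1e-10)

    def test_zero_variance_y_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pls1(np.random.default_rng(0).normal(size=(5, 3)), np.ones(5))

    def test_orthogonal_xty_rejected(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        with pytest.raises(ValueError, match="predictive direction"):
            fit_pls1(X, y, scaling="none")


class TestOpls:
    def test_n_orth_zero_equals_pls1(self):
        rng = np.random.default_rng(3)
        X, y = random_problem(rng)
        a = OPLS(y, X, n_orth=0).fit()
        b = fit_pls1(X, y)
        np.testing.assert_allclose(a.fittedvalues, b.fittedvalues, atol=1e-10)

    def test_equals_two_component_pls_oracle(self):
        # O-PLS with 1 orthogonal component reproduces 2-component PLS1
        # training predictions (classical algebraic equivalence)
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, y = random_problem(rng)
            res = OPLS(y, X, n_orth=1).fit()
            np.testing.assert_allclose(res.fittedvalues, nipals_pls1(X, y, 2),
                                       atol=1e-6)

    def test_orthogonal_structure_filtered(self):
        rng = np.random.default_rng(5)
        n = 30
        y = rng.normal(size=n)
        s = rng.normal(size=n)
        s -= s @ y / (y @ y) * y          # s'y = 0
        a, b = rng.normal(size=8), rng.normal(size=8)
        X = np.outer(y, a) + 3.0 * np.outer(s, b) + 0.01 * rng.normal(size=(n, 8))
        r0 = OPLS(y, X, n_orth=0).fit()
        r1 = OPLS(y, X, n_orth=1).fit()
        assert r1.r2y >= r0.r2y - 1e-12

    def test_weight_invariants(self):
        rng = np.random.default_rng(6)
        X, y = random_problem(rng, n=25, p=12)
        res = OPLS(y, X, n_orth=2).fit()
        assert np.linalg.norm(res.w) == pytest.approx(1.0)
        for w_o in res.w_orth:
            assert np.linalg.norm(w_o) == pytest.approx(1.0)
            assert abs(res.w @ w_o) < 1e-8
        for j in range(res.t_orth.shape[1]):
            t_o = res.t_orth[:, j]
            c = np.corrcoef(res.t, t_o)[0, 1]
            assert abs(c) < 1e-8

    def test_early_stop_records_actual_n_orth(self):
        rng = np.random.default_rng(7)
        col = rng.normal(size=20)
        X = np.outer(col, np.ones(4))      # rank-1: no orthogonal variation
        y = col + 0.01 * rng.normal(size=20)
        res = OPLS(y, X, n_orth=3, scaling="none").fit()
        assert res.n_orth < 3

    def test_r2_ranges(self):
        rng = np.random.default_rng(8)
        X, y = random_problem(rng)
        res = OPLS(y, X, n_orth=1).fit()
        assert 0.0 <= res.r2y <= 1.0
        assert 0.0 <= res.r2x <= 1.0


class TestPredict:
    def test_training_consistency(self):
        rng = np.random.default_rng(9)
        X, y = random_problem(rng)
        res = OPLS(y, X, n_orth=1).fit()
        np.testing.assert_allclose(res.predict(X), res.fittedvalues, atol=1e-10)

    def test_duplicated_sample_duplicated_prediction(self):
        rng = np.random.default_rng(10)
        X, y = random_problem(rng)
        res = OPLS(y, X, n_orth=1).fit()
        pair = np.vstack([X[3], X[3]])
        p = res.predict(pair)
        assert p[0] == p[1]

    def test_affine_equivariance_in_y(self):
        rng = np.random.default_rng(11)
        X, y = random_problem(rng)
        base = OPLS(y, X, n_orth=1).fit()
        shifted = OPLS(y + 5.0, X, n_orth=1).fit()
        np.testing.assert_allclose(shifted.predict(X), base.predict(X) + 5.0,
                                   atol=1e-9)

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(12)
        X, y = random_problem(rng)
        res = OPLS(y, X, n_orth=0).fit()
        with pytest.raises(ValueError, match="columns"):
            res.predict(X[:, :5])

    def test_centering_estimated_on_training_only(self):
        # shifting held-out X propagates through the model coefficients,
        # it is not silently re-centered away
        rng = np.random.default_rng(13)
        X, y = random_problem(rng)
        res = OPLS(y, X, n_orth=1).fit()
        delta = np.full(X.shape[1], 2.0)
        diff = res.predict(X + delta) - res.predict(X)
        expected = float(res.coefficients() @ delta)
        np.testing.assert_allclose(diff, expected, atol=1e-9)


class TestKfoldCv:
    def test_noise_free_signal_q2(self):
        # a single latent direction, exactly recoverable by one component
        rng = np.random.default_rng(14)
        t = rng.normal(size=35)
        p = rng.normal(size=10)
        X = np.outer(t, p)
        y = 2.0 * t
        cv = kfold_cv(X, y, k=7, n_orth=0, scaling="none", seed=0)
        assert cv.q2 > 0.99

    def test_null_q2_negative_in_most_replicates(self):
        neg = 0
        for seed in range(100):
            rng = np.random.default_rng(200 + seed)
            X = rng.normal(size=(21, 8))
            y = rng.normal(size=21)
            cv = kfold_cv(X, y, k=7, n_orth=0, seed=seed)
            neg += cv.q2 <= 0
        assert neg >= 90

    def test_loo_matches_hand_loop(self):
        rng = np.random.default_rng(15)
        X, y = random_problem(rng, n=10, p=5)
        preds, q2 = loo_cv_oracle(
            X, y, lambda Xtr, ytr, Xte: OPLS(ytr, Xtr, n_orth=1).fit().predict(Xte)
        )
        cv = kfold_cv(X, y, k=10, n_orth=1, seed=0)
        np.testing.assert_array_equal(np.sort(cv.y_pred), np.sort(preds))
        assert cv.q2 == q2

    def test_every_sample_predicted_once(self):
        rng = np.random.default_rng(16)
        X, y = random_problem(rng, n=23)
        cv = kfold_cv(X, y, k=7, seed=3)
        assert np.bincount(cv.folds)[1:].sum() == 23
        assert np.unique(cv.folds).size == 7

    def test_k_exceeding_n_rejected(self):
        rng = np.random.default_rng(17)
        X, y = random_problem(rng, n=5, p=3)
        with pytest.raises(ValueError, match="exceeds"):
            kfold_cv(X, y, k=6)

    def test_stratified_fallback_warns(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(10, 4))
        y = np.array([0.0] * 8 + [1.0] * 2)
        with pytest.warns(UserWarning, match="unstratified"):
            kfold_cv(X, y + 0.0, k=5, stratified=True, seed=0)


class TestEncodeClasses:
    def test_sorted_level_coding(self):
        y, mapping = encode_classes(["HFD", "CHD", "CHD", "HFD"])
        assert mapping == {"CHD": 0, "HFD": 1}
        np.testing.assert_array_equal(y, [1, 0, 0, 1])

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="2 class levels"):
            encode_classes(["a", "a", "a"])

    def test_three_levels_rejected(self):
        with pytest.raises(ValueError, match="one-vs-rest"):
            encode_classes(["a", "a", "b", "b", "c", "c"])

    def test_label_swap_flips_scores_auc_invariant(self):
        from metabopredict.validation import mann_whitney_auc

        rng = np.random.default_rng(19)
        X = rng.normal(size=(20, 6))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        X[10:] += 1.0
        y, _ = encode_classes(labels)
        folds = np.tile(np.arange(1, 6), 4)
        cv1 = kfold_cv(X, y, k=5, n_orth=0, folds=folds)
        cv2 = kfold_cv(X, 1 - y, k=5, n_orth=0, folds=folds)
        np.testing.assert_allclose(cv1.cv_scores, -cv2.cv_scores, atol=1e-9)
        a1 = mann_whitney_auc(cv1.cv_scores, y)
        a2 = mann_whitney_auc(-cv2.cv_scores, y)
        assert a1 == pytest.approx(a2)


def test_summary_mentions_key_fields():
    rng = np.random.default_rng(20)
    X = rng.normal(size=(15, 4))
    y = X @ rng.normal(size=4) + rng.normal(size=15)
    res = OPLS(y, X, n_orth=1, feature_names=["a", "b", "c", "d"]).fit()
    text = res.summary()
    assert "R2Y" in text and "orthogonal components" in text


def test_oplsda_records_mapping():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(12, 5))
    X[6:] += 2.0
    labels = ["ctl"] * 6 + ["case"] * 6
    res = OPLSDA(labels, X, n_orth=0).fit()
    assert res.class_mapping == {"case": 0, "ctl": 1}
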