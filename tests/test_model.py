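import numpy as np
import pytest

from polysol.data import Dataset, SolubilityRecord
from polysol.kernels import KernelSpec, cross_gram
from polysol.model import LSSVR, LSSVRResults


def _primal_objective(w, b, Phi, y, gamma):
    e = y - Phi @ w - b
    return 0.5 * w @ w + gamma / 2.0 * e @ e


class TestFitBasics:
    def test_constant_target_reproduced_exactly(self, rng):
        X = rng.uniform(0, 1, size=(8, 3))
        y = np.full(8, 42.0)
        for spec in (KernelSpec.linear(), KernelSpec.gaussian(0.1),
                     KernelSpec.polynomial(1.0, 2)):
            res = LSSVR(y, X, spec, gamma=1.0, scaling=None).fit()
            np.testing.assert_allclose(res.predict(X), y, atol=1e-8)
            assert res.bias == pytest.approx(42.0, abs=1e-8)
            np.testing.assert_allclose(res.alpha, 0.0, atol=1e-8)

    def test_near_interpolation_at_large_gamma(self, rng):
        X = rng.uniform(0, 1, size=(20, 3))
        y = 100 + 50 * rng.normal(size=20)
        res = LSSVR(y, X, KernelSpec.gaussian(0.05), gamma=1e8, scaling=None).fit()
        assert np.max(np.abs(res.predict(X) - y)) < 1e-3

    def test_prediction_invariant_to_record_order(self, tiny_xy):
        X, y = tiny_xy
        res = LSSVR(y, X, KernelSpec.gaussian(0.1), gamma=10.0, scaling=None).fit()
        Xq = X[::-1]
        np.testing.assert_allclose(res.predict(Xq), res.predict(X)[::-1], rtol=1e-12)

    def test_kkt_residual_small(self, tiny_xy):
        X, y = tiny_xy
        res = LSSVR(y, X, KernelSpec.gaussian(0.1), gamma=5.0, scaling=None).fit()
        n = len(y)
        K = cross_gram(KernelSpec.gaussian(0.1), X, X)
        top = np.sum(res.alpha)
        rows = res.alpha @ (K + np.eye(n) / 5.0).T + res.bias
        resid = np.concatenate(([top], rows - y))
        assert np.linalg.norm(resid) / np.linalg.norm(y) < 1e-8

    def test_invalid_gamma_rejected(self, tiny_xy):
        X, y = tiny_xy
        for g in (0.0, -1.0, np.inf):
            with pytest.raises(ValueError):
                LSSVR(y, X, KernelSpec.linear(), gamma=g)


class TestRidgeEquivalence:
    """Linear-kernel LS-SVR equals closed-form ridge with penalty 1/gamma."""

    @pytest.mark.parametrize("gamma", [0.1, 1.0, 100.0])
    def test_against_closed_form(self, gamma, rng):
        X = rng.uniform(0, 1, size=(30, 3))
        y = 120 + 60 * X[:, 2] - 30 * X[:, 0] + rng.normal(0, 5, 30)
        res = LSSVR(y, X, KernelSpec.linear(), gamma=gamma, scaling=None).fit()
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = np.linalg.solve(Xc.T @ Xc + np.eye(3) / gamma, Xc.T @ yc)
        b = y.mean() - X.mean(axis=0) @ w
        Xq = rng.uniform(-0.2, 1.2, size=(10, 3))
        np.testing.assert_allclose(res.predict(Xq), Xq @ w + b, atol=1e-8)

    def test_against_sklearn_ridge(self, rng):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        gamma = 2.5
        X = rng.uniform(0, 1, size=(25, 3))
        y = 80 + 40 * X[:, 1] + rng.normal(0, 3, 25)
        res = LSSVR(y, X, KernelSpec.linear(), gamma=gamma, scaling=None).fit()
        ridge = sklearn_lm.Ridge(alpha=1.0 / gamma).fit(X, y)
        np.testing.assert_allclose(res.predict(X), ridge.predict(X), atol=1e-8)


class TestDualIsTheMinimizer:
    def test_beats_random_candidates_on_tiny_problem(self, rng):
        # N=5, linear kernel: dual solution attains a lower primal objective
        # than 1000 random (w, b) candidates
        X = rng.uniform(0, 1, size=(5, 3))
        y = rng.uniform(50, 250, size=5)
        gamma = 3.0
        res = LSSVR(y, X, KernelSpec.linear(), gamma=gamma, scaling=None).fit()
        w_dual = X.T @ res.alpha  # w = sum_i alpha_i x_i for the linear map
        f_dual = _primal_objective(w_dual, res.bias, X, y, gamma)
        for _ in range(1000):
            w = w_dual + rng.normal(0, 1.0, size=3)
            b = res.bias + rng.normal(0, 10.0)
            assert _primal_objective(w, b, X, y, gamma) >= f_dual - 1e-9

    def test_monotone_regularization(self, rng):
        X = rng.uniform(0, 1, size=(25, 3))
        y = 100 + 50 * np.sin(6 * X[:, 2]) + rng.normal(0, 5, 25)
        rmses = []
        for gamma in 10.0 ** np.arange(-2, 7):
            res = LSSVR(y, X, KernelSpec.gaussian(0.1), gamma=gamma, scaling=None).fit()
            rmses.append(np.sqrt(np.mean(res.resid ** 2)))
        assert all(b <= a + 1e-9 for a, b in zip(rmses, rmses[1:]))


class TestSerialization:
    def test_round_trip_predicts_identically(self, tmp_path, small_corpus):
        res = LSSVR.from_dataset(small_corpus, KernelSpec.gaussian(0.02), 50.0).fit()
        p = tmp_path / "model.json"
        res.save(p)
        back = LSSVRResults.load(p)
        np.testing.assert_array_equal(back.predict(small_corpus), res.predict(small_corpus))

    def test_summary_mentions_kernel_and_gamma(self, tiny_xy):
        X, y = tiny_xy
        res = LSSVR(y, X, KernelSpec.gaussian(0.1), gamma=5.0, scaling=None).fit()
        text = res.summary()
        assert "gaussian" in text and "gamma" in text and "MARDP" in text


class TestDatasetInterface:
    def test_from_dataset_scales_to_unit_box(self, small_corpus):
        model = LSSVR.from_dataset(small_corpus, KernelSpec.gaussian(0.05), 10.0)
        Z = model._scaled(model.exog)
        assert Z.min() == pytest.approx(0.0) and Z.max() == pytest.approx(1.0)

    def test_predict_accepts_dataset(self, small_corpus):
        res = LSSVR.from_dataset(small_corpus, KernelSpec.gaussian(0.05), 10.0).fit()
        preds = res.predict(small_corpus)
        assert preds.shape == (len(small_corpus),)
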