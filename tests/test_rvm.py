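import numpy as np
import pytest

from ppgrr.rvm import (
    FitConfig,
    HRVMModel,
    KernelParams,
    gram_matrix,
    kernel_value,
    rvm_fit,
    rvm_predict,
)

GAUSS = KernelParams(weights=np.array([1.0, 0.0, 0.0, 0.0]))
LAPL = KernelParams(weights=np.array([0.0, 0.0, 0.0, 1.0]))


class TestKernel:
    def test_gaussian_at_zero_distance(self):
        assert kernel_value(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                            GAUSS) == pytest.approx(1.0)

    def test_gaussian_closed_form(self):
        assert kernel_value(np.array([0.0]), np.array([1.0]),
                            GAUSS) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_laplacian_closed_form(self):
        assert kernel_value(np.array([0.0, 0.0]), np.array([1.0, 1.0]),
                            LAPL) == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            kernel_value(np.array([1.0]), np.array([1.0, 2.0]), GAUSS)

    def test_gram_symmetry_and_unit_diagonal(self, rng):
        X = rng.normal(size=(15, 3))
        K = gram_matrix(X, X, GAUSS)
        np.testing.assert_array_equal(K, K.T)
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_psd_mix_of_gaussian_and_laplacian(self, rng):
        p = KernelParams(weights=np.array([0.5, 0.0, 0.0, 0.5]))
        X = rng.normal(size=(20, 4))
        K = gram_matrix(X, X, p)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            KernelParams(weights=np.array([0.5, 0.5, 0.5, 0.5]))
        with pytest.raises(ValueError):
            KernelParams(weights=np.array([1.5, -0.5, 0.0, 0.0]))

    def test_raw_weights_normalized_with_uniform_fallback(self):
        p = KernelParams.from_raw_weights(np.array([2.0, 0.0, 0.0, 2.0]))
        np.testing.assert_allclose(p.weights, [0.5, 0.0, 0.0, 0.5])
        q = KernelParams.from_raw_weights(np.zeros(4))
        np.testing.assert_allclose(q.weights, 0.25)


class TestRvmFit:
    def _sparse_problem(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        K = gram_matrix(X, X, GAUSS)
        w = np.zeros(n + 1)
        w[0] = 0.5  # bias
        w[[3, 11, 27]] = [2.0, -1.5, 1.0]  # three kernel columns
        Phi = np.column_stack([np.ones(n), K])
        return X, Phi @ w

    def test_noise_free_sparse_recovery(self):
        X, y = self._sparse_problem()
        model = rvm_fit(X, y, GAUSS)
        pred = rvm_predict(model, X)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 1e-3

    def test_constant_target_carried_by_bias(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.full(30, 5.0)
        model = rvm_fit(X, y, GAUSS)
        assert len(model.relevance_vectors) <= 2
        pred = rvm_predict(model, rng.normal(size=(10, 2)))
        np.testing.assert_allclose(pred, 5.0, atol=1e-6)

    def test_sparsity_on_noisy_data(self):
        rng = np.random.default_rng(8)
        n = 200
        X = rng.normal(size=(n, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=n)
        model = rvm_fit(X, y, GAUSS)
        assert len(model.relevance_vectors) < n

    def test_marginal_likelihood_non_decreasing(self):
        X, y = self._sparse_problem(seed=3)
        y = y + 0.05 * np.random.default_rng(3).normal(size=y.size)
        model = rvm_fit(X, y, GAUSS)
        ml = np.asarray(model.ml_history)
        assert np.all(np.diff(ml) >= -1e-8 * np.maximum(1.0, np.abs(ml[:-1])))

    def test_tiny_training_set_rejected(self):
        with pytest.raises(ValueError):
            rvm_fit(np.zeros((2, 1)), np.zeros(2), GAUSS)


class TestRvmPredict:
    def test_training_points_reproduced_noise_free(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        K = gram_matrix(X, X, GAUSS)
        y = np.column_stack([np.ones(40), K]) @ np.concatenate(
            [[0.2], np.where(np.arange(40) % 13 == 0, 1.0, 0.0)]
        )
        model = rvm_fit(X, y, GAUSS)
        pred = rvm_predict(model, X)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 1e-3

    def test_predictive_variance_at_least_noise_floor(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=30)
        model = rvm_fit(X, y, GAUSS)
        _, var = rvm_predict(model, rng.normal(size=(20, 2)), return_var=True)
        assert np.all(var >= 1.0 / model.noise_precision - 1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        model = rvm_fit(X, X[:, 0], GAUSS)
        with pytest.raises(ValueError, match="mismatch"):
            rvm_predict(model, rng.normal(size=(5, 3)))

    def test_serialization_round_trip(self, rng):
        X = rng.normal(size=(25, 2))
        y = np.cos(X[:, 1])
        p = KernelParams(weights=np.array([0.4, 0.1, 0.2, 0.3]))
        model = rvm_fit(X, y, p)
        model.feature_mean = X.mean(axis=0)
        model.feature_sd = X.std(axis=0)
        back = HRVMModel.from_dict(model.to_dict())
        Xq = rng.normal(size=(10, 2))
        np.testing.assert_allclose(
            rvm_predict(back, Xq), rvm_predict(model, Xq), atol=1e-12
        )
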