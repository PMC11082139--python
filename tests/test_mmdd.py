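"""Tests for the deep-kernel MMD test."""

import copy
import itertools
import math

import numpy as np
import pytest

import shiftwatch as sw
from shiftwatch import TestConfig, TrainConfig
from shiftwatch._nn import MLP
from shiftwatch.mmdd import (
    DeepKernelParams,
    _RawKernelState,
    _mmd_objective_and_grads,
    deep_kernel,
    kernel_matrix,
    mmd_from_kernel_matrix,
    mmd_unbiased,
    train_kernel,
)


def _identity_params(sigma_a=1.0, sigma_b=1.0, delta=0.5):
    return DeepKernelParams(
        feature_map=lambda x: x.reshape(len(x), -1),
        sigma_a=sigma_a,
        sigma_b=sigma_b,
        delta=delta,
    )


class TestDeepKernel:
    def test_kernel_of_identical_inputs_is_one(self, rng):
        params = _identity_params(sigma_a=0.7, sigma_b=2.0, delta=0.3)
        for _ in range(5):
            x = rng.random((4, 4, 3))
            assert deep_kernel(x, x, params) == pytest.approx(1.0)

    def test_delta_to_one_reduces_to_image_space_gaussian(self, rng):
        x, y = rng.random((2, 2, 3)), rng.random((2, 2, 3))
        params = _identity_params(sigma_b=1.3, delta=1 - 1e-9)
        d2 = float(((x - y) ** 2).sum())
        g_b = math.exp(-d2 / (2 * 1.3**2))
        assert deep_kernel(x, y, params) == pytest.approx(g_b, rel=1e-6)

    def test_toy_value_matches_hand_evaluation(self):
        """2-pixel toy images, linear features, delta=0.5, sigma_a=sigma_b=1."""
        x = np.array([1.0, 0.0])
        y = np.array([0.0, 1.0])
        # linear feature map f(v) = 2v
        params = DeepKernelParams(
            feature_map=lambda b: 2.0 * b.reshape(len(b), -1),
            sigma_a=1.0,
            sigma_b=1.0,
            delta=0.5,
        )
        d_img = 2.0  # |x-y|^2
        d_feat = 8.0  # |2x-2y|^2
        expected = (0.5 * math.exp(-d_feat / 2) + 0.5) * math.exp(-d_img / 2)
        assert deep_kernel(x, y, params) == pytest.approx(expected, rel=1e-10)

    def test_symmetry_and_bounds_on_random_pairs(self, rng):
        net = MLP((12, 6, 4), seed=0)
        params = DeepKernelParams(feature_map=net, sigma_a=1.5, sigma_b=3.0, delta=0.4)
        for _ in range(10):
            x, y = rng.random((2, 2, 3)), rng.random((2, 2, 3))
            kxy = deep_kernel(x, y, params)
            kyx = deep_kernel(y, x, params)
            assert kxy == pytest.approx(kyx, rel=1e-9)
            assert 0.0 < kxy <= 1.0
            assert deep_kernel(x, x, params) == pytest.approx(1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            _identity_params(sigma_a=0.0)
        with pytest.raises(ValueError):
            _identity_params(delta=1.0)


class TestUnbiasedEstimator:
    def test_identical_folds_give_exactly_zero(self, rng):
        X = rng.random((5, 3, 3, 3))
        params = _identity_params()
        assert mmd_unbiased(X, X.copy(), params) == 0.0

    @pytest.mark.parametrize("m", [3, 4, 5])
    def test_matches_double_loop_oracle(self, m, rng):
        """Naive O(m^2) loop over Eq-style H terms, to machine precision."""
        X = rng.random((m, 2, 2, 3))
        Y = rng.random((m, 2, 2, 3)) + 0.2
        params = _identity_params(sigma_a=1.2, sigma_b=2.5, delta=0.35)
        total = 0.0
        for i in range(m):
            for j in range(m):
                if i == j:
                    continue
                total += (
                    deep_kernel(X[i], X[j], params)
                    + deep_kernel(Y[i], Y[j], params)
                    - deep_kernel(X[i], Y[j], params)
                    - deep_kernel(Y[i], X[j], params)
                )
        oracle = total / (m * (m - 1))
        assert mmd_unbiased(X, Y, params) == pytest.approx(oracle, abs=1e-10)

    def test_mean_zero_under_the_null(self, rng):
        """Unbiasedness: toy resampling distribution centred on zero."""
        params = _identity_params(sigma_b=2.0)
        vals = []
        for _ in range(1000):
            X = rng.standard_normal((4, 2))
            Y = rng.standard_normal((4, 2))
            vals.append(mmd_unbiased(X, Y, params))
        vals = np.array(vals)
        assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(len(vals))

    def test_small_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            mmd_unbiased(rng.random((1, 2)), rng.random((1, 2)), _identity_params())

    def test_population_mmd_monotone_in_mean_shift(self, rng):
        """Fixed Gaussian kernel: the estimate grows with mean separation."""
        params = _identity_params(sigma_a=2.0, sigma_b=2.0, delta=0.5)
        X = rng.standard_normal((60, 4))
        noise = rng.standard_normal((60, 4))
        estimates = [
            mmd_unbiased(X, noise + shift, params) for shift in (0.0, 0.5, 1.0, 2.0)
        ]
        assert estimates[1] < estimates[2] < estimates[3]


class TestPermutationConsistency:
    @pytest.mark.parametrize("m", [3, 5])
    def test_kernel_matrix_repartition_equals_direct_recomputation(self, m, rng):
        """Statistics from the joint kernel matrix equal fold recomputation."""
        X = rng.random((m, 2, 2, 3))
        Y = rng.random((m, 2, 2, 3))
        params = _identity_params(sigma_a=1.1, sigma_b=1.7, delta=0.25)
        Z = np.concatenate([X, Y])
        K = kernel_matrix(Z, Z, params)
        for combo in itertools.combinations(range(2 * m), m):
            ix = np.array(combo)
            iy = np.array([i for i in range(2 * m) if i not in combo])
            from_matrix = mmd_from_kernel_matrix(K, ix, iy)
            direct = mmd_unbiased(Z[ix], Z[iy], params)
            assert from_matrix == pytest.approx(direct, abs=1e-12)

    def test_m2_pvalue_matches_exhaustive_enumeration(self, rng):
        X = rng.random((2, 2, 2, 3))
        Y = rng.random((2, 2, 2, 3)) + 1.0
        params = _identity_params(sigma_b=2.0)
        Z = np.concatenate([X, Y])
        K = kernel_matrix(Z, Z, params)
        t_obs = mmd_from_kernel_matrix(K, np.arange(2), np.arange(2, 4))
        # the U-statistic excludes same-index cross pairs, so the value
        # depends on the within-fold pairing; enumerate ordered
        # re-partitions exactly as the engine draws them
        count, total = 0, 0
        for perm in itertools.permutations(range(4)):
            ix, iy = np.array(perm[:2]), np.array(perm[2:])
            count += mmd_from_kernel_matrix(K, ix, iy) >= t_obs - 1e-12
            total += 1
        p_exact = count / total
        cfg = TestConfig(n_permutations=20_000, seed=3, sidedness="upper_tail")
        p_mc = sw.permutation_pvalue(
            t_obs,
            lambda ix, iy: mmd_from_kernel_matrix(K, ix, iy),
            np.arange(2),
            np.arange(2, 4),
            cfg,
        )
        se = np.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(p_mc - p_exact) < 3 * se + 2 / 20_000


class TestKernelTraining:
    def test_gradients_match_finite_differences(self, rng):
        xb = rng.random((5, 2, 2, 3)).astype(np.float32)
        yb = (rng.random((5, 2, 2, 3)) + 0.3).astype(np.float32)
        state = _RawKernelState(net=MLP((12, 6, 4), seed=3), s_a=0.3, s_b=-0.2, c=0.1)
        _, net_grads, dsa, dsb, dc = _mmd_objective_and_grads(state, xb, yb)
        eps = 1e-4
        for name, grad in [("s_a", dsa), ("s_b", dsb), ("c", dc)]:
            hi = copy.deepcopy(state)
            lo = copy.deepcopy(state)
            setattr(hi, name, getattr(state, name) + eps)
            setattr(lo, name, getattr(state, name) - eps)
            fd = (
                _mmd_objective_and_grads(hi, xb, yb)[0]
                - _mmd_objective_and_grads(lo, xb, yb)[0]
            ) / (2 * eps)
            assert grad == pytest.approx(fd, rel=1e-4, abs=1e-9)
        # two representative network weights (float32 forward noise allowed)
        W = state.net.weights[0]
        for i, j in [(3, 2), (7, 1)]:
            orig = W[i, j]
            W[i, j] = orig + eps
            lp = _mmd_objective_and_grads(state, xb, yb)[0]
            W[i, j] = orig - eps
            lm = _mmd_objective_and_grads(state, xb, yb)[0]
            W[i, j] = orig
            fd = (lp - lm) / (2 * eps)
            assert net_grads[0][i, j] == pytest.approx(fd, rel=0.05, abs=1e-5)

    def test_training_is_deterministic(self, dataset):
        cfg = TrainConfig(epochs=2, batch_size=16, seed=5)
        a = train_kernel(dataset.images[:40], dataset.images[40:80], cfg)
        b = train_kernel(dataset.images[:40], dataset.images[40:80], cfg)
        assert a.sigma_a == b.sigma_a and a.delta == b.delta
        for pa, pb in zip(a.feature_map.get_params(), b.feature_map.get_params()):
            np.testing.assert_array_equal(pa, pb)

    def test_small_folds_rejected(self, dataset):
        with pytest.raises(ValueError):
            train_kernel(dataset.images[:1], dataset.images[:1])

    def test_trained_kernel_separates_strong_shift(self, dataset, ood_dataset):
        """Held-out MMD exceeds its permutation null for an OOD target."""
        params = train_kernel(
            dataset.images[:150],
            ood_dataset.images[:150],
            TrainConfig(batch_size=32, seed=0),
        )
        X = dataset.images[500:600]
        Y = ood_dataset.images[200:300]
        Z = np.concatenate([X, Y])
        K = kernel_matrix(Z, Z, params)
        m = len(X)
        t_obs = mmd_from_kernel_matrix(K, np.arange(m), np.arange(m, 2 * m))
        rng = np.random.default_rng(0)
        null = []
        for _ in range(200):
            perm = rng.permutation(2 * m)
            null.append(mmd_from_kernel_matrix(K, perm[:m], perm[m:]))
        assert t_obs > np.quantile(null, 0.95)


class TestEndToEnd:
    def test_mmdd_detects_ood_shift(self, dataset, ood_dataset):
        src = sw.null_sampler(dataset, "source")
        tgt = sw.ood_sampler(ood_dataset, "target")
        splits = sw.make_splits(src, tgt, n_train=100, m=100, seed=31)
        res = sw.mmdd_test(splits, TestConfig(seed=31, sidedness="upper_tail"))
        assert res.method == "mmdd"
        assert res.reject

    def test_mmdd_requires_two_training_samples(self, dataset):
        src = sw.null_sampler(dataset, "source")
        splits = sw.make_splits(src, src, n_train=0, m=20, seed=0)
        with pytest.raises(ValueError):
            sw.mmdd_test(splits)
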