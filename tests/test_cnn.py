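import numpy as np
import pytest

from semindex.cnn import (
    CNN,
    CNNConfig,
    ConvLayerParams,
    FCLayerParams,
    PoolLayerParams,
    conv_forward,
    default_config,
    dropout,
    fc_forward,
    pool_forward,
    relu,
)


def conv_oracle(A, kernels, bias, act=lambda x: x):
    """Four-nested-loop direct summation; A is (P, S, C)."""
    n_k, h, depth = kernels.shape
    P, S, C = A.shape
    out = np.zeros((n_k, P - h + 1, S))
    for k in range(n_k):
        for p in range(P - h + 1):
            for s in range(S):
                acc = 0.0
                for u in range(h):
                    for c in range(depth):
                        acc += A[p + u, s, c] * kernels[k, u, c]
                out[k, p, s] = act(acc + bias[k])
    return out


class TestRelu:
    def test_negative(self):
        assert relu(-2.0) == 0.0

    def test_positive(self):
        assert relu(3.0) == 3.0

    def test_zero_boundary(self):
        assert relu(0.0) == 0.0


class TestDropout:
    def test_rate_zero_identity(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(dropout(x, 0.0, "train"), x)

    def test_inference_identity(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(dropout(x, 0.9, "inference"), x)

    def test_half_rate_zeroes_half(self):
        rng = np.random.default_rng(0)
        x = np.ones(100_000)
        out = dropout(x, 0.5, "train", rng)
        frac = np.mean(out == 0)
        assert abs(frac - 0.5) < 0.01

    def test_mean_network_property(self):
        rng = np.random.default_rng(1)
        x = np.linspace(1, 2, 50)
        n = 30_000
        masks = (rng.random((n, x.size)) >= 0.5) / 0.5
        acc = (masks * x).mean(axis=0)
        np.testing.assert_allclose(acc, x, rtol=0.02)

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            dropout(np.ones(3), 1.0, "train")


class TestConvForward:
    def test_zero_kernel_zero_maps(self):
        A = np.random.default_rng(0).standard_normal((6, 12))
        layer = ConvLayerParams(np.zeros((2, 2, 3)), np.zeros(2))
        maps = conv_forward(A, layer, "relu")
        np.testing.assert_array_equal(maps, np.zeros((2, 5, 4)))

    def test_h1_one_hot_kernel_selects_column(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((5, 4, 3))
        kernel = np.zeros((1, 1, 3))
        kernel[0, 0, 2] = 1.0
        layer = ConvLayerParams(kernel, np.zeros(1))
        maps = conv_forward(A, layer, "identity")
        np.testing.assert_allclose(maps[0], A[:, :, 2])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            P = int(rng.integers(3, 7))
            d = int(rng.integers(1, 4))
            h = int(rng.integers(1, P))
            n_k = int(rng.integers(1, 4))
            A = rng.standard_normal((P, 4 * d))
            K = rng.standard_normal((n_k, h, d))
            b = rng.standard_normal(n_k)
            got = conv_forward(A, ConvLayerParams(K, b), "identity")
            want = conv_oracle(A.reshape(P, 4, d), K, b)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_kernel_taller_than_input_errors(self):
        layer = ConvLayerParams(np.ones((1, 5, 2)), np.zeros(1))
        with pytest.raises(ValueError):
            conv_forward(np.ones((3, 8)), layer)


class TestPoolForward:
    def test_k1_plain_max(self):
        layer = PoolLayerParams(1, np.ones(1), np.zeros(1))
        np.testing.assert_array_equal(
            pool_forward(np.array([1.0, 3.0, 2.0]), layer), [3.0])

    def test_k2_preserves_order(self):
        layer = PoolLayerParams(2, np.ones(1), np.zeros(1))
        got = pool_forward(np.array([1.0, 3.0, 2.0]), layer)
        # sort-and-reorder oracle: top-2 values {3, 2} in original order
        np.testing.assert_array_equal(got, [3.0, 2.0])

    def test_beta_zero_gives_bias(self):
        layer = PoolLayerParams(2, np.zeros(1), np.full(1, 0.7))
        got = pool_forward(np.array([5.0, 1.0, 2.0]), layer)
        np.testing.assert_allclose(got, [0.7, 0.7])

    def test_k_too_large_errors(self):
        layer = PoolLayerParams(4, np.ones(1), np.zeros(1))
        with pytest.raises(ValueError):
            pool_forward(np.array([1.0, 2.0]), layer)

    def test_matches_sort_reorder_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            P = int(rng.integers(2, 10))
            k = int(rng.integers(1, P + 1))
            x = rng.standard_normal(P)
            layer = PoolLayerParams(k, np.ones(1), np.zeros(1))
            got = pool_forward(x, layer)
            idx = sorted(np.argsort(-x, kind="stable")[:k])
            np.testing.assert_allclose(got, x[idx], atol=1e-12)


class TestFCForward:
    def test_zero_weight_gives_bias(self):
        layer = FCLayerParams(np.zeros((2, 3)), np.array([1.0, -1.0]),
                              "identity")
        np.testing.assert_array_equal(fc_forward(np.ones(3), layer), [1.0, -1.0])

    def test_identity(self):
        layer = FCLayerParams(np.eye(3), np.zeros(3), "identity")
        x = np.array([0.1, 0.2, 0.3])
        np.testing.assert_array_equal(fc_forward(x, layer), x)

    def test_matches_matmul_oracle(self):
        rng = np.random.default_rng(4)
        W = rng.standard_normal((4, 3))
        b = rng.standard_normal(4)
        x = rng.standard_normal(3)
        got = fc_forward(x, FCLayerParams(W, b, "identity"))
        want = np.array([sum(W[i, j] * x[j] for j in range(3)) + b[i]
                         for i in range(4)])
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_shape_mismatch_errors(self):
        layer = FCLayerParams(np.zeros((2, 3)), np.zeros(2))
        with pytest.raises(ValueError):
            fc_forward(np.ones(4), layer)


class TestCNNForward:
    def test_inference_deterministic(self):
        cnn = CNN(CNNConfig(stages=[{"h": 2, "n_kernels": 3, "k": 1}],
                            fc_sizes=[5]), L=4, d=2, seed=0)
        X = np.random.default_rng(0).standard_normal((4, 8))
        np.testing.assert_array_equal(cnn.forward(X), cnn.forward(X))

    def test_zero_input_zero_bias(self):
        cnn = CNN(CNNConfig(stages=[{"h": 1, "n_kernels": 2, "k": 1}],
                            fc_sizes=[3]), L=3, d=2, seed=1)
        y = cnn.forward(np.zeros((3, 8)))
        # final sigmoid of w@0 + 0 = 0.5 everywhere
        np.testing.assert_allclose(y, 0.5)

    def test_default_depth(self):
        config = default_config()
        assert len(config.stages) == 5
        assert len(config.fc_sizes) == 3

    def test_tiny_config_matches_scripted_oracle(self):
        from semindex.dbm import sigmoid
        cnn = CNN(CNNConfig(stages=[{"h": 2, "n_kernels": 2, "k": 1}],
                            fc_sizes=[3], dropout_rate=0.0),
                  L=4, d=2, seed=7)
        rng = np.random.default_rng(8)
        X = rng.standard_normal((4, 8))
        got = cnn.forward(X)
        conv = cnn.stages[0][0]
        pool = cnn.stages[0][2]
        dense = cnn.fc[0][0]
        maps = conv_oracle(X.reshape(4, 4, 2), conv.K, conv.b,
                           act=lambda v: max(v, 0.0))  # (n_k, P', S)
        pooled = np.empty((2, 1, 4))
        for k in range(2):
            for s in range(4):
                m = maps[k, :, s]
                pooled[k, 0, s] = pool.beta[k] * m.max() + pool.b[k]
        # flatten in (position, slot, channel) order to mirror the network
        flat = np.transpose(pooled, (1, 2, 0)).ravel()
        want = sigmoid(dense.W @ flat + dense.b)
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestBackward:
    @staticmethod
    def loss_and_grads(cnn, X, R):
        y = cnn.forward(X)
        cnn.backward(R)
        return float((y * R).sum()), cnn.gradients()

    def test_gradient_check(self):
        cnn = CNN(CNNConfig(stages=[{"h": 2, "n_kernels": 2, "k": 2}],
                            fc_sizes=[4, 3], dropout_rate=0.0),
                  L=5, d=2, seed=3)
        rng = np.random.default_rng(5)
        X = rng.standard_normal((2, 5, 4, 2))
        R = rng.standard_normal((2, 3))
        _, grads = self.loss_and_grads(cnn, X, R)
        grads = [g.copy() for g in grads]
        eps = 1e-6
        for param, grad in zip(cnn.parameters(), grads):
            flat = param.ravel()
            idx = np.random.default_rng(0).choice(
                flat.size, size=min(8, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp = float((cnn.forward(X) * R).sum())
                flat[i] = orig - eps
                lm = float((cnn.forward(X) * R).sum())
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(grad.ravel()[i]), 1e-8)
                assert abs(num - grad.ravel()[i]) / denom < 1e-4

    def test_kmax_permutation_covariant_over_channels(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, 6, 2, 4))
        from semindex.cnn import _Pool
        pool = _Pool(3, 4)
        out = pool.forward(x)
        perm = np.array([2, 0, 3, 1])
        pool2 = _Pool(3, 4)
        out2 = pool2.forward(x[:, :, :, perm])
        np.testing.assert_allclose(out[:, :, :, perm], out2)
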