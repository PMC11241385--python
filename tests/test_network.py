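"""Architecture conformance, layer oracles, training and splitting."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from neosono import (
    CompositeCNNClassifier,
    NetworkConfig,
    build_network,
    crossvalidate,
    layer_shapes,
    split_dataset,
)
from neosono import _nn
from neosono.network import load_checkpoint, save_checkpoint

TINY = NetworkConfig(
    input_height=8, input_width=8, input_channels=3,
    block_channels=(2, 3, 4), head_channels=5,
)


def naive_conv_same(x, kernel):
    """Zero-padded sliding-window sum, the textbook convolution loop."""
    h, w = x.shape
    k = kernel.shape[0]
    pad = k // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            for di in range(k):
                for dj in range(k):
                    r, c = i + di - pad, j + dj - pad
                    if 0 <= r < h and 0 <= c < w:
                        out[i, j] += x[r, c] * kernel[di, dj]
    return out


def naive_maxpool(x, s=2):
    h2, w2 = x.shape[0] // s, x.shape[1] // s
    out = np.zeros((h2, w2))
    for i in range(h2):
        for j in range(w2):
            out[i, j] = x[i * s : (i + 1) * s, j * s : (j + 1) * s].max()
    return out


class TestArchitecture:
    def test_feature_map_sides_shrink_100_50_25_12(self):
        sizes = NetworkConfig().spatial_sizes()
        assert sizes == [(100, 100), (50, 50), (25, 25), (12, 12)]

    def test_default_layer_stack_shapes(self):
        shapes = dict(layer_shapes())
        assert shapes["Input"] == (100, 100, 3)
        assert shapes["Conv1"] == (100, 100, 16)
        assert shapes["MaxPool1"] == (50, 50, 16)
        assert shapes["Conv2"] == (50, 50, 32)
        assert shapes["MaxPool2"] == (25, 25, 32)
        assert shapes["Conv3"] == (25, 25, 64)
        assert shapes["MaxPool3"] == (12, 12, 64)
        assert shapes["Conv4"] == (12, 12, 128)
        assert shapes["FullyConnected"] == (1, 1, 3)

    def test_forward_pass_yields_probability_simplex(self, rng):
        net = build_network(NetworkConfig(), np.random.default_rng(0))
        x = rng.random((2, 100, 100, 3), dtype=np.float64).astype(np.float32)
        p = _nn.softmax(net.forward(x))
        assert p.shape == (2, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_misconfiguration_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(kernel_size=4)
        with pytest.raises(ValueError):
            NetworkConfig(block_channels=(16, 0))


class TestLayerOracles:
    def test_conv_matches_naive_sliding_window(self, rng):
        for _ in range(20):
            x = rng.normal(size=(5, 5)).astype(np.float32)
            ker = rng.normal(size=(3, 3)).astype(np.float32)
            conv = _nn.Conv2D(3, 1, 1, np.random.default_rng(0))
            conv.W[...] = ker.reshape(9, 1)
            conv.b[...] = 0
            got = conv.forward(x[None, :, :, None], train=False)[0, :, :, 0]
            np.testing.assert_allclose(
                got, naive_conv_same(x, ker), rtol=1e-5, atol=1e-5
            )

    def test_maxpool_matches_naive_block_max_including_odd_sizes(self, rng):
        pool = _nn.MaxPool2D()
        for n in (4, 5, 6, 7, 25):
            for _ in range(5):
                x = rng.normal(size=(n, n)).astype(np.float32)
                got = pool.forward(x[None, :, :, None], train=False)[0, :, :, 0]
                np.testing.assert_allclose(got, naive_maxpool(x))

    def test_softmax_formula(self):
        np.testing.assert_allclose(_nn.softmax(np.zeros(3)), np.full(3, 1 / 3))
        z = np.array([2.0, 1.0, 0.0])
        want = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(_nn.softmax(z), want, atol=1e-12)

    def test_relu_nonnegative_and_identity_on_positives(self, rng):
        x = rng.normal(size=(2, 4, 4, 3)).astype(np.float32)
        out = _nn.ReLU().forward(x, train=False)
        assert np.all(out >= 0)
        np.testing.assert_array_equal(out[x >= 0], x[x >= 0])

    def test_conv_backward_matches_numerical_gradient(self, rng):
        # finite-difference check of dW on a tiny instance
        x = rng.normal(size=(1, 4, 4, 2)).astype(np.float64)
        conv = _nn.Conv2D(3, 2, 1, np.random.default_rng(3))
        w0 = conv.W.copy()

        def loss(wflat):
            conv.W[...] = wflat.reshape(conv.W.shape)
            return float(conv.forward(x.astype(np.float32), train=True).sum())

        base = loss(w0.ravel())
        conv.W[...] = w0
        out = conv.forward(x.astype(np.float32), train=True)
        conv.backward(np.ones_like(out))
        analytic = conv.dW.copy()
        eps = 1e-2
        for idx in [(0, 0), (8, 0), (17, 0)]:
            w = w0.ravel().copy()
            w[idx[0] * conv.W.shape[1] + idx[1]] += eps
            num = (loss(w) - base) / eps
            assert analytic[idx] == pytest.approx(num, rel=1e-2, abs=1e-2)


class TestRMSProp:
    def test_scalar_trajectory_matches_hand_recursion(self):
        w = np.array([1.0])
        g = np.zeros(1)
        opt = _nn.RMSProp([(w, g)], lr=0.1, decay=0.9, eps=1e-8)
        # quadratic loss J = w^2 / 2, gradient = w; recursion done by hand
        w_ref, c_ref = 1.0, 0.0
        for _ in range(3):
            grad = w_ref
            c_ref = 0.9 * c_ref + 0.1 * grad * grad
            w_ref = w_ref - 0.1 * grad / (c_ref**0.5 + 1e-8)
            g[0] = w[0]
            opt.step()
            assert w[0] == pytest.approx(w_ref, abs=1e-12)

    def test_zero_learning_rate_leaves_weights_unchanged(self, rng):
        X = rng.integers(0, 256, (12, 8, 8, 3), dtype=np.uint8)
        y = np.array(["a", "b", "c"] * 4, dtype=object)
        clfs = [
            CompositeCNNClassifier(
                learning_rate=0.0, max_epochs=n, config=TINY, random_state=5
            ).fit(X, y)
            for n in (1, 5)
        ]
        for w1, w5 in zip(
            clfs[0].network_.get_weights(), clfs[1].network_.get_weights()
        ):
            np.testing.assert_array_equal(w1, w5)


class TestSplitDataset:
    def test_200_samples_split_140_30_30(self):
        y = np.repeat(["Normal", "Moderate", "Intensive"], [67, 67, 66])
        tr, va, te = split_dataset(y, seed=0)
        assert (len(tr), len(va), len(te)) == (140, 30, 30)
        all_idx = np.sort(np.concatenate([tr, va, te]))
        np.testing.assert_array_equal(all_idx, np.arange(200))

    def test_stratification_preserves_class_balance(self):
        y = np.repeat(["Normal", "Moderate", "Intensive"], 40)
        tr, va, te = split_dataset(y, seed=3)
        for part in (tr, va, te):
            _, counts = np.unique(y[part], return_counts=True)
            assert counts.min() == counts.max()

    def test_degenerate_fractions_all_train(self):
        y = np.array(["a", "b"] * 5)
        tr, va, te = split_dataset(y, fractions=(1.0, 0.0, 0.0), seed=0)
        assert len(tr) == 10 and len(va) == 0 and len(te) == 0

    def test_seed_reproducibility_and_variation(self):
        y = np.repeat(["a", "b", "c"], 20)
        s1 = split_dataset(y, seed=7)
        s2 = split_dataset(y, seed=7)
        s3 = split_dataset(y, seed=8)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a, b)
        assert any(not np.array_equal(a, b) for a, b in zip(s1, s3))
        assert [len(p) for p in s1] == [len(p) for p in s3]

    def test_class_smaller_than_partitions_rejected(self):
        y = np.array(["a"] * 10 + ["b"] * 2)
        with pytest.raises(ValueError, match="fewer samples"):
            split_dataset(y, seed=0)


@pytest.fixture(scope="module")
def tiny_fit():
    rng = np.random.default_rng(9)
    # classes separated by mean brightness so the tiny net can learn
    X = np.concatenate(
        [
            rng.integers(lo, lo + 40, (8, 8, 8, 3), dtype=np.uint8)
            for lo in (0, 100, 200)
        ]
    )
    y = np.array(["dark"] * 8 + ["mid"] * 8 + ["bright"] * 8, dtype=object)
    clf = CompositeCNNClassifier(
        max_epochs=60, learning_rate=3e-3, config=TINY,
        random_state=1, batch_size=6,
    ).fit(X, y)
    return clf, X, y


class TestTrainingAndPrediction:
    def test_history_and_probability_contract(self, tiny_fit):
        clf, X, _ = tiny_fit
        assert len(clf.history_["epoch"]) <= 60
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_separable_classes_learned(self, tiny_fit):
        clf, X, y = tiny_fit
        assert (clf.predict(X) == y).mean() > 0.9

    def test_same_seed_identical_history(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 256, (12, 8, 8, 3), dtype=np.uint8)
        y = np.array(["a", "b", "c"] * 4, dtype=object)
        h = [
            CompositeCNNClassifier(
                max_epochs=3, config=TINY, random_state=11
            ).fit(X, y).history_
            for _ in range(2)
        ]
        assert h[0] == h[1]

    def test_wrong_input_shape_rejected(self, tiny_fit):
        clf, _, _ = tiny_fit
        with pytest.raises(ValueError, match="shape"):
            clf.predict(np.zeros((2, 5, 5, 3), np.uint8))

    def test_checkpoint_round_trip(self, tiny_fit, tmp_path):
        clf, X, _ = tiny_fit
        path = tmp_path / "model.npz"
        save_checkpoint(clf, path)
        loaded = load_checkpoint(path)
        np.testing.assert_allclose(
            clf.predict_proba(X), loaded.predict_proba(X), atol=1e-6
        )


class _OracleClassifier(ClassifierMixin, BaseEstimator):
    """Predicts the true label, which is encoded as the only feature."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.asarray(X).ravel()


class TestCrossvalidate:
    def test_oracle_classifier_scores_perfectly_with_zero_sd(self):
        y = np.repeat(["Normal", "Moderate", "Intensive"], 10).astype(object)
        X = y.reshape(-1, 1)
        reports, agg = crossvalidate(
            _OracleClassifier(), X, y, k=5, seed=0, probabilities=False
        )
        accs = agg[(agg.metric == "accuracy") & (agg["class"] == "Overall")]
        assert accs["mean"].iloc[0] == 1.0
        assert accs["sd"].iloc[0] == 0.0

    def test_every_sample_tested_exactly_once(self):
        y = np.repeat(["a", "b", "c"], 7).astype(object)
        X = y.reshape(-1, 1)
        reports, _ = crossvalidate(
            _OracleClassifier(), X, y, k=3, seed=0, probabilities=False
        )
        assert sum(r.matrix.total for r in reports) == len(y)

    def test_k_below_two_rejected(self):
        y = np.repeat(["a", "b"], 5).astype(object)
        with pytest.raises(ValueError):
            crossvalidate(_OracleClassifier(), y.reshape(-1, 1), y, k=1)
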