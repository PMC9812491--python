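import numpy as np
import pytest

from conftest import tiny_cnn_config
from drugrelink.pair_cnn import (
    CNNConfig,
    CNNParams,
    PairPrediction,
    build_pair_tensor,
    cnn_forward,
    cnn_loss,
    conv_forward,
    max_pool,
    predict_pairs,
    train_classifier,
)
from drugrelink.vgae import NodeEmbeddings

DRUGS = ["r1", "r2", "r3"]
DISEASES = ["d1", "d2"]


class TestPairTensor:
    def test_content_centered_in_zero_ring(self):
        emb = NodeEmbeddings(np.array([[1.0, 2.0], [9., 9.], [9., 9.], [3.0, 4.0], [9., 9.]]), 3, 2)
        t = build_pair_tensor(emb, "r1", "d1", DRUGS, DISEASES)
        assert t.values.shape == (4, 4)
        np.testing.assert_array_equal(t.content(), [[1, 2], [3, 4]])
        ring = t.values.copy()
        ring[1:-1, 1:-1] = 0
        assert not ring.any()

    def test_rows_are_copies(self, small_emb):
        t = build_pair_tensor(small_emb, "r1", "d1", DRUGS, DISEASES)
        before = t.values.copy()
        small_emb.x2 += 100.0
        np.testing.assert_array_equal(t.values, before)

    def test_zero_embeddings_give_zero_tensor(self):
        emb = NodeEmbeddings(np.zeros((5, 3)), 3, 2)
        t = build_pair_tensor(emb, "r2", "d2", DRUGS, DISEASES)
        assert not t.values.any()

    def test_unknown_ids_raise(self, small_emb):
        with pytest.raises(KeyError, match="rX"):
            build_pair_tensor(small_emb, "rX", "d1", DRUGS, DISEASES)
        with pytest.raises(KeyError, match="dX"):
            build_pair_tensor(small_emb, "r1", "dX", DRUGS, DISEASES)


class TestConvPrimitives:
    def test_unit_filter_is_relu(self):
        x = np.array([[1.0, -2.0], [-3.0, 4.0]])
        out = conv_forward(x, np.ones((1, 1, 1, 1)), np.zeros(1))
        np.testing.assert_array_equal(out[0], np.maximum(x, 0))

    def test_sum_filter(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = conv_forward(x, np.ones((1, 1, 2, 2)), np.zeros(1))
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == pytest.approx(10.0)

    def test_large_negative_bias_zeroes_output(self):
        x = np.random.default_rng(0).random((3, 5))
        out = conv_forward(x, np.ones((2, 1, 2, 2)), np.full(2, -100.0))
        assert not out.any()

    def test_oversized_filter_rejected(self):
        with pytest.raises(ValueError, match="larger than input"):
            conv_forward(np.ones((2, 2)), np.ones((1, 1, 3, 3)), np.zeros(1))

    def test_pool_whole_map(self):
        assert max_pool(np.array([[1.0, 3.0], [2.0, 0.0]]), 2, 2) == pytest.approx(3.0)

    def test_pool_windows(self):
        out = max_pool(np.array([[1.0, 4.0, 2.0, 8.0]]), 1, 2)
        np.testing.assert_array_equal(out, [[4.0, 8.0]])

    def test_pool_constant_map(self):
        out = max_pool(np.full((2, 4), 7.0), 1, 2)
        np.testing.assert_array_equal(out, np.full((2, 2), 7.0))

    def test_pool_ceil_mode_truncated_window(self):
        out = max_pool(np.array([[1.0, 2.0, 3.0]]), 1, 2)
        np.testing.assert_array_equal(out, [[2.0, 3.0]])


def naive_forward(pair_values, params):
    """Direct nested-loop evaluation of the conv/pool/FC/softmax stack."""
    maps = [pair_values[None]]  # channel dim
    x = maps[0]
    for (w, b), (pl, pw) in zip(params.conv, params.config.pools):
        k, c, fl, fw = w.shape
        ho, wo = x.shape[1] - fl + 1, x.shape[2] - fw + 1
        out = np.zeros((k, ho, wo))
        for kk in range(k):
            for i in range(ho):
                for j in range(wo):
                    acc = b[kk]
                    for cc in range(c):
                        for di in range(fl):
                            for dj in range(fw):
                                acc += w[kk, cc, di, dj] * x[cc, i + di, j + dj]
                    out[kk, i, j] = max(acc, 0.0)
        hp, wp = -(-ho // pl), -(-wo // pw)
        pooled = np.zeros((k, hp, wp))
        for kk in range(k):
            for i in range(hp):
                for j in range(wp):
                    win = out[kk, i * pl:(i + 1) * pl, j * pw:(j + 1) * pw]
                    pooled[kk, i, j] = win.max()
        x = pooled
    y = x.reshape(-1)
    for w, b in params.fc:
        y = np.maximum(y @ w + b, 0.0)
    logits = y @ params.out[0] + params.out[1]
    e = np.exp(logits - logits.max())
    return (e / e.sum())[1]


class TestCNNForward:
    def test_matches_naive_nested_loop_oracle(self):
        rng = np.random.default_rng(8)
        cfg = tiny_cnn_config()
        params = CNNParams.init(6, cfg, rng)
        emb = NodeEmbeddings(rng.standard_normal((5, 6)), 3, 2)
        for drug, disease in [("r1", "d1"), ("r3", "d2")]:
            pair = build_pair_tensor(emb, drug, disease, DRUGS, DISEASES)
            trace = cnn_forward(pair, params)
            assert trace.probability == pytest.approx(naive_forward(pair.values, params), abs=1e-12)

    def test_zero_everything_gives_half(self):
        cfg = tiny_cnn_config()
        params = CNNParams.init(6, cfg, np.random.default_rng(0))
        params.conv = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params.conv]
        params.fc = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params.fc]
        params.out = (np.zeros_like(params.out[0]), np.zeros_like(params.out[1]))
        emb = NodeEmbeddings(np.zeros((5, 6)), 3, 2)
        pair = build_pair_tensor(emb, "r1", "d1", DRUGS, DISEASES)
        assert cnn_forward(pair, params).probability == pytest.approx(0.5)

    def test_output_bias_sets_softmax(self):
        cfg = tiny_cnn_config()
        params = CNNParams.init(6, cfg, np.random.default_rng(0))
        params.conv = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params.conv]
        params.out = (np.zeros_like(params.out[0]), np.array([0.0, np.log(3.0)]))
        emb = NodeEmbeddings(np.zeros((5, 6)), 3, 2)
        pair = build_pair_tensor(emb, "r1", "d1", DRUGS, DISEASES)
        assert cnn_forward(pair, params).probability == pytest.approx(0.75, abs=1e-12)

    def test_inference_is_deterministic(self, small_emb):
        cfg = tiny_cnn_config()
        params = CNNParams.init(4, cfg, np.random.default_rng(1))
        pair = build_pair_tensor(small_emb, "r2", "d1", DRUGS, DISEASES)
        assert cnn_forward(pair, params).probability == cnn_forward(pair, params).probability

    def test_filter_count_ratio_enforced(self):
        cfg = tiny_cnn_config()
        params = CNNParams.init(6, cfg, np.random.default_rng(0))
        bad_conv = [params.conv[0], params.conv[0], params.conv[2]]
        with pytest.raises(ValueError, match="1:2:3"):
            CNNParams(bad_conv, params.fc, params.out, cfg)

    def test_geometry_collapse_named(self):
        cfg = CNNConfig(n_conv=1, filters=((2, 3), (1, 3), (1, 3)),
                        pools=((1, 2), (1, 2), (1, 2)))
        with pytest.raises(ValueError, match="stage"):
            CNNParams.init(4, cfg, np.random.default_rng(0))


class TestCNNLoss:
    def test_confident_correct_is_near_zero(self):
        batch = [PairPrediction("r", "d", 1 - 1e-12, 1)]
        assert cnn_loss(batch) == pytest.approx(0.0, abs=1e-9)

    def test_half_is_ln2_both_classes(self):
        assert cnn_loss([PairPrediction("r", "d", 0.5, 1)]) == pytest.approx(np.log(2))
        assert cnn_loss([PairPrediction("r", "d", 0.5, 0)]) == pytest.approx(np.log(2))

    def test_missing_label_raises(self):
        with pytest.raises(ValueError, match="no label"):
            cnn_loss([PairPrediction("r", "d", 0.5, None)])


class TestTrainPredict:
    def make_separable(self, rng, n=10):
        emb = np.zeros((5, 6))
        emb[:3] = rng.standard_normal((3, 6))
        emb[3] = emb[0] + 0.1  # d1 close to r1
        emb[4] = -emb[0]
        e = NodeEmbeddings(emb, 3, 2)
        pairs = [("r1", "d1"), ("r1", "d2")] * n
        labels = [1, 0] * n
        return e, pairs, labels

    def test_training_reduces_loss(self):
        rng = np.random.default_rng(3)
        emb, pairs, labels = self.make_separable(rng)
        cfg = tiny_cnn_config(epochs=40)
        _, trace = train_classifier(emb, pairs, labels, DRUGS, DISEASES, cfg, seed=0)
        assert trace[-1] < trace[0]

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(3)
        emb, pairs, labels = self.make_separable(rng)
        cfg = tiny_cnn_config(epochs=5)
        _, t1 = train_classifier(emb, pairs, labels, DRUGS, DISEASES, cfg, seed=4)
        _, t2 = train_classifier(emb, pairs, labels, DRUGS, DISEASES, cfg, seed=4)
        assert t1 == t2

    def test_all_positive_labels_drift_up(self):
        rng = np.random.default_rng(6)
        emb = NodeEmbeddings(rng.standard_normal((5, 6)), 3, 2)
        pairs = [(r, d) for r in DRUGS for d in DISEASES]
        cfg = tiny_cnn_config(epochs=1)
        params0, _ = train_classifier(emb, pairs, [1] * len(pairs), DRUGS, DISEASES, cfg, seed=0)
        p0 = np.mean([p.probability for p in predict_pairs(emb, params0, pairs, DRUGS, DISEASES)])
        cfg = tiny_cnn_config(epochs=30)
        params1, _ = train_classifier(emb, pairs, [1] * len(pairs), DRUGS, DISEASES, cfg, seed=0)
        p1 = np.mean([p.probability for p in predict_pairs(emb, params1, pairs, DRUGS, DISEASES)])
        assert p1 > p0

    def test_empty_training_set_raises(self):
        emb = NodeEmbeddings(np.zeros((5, 4)), 3, 2)
        with pytest.raises(ValueError, match="empty"):
            train_classifier(emb, [], [], DRUGS, DISEASES, tiny_cnn_config(), seed=0)

    def test_predictions_preserve_order_and_range(self, small_emb):
        cfg = tiny_cnn_config()
        params = CNNParams.init(4, cfg, np.random.default_rng(0))
        pairs = [("r1", "d1"), ("r2", "d2"), ("r1", "d1")]
        preds = predict_pairs(small_emb, params, pairs, DRUGS, DISEASES)
        assert [(p.drug_id, p.disease_id) for p in preds] == pairs
        assert preds[0].probability == preds[2].probability
        assert all(0 < p.probability < 1 for p in preds)

    def test_gradients_match_finite_differences(self):
        from drugrelink.pair_cnn import _backward_batch, _forward_batch

        rng = np.random.default_rng(12)
        cfg = tiny_cnn_config(n_conv=1)
        params = CNNParams.init(4, cfg, rng)
        # move biases off zero: with zero biases the padded input's zero
        # regions put pre-activations exactly on the ReLU kink, where the
        # derivative is undefined and finite differences disagree
        for _, b in params.conv + params.fc + [params.out]:
            b += rng.uniform(0.01, 0.05, size=b.shape)
        x = rng.standard_normal((2, 1, 4, 6))
        y = np.array([1, 0])

        def loss():
            probs, _ = _forward_batch(x, params, False, None)
            return -np.log(probs[np.arange(2), y]).mean()

        probs, cache = _forward_batch(x, params, False, None)
        grads = _backward_batch(cache, y, params)
        flat = params.flat()
        h = 1e-6
        for w, g in zip(flat, grads):
            num = np.zeros_like(g)
            for idx in np.ndindex(w.shape):
                orig = w[idx]
                w[idx] = orig + h
                up = loss()
                w[idx] = orig - h
                down = loss()
                w[idx] = orig
                num[idx] = (up - down) / (2 * h)
            denom = max(np.abs(num).max(), np.abs(g).max(), 1e-10)
            assert np.abs(num - g).max() / denom < 1e-4
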