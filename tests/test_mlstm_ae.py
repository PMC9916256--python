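"""MLSTM-AE: loss oracles, recurrence correctness, gradients, training."""

import numpy as np
import pytest

from ssoddi import mlstm_ae as m


def naive_reconstruction_loss(x, x_hat):
    """Triple-loop oracle: sum over time and feature, mean over samples."""
    N, T, d = x.shape
    total = 0.0
    for i in range(N):
        for t in range(T):
            for k in range(d):
                total += (x[i, t, k] - x_hat[i, t, k]) ** 2
    return total / N


def naive_classification_loss(p, y):
    """Double-loop oracle with explicit L1 normalization, zero rows skipped."""
    total, n_valid = 0.0, 0
    for i in range(len(y)):
        norm = y[i].sum()
        if norm == 0:
            continue
        n_valid += 1
        for c in range(y.shape[1]):
            total += (p[i, c] - y[i, c] / norm) ** 2
    return total / max(n_valid, 1)


def naive_lstm_forward(x, Wx, Wh, b):
    """Per-sample, per-step recurrence oracle (no vectorization)."""
    def sigmoid(v):
        return 1.0 / (1.0 + np.exp(-v))

    N, T, _ = x.shape
    H = Wh.shape[1]
    hs = np.zeros((N, T, H))
    for n in range(N):
        h = np.zeros(H)
        c = np.zeros(H)
        for t in range(T):
            a = Wx @ x[n, t] + Wh @ h + b
            i, f, g, o = a[:H], a[H:2 * H], a[2 * H:3 * H], a[3 * H:]
            c = sigmoid(f) * c + sigmoid(i) * np.tanh(g)
            h = sigmoid(o) * np.tanh(c)
            hs[n, t] = h
    return hs


def small_params(rng, d=3, H=4, C=2, gamma=1.0):
    return m.ModelParams.init(d, H, C, rng, gamma=gamma)


class TestLossOracles:
    @pytest.mark.parametrize("seed", range(20))
    def test_reconstruction_matches_naive_loops(self, seed):
        rng = np.random.default_rng(seed)
        N, T, d = rng.integers(1, 6, size=3)
        x = rng.standard_normal((N, T, d))
        x_hat = rng.standard_normal((N, T, d))
        assert m.reconstruction_loss(x, x_hat) == pytest.approx(
            naive_reconstruction_loss(x, x_hat), abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_classification_matches_naive_loops(self, seed):
        rng = np.random.default_rng(100 + seed)
        N, C = rng.integers(1, 6, size=2)
        p = rng.uniform(size=(N, C))
        y = rng.integers(0, 2, size=(N, C)).astype(float)
        if (y.sum(axis=1) == 0).any():
            with pytest.warns(UserWarning):
                got = m.classification_loss(p, y)
        else:
            got = m.classification_loss(p, y)
        assert got == pytest.approx(naive_classification_loss(p, y), abs=1e-10)

    def test_reconstruction_worked_examples(self):
        assert m.reconstruction_loss(np.zeros((1, 2, 1)), np.zeros((1, 2, 1))) == 0.0
        x = np.zeros((1, 2, 1))
        x_hat = np.ones((1, 2, 1))
        assert m.reconstruction_loss(x, x_hat) == pytest.approx(2.0)
        # two samples with per-sample sums 2 and 4 -> mean 3
        x2 = np.zeros((2, 2, 1))
        xh2 = np.stack([np.ones((2, 1)), np.sqrt(2.0) * np.ones((2, 1))])
        assert m.reconstruction_loss(x2, xh2) == pytest.approx(3.0)

    def test_classification_worked_examples(self):
        p_hat, valid = m.label_probabilities(np.array([[1.0, 1.0, 0.0]]))
        np.testing.assert_allclose(p_hat, [[0.5, 0.5, 0.0]])
        assert valid.all()
        assert m.classification_loss(np.array([[0.5, 0.5, 0.0]]),
                                     np.array([[1.0, 1.0, 0.0]])) == 0.0
        assert m.classification_loss(np.array([[1.0, 0.0]]),
                                     np.array([[1.0, 1.0]])) == pytest.approx(0.5)

    def test_total_loss_linearity_in_gamma(self):
        for gamma in (0.0, 0.5, 2.0):
            assert m.total_loss(0.2, 0.3, gamma) == pytest.approx(0.2 + gamma * 0.3)
        assert m.total_loss(0.0, 0.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            m.total_loss(0.1, 0.1, -1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.reconstruction_loss(np.zeros((1, 2, 1)), np.zeros((1, 3, 1)))
        with pytest.raises(ValueError):
            m.classification_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestEncoderDecoder:
    def test_encoder_matches_naive_recurrence(self):
        rng = np.random.default_rng(0)
        params = small_params(rng)
        x = rng.standard_normal((3, 5, 3))
        batch = m.SequenceBatch(x, np.ones((3, 2)))
        hs, h_T = m.encode(batch, params)
        oracle = naive_lstm_forward(x, params.enc_Wx, params.enc_Wh, params.enc_b)
        np.testing.assert_allclose(hs, oracle, atol=1e-12)
        np.testing.assert_allclose(h_T, oracle[:, -1, :], atol=1e-12)

    def test_zero_input_zero_params_gives_zero_states(self):
        rng = np.random.default_rng(0)
        params = small_params(rng)
        for f in params.weight_fields():
            getattr(params, f)[...] = 0.0
        hs, h_T = m.encode(m.SequenceBatch(np.zeros((2, 4, 3)), np.ones((2, 2))), params)
        np.testing.assert_array_equal(hs, np.zeros_like(hs))

    def test_final_state_is_last_step_and_single_step_degenerate(self):
        rng = np.random.default_rng(1)
        params = small_params(rng)
        x = rng.standard_normal((2, 1, 3))
        hs, h_T = m.encode(m.SequenceBatch(x, np.ones((2, 2))), params)
        np.testing.assert_array_equal(h_T, hs[:, 0, :])

    def test_encode_is_deterministic(self):
        rng = np.random.default_rng(2)
        params = small_params(rng)
        x = rng.standard_normal((2, 3, 3))
        b = m.SequenceBatch(x, np.ones((2, 2)))
        np.testing.assert_array_equal(m.encode(b, params)[0], m.encode(b, params)[0])

    def test_flip_time_target(self):
        x = np.arange(6, dtype=float).reshape(1, 3, 2)
        flipped = m.flip_time(x)
        np.testing.assert_array_equal(flipped[0, 0], x[0, 2])
        np.testing.assert_array_equal(flipped[0, 2], x[0, 0])
        # length-1 flip is the identity
        x1 = np.arange(2, dtype=float).reshape(1, 1, 2)
        np.testing.assert_array_equal(m.flip_time(x1), x1)

    def test_decoder_output_shape_and_validation(self):
        rng = np.random.default_rng(3)
        params = small_params(rng)
        h = rng.standard_normal((4, params.hidden))
        assert m.decode_reconstruct(h, params, T=6).shape == (4, 6, 3)
        with pytest.raises(ValueError):
            m.decode_reconstruct(h, params, T=0)

    def test_classify_zero_weights_uniform_sigmoid(self):
        rng = np.random.default_rng(4)
        params = small_params(rng, C=4)
        params.cls_W[...] = 0.0
        params.cls_b[...] = 0.0
        p = m.classify(rng.standard_normal((3, params.hidden)), params)
        # per-label sigmoid head: zero logits score 0.5 for every label
        np.testing.assert_allclose(p, 0.5)

    def test_classify_scores_bounded(self):
        rng = np.random.default_rng(5)
        params = small_params(rng)
        p = m.classify(10.0 * rng.standard_normal((8, params.hidden)), params)
        assert p.shape == (8, 2)
        assert ((p >= 0) & (p <= 1)).all()


class TestGradients:
    def test_analytic_gradients_match_numerical(self):
        rng = np.random.default_rng(0)
        N, T, d, H, C = 3, 4, 2, 3, 2
        params = m.ModelParams.init(d, H, C, rng, gamma=0.7)
        x = rng.standard_normal((N, T, d))
        y = rng.integers(0, 2, size=(N, C)).astype(float)
        y[0] = [1, 0]
        _, _, _, grads = m._forward_backward(params, x, y, 0.0, rng)
        eps = 1e-6
        for fld in params.weight_fields():
            W = getattr(params, fld)
            flat = W.reshape(-1)
            for ix in range(0, flat.size, max(1, flat.size // 5)):
                old = flat[ix]
                flat[ix] = old + eps
                lp = m._forward_backward(params, x, y, 0.0, rng)[0]
                flat[ix] = old - eps
                lm = m._forward_backward(params, x, y, 0.0, rng)[0]
                flat[ix] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[fld].reshape(-1)[ix]
                assert ana == pytest.approx(num, abs=1e-6, rel=1e-4), fld


class TestTraining:
    def _tiny_batch(self, seed=7, n=60):
        rng = np.random.default_rng(seed)
        # two separable sequence classes
        y = np.zeros((n, 2))
        y[: n // 2, 0] = 1
        y[n // 2:, 1] = 1
        x = rng.normal(0, 0.2, size=(n, 4, 3))
        x[: n // 2] += 1.0
        return m.SequenceBatch(x, y)

    def test_loss_decreases_on_separable_fixture(self):
        batch = self._tiny_batch()
        _, hist = m.train(batch, {"epochs": 15, "hidden": 8}, seed=7)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_zero_epochs_returns_initialization(self):
        batch = self._tiny_batch()
        params, hist = m.train(batch, {"epochs": 0, "hidden": 8}, seed=7)
        assert hist == []
        assert params.hidden == 8

    def test_same_seed_bitwise_identical_history(self):
        batch = self._tiny_batch()
        _, h1 = m.train(batch, {"epochs": 5, "hidden": 8}, seed=3)
        _, h2 = m.train(batch, {"epochs": 5, "hidden": 8}, seed=3)
        assert h1 == h2

    def test_history_length_equals_epochs(self):
        batch = self._tiny_batch()
        _, hist = m.train(batch, {"epochs": 7, "hidden": 6}, seed=0)
        assert len(hist) == 7

    def test_predict_scores_bounds_and_row_permutation(self):
        batch = self._tiny_batch()
        params, _ = m.train(batch, {"epochs": 5, "hidden": 8}, seed=1)
        scores = m.predict_scores(params, batch.x)
        assert ((scores >= 0) & (scores <= 1)).all()
        perm = np.random.default_rng(0).permutation(batch.n)
        np.testing.assert_allclose(
            m.predict_scores(params, batch.x[perm]), scores[perm], atol=1e-12
        )

    def test_checkpoint_round_trip(self, tmp_path):
        batch = self._tiny_batch()
        params, hist = m.train(batch, {"epochs": 3, "hidden": 6}, seed=2)
        m.save_checkpoint(params, tmp_path / "model.npz", meta={"seed": 2})
        back = m.load_checkpoint(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.cls_W, params.cls_W)
        np.testing.assert_allclose(
            m.predict_scores(back, batch.x), m.predict_scores(params, batch.x)
        )

    def test_label_validation(self):
        with pytest.raises(ValueError):
            m.SequenceBatch(np.zeros((2, 3, 1)), np.array([[0.5], [1.0]]))
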