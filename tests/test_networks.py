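"""Network math: initialization, recurrences, losses, and gradient oracles."""

import numpy as np
import pytest

from semlearn.networks import (
    ContextWindow,
    InitSpec,
    LSTMWeights,
    SRNWeights,
    backprop_window,
    init_weights,
    lstm_step,
    make_windows,
    output_distribution,
    sgns_loss_and_grads,
    skipgram_pairs,
    skipgram_update,
    softmax,
    srn_step,
    window_loss,
)

from .conftest import assert_grads_close, finite_difference_grads


def _random_srn(v=10, h=4, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    return SRNWeights(
        w_in=rng.normal(0, scale, (v, h)),
        w_rec=rng.normal(0, scale, (h, h)),
        w_out=rng.normal(0, scale, (h, v)),
        b_out=rng.normal(0, scale, v),
    )


def _random_lstm(v=10, h=4, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    return LSTMWeights(
        w_x=rng.normal(0, scale, (v, 4 * h)),
        w_h=rng.normal(0, scale, (h, 4 * h)),
        b=rng.normal(0, scale, 4 * h),
        w_out=rng.normal(0, scale, (h, v)),
        b_out=rng.normal(0, scale, v),
    )


class TestInit:
    # a normal truncated at ±2σ has sd 0.8796σ (σ the nominal 1/m scale)
    TRUNC_SD = 0.87962

    def test_hidden_to_output_sd_is_one_over_output_units(self):
        w = init_weights(InitSpec(seed=0), "srn", 4096, 512)
        assert w.w_out.std() == pytest.approx(self.TRUNC_SD / 4096, rel=0.02)
        assert w.w_in.std() == pytest.approx(self.TRUNC_SD / 512, rel=0.02)

    def test_truncation_at_two_sd(self):
        w = init_weights(InitSpec(seed=1), "srn", 64, 16)
        assert np.abs(w.w_in).max() <= 2 / 16 + 1e-12
        assert np.abs(w.w_out).max() <= 2 / 64 + 1e-12

    def test_output_bias_is_zero(self):
        for arch in ("srn", "lstm"):
            w = init_weights(InitSpec(seed=0), arch, 32, 8)
            assert np.all(w.b_out == 0.0)

    def test_same_seed_same_weights(self):
        a = init_weights(InitSpec(seed=9), "lstm", 32, 8)
        b = init_weights(InitSpec(seed=9), "lstm", 32, 8)
        for k in a.params():
            assert np.array_equal(a.params()[k], b.params()[k])


class TestSRNStep:
    def test_zero_weights_give_zero_hidden(self):
        w = SRNWeights(np.zeros((4, 3)), np.zeros((3, 3)),
                       np.zeros((3, 4)), np.zeros(4))
        assert np.array_equal(srn_step(w, 1, np.zeros(3)), np.zeros(3))

    def test_hand_computed_recurrence(self):
        # V=2, H=1: h = tanh(w_in + w_rec * h_prev) = tanh(1 + 0.5*0.2)
        w = SRNWeights(np.array([[1.0], [0.0]]), np.array([[0.5]]),
                       np.zeros((1, 2)), np.zeros(2))
        h = srn_step(w, 0, np.array([0.2]))
        assert h[0] == pytest.approx(np.tanh(1.1))

    def test_activation_strictly_bounded(self):
        w = _random_srn(scale=1.0)
        h = np.zeros(4)
        for tok in [0, 3, 7, 2]:
            h = srn_step(w, tok, h)
            assert np.abs(h).max() < 1.0

    def test_out_of_range_token_rejected(self):
        w = _random_srn(v=10)
        with pytest.raises(ValueError):
            srn_step(w, 10, np.zeros(4))


class TestLSTMStep:
    def test_forget_zero_flushes_memory_cell(self):
        w = _random_lstm()
        c1, _ = lstm_step(w, 2, (np.ones(4), np.zeros(4)),
                          forced_gates={"forget": 0.0})
        c2, _ = lstm_step(w, 2, (-np.ones(4) * 7, np.zeros(4)),
                          forced_gates={"forget": 0.0})
        assert np.allclose(c1, c2)  # new cell independent of previous cell

    def test_input_zero_gives_pure_decay(self):
        w = _random_lstm()
        c_prev = np.array([1.0, -2.0, 0.5, 3.0])
        c, _ = lstm_step(w, 1, (c_prev, np.zeros(4)),
                         forced_gates={"input": 0.0})
        # cell = forget ⊙ cell_prev exactly
        h = w.hidden_size
        z = w.w_x[1] + w.b
        f = 1 / (1 + np.exp(-z[h:2 * h]))
        assert np.allclose(c, f * c_prev)

    def test_zero_weights_closed_form(self):
        w = LSTMWeights(np.zeros((4, 16)), np.zeros((4, 16)), np.zeros(16),
                        np.zeros((4, 4)), np.zeros(4))
        c_prev = np.array([1.0, 2.0, -1.0, 0.0])
        c, h = lstm_step(w, 0, (c_prev, np.zeros(4)))
        # gates all 0.5, candidate tanh(0)=0: c = 0.5*c_prev, h = 0.5*tanh(c)
        assert np.allclose(c, 0.5 * c_prev)
        assert np.allclose(h, 0.5 * np.tanh(0.5 * c_prev))

    def test_all_gates_open_accumulates_unboundedly(self):
        # limiting case: forget=input=output=1 degrades the unit to an
        # unbounded accumulator of the candidate signal
        w = LSTMWeights(np.zeros((4, 8)), np.zeros((2, 8)), np.zeros(8),
                        np.zeros((2, 4)), np.zeros(4))
        w.b[6:] = 1.0  # candidate pre-activation -> tanh(1) each step
        state = (np.zeros(2), np.zeros(2))
        forced = {"input": 1.0, "forget": 1.0, "output": 1.0}
        for _ in range(50):
            c, _ = lstm_step(w, 0, state, forced_gates=forced)
            state = (c, np.zeros(2))
        assert np.allclose(state[0], 50 * np.tanh(1.0))


class TestOutputDistribution:
    def test_zero_logits_uniform(self):
        w = _random_srn(v=8)
        w.w_out[:] = 0.0
        w.b_out[:] = 0.0
        p = output_distribution(w, np.ones(4))
        assert np.allclose(p, 1 / 8)

    def test_closed_form_two_way(self):
        assert np.allclose(softmax(np.array([0.0, np.log(3.0)])), [0.25, 0.75])

    def test_shift_invariance_and_normalization(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(0, 10, 100)
        p = softmax(logits)
        assert np.allclose(p, softmax(logits + 123.4))
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0)


class TestWindowLoss:
    def test_near_certain_prediction_near_zero_loss(self):
        w = _random_srn()
        w.w_out[:] = 0.0
        w.b_out[:] = -100.0
        w.b_out[3] = 100.0
        loss, _ = window_loss(w, ContextWindow([1, 2], target=3))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_uniform_model_loss_is_log_vocab(self):
        w = SRNWeights(np.zeros((4096, 4)), np.zeros((4, 4)),
                       np.zeros((4, 4096)), np.zeros(4096))
        loss, _ = window_loss(w, ContextWindow([5, 9, 2], target=77))
        assert loss == pytest.approx(np.log(4096))

    def test_fifty_fifty_loss_is_log_two(self):
        w = SRNWeights(np.zeros((2, 2)), np.zeros((2, 2)),
                       np.zeros((2, 2)), np.zeros(2))
        loss, _ = window_loss(w, ContextWindow([0], target=1))
        assert loss == pytest.approx(np.log(2.0))


class TestGradientOracles:
    """Backpropagation checked against central finite differences."""

    def test_srn_bptt_matches_finite_differences(self):
        w = _random_srn(v=10, h=4, seed=3)
        window = ContextWindow([4, 1, 9, 0, 2, 7, 5], target=8)
        analytic = backprop_window(w, window)
        numeric = finite_difference_grads(w, window)
        assert_grads_close(analytic, numeric, rtol=1e-4)

    def test_lstm_bptt_matches_finite_differences(self):
        w = _random_lstm(v=10, h=4, seed=4)
        window = ContextWindow([3, 8, 1, 6, 0, 9, 2], target=5)
        analytic = backprop_window(w, window)
        numeric = finite_difference_grads(w, window)
        assert_grads_close(analytic, numeric, rtol=1e-4)

    def test_zero_loss_input_gives_zero_gradients(self):
        w = _random_srn()
        w.w_out[:] = 0.0
        w.b_out[:] = -300.0
        w.b_out[3] = 300.0
        grads = backprop_window(w, ContextWindow([1, 2], target=3))
        for name in ("w_in", "w_rec", "w_out"):
            assert np.abs(grads[name]).max() < 1e-12

    def test_absent_word_embedding_row_has_zero_gradient(self):
        w = _random_srn(v=10)
        window = ContextWindow([1, 2, 3], target=4)
        grads = backprop_window(w, window)
        for absent in (0, 5, 9):
            assert np.all(grads["w_in"][absent] == 0.0)

    def test_skipgram_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        w = init_weights(InitSpec(seed=5), "skipgram", 8, 3)
        w.w_in[:] = rng.normal(0, 0.5, w.w_in.shape)
        w.w_out[:] = rng.normal(0, 0.5, w.w_out.shape)
        center, context, negatives = 2, 5, [1, 6, 7]
        _, grad_in, grad_out = sgns_loss_and_grads(w, center, context, negatives)

        def loss_of():
            return sgns_loss_and_grads(w, center, context, negatives)[0]

        eps = 1e-6
        for table, sparse in (("w_in", grad_in), ("w_out", grad_out)):
            arr = getattr(w, table)
            for row, g in sparse.items():
                for j in range(arr.shape[1]):
                    orig = arr[row, j]
                    arr[row, j] = orig + eps
                    lp = loss_of()
                    arr[row, j] = orig - eps
                    lm = loss_of()
                    arr[row, j] = orig
                    num = (lp - lm) / (2 * eps)
                    assert num == pytest.approx(g[j], rel=1e-4, abs=1e-8)


class TestSkipGramPairs:
    def test_window_one_enumeration(self):
        assert list(skipgram_pairs([0, 1, 2], 1)) == [
            (0, 1), (1, 0), (1, 2), (2, 1)
        ]

    def test_single_token_yields_nothing(self):
        assert list(skipgram_pairs([7], 3)) == []

    def test_pair_count_with_truncation(self):
        assert len(list(skipgram_pairs([0, 1, 2, 3], 3))) == 12

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        w = init_weights(InitSpec(seed=0), "skipgram", 8, 3)
        before = {k: v.copy() for k, v in w.params().items()}
        noise = np.full(8, 1 / 8)
        skipgram_update(w, (1, 2), 3, noise, learning_rate=0.0,
                        rng=np.random.default_rng(0))
        for k, v in w.params().items():
            assert np.array_equal(v, before[k])

    def test_negatives_exclude_true_context(self):
        from semlearn.networks import sample_negatives
        rng = np.random.default_rng(1)
        noise = np.array([0.5, 0.5])
        contexts = np.zeros(100, dtype=int)
        negs = sample_negatives(rng, noise, contexts, k=4)
        assert np.all(negs == 1)


class TestWindows:
    def test_stream_initial_windows_are_boundary_padded(self):
        windows, targets = make_windows(np.array([5, 6, 7]), pad_id=0)
        assert windows.shape == (3, 7)
        assert np.array_equal(targets, [5, 6, 7])
        assert np.array_equal(windows[0], [0] * 7)
        assert np.array_equal(windows[2], [0, 0, 0, 0, 0, 5, 6])

    def test_window_rejects_bad_length(self):
        with pytest.raises(ValueError):
            ContextWindow(np.arange(8), target=0)
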