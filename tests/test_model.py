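"""CNN-GRU primitives against brute-force oracles, plus training behaviour."""

import numpy as np
import pytest

import topogru as tg
from topogru.model import (CnnConfig, CnnGruModel, GruWeights, ModelConfig,
                           TrainConfig, cross_entropy)


# --- independent nested-loop oracles ---------------------------------------

def conv_oracle(x, kernels, bias):
    """4-nested-loop cross-correlation, the slow reference."""
    f, kh, kw, c = kernels.shape
    hh = x.shape[0] - kh + 1
    ww = x.shape[1] - kw + 1
    out = np.zeros((hh, ww, f))
    for o in range(f):
        for i in range(hh):
            for j in range(ww):
                acc = 0.0
                for a in range(kh):
                    for b in range(kw):
                        for ch in range(c):
                            acc += x[i + a, j + b, ch] * kernels[o, a, b, ch]
                out[i, j, o] = acc + bias[o]
    return out


def gru_oracle_step(x, h, w: GruWeights):
    """Scalar-loop evaluation of the gate equations."""
    d, hid = w.W.shape
    r = np.zeros(hid); z = np.zeros(hid); hc = np.zeros(hid)
    for j in range(hid):
        ar = w.b_r[j] + sum(x[i] * w.W_r[i, j] for i in range(d)) \
            + sum(h[k] * w.U_r[k, j] for k in range(hid))
        az = w.b_z[j] + sum(x[i] * w.W_z[i, j] for i in range(d)) \
            + sum(h[k] * w.U_z[k, j] for k in range(hid))
        r[j] = 1 / (1 + np.exp(-ar))
        z[j] = 1 / (1 + np.exp(-az))
    for j in range(hid):
        ah = w.b[j] + sum(x[i] * w.W[i, j] for i in range(d)) \
            + sum(r[k] * h[k] * w.U[k, j] for k in range(hid))
        hc[j] = np.tanh(ah)
    return (1 - z) * h + z * hc


def random_gru_weights(rng, d, hid):
    return GruWeights(*(rng.normal(size=s) for s in
                        [(d, hid), (d, hid), (d, hid),
                         (hid, hid), (hid, hid), (hid, hid),
                         (hid,), (hid,), (hid,)]))


class TestConv:
    def test_delta_kernel_recovers_the_centre_crop(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 6, 1))
        k = np.zeros((1, 3, 3, 1)); k[0, 1, 1, 0] = 1.0
        out = tg.conv2d_forward(x, k)
        assert np.allclose(out[:, :, 0], x[1:5, 1:5, 0])

    def test_all_ones_kernel_sums_the_window(self):
        x = np.ones((28, 28, 3))
        k = np.ones((1, 3, 3, 3))
        out = tg.conv2d_forward(x, k)
        assert out.shape == (26, 26, 1)
        assert np.allclose(out, 27.0)

    def test_matches_the_nested_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=(5, 5, 2))
            k = rng.normal(size=(3, 3, 3, 2))
            b = rng.normal(size=3)
            assert np.allclose(tg.conv2d_forward(x, k, b),
                               conv_oracle(x, k, b), atol=1e-12)

    def test_oversized_kernel_is_an_error(self):
        with pytest.raises(ValueError, match="larger"):
            tg.conv2d_forward(np.zeros((2, 2, 1)), np.zeros((1, 3, 3, 1)))

    def test_depth_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="depth"):
            tg.conv2d_forward(np.zeros((5, 5, 2)), np.zeros((1, 3, 3, 3)))


class TestActivationsAndPooling:
    def test_leaky_relu_values(self):
        assert tg.leaky_relu(-1.0, 0.01) == -0.01
        assert tg.leaky_relu(2.5, 0.01) == 2.5

    def test_pooling_a_constant_grid_is_constant(self):
        assert np.allclose(tg.max_pool(np.full((9, 9), 4.2), 3), 4.2)

    def test_pooling_26_by_3_stride_3_gives_8(self):
        out = tg.max_pool(np.zeros((26, 26, 32)), 3, 3)
        assert out.shape == (8, 8, 32)

    def test_incomplete_trailing_windows_are_dropped(self):
        x = np.arange(25, dtype=float).reshape(5, 5)
        out = tg.max_pool(x, 2, 2)
        assert out.shape == (2, 2)
        assert out[1, 1] == x[2:4, 2:4].max()


class TestGru:
    def test_zero_weights_halve_the_hidden_state(self):
        rng = np.random.default_rng(0)
        w = GruWeights(*(np.zeros(s) for s in
                         [(3, 2), (3, 2), (3, 2), (2, 2), (2, 2), (2, 2),
                          (2,), (2,), (2,)]))
        h = rng.normal(size=2)
        out = tg.gru_cell_step(np.zeros(3), h, w)
        assert np.allclose(out, 0.5 * h)

    def test_saturated_update_gate_returns_the_candidate(self):
        rng = np.random.default_rng(1)
        w = random_gru_weights(rng, 3, 2)
        w.b_z[:] = 50.0  # z_t → 1
        x = rng.normal(size=3); h = rng.normal(size=2)
        out = tg.gru_cell_step(x, h, w)
        r = 1 / (1 + np.exp(-(x @ w.W_r + h @ w.U_r + w.b_r)))
        cand = np.tanh(x @ w.W + (r * h) @ w.U + w.b)
        assert np.allclose(out, cand, atol=1e-9)

    def test_cell_matches_the_scalar_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            w = random_gru_weights(rng, 3, 2)
            x = rng.normal(size=3); h = rng.normal(size=2)
            assert np.allclose(tg.gru_cell_step(x, h, w),
                               gru_oracle_step(x, h, w), atol=1e-12)

    def test_forward_is_a_left_fold(self):
        rng = np.random.default_rng(3)
        w = random_gru_weights(rng, 3, 2)
        xs = rng.normal(size=(4, 3))
        h = np.zeros(2)
        for x in xs:
            h = gru_oracle_step(x, h, w)
        assert np.allclose(tg.gru_forward(xs, w), h, atol=1e-12)

    def test_length_one_sequence_is_a_single_step(self):
        rng = np.random.default_rng(4)
        w = random_gru_weights(rng, 3, 2)
        x = rng.normal(size=(1, 3))
        assert np.allclose(tg.gru_forward(x, w),
                           tg.gru_cell_step(x[0], np.zeros(2), w))

    def test_zero_weights_and_zero_h0_stay_at_zero(self):
        w = GruWeights(*(np.zeros(s) for s in
                         [(3, 2)] * 3 + [(2, 2)] * 3 + [(2,)] * 3))
        xs = np.random.default_rng(5).normal(size=(6, 3))
        assert np.allclose(tg.gru_forward(xs, w), 0.0)

    def test_shape_mismatch_is_an_error(self):
        w = random_gru_weights(np.random.default_rng(6), 3, 2)
        with pytest.raises(ValueError, match="dimensions"):
            tg.gru_cell_step(np.zeros(4), np.zeros(2), w)


TINY = ModelConfig(cnn=CnnConfig(input_shape=(8, 8, 2), conv_filters=(3,),
                                 pool_size=2, pool_stride=2),
                   hidden_size=4, dropout_rate=0.0)


class TestFullModel:
    def test_softmax_of_equal_logits_is_uniform(self):
        assert np.allclose(tg.softmax(np.zeros(2)), [0.5, 0.5])

    def test_probabilities_are_a_distribution(self):
        m = CnnGruModel(TINY, seed=0)
        x = np.random.default_rng(0).normal(size=(3, 8, 8, 2))
        p = m.forward(x)
        assert p.shape == (2,)
        assert np.all((p > 0) & (p < 1))
        assert abs(p.sum() - 1) < 1e-9

    def test_forward_is_a_pure_function(self):
        m = CnnGruModel(TINY, seed=1)
        x = np.random.default_rng(1).normal(size=(3, 8, 8, 2))
        assert np.array_equal(m.forward(x), m.forward(x))

    def test_frame_order_changes_the_output(self):
        m = CnnGruModel(TINY, seed=2)
        x = np.random.default_rng(2).normal(size=(3, 8, 8, 2))
        swapped = x[[2, 1, 0]]
        assert not np.allclose(m.forward(x), m.forward(swapped))

    def test_parameter_counts(self):
        # canonical 1-layer configuration: 3·3·3·32 + 32
        assert tg.count_parameters(CnnConfig(), "conv_layer") == 896
        assert tg.count_parameters(
            CnnConfig(kernel_size=1, conv_filters=(1,),
                      input_shape=(28, 28, 1)), "conv_layer") == 2
        assert tg.count_parameters(
            CnnConfig(kernel_size=5, conv_filters=(8,)), "conv_layer") == 608

    def test_total_count_equals_the_sum_of_tensor_sizes(self):
        m = CnnGruModel(ModelConfig(), seed=0)
        total = tg.count_parameters(m)
        assert total == sum(v.size for v in m.params.values())
        # closed form: conv + 3 GRU input/hidden/bias groups + dense
        d, h = 2048, 64
        expected = 896 + 3 * (d * h + h * h + h) + (h * 2 + 2)
        assert total == expected

    def test_describe_lists_six_layers(self):
        text = tg.describe(ModelConfig())
        for word in ("conv1", "max-pool", "GRU", "dropout", "dense", "softmax"):
            assert word in text


class TestTraining:
    def _separable(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        X = 0.1 * rng.normal(size=(n, 3, 8, 8, 2))
        y = np.arange(n) % 2
        X[y == 1] += 1.0
        return X, y

    def test_separable_set_is_fit_to_full_accuracy(self):
        X, y = self._separable()
        m = CnnGruModel(TINY, seed=0)
        hist = m.fit(X, y, TrainConfig(epochs=200, val_fraction=0.0,
                                       patience=200, seed=0))
        assert hist["accuracy"][-1] == 1.0
        assert len(hist["loss"]) <= 200

    def test_initial_loss_is_near_log_two(self):
        X, y = self._separable()
        m = CnnGruModel(TINY, seed=3)
        loss = cross_entropy(m.predict_proba(X), y)
        assert abs(loss - np.log(2)) < 0.05

    def test_training_is_deterministic_given_the_seed(self):
        X, y = self._separable()
        runs = []
        for _ in range(2):
            m = CnnGruModel(TINY, seed=4)
            m.fit(X, y, TrainConfig(epochs=15, val_fraction=0.0,
                                    patience=99, seed=4))
            runs.append(m.params)
        assert all(np.array_equal(runs[0][k], runs[1][k]) for k in runs[0])

    def test_full_batch_descent_is_monotone(self):
        X, y = self._separable(n=12, seed=5)
        m = CnnGruModel(TINY, seed=5)
        hist = m.fit(X, y, TrainConfig(optimizer="sgd", learning_rate=1e-3,
                                       batch_size=12, epochs=30,
                                       val_fraction=0.0, patience=99, seed=5))
        losses = np.array(hist["loss"])
        assert np.all(np.diff(losses) <= 1e-9)

    def test_single_class_training_set_is_an_error(self):
        X, _ = self._separable()
        with pytest.raises(ValueError, match="single class"):
            CnnGruModel(TINY, seed=0).fit(X, np.zeros(len(X), dtype=int))

    def test_save_load_round_trip(self, tmp_path):
        X, y = self._separable()
        m = CnnGruModel(TINY, seed=6)
        m.fit(X, y, TrainConfig(epochs=5, val_fraction=0.0, patience=99,
                                seed=6))
        p = tmp_path / "model.npz"
        m.save(p)
        back = CnnGruModel.load(p)
        assert np.array_equal(back.predict(X), m.predict(X))
        assert all(np.array_equal(back.params[k], m.params[k])
                   for k in m.params)
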