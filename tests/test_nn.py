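import math

import numpy as np
import pytest

from oracles import numerical_gradient
from sevodoa import nn
from sevodoa.model import corrupt


def _named_cell_weights(rng, d, h, scale=0.1):
    w = {}
    for gate in ("c", "f", "i", "o"):
        w[f"Wx{gate}"] = scale * rng.standard_normal((d, h))
        w[f"Wh{gate}"] = scale * rng.standard_normal((h, h))
        w[f"b{gate}"] = scale * rng.standard_normal(h)
    return w


class TestLSTMCell:
    def test_all_zero_weights(self):
        d, h = 3, 2
        w = {k: np.zeros_like(v) for k, v in _named_cell_weights(np.random.default_rng(0), d, h).items()}
        c_prev = np.array([0.4, -1.2])
        h_t, c_t = nn.lstm_cell(np.zeros(d), np.zeros(h), c_prev, w)
        # all gates sigmoid(0)=0.5 and candidate tanh(0)=0
        np.testing.assert_allclose(c_t, 0.5 * c_prev, atol=1e-12)
        np.testing.assert_allclose(h_t, 0.5 * np.tanh(0.5 * c_prev), atol=1e-12)

    def test_saturated_forget_gate_is_perfect_memory(self):
        d, h = 2, 3
        w = {k: np.zeros_like(v) for k, v in _named_cell_weights(np.random.default_rng(0), d, h).items()}
        w["bf"] = np.full(h, 50.0)
        c_prev = np.array([1.0, -2.0, 0.3])
        _, c_t = nn.lstm_cell(np.zeros(d), np.zeros(h), c_prev, w)
        np.testing.assert_allclose(c_t, c_prev, atol=1e-9)

    def test_matches_hand_unrolled_equations(self):
        rng = np.random.default_rng(42)
        d, h = 3, 2
        w = _named_cell_weights(rng, d, h)
        x = rng.standard_normal(d)
        h_prev = rng.standard_normal(h)
        c_prev = rng.standard_normal(h)
        h_t, c_t = nn.lstm_cell(x, h_prev, c_prev, w)
        # independent scalar evaluation of the six gate equations
        sig = lambda z: 1.0 / (1.0 + math.exp(-z))
        for j in range(h):
            zf = sum(x[i] * w["Wxf"][i, j] for i in range(d)) + sum(
                h_prev[i] * w["Whf"][i, j] for i in range(h)) + w["bf"][j]
            zi = sum(x[i] * w["Wxi"][i, j] for i in range(d)) + sum(
                h_prev[i] * w["Whi"][i, j] for i in range(h)) + w["bi"][j]
            zo = sum(x[i] * w["Wxo"][i, j] for i in range(d)) + sum(
                h_prev[i] * w["Who"][i, j] for i in range(h)) + w["bo"][j]
            zc = sum(x[i] * w["Wxc"][i, j] for i in range(d)) + sum(
                h_prev[i] * w["Whc"][i, j] for i in range(h)) + w["bc"][j]
            c_ref = sig(zf) * c_prev[j] + sig(zi) * math.tanh(zc)
            h_ref = sig(zo) * math.tanh(c_ref)
            assert c_t[j] == pytest.approx(c_ref, abs=1e-12)
            assert h_t[j] == pytest.approx(h_ref, abs=1e-12)

    def test_gates_open_interval(self):
        rng = np.random.default_rng(1)
        w = _named_cell_weights(rng, 4, 5, scale=1.0)
        h_t, c_t = nn.lstm_cell(rng.standard_normal(4), rng.standard_normal(5),
                                rng.standard_normal(5), w)
        assert np.all(np.abs(h_t) < 1.0)  # |o_t * tanh(c_t)| < 1

    def test_packed_forward_consistent_with_cell(self):
        rng = np.random.default_rng(2)
        d, h = 3, 4
        named = _named_cell_weights(rng, d, h)
        packed = nn.pack_cell_weights(named)
        x = rng.standard_normal((1, 1, d))
        H, _ = nn.lstm_forward(x, packed["Wx"], packed["Wh"], packed["b"])
        h_ref, _ = nn.lstm_cell(x[0, 0], np.zeros(h), np.zeros(h), named)
        np.testing.assert_allclose(H[0, 0], h_ref, atol=1e-12)

    def test_shape_mismatch(self):
        w = _named_cell_weights(np.random.default_rng(0), 3, 2)
        with pytest.raises(ValueError):
            nn.lstm_cell(np.zeros(5), np.zeros(2), np.zeros(2), w)


class TestGradients:
    def _relerr(self, analytic, numeric):
        num = np.linalg.norm(analytic - numeric)
        den = np.linalg.norm(analytic) + np.linalg.norm(numeric) + 1e-12
        return num / den

    def test_autoencoder_gradients(self, rng):
        params = nn.init_autoencoder(5, 4, rng)
        Xc = rng.standard_normal((3, 5))
        Xn = corrupt(Xc, 0.3, 7)
        kw = dict(sparsity_target=0.1, sparsity_weight=0.5, weight_decay=0.01)
        _, grads = nn.ae_loss_and_grads(params, Xc, Xn, **kw)
        num = numerical_gradient(lambda p: nn.ae_loss_and_grads(p, Xc, Xn, **kw)[0], params)
        for k in params:
            assert self._relerr(grads[k], num[k]) < 1e-6, k

    def test_lstm_sequence_gradients(self, rng):
        h = 4
        lstm = nn.init_lstm(3, h, rng)
        params = {
            "lstm_Wx": lstm["Wx"], "lstm_Wh": lstm["Wh"], "lstm_b": lstm["b"],
            "out_W": rng.standard_normal((h, 1)), "out_b": np.zeros(1),
        }
        X = rng.standard_normal((3, 5, 3))  # 3-sample toy batch
        y = rng.standard_normal((3, 5))
        _, grads, _ = nn.sequence_loss_and_grads(params, X, y, weight_decay=0.01)
        num = numerical_gradient(
            lambda p: nn.sequence_loss_and_grads(p, X, y, weight_decay=0.01)[0], params
        )
        for k in params:
            assert self._relerr(grads[k], num[k]) < 1e-4, k

    def test_full_stack_gradients_through_encoders(self, rng):
        h = 3
        lstm = nn.init_lstm(2, h, rng)
        params = {
            "enc1_W": 0.3 * rng.standard_normal((5, 4)), "enc1_b": np.zeros(4),
            "enc2_W": 0.3 * rng.standard_normal((4, 2)), "enc2_b": np.zeros(2),
            "lstm_Wx": lstm["Wx"], "lstm_Wh": lstm["Wh"], "lstm_b": lstm["b"],
            "out_W": rng.standard_normal((h, 1)), "out_b": np.zeros(1),
        }
        X = rng.standard_normal((2, 4, 5))
        y = rng.standard_normal((2, 4))
        _, grads, _ = nn.sequence_loss_and_grads(params, X, y)
        num = numerical_gradient(lambda p: nn.sequence_loss_and_grads(p, X, y)[0], params)
        for k in params:
            assert self._relerr(grads[k], num[k]) < 1e-4, k


class TestCorruption:
    def test_p_zero_identity(self, rng):
        x = rng.standard_normal((10, 10))
        np.testing.assert_array_equal(corrupt(x, 0.0, 1), x)

    def test_zeroed_fraction(self):
        x = np.ones((1000, 100))
        frac = np.mean(corrupt(x, 0.5, 123) == 0)
        se = np.sqrt(0.25 / x.size)
        assert abs(frac - 0.5) < 3 * se

    def test_seed_determinism(self, rng):
        x = rng.standard_normal((50, 46))
        np.testing.assert_array_equal(corrupt(x, 0.3, 9), corrupt(x, 0.3, 9))

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            corrupt(np.ones((2, 2)), 1.0, 0)


def test_flatten_roundtrip(rng):
    params = nn.init_autoencoder(4, 3, rng)
    vec, shapes = nn.flatten_params(params)
    back = nn.unflatten_params(vec, shapes)
    for k in params:
        np.testing.assert_array_equal(back[k], params[k])
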