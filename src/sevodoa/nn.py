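"""Numerical core of the SDAE-LSTM: layers, losses and analytic gradients.

Everything is plain float64 numpy with hand-written backpropagation, which
keeps the model dependency-free and makes the analytic gradients directly
checkable against finite differences.

Conventions
-----------
* Dense/autoencoder parameters: ``W1, b1, W2, b2`` (encoder then decoder).
* LSTM parameters are packed: ``Wx (D, 4H)``, ``Wh (H, 4H)``, ``b (4H,)``
  with gate blocks ordered [input, forget, output, candidate].
* Losses are 0.5 * mean squared error over all predicted elements, plus
  optional L2 weight decay on weight matrices (never biases) and, for the
  autoencoder, a KL-divergence sparsity penalty on the mean hidden
  activation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "init_autoencoder",
    "ae_loss_and_grads",
    "init_lstm",
    "lstm_cell",
    "lstm_forward",
    "lstm_backward",
    "sequence_loss_and_grads",
    "AdamState",
    "flatten_params",
    "unflatten_params",
]

GATE_ORDER = ("input", "forget", "output", "candidate")


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-s, s, size=(n_in, n_out))


# ---------------------------------------------------------------------------
# Sparse denoising autoencoder (one hidden layer)
# ---------------------------------------------------------------------------

def init_autoencoder(n_in: int, n_hidden: int, rng: np.random.Generator) -> dict:
    return {
        "W1": _glorot(rng, n_in, n_hidden),
        "b1": np.zeros(n_hidden),
        "W2": _glorot(rng, n_hidden, n_in),
        "b2": np.zeros(n_in),
    }


def ae_loss_and_grads(
    params: dict,
    x_clean: np.ndarray,
    x_in: np.ndarray,
    sparsity_target: float = 0.05,
    sparsity_weight: float = 0.0,
    weight_decay: float = 0.0,
) -> tuple[float, dict]:
    """Denoising-autoencoder loss and analytic gradients.

    The encoder is sigmoid, the decoder linear.  ``x_in`` is the (possibly
    corrupted) input; the reconstruction target is always ``x_clean``.  The
    sparsity penalty is the KL divergence between ``sparsity_target`` and the
    batch-mean hidden activation of each unit.
    """
    W1, b1, W2, b2 = params["W1"], params["b1"], params["W2"], params["b2"]
    B = x_in.shape[0]
    H = sigmoid(x_in @ W1 + b1)
    R = H @ W2 + b2
    err = R - x_clean
    loss = 0.5 * float((err**2).sum()) / B

    dR = err / B
    grads = {
        "W2": H.T @ dR,
        "b2": dR.sum(axis=0),
    }
    dH = dR @ W2.T

    if sparsity_weight > 0:
        rho = sparsity_target
        rho_hat = np.clip(H.mean(axis=0), 1e-8, 1.0 - 1e-8)
        kl = rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))
        loss += sparsity_weight * float(kl.sum())
        dH = dH + sparsity_weight * (-rho / rho_hat + (1 - rho) / (1 - rho_hat)) / B

    dZ = dH * H * (1.0 - H)
    grads["W1"] = x_in.T @ dZ
    grads["b1"] = dZ.sum(axis=0)

    if weight_decay > 0:
        loss += 0.5 * weight_decay * float((W1**2).sum() + (W2**2).sum())
        grads["W1"] += weight_decay * W1
        grads["W2"] += weight_decay * W2
    return loss, grads


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

def init_lstm(n_in: int, n_hidden: int, rng: np.random.Generator) -> dict:
    b = np.zeros(4 * n_hidden)
    b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias: remember by default
    return {
        "Wx": _glorot(rng, n_in, 4 * n_hidden),
        "Wh": _glorot(rng, n_hidden, 4 * n_hidden),
        "b": b,
    }


def lstm_cell(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, weights: dict
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step from explicitly named gate weights.

    Implements the standard cell: sigmoid forget/input/output gates and a
    tanh candidate,

        f_t = sigma(Wxf x_t + Whf h_{t-1} + bf)
        i_t = sigma(Wxi x_t + Whi h_{t-1} + bi)
        c'_t = tanh(Wxc x_t + Whc h_{t-1} + bc)
        c_t = f_t * c_{t-1} + i_t * c'_t
        o_t = sigma(Wxo x_t + Who h_{t-1} + bo)
        h_t = o_t * tanh(c_t)

    ``weights`` holds Wxc/Whc/bc, Wxf/Whf/bf, Wxi/Whi/bi, Wxo/Who/bo with
    input-to-hidden shapes (D, H), hidden-to-hidden (H, H), biases (H,).
    """
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_1d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_1d(np.asarray(c_prev, dtype=float))
    D, Hn = weights["Wxc"].shape
    if x_t.shape[-1] != D or h_prev.shape[-1] != Hn or c_prev.shape[-1] != Hn:
        raise ValueError(
            f"shape mismatch: x {x_t.shape}, h {h_prev.shape}, c {c_prev.shape} "
            f"vs weights ({D}, {Hn})"
        )
    f_t = sigmoid(x_t @ weights["Wxf"] + h_prev @ weights["Whf"] + weights["bf"])
    i_t = sigmoid(x_t @ weights["Wxi"] + h_prev @ weights["Whi"] + weights["bi"])
    cand = np.tanh(x_t @ weights["Wxc"] + h_prev @ weights["Whc"] + weights["bc"])
    c_t = f_t * c_prev + i_t * cand
    o_t = sigmoid(x_t @ weights["Wxo"] + h_prev @ weights["Who"] + weights["bo"])
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


def pack_cell_weights(named: dict) -> dict:
    """Convert named gate weights to the packed [i, f, o, g] layout."""
    return {
        "Wx": np.concatenate([named["Wxi"], named["Wxf"], named["Wxo"], named["Wxc"]], axis=1),
        "Wh": np.concatenate([named["Whi"], named["Whf"], named["Who"], named["Whc"]], axis=1),
        "b": np.concatenate([named["bi"], named["bf"], named["bo"], named["bc"]]),
    }


def lstm_forward(
    X: np.ndarray,
    Wx: np.ndarray,
    Wh: np.ndarray,
    b: np.ndarray,
    h0: np.ndarray | None = None,
    c0: np.ndarray | None = None,
) -> tuple[np.ndarray, list]:
    """Run the LSTM over a (B, T, D) batch; returns hidden states (B, T, H)."""
    B, T, D = X.shape
    Hn = Wh.shape[0]
    h = np.zeros((B, Hn)) if h0 is None else h0
    c = np.zeros((B, Hn)) if c0 is None else c0
    H_all = np.empty((B, T, Hn))
    cache = []
    for t in range(T):
        x_t = X[:, t, :]
        Z = x_t @ Wx + h @ Wh + b
        i = sigmoid(Z[:, :Hn])
        f = sigmoid(Z[:, Hn : 2 * Hn])
        o = sigmoid(Z[:, 2 * Hn : 3 * Hn])
        g = np.tanh(Z[:, 3 * Hn :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache.append((x_t, h, c, i, f, o, g, tc))
        h, c = h_new, c_new
        H_all[:, t, :] = h
    return H_all, cache


def lstm_backward(
    dH: np.ndarray, cache: list, Wx: np.ndarray, Wh: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Backpropagation through time for :func:`lstm_forward`.

    ``dH`` is dLoss/d(hidden state) at every step, shape (B, T, H).  Returns
    the gradient w.r.t. the inputs and the packed weight gradients.
    """
    B, T, Hn = dH.shape
    D = Wx.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(Wx.shape[1])
    dX = np.empty((B, T, D))
    dh_next = np.zeros((B, Hn))
    dc_next = np.zeros((B, Hn))
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, o, g, tc = cache[t]
        dh = dH[:, t, :] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc**2) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dZ = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
                dg * (1.0 - g**2),
            ],
            axis=1,
        )
        dWx += x_t.T @ dZ
        dWh += h_prev.T @ dZ
        db += dZ.sum(axis=0)
        dX[:, t, :] = dZ @ Wx.T
        dh_next = dZ @ Wh.T
        dc_next = dc * f
    return dX, {"Wx": dWx, "Wh": dWh, "b": db}


# ---------------------------------------------------------------------------
# Full-network sequence loss (optionally through the SDAE encoders)
# ---------------------------------------------------------------------------

_WEIGHT_KEYS = ("enc1_W", "enc2_W", "lstm_Wx", "lstm_Wh", "out_W")


def sequence_loss_and_grads(
    params: dict, X: np.ndarray, y: np.ndarray, weight_decay: float = 0.0
) -> tuple[float, dict, np.ndarray]:
    """Squared-error sequence loss with analytic gradients.

    ``X`` is (B, T, D); ``y`` is (B, T).  If ``params`` contains ``enc1_W``
    the input is first passed per-step through the two sigmoid encoders
    (the fine-tuning configuration); otherwise ``X`` feeds the LSTM
    directly.  Returns (loss, gradients, predictions).
    """
    B, T = y.shape
    n = B * T
    has_enc = "enc1_W" in params

    if has_enc:
        Xf = X.reshape(n, -1)
        A1 = sigmoid(Xf @ params["enc1_W"] + params["enc1_b"])
        A2 = sigmoid(A1 @ params["enc2_W"] + params["enc2_b"])
        E = A2.reshape(B, T, -1)
    else:
        E = X

    H_all, cache = lstm_forward(E, params["lstm_Wx"], params["lstm_Wh"], params["lstm_b"])
    pred = (H_all @ params["out_W"]).squeeze(-1) + params["out_b"]
    err = pred - y
    loss = 0.5 * float((err**2).sum()) / n

    dpred = err / n
    Hn = H_all.shape[-1]
    grads = {
        "out_W": H_all.reshape(n, Hn).T @ dpred.reshape(n, 1),
        "out_b": np.array([dpred.sum()]),
    }
    dH = dpred[:, :, None] * params["out_W"][None, None, :, 0]
    dE, lstm_grads = lstm_backward(dH, cache, params["lstm_Wx"], params["lstm_Wh"])
    grads["lstm_Wx"] = lstm_grads["Wx"]
    grads["lstm_Wh"] = lstm_grads["Wh"]
    grads["lstm_b"] = lstm_grads["b"]

    if has_enc:
        dA2 = dE.reshape(n, -1)
        dZ2 = dA2 * A2 * (1.0 - A2)
        grads["enc2_W"] = A1.T @ dZ2
        grads["enc2_b"] = dZ2.sum(axis=0)
        dA1 = dZ2 @ params["enc2_W"].T
        dZ1 = dA1 * A1 * (1.0 - A1)
        grads["enc1_W"] = Xf.T @ dZ1
        grads["enc1_b"] = dZ1.sum(axis=0)

    if weight_decay > 0:
        for k in _WEIGHT_KEYS:
            if k in params:
                loss += 0.5 * weight_decay * float((params[k] ** 2).sum())
                grads[k] = grads[k] + weight_decay * params[k]
    return loss, grads, pred


# ---------------------------------------------------------------------------
# Optimiser and parameter-vector utilities
# ---------------------------------------------------------------------------

class AdamState:
    """Adam with bias correction, operating in place on a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-2, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] = params[k] - self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )


def flatten_params(params: dict) -> tuple[np.ndarray, list]:
    """Concatenate a parameter dict into one vector (for gradient checks)."""
    keys = sorted(params)
    vec = np.concatenate([np.ravel(params[k]) for k in keys])
    shapes = [(k, params[k].shape) for k in keys]
    return vec, shapes


def unflatten_params(vec: np.ndarray, shapes: list) -> dict:
    out = {}
    pos = 0
    for k, shape in shapes:
        size = int(np.prod(shape)) if shape else 1
        out[k] = vec[pos : pos + size].reshape(shape)
        pos += size
    return out
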