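"""Vectorized numpy primitives for the small neural networks in this package.

All forward passes are batched float32 array ops; every primitive has a
matching analytic backward pass (gradient-checked in the test suite), and
parameters are updated with Adam.  Shapes follow the convention

* sequences: ``(batch, time, features)``
* convolution stacks: ``(batch, channels, time)``
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self._m:
                self._m[k] = np.zeros_like(params[k])
                self._v[k] = np.zeros_like(params[k])
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1**self.t)
            vhat = self._v[k] / (1 - b2**self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(params[k].dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # direct form is IEEE-safe: exp overflow saturates to 0 exactly
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

def lstm_init(rng: np.random.Generator, input_size: int, hidden_size: int) -> dict[str, np.ndarray]:
    """Glorot input weights, per-gate orthogonal recurrent weights, and a
    forget-gate bias of 1 — the standard recipe for stable training of
    recurrences over long sequences."""
    Wh = np.empty((hidden_size, 4 * hidden_size), dtype=F32)
    for gate in range(4):
        q, _ = np.linalg.qr(rng.standard_normal((hidden_size, hidden_size)))
        Wh[:, gate * hidden_size : (gate + 1) * hidden_size] = q.astype(F32)
    params = {
        "Wx": glorot(rng, (input_size, 4 * hidden_size)),
        "Wh": Wh,
        "b": np.zeros(4 * hidden_size, dtype=F32),
    }
    params["b"][hidden_size : 2 * hidden_size] = 1.0
    return params


def lstm_forward(X: np.ndarray, params: dict[str, np.ndarray]) -> tuple[np.ndarray, dict]:
    """Run an LSTM over ``X (B, T, In)``; returns all hidden states
    ``H (B, T, hid)`` and a cache for the backward pass."""
    B, T, _ = X.shape
    hid = params["Wh"].shape[0]
    h = np.zeros((B, hid), dtype=F32)
    c = np.zeros((B, hid), dtype=F32)
    H = np.empty((B, T, hid), dtype=F32)
    gates_i = np.empty((B, T, hid), dtype=F32)
    gates_f = np.empty((B, T, hid), dtype=F32)
    gates_g = np.empty((B, T, hid), dtype=F32)
    gates_o = np.empty((B, T, hid), dtype=F32)
    cells = np.empty((B, T, hid), dtype=F32)
    tanhc = np.empty((B, T, hid), dtype=F32)
    Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
    # input contributions for all timesteps in one matmul
    XW = (X.reshape(B * T, -1).astype(F32) @ Wx + b).reshape(B, T, 4 * hid)
    for t in range(T):
        z = XW[:, t] + h @ Wh
        i = _sigmoid(z[:, :hid])
        f = _sigmoid(z[:, hid : 2 * hid])
        g = np.tanh(z[:, 2 * hid : 3 * hid])
        o = _sigmoid(z[:, 3 * hid :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        H[:, t] = h
        gates_i[:, t], gates_f[:, t], gates_g[:, t], gates_o[:, t] = i, f, g, o
        cells[:, t] = c
        tanhc[:, t] = tc
    cache = {
        "X": X, "H": H, "i": gates_i, "f": gates_f, "g": gates_g, "o": gates_o,
        "c": cells, "tc": tanhc,
    }
    return H, cache


def lstm_backward(dH: np.ndarray, cache: dict, params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Backprop-through-time given gradients w.r.t. every hidden state."""
    X, H = cache["X"], cache["H"]
    B, T, hid = H.shape
    Wh = params["Wh"]
    dZ = np.empty((B, T, 4 * hid), dtype=F32)
    dh_next = np.zeros((B, hid), dtype=F32)
    dc_next = np.zeros((B, hid), dtype=F32)
    for t in range(T - 1, -1, -1):
        i, f, g, o = cache["i"][:, t], cache["f"][:, t], cache["g"][:, t], cache["o"][:, t]
        c_prev = cache["c"][:, t - 1] if t > 0 else np.zeros_like(cache["c"][:, t])
        dh = dH[:, t] + dh_next
        tc = cache["tc"][:, t]
        do = dh * tc
        dc = dh * o * (1 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = dZ[:, t]
        dz[:, :hid] = di * i * (1 - i)
        dz[:, hid : 2 * hid] = df * f * (1 - f)
        dz[:, 2 * hid : 3 * hid] = dg * (1 - g * g)
        dz[:, 3 * hid :] = do * o * (1 - o)
        dh_next = dz @ Wh.T
    # weight gradients in three batched matmuls
    dZ_flat = dZ.reshape(B * T, 4 * hid)
    dWx = X.reshape(B * T, -1).astype(F32).T @ dZ_flat
    H_prev = np.concatenate((np.zeros((B, 1, hid), dtype=F32), H[:, :-1]), axis=1)
    dWh = H_prev.reshape(B * T, hid).T @ dZ_flat
    db = dZ_flat.sum(axis=0)
    return {"Wx": dWx, "Wh": dWh, "b": db}


# ---------------------------------------------------------------------------
# Dot-product attention over encoder states
# ---------------------------------------------------------------------------

def attention_forward(H: np.ndarray) -> dict[str, np.ndarray]:
    """Dot-product attention with the final state as query.

    ``H (B, T, d)`` -> scores ``s_i = h_t . h_i``; softmax weights; context
    vector ``cv = sum_i w_i h_i``; output ``av = [cv, h_t] (B, 2d)``.
    """
    q = H[:, -1]  # (B, d)
    scores = np.einsum("btd,bd->bt", H, q)
    weights = softmax(scores, axis=1)
    cv = np.einsum("bt,btd->bd", weights, H)
    av = np.concatenate((cv, q), axis=1)
    return {"scores": scores, "weights": weights, "cv": cv, "av": av}


def attention_backward(dav: np.ndarray, H: np.ndarray, att: dict[str, np.ndarray]) -> np.ndarray:
    """Gradient of the attention output w.r.t. the encoder states ``H``."""
    d = H.shape[2]
    w = att["weights"]
    q = H[:, -1]
    dcv = dav[:, :d]
    dq_direct = dav[:, d:]
    dw = np.einsum("bd,btd->bt", dcv, H)
    ds = w * (dw - np.sum(w * dw, axis=1, keepdims=True))
    dH = w[:, :, None] * dcv[:, None, :]  # cv key-side
    dH += ds[:, :, None] * q[:, None, :]  # score key-side
    dq = np.einsum("bt,btd->bd", ds, H)  # score query-side
    dH[:, -1] += dq + dq_direct
    return dH


# ---------------------------------------------------------------------------
# Dense / dropout / losses
# ---------------------------------------------------------------------------

def dense_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    return X @ W + b


def dense_backward(dY: np.ndarray, X: np.ndarray, W: np.ndarray):
    return dY @ W.T, X.T @ dY, dY.sum(axis=0)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...], rate: float) -> np.ndarray:
    """Inverted-dropout mask; multiply activations by it during training."""
    if rate <= 0:
        return np.ones(shape, dtype=F32)
    keep = (rng.random(shape) >= rate).astype(F32)
    return keep / F32(1.0 - rate)


def binary_ce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def categorical_ce(P: np.ndarray, y_idx: np.ndarray) -> float:
    P = np.clip(P, 1e-7, 1.0)
    return float(-np.mean(np.log(P[np.arange(len(y_idx)), y_idx])))


def sigmoid_head(logits: np.ndarray) -> np.ndarray:
    return _sigmoid(logits)


# ---------------------------------------------------------------------------
# Dilated causal convolution stacks
# ---------------------------------------------------------------------------

def causal_conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray, d: int) -> np.ndarray:
    """Dilated causal convolution.

    ``X (B, Cin, T)``, ``W (Cout, Cin, k)`` ->  ``Y (B, Cout, T)`` with
    ``Y[.., t] = b + sum_i W[.., i] @ X[.., t - d*i]`` and X taken as zero at
    negative indices, so outputs depend only on past and present inputs and
    the output length equals the input length.
    """
    B, Cin, T = X.shape
    Cout, _, k = W.shape
    Y = np.broadcast_to(b[None, :, None], (B, Cout, T)).astype(F32).copy()
    for i in range(k):
        s = d * i
        if s >= T:
            break
        # contribution of tap i: X shifted right by s
        Y[:, :, s:] += np.einsum("oc,bct->bot", W[:, :, i], X[:, :, : T - s]).astype(F32)
    return Y


def causal_conv_backward(dY: np.ndarray, X: np.ndarray, W: np.ndarray, d: int):
    B, Cin, T = X.shape
    Cout, _, k = W.shape
    dX = np.zeros_like(X)
    dW = np.zeros_like(W)
    for i in range(k):
        s = d * i
        if s >= T:
            break
        dW[:, :, i] = np.einsum("bot,bct->oc", dY[:, :, s:], X[:, :, : T - s])
        dX[:, :, : T - s] += np.einsum("bot,oc->bct", dY[:, :, s:], W[:, :, i])
    db = dY.sum(axis=(0, 2))
    return dX, dW, db
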