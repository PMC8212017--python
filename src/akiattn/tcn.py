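"""Temporal convolutional network forecaster for clinical time series.

A TCN is a stack of dilated causal convolutions: the output sequence has the
same length as the input, and output element ``y_v`` depends only on inputs
at indices ``<= v``.  A single dilated causal convolution with filter ``f``
of size ``k`` and dilation ``d`` maps element ``v`` of input ``X`` to

    F_v = sum_{i=0..k-1} f(i) * X[v - d*i]

with ``X`` taken as zero outside its support (causal zero left-padding).
Stacking layers with dilations 1, 2, 4 gives a receptive field of
``1 + (k-1)*(1+2+4)`` past steps.

The forecaster trains one-step-ahead regression with squared loss: the
target is the input sequence shifted left by one, and the *last* output
element is the forecast of the feature's next (future) value.  Each
normalized lab/vital channel gets its own model by default; a shared
multi-channel model can be had by pooling series from several channels into
one fit.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nnops
from .nnops import F32

__all__ = ["dilated_causal_conv", "TCNForecaster"]


def dilated_causal_conv(X, f, d: int = 1) -> np.ndarray:
    """Single-channel dilated causal convolution (see module docstring).

    Parameters
    ----------
    X : array-like, shape (T,)
    f : array-like, shape (k,)
        ``f[i]`` multiplies the input ``d*i`` steps back.
    d : int
        Dilation factor (>= 1).
    """
    X = np.asarray(X, dtype=float)
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or len(f) < 1:
        raise ValueError("filter must be 1-d and non-empty")
    if d < 1:
        raise ValueError("dilation must be >= 1")
    T = len(X)
    if T == 0:
        return np.empty(0)
    out = np.zeros(T)
    for i, fi in enumerate(f):
        s = d * i
        if s >= T:
            break
        out[s:] += fi * X[: T - s]
    return out


class TCNForecaster(BaseEstimator, RegressorMixin):
    """One-step-ahead forecaster built from dilated causal convolutions.

    Parameters
    ----------
    dilations : tuple of int
        Per-layer dilation factors; the default (1, 2, 4) gives three layers.
    kernel_size : int
        Filter size ``k`` of every layer.
    hidden_channels : int
        Channels of the hidden layers; the final layer projects back to one.
    learning_rate, epochs : float, int
        Adam step size and number of full passes over the training series.
    batch_size : int or None
        Series per update; None trains full-batch.
    max_series : int or None
        Fit on at most this many randomly chosen series (None = all); lets
        large cohorts train per-channel models at fixed cost.
    random_state : int
        Seeds initialization and shuffling; fits are deterministic per seed.

    Attributes
    ----------
    params_ : dict of weight arrays (fitted)
    loss_curve_ : list of per-epoch masked mean-squared training losses
    receptive_field_ : int, number of past steps that can influence an output
    """

    def __init__(
        self,
        dilations: tuple[int, ...] = (1, 2, 4),
        kernel_size: int = 3,
        hidden_channels: int = 16,
        learning_rate: float = 1e-3,
        epochs: int = 100,
        batch_size: int | None = None,
        max_series: int | None = None,
        random_state: int = 0,
    ):
        self.dilations = dilations
        self.kernel_size = kernel_size
        self.hidden_channels = hidden_channels
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_series = max_series
        self.random_state = random_state

    # -- internals ----------------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        k, ch = self.kernel_size, self.hidden_channels
        sizes = [1] + [ch] * (len(self.dilations) - 1) + [1]
        params: dict[str, np.ndarray] = {}
        for layer, d in enumerate(self.dilations):
            cin, cout = sizes[layer], sizes[layer + 1]
            scale = np.sqrt(2.0 / (cin * k))
            params[f"W{layer}"] = (rng.standard_normal((cout, cin, k)) * scale).astype(F32)
            params[f"b{layer}"] = np.zeros(cout, dtype=F32)
        return params

    def _forward(self, X: np.ndarray, params: dict[str, np.ndarray]):
        """X (B, T) -> output (B, T); caches pre/post activations."""
        a = X[:, None, :].astype(F32)
        cache = []
        n_layers = len(self.dilations)
        for layer, d in enumerate(self.dilations):
            z = nnops.causal_conv_forward(a, params[f"W{layer}"], params[f"b{layer}"], d)
            last = layer == n_layers - 1
            out = z if last else nnops.relu(z)
            cache.append((a, z))
            a = out
        return a[:, 0, :], cache

    def _backward(self, dOut, cache, params):
        dA = dOut[:, None, :].astype(F32)
        grads: dict[str, np.ndarray] = {}
        n_layers = len(self.dilations)
        for layer in range(n_layers - 1, -1, -1):
            a_in, z = cache[layer]
            if layer != n_layers - 1:
                dA = dA * (z > 0)
            dX, dW, db = nnops.causal_conv_backward(dA, a_in, params[f"W{layer}"], self.dilations[layer])
            grads[f"W{layer}"] = dW
            grads[f"b{layer}"] = db
            dA = dX
        return grads

    @staticmethod
    def _pad_left(series_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Left-pad with zeros to a common length.  Because convolutions are
        causal with zero padding, outputs at in-series positions are
        identical to the unpadded computation."""
        T = max(len(s) for s in series_list)
        B = len(series_list)
        X = np.zeros((B, T), dtype=F32)
        mask = np.zeros((B, T), dtype=bool)
        for j, s in enumerate(series_list):
            L = len(s)
            X[j, T - L :] = s
            mask[j, T - L :] = True
        return X, mask

    # -- sklearn surface ----------------------------------------------------
    def fit(self, series_list: list, y=None) -> "TCNForecaster":
        """Fit on a collection of 1-d normalized series (each length >= 1).

        Series of length 1 carry no one-step-ahead target and are ignored;
        if none is longer, training is impossible and a ValueError is raised.
        """
        series = [np.asarray(s, dtype=float).ravel() for s in series_list]
        if not series:
            raise ValueError("need at least one training series")
        usable = [s for s in series if len(s) >= 2]
        if not usable:
            raise ValueError("training impossible: every series has length < 2")
        rng = np.random.default_rng(self.random_state)
        if self.max_series is not None and len(usable) > self.max_series:
            # fit on a fixed-size random subsample of series
            pick = rng.choice(len(usable), self.max_series, replace=False)
            usable = [usable[i] for i in pick]
        params = self._init_params(rng)
        # one-step-ahead pairs: feed x_0..x_{L-2}, supervise x_1..x_{L-1},
        # so every output position -- including the last -- carries a target
        X, mask = self._pad_left([s[:-1] for s in usable])
        target, _ = self._pad_left([s[1:] for s in usable])
        opt = nnops.Adam(lr=self.learning_rate)
        n = len(usable)
        bs = self.batch_size or n
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                out, cache = self._forward(X[idx], params)
                resid = (out - target[idx]) * mask[idx]
                m = mask[idx].sum()
                loss = float((resid**2).sum() / max(m, 1))
                dOut = (2.0 / max(m, 1)) * resid
                grads = self._backward(dOut, cache, params)
                opt.step(params, grads)
                epoch_loss += loss * m
                seen += m
            self.loss_curve_.append(epoch_loss / max(seen, 1))
        self.params_ = params
        self.receptive_field_ = 1 + (self.kernel_size - 1) * sum(self.dilations)
        return self

    def transform_sequence(self, series) -> np.ndarray:
        """Full output sequence for one input series (same length)."""
        s = np.asarray(series, dtype=float).ravel()
        if len(s) == 0:
            return np.empty(0)
        out, _ = self._forward(s[None, :], self.params_)
        return out[0].astype(float)

    def predict(self, series_list: list) -> np.ndarray:
        """Forecast future value(s): the last output element per series,
        clipped to [0, 1]."""
        if isinstance(series_list, np.ndarray) and series_list.ndim == 1:
            series_list = [series_list]
        series = [np.asarray(s, dtype=float).ravel() for s in series_list]
        if any(len(s) == 0 for s in series):
            raise ValueError("cannot forecast from an empty series")
        X, _ = self._pad_left(series)
        out, _ = self._forward(X, self.params_)
        return np.clip(out[:, -1].astype(float), 0.0, 1.0)
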