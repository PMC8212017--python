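"""Attention-based encoder-decoder for AKI case / stage / onset prediction.

The model reads the assembled per-stay feature sequence element by element
with an LSTM encoder (one recurrent unit per schema position, hidden size
64), computes dot-product attention of the final hidden state ``h_t``
against every state ``h_i``

    s_i = h_t . h_i,   w = softmax(s),   cv = sum_i w_i h_i,
    av = concatenate(cv, h_t)            (dimension 128),

and decodes ``av`` with a three-layer head: dense(128) -> dropout(0.2) ->
task output.  The case head is a sigmoid scalar; the stage head is a
3-way softmax; the onset head is a softmax over the scheme's onset
intervals.  Training minimizes binary / categorical cross-entropy with
Adam (initial learning rate 0.001, multiplied by 0.9 when the monitored
loss plateaus), 1,000 epochs and batch size 128 by default.

Implemented as self-contained numpy forward/backward passes (see
:mod:`akiattn.nnops`); fits are deterministic per ``random_state``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nnops
from .nnops import F32

__all__ = [
    "AttentionAKIClassifier",
    "attention",
    "threshold_decision",
    "TASK_OUTPUTS",
]

#: output dimension per task (onset is resolved from the interval scheme)
TASK_OUTPUTS = {"case": 1, "stage": 3, "onset": None}


def attention(H: np.ndarray) -> dict[str, np.ndarray]:
    """Dot-product attention for a single encoder-state matrix ``H (T, d)``.

    Returns scores, softmax weights, the context vector ``cv`` and the
    concatenated output ``av`` of dimension ``2 d``.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("H must be a non-empty (T, d) matrix")
    q = H[-1]
    scores = H @ q
    e = np.exp(scores - scores.max())
    weights = e / e.sum()
    cv = weights @ H
    return {
        "scores": scores,
        "weights": weights,
        "cv": cv,
        "av": np.concatenate((cv, q)),
    }


def threshold_decision(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Element-wise strict 'exceeds threshold' decision (0/1)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(probabilities, dtype=float) > threshold).astype(int)


class AttentionAKIClassifier(BaseEstimator, ClassifierMixin):
    """LSTM encoder + dot-product attention + dense decoder.

    Parameters
    ----------
    task : {"case", "stage", "onset"}
        Selects the output head: sigmoid scalar for the binary case task,
        softmax over classes otherwise.
    hidden_size : int
        LSTM state dimension (64: ``av`` is 128 after concatenation).
    decoder_hidden : int
        Width of the first decoder layer (equals ``2 * hidden_size``).
    dropout : float
        Dropout rate of the second decoder layer (training only).
    learning_rate, lr_decay, decay_patience : float, float, int
        Adam initial step size; multiplicative decay applied when the
        monitored loss has not improved for ``decay_patience`` epochs.
    epochs, batch_size : int, int
    threshold : float
        Decision threshold for :meth:`predict` (strict >).
    early_stopping, patience : bool, int
        Optional stop on monitored-loss plateau (off by default to honor the
        fixed epoch budget).
    validation_fraction : float
        Held-out fraction used to monitor the plateau; 0 monitors training
        loss instead.
    random_state : int
        Seeds init, shuffling and dropout; fits are bitwise deterministic.

    Attributes
    ----------
    classes_ : label vocabulary seen in fit
    params_ : dict of fitted weight arrays
    loss_curve_ : monitored loss per epoch
    n_outputs_ : head dimension
    """

    def __init__(
        self,
        task: str = "case",
        hidden_size: int = 64,
        decoder_hidden: int = 128,
        dropout: float = 0.2,
        learning_rate: float = 1e-3,
        lr_decay: float = 0.9,
        decay_patience: int = 10,
        epochs: int = 1000,
        batch_size: int = 128,
        threshold: float = 0.5,
        early_stopping: bool = False,
        patience: int = 50,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.task = task
        self.hidden_size = hidden_size
        self.decoder_hidden = decoder_hidden
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.decay_patience = decay_patience
        self.epochs = epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.early_stopping = early_stopping
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ fwd
    @staticmethod
    def _recenter(X: np.ndarray) -> np.ndarray:
        # affine map of [0,1]-normalized inputs onto [-1,1]: zero-centred
        # inputs condition the recurrence much better and the map is fixed
        # and invertible, so the normalization contract is unchanged
        return 2.0 * X - 1.0

    def _forward(self, X: np.ndarray, params: dict, drop_mask: np.ndarray | None = None):
        """X (B, T) -> probabilities; returns cache when training."""
        Xs = self._recenter(X)[:, :, None].astype(F32)
        H, lstm_cache = nnops.lstm_forward(Xs, params)
        att = nnops.attention_forward(H)
        av = att["av"]
        z1 = nnops.dense_forward(av, params["W1"], params["b1"])
        a1 = nnops.relu(z1)
        a1d = a1 * drop_mask if drop_mask is not None else a1
        logits = nnops.dense_forward(a1d, params["W2"], params["b2"])
        if self.n_outputs_ == 1:
            probs = nnops.sigmoid_head(logits)
        else:
            probs = nnops.softmax(logits, axis=1)
        cache = {"H": H, "lstm": lstm_cache, "att": att, "av": av, "z1": z1, "a1d": a1d}
        return probs, cache

    def _backward(self, dlogits: np.ndarray, cache: dict, params: dict, drop_mask):
        grads: dict[str, np.ndarray] = {}
        da1d, grads["W2"], grads["b2"] = nnops.dense_backward(dlogits, cache["a1d"], params["W2"])
        da1 = da1d * drop_mask if drop_mask is not None else da1d
        dz1 = da1 * (cache["z1"] > 0)
        dav, grads["W1"], grads["b1"] = nnops.dense_backward(dz1, cache["av"], params["W1"])
        dH = nnops.attention_backward(dav.astype(F32), cache["H"], cache["att"])
        grads.update(nnops.lstm_backward(dH, cache["lstm"], params))
        return grads

    # ------------------------------------------------------------------ fit
    def fit(self, X, y) -> "AttentionAKIClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_samples, sequence_length) matching y")
        if X.shape[1] < 1:
            raise ValueError("empty input sequence")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training requires at least two classes")
        if self.task == "case":
            if len(self.classes_) != 2:
                raise ValueError("case task is binary")
            self.n_outputs_ = 1
        else:
            expected = TASK_OUTPUTS[self.task]
            self.n_outputs_ = expected if expected is not None else len(self.classes_)
        y_idx = np.searchsorted(self.classes_, y)

        rng = np.random.default_rng(self.random_state)
        params = nnops.lstm_init(rng, 1, self.hidden_size)
        av_dim = 2 * self.hidden_size
        params["W1"] = nnops.glorot(rng, (av_dim, self.decoder_hidden))
        params["b1"] = np.zeros(self.decoder_hidden, dtype=F32)
        params["W2"] = nnops.glorot(rng, (self.decoder_hidden, self.n_outputs_))
        params["b2"] = np.zeros(self.n_outputs_, dtype=F32)
        self.params_ = params
        self.n_features_in_ = X.shape[1]

        n = len(X)
        if self.validation_fraction > 0 and n >= 20:
            n_val = max(1, int(round(self.validation_fraction * n)))
            perm = rng.permutation(n)
            val_idx, train_idx = perm[:n_val], perm[n_val:]
        else:
            val_idx, train_idx = np.empty(0, dtype=int), np.arange(n)
        Xtr, ytr = X[train_idx], y_idx[train_idx]
        Xval, yval = X[val_idx], y_idx[val_idx]

        opt = nnops.Adam(lr=self.learning_rate)
        self.loss_curve_ = []
        best = np.inf
        stall = 0
        stop_stall = 0
        for _ in range(self.epochs):
            order = rng.permutation(len(Xtr))
            train_loss, seen = 0.0, 0
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                drop = (
                    nnops.dropout_mask(rng, (len(xb), self.decoder_hidden), self.dropout)
                    if self.dropout > 0
                    else None
                )
                probs, cache = self._forward(xb, params, drop)
                B = len(xb)
                if self.n_outputs_ == 1:
                    loss = nnops.binary_ce(probs[:, 0], yb)
                    dlogits = ((probs[:, 0] - yb) / B)[:, None].astype(F32)
                else:
                    loss = nnops.categorical_ce(probs, yb)
                    onehot = np.zeros_like(probs)
                    onehot[np.arange(B), yb] = 1
                    dlogits = ((probs - onehot) / B).astype(F32)
                grads = self._backward(dlogits, cache, params, drop)
                opt.step(params, grads)
                train_loss += loss * B
                seen += B
            monitored = (
                self._loss_on(Xval, yval, params) if len(val_idx) else train_loss / max(seen, 1)
            )
            self.loss_curve_.append(monitored)
            if monitored < best - 1e-6:
                best = monitored
                stall = stop_stall = 0
            else:
                stall += 1
                stop_stall += 1
            if stall >= self.decay_patience:
                opt.lr *= self.lr_decay
                stall = 0
            if self.early_stopping and stop_stall >= self.patience:
                break
        return self

    def _loss_on(self, X, y_idx, params) -> float:
        probs, _ = self._forward(X, params, None)
        if self.n_outputs_ == 1:
            return nnops.binary_ce(probs[:, 0], y_idx)
        return nnops.categorical_ce(probs, y_idx)

    # ---------------------------------------------------------------- infer
    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"sequence length {X.shape[1]} != fitted length {self.n_features_in_}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities; dropout is disabled, so this is a
        deterministic function of the input."""
        X = self._check_X(X)
        probs, _ = self._forward(X, self.params_, None)
        if self.n_outputs_ == 1:
            p = probs[:, 0]
            return np.column_stack((1 - p, p)).astype(float)
        return probs.astype(float)

    def decision_scores(self, X) -> np.ndarray:
        """Raw head probabilities (scalar for the case task)."""
        proba = self.predict_proba(X)
        return proba[:, 1] if self.n_outputs_ == 1 else proba

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        if self.n_outputs_ == 1:
            dec = threshold_decision(proba[:, 1], self.threshold)
            return self.classes_[dec]
        return self.classes_[np.argmax(proba, axis=1)]

    def encode(self, X) -> np.ndarray:
        """Encoder hidden states H (n, T, hidden) for assembled sequences."""
        X = self._check_X(X)
        H, _ = nnops.lstm_forward(self._recenter(X)[:, :, None].astype(F32), self.params_)
        return H.astype(float)

    def attention_weights(self, X) -> np.ndarray:
        """Per-position attention weights (n, T); each row sums to 1."""
        att = nnops.attention_forward(self.encode(X).astype(F32))
        return att["weights"].astype(float)

    def decode(self, av: np.ndarray) -> np.ndarray:
        """Run the decoder head alone on attention outputs ``av (n, 128)``."""
        av = np.atleast_2d(np.asarray(av, dtype=float)).astype(F32)
        if av.shape[1] != 2 * self.hidden_size:
            raise ValueError(f"av must have dimension {2 * self.hidden_size}")
        z1 = nnops.dense_forward(av, self.params_["W1"], self.params_["b1"])
        a1 = nnops.relu(z1)
        logits = nnops.dense_forward(a1, self.params_["W2"], self.params_["b2"])
        if self.n_outputs_ == 1:
            return nnops.sigmoid_head(logits)[:, 0].astype(float)
        return nnops.softmax(logits, axis=1).astype(float)

    # ------------------------------------------------------------- persist
    def save(self, path: str | Path, schema_hash: str | None = None) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.params_)
        meta = {
            "config": self.get_params(),
            "classes": self.classes_.tolist(),
            "n_outputs": self.n_outputs_,
            "n_features_in": self.n_features_in_,
            "schema_hash": schema_hash,
        }
        (path / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path, schema_hash: str | None = None) -> "AttentionAKIClassifier":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        if (
            schema_hash is not None
            and meta["schema_hash"] is not None
            and schema_hash != meta["schema_hash"]
        ):
            raise ValueError(
                "feature schema hash differs from the one the model was trained with"
            )
        model = cls(**meta["config"])
        model.classes_ = np.asarray(meta["classes"])
        model.n_outputs_ = meta["n_outputs"]
        model.n_features_in_ = meta["n_features_in"]
        with np.load(path / "weights.npz") as npz:
            model.params_ = {k: npz[k] for k in npz.files}
        return model
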