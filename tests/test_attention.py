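"""Attention mechanism semantics, decoder wiring, and training contracts."""

import numpy as np
import pytest

from akiattn import nnops
from akiattn.attention import AttentionAKIClassifier, attention, threshold_decision


# ------------------------------------------------------------ attention math

def test_single_state_attention():
    h0 = np.array([[0.3, -1.2, 0.5]])
    out = attention(h0)
    assert np.allclose(out["weights"], [1.0])
    assert np.allclose(out["cv"], h0[0])
    assert np.allclose(out["av"], np.concatenate((h0[0], h0[0])))


def test_two_identical_states():
    h = np.array([0.5, 1.0])
    out = attention(np.stack((h, h)))
    assert np.allclose(out["weights"], [0.5, 0.5])
    assert np.allclose(out["cv"], h)


def test_hand_computed_two_state_example():
    """h0=(1,0), h1=(0,1): scores (0,1), weights (1/(1+e), e/(1+e))."""
    out = attention(np.array([[1.0, 0.0], [0.0, 1.0]]))
    assert np.allclose(out["scores"], [0.0, 1.0])
    assert np.allclose(out["weights"], [0.2689, 0.7311], atol=5e-5)
    assert np.allclose(out["cv"], [0.2689, 0.7311], atol=5e-5)


def direct_attention(H):
    """Direct-summation oracle, scalar loops only."""
    T, d = H.shape
    q = H[-1]
    s = np.array([sum(q[k] * H[i, k] for k in range(d)) for i in range(T)])
    e = np.exp(s - s.max())
    w = e / e.sum()
    cv = np.zeros(d)
    for i in range(T):
        cv += w[i] * H[i]
    return s, w, cv


def test_attention_matches_direct_summation(rng):
    for _ in range(50):
        H = rng.standard_normal((int(rng.integers(1, 12)), int(rng.integers(1, 8))))
        out = attention(H)
        s, w, cv = direct_attention(H)
        assert np.allclose(out["weights"], w, atol=1e-8)
        assert np.allclose(out["cv"], cv, atol=1e-8)
        assert out["weights"].sum() == pytest.approx(1.0, abs=1e-6)
        assert (out["weights"] >= 0).all()
        assert len(out["av"]) == 2 * H.shape[1]


def test_softmax_shift_invariance_and_monotonicity(rng):
    for _ in range(30):
        s = rng.standard_normal(9)
        w = nnops.softmax(s)
        assert np.allclose(w, nnops.softmax(s + 3.7), atol=1e-7)
        # increasing one score strictly increases its weight, decreases others
        s2 = s.copy()
        s2[4] += 0.5
        w2 = nnops.softmax(s2)
        assert w2[4] > w[4]
        others = np.delete(w2, 4) < np.delete(w, 4)
        assert others.all()


def test_attention_rejects_empty():
    with pytest.raises(ValueError):
        attention(np.empty((0, 4)))


# ------------------------------------------------------------------ decisions

def test_threshold_decision_is_strict():
    assert threshold_decision(0.7, 0.5) == 1
    assert threshold_decision(0.5, 0.5) == 0
    assert threshold_decision([0.2, 0.9], 0.5).tolist() == [0, 1]
    with pytest.raises(ValueError):
        threshold_decision([0.5], 1.5)


# ----------------------------------------------------------------- the model

def _toy(rng, n=240, T=12, informative=(2, 8)):
    y = rng.integers(0, 2, n)
    X = rng.random((n, T))
    for pos in informative:
        X[:, pos] = np.clip(0.25 + 0.5 * y + rng.normal(0, 0.05, n), 0, 1)
    return X, y


@pytest.fixture(scope="module")
def toy_model():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 240)
    X = rng.random((240, 12))
    for pos in (2, 8):
        X[:, pos] = np.clip(0.25 + 0.5 * y + rng.normal(0, 0.05, 240), 0, 1)
    model = AttentionAKIClassifier(
        hidden_size=16, decoder_hidden=32, epochs=40, batch_size=32,
        learning_rate=3e-3, validation_fraction=0.0, random_state=0,
    )
    return model.fit(X[:200], y[:200]), X, y


def test_linearly_separable_toy_trains(toy_model):
    from sklearn.metrics import roc_auc_score

    model, X, y = toy_model
    p = model.predict_proba(X[:200])[:, 1]
    assert roc_auc_score(y[:200], p) > 0.95


def test_label_shuffled_control(rng):
    X, y = _toy(rng)
    y_shuf = rng.permutation(y)
    model = AttentionAKIClassifier(
        hidden_size=16, decoder_hidden=32, epochs=15, batch_size=32,
        validation_fraction=0.0, random_state=1,
    ).fit(X[:200], y_shuf[:200])
    from sklearn.metrics import roc_auc_score

    p = model.predict_proba(X[200:])[:, 1]
    assert 0.3 <= roc_auc_score(y_shuf[200:], p) <= 0.7


def test_seeded_determinism(rng):
    X, y = _toy(rng, n=80)
    kw = dict(hidden_size=8, decoder_hidden=16, epochs=5, batch_size=16, random_state=3)
    a = AttentionAKIClassifier(**kw).fit(X, y)
    b = AttentionAKIClassifier(**kw).fit(X, y)
    for k in a.params_:
        assert np.array_equal(a.params_[k], b.params_[k])
    assert np.array_equal(a.predict_proba(X), b.predict_proba(X))


def test_encoder_shapes(toy_model):
    model, X, _ = toy_model
    H = model.encode(X[:5])
    assert H.shape == (5, 12, 16)
    w = model.attention_weights(X[:5])
    assert w.shape == (5, 12)
    assert np.allclose(w.sum(axis=1), 1.0, atol=1e-5)


def test_predict_proba_is_deterministic_without_dropout(toy_model):
    model, X, _ = toy_model
    assert np.array_equal(model.predict_proba(X[:20]), model.predict_proba(X[:20]))


def test_decode_head_dimensions(toy_model):
    model, _, _ = toy_model
    av = np.zeros(2 * model.hidden_size)
    p = model.decode(av)
    assert p.shape == (1,) and 0 < p[0] < 1
    with pytest.raises(ValueError):
        model.decode(np.zeros(7))


def test_predict_thresholds_strictly(toy_model):
    model, X, _ = toy_model
    proba = model.predict_proba(X[:30])[:, 1]
    pred = model.predict(X[:30])
    assert np.array_equal(pred, model.classes_[(proba > 0.5).astype(int)])


def test_sequence_length_mismatch_raises(toy_model):
    model, _, _ = toy_model
    with pytest.raises(ValueError, match="length"):
        model.predict_proba(np.zeros((2, 9)))


def test_single_class_training_rejected(rng):
    X = rng.random((30, 6))
    with pytest.raises(ValueError):
        AttentionAKIClassifier(epochs=1).fit(X, np.zeros(30))


def test_multiclass_head_sums_to_one(rng):
    X = rng.random((90, 8))
    y = rng.integers(0, 3, 90)
    model = AttentionAKIClassifier(
        task="stage", hidden_size=8, decoder_hidden=16, epochs=3,
        batch_size=32, random_state=0,
    ).fit(X, y)
    proba = model.predict_proba(X[:10])
    assert proba.shape == (10, 3)
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-5)


def test_save_load_roundtrip(tmp_path, toy_model):
    model, X, _ = toy_model
    model.save(tmp_path / "m", schema_hash="abc")
    back = AttentionAKIClassifier.load(tmp_path / "m", schema_hash="abc")
    assert np.allclose(back.predict_proba(X[:8]), model.predict_proba(X[:8]))
    with pytest.raises(ValueError, match="schema"):
        AttentionAKIClassifier.load(tmp_path / "m", schema_hash="different")


# ------------------------------------------------------------ gradient check

def test_analytic_gradients_match_finite_differences(monkeypatch, rng):
    """End-to-end backprop through decoder, attention and the LSTM equals
    central finite differences (run in float64 to remove rounding noise)."""
    import importlib

    attmod = importlib.import_module("akiattn.attention")
    monkeypatch.setattr(nnops, "F32", np.float64)
    monkeypatch.setattr(attmod, "F32", np.float64)
    model = AttentionAKIClassifier(
        hidden_size=5, decoder_hidden=10, dropout=0.0, epochs=1,
        batch_size=4, validation_fraction=0.0, random_state=0,
    )
    X = rng.random((6, 7))
    y = np.array([0, 1, 0, 1, 1, 0])
    model.fit(X, y)
    params = {k: v.astype(np.float64) for k, v in model.params_.items()}

    def loss(params):
        probs, _ = model._forward(X, params, None)
        return nnops.binary_ce(probs[:, 0], y)

    probs, cache = model._forward(X, params, None)
    dlogits = ((probs[:, 0] - y) / len(y))[:, None]
    grads = model._backward(dlogits, cache, params, None)
    for name, P in params.items():
        flat = P.ravel()
        for idx in rng.choice(flat.size, size=min(12, flat.size), replace=False):
            old = flat[idx]
            eps = 1e-6
            flat[idx] = old + eps
            lp = loss(params)
            flat[idx] = old - eps
            lm = loss(params)
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            got = grads[name].ravel()[idx]
            assert got == pytest.approx(num, rel=1e-4, abs=1e-9), name
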