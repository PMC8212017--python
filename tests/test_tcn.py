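"""Dilated causal convolution semantics and the TCN forecaster contract."""

import numpy as np
import pytest

from akiattn.tcn import TCNForecaster, dilated_causal_conv


def naive_conv(X, f, d):
    """Double-loop reference: F_v = sum_i f(i) * X[v - d*i], X zero outside."""
    T = len(X)
    out = np.zeros(T)
    for v in range(T):
        for i, fi in enumerate(f):
            idx = v - d * i
            if idx >= 0:
                out[v] += fi * X[idx]
    return out


def test_identity_filter_preserves_input(rng):
    X = rng.standard_normal(17)
    assert np.allclose(dilated_causal_conv(X, [1, 0, 0], 2), X)


def test_hand_examples():
    assert np.allclose(dilated_causal_conv([1, 2, 3, 4], [1, 1, 1], 1), [1, 3, 6, 9])
    assert np.allclose(dilated_causal_conv([1, 2, 3, 4], [1, 1, 1], 2), [1, 2, 4, 6])


def test_empty_input_gives_empty_output():
    assert dilated_causal_conv(np.empty(0), [1, 1], 1).size == 0


def test_conv_matches_naive_oracle(rng):
    for _ in range(300):
        T = int(rng.integers(1, 50))
        k = int(rng.integers(1, 6))
        d = int(rng.integers(1, 6))
        X = rng.standard_normal(T)
        f = rng.standard_normal(k)
        assert np.max(np.abs(dilated_causal_conv(X, f, d) - naive_conv(X, f, d))) <= 1e-10


def test_conv_validation():
    with pytest.raises(ValueError):
        dilated_causal_conv([1.0], [], 1)
    with pytest.raises(ValueError):
        dilated_causal_conv([1.0], [1.0], 0)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    series = [np.clip(0.5 + 0.1 * rng.standard_normal(12), 0, 1) for _ in range(40)]
    return TCNForecaster(epochs=30, random_state=0).fit(series)


def test_model_is_causal(fitted, rng):
    """Zeroing inputs strictly after t never changes outputs at indices <= t."""
    x = rng.random(20)
    full = fitted.transform_sequence(x)
    for t in (0, 5, 13, 18):
        trunc = x.copy()
        trunc[t + 1 :] = 0.0
        assert np.allclose(fitted.transform_sequence(trunc)[: t + 1], full[: t + 1], atol=1e-6)


def test_length_preserved_for_all_lengths(fitted, rng):
    for L in list(range(1, 20)) + [33, 64]:
        out = fitted.transform_sequence(rng.random(L))
        assert len(out) == L


def test_variable_length_without_refit(fitted, rng):
    """The same fitted model accepts any series length, including length 1."""
    preds = fitted.predict([rng.random(1), rng.random(7), rng.random(40)])
    assert preds.shape == (3,) and np.all((preds >= 0) & (preds <= 1))


def test_forecast_is_last_output_element(fitted, rng):
    x = rng.random(9)
    seq = fitted.transform_sequence(x)
    assert fitted.predict([x])[0] == pytest.approx(np.clip(seq[-1], 0, 1), abs=1e-9)


def test_receptive_field_arithmetic(fitted, rng):
    """Perturbing x0 moves the last output iff the sequence fits inside the
    receptive field 1 + (k-1)(1+2+4) = 15."""
    assert fitted.receptive_field_ == 15
    for L, inside in [(10, True), (15, True), (16, False), (30, False)]:
        x = rng.random(L)
        x2 = x.copy()
        x2[0] += 0.5
        delta = abs(fitted.predict([x])[0] - fitted.predict([x2])[0])
        if inside:
            assert delta > 1e-7
        else:
            assert delta == pytest.approx(0.0, abs=1e-7)


def test_training_on_constant_series_converges():
    rng = np.random.default_rng(11)
    series = [np.full(int(rng.integers(6, 15)), 0.5) for _ in range(30)]
    model = TCNForecaster(epochs=250, batch_size=4, random_state=1).fit(series)
    assert model.loss_curve_[-1] < 1e-3
    assert model.predict([np.full(10, 0.5)])[0] == pytest.approx(0.5, abs=0.05)


def test_ramp_beats_persistence_baseline(rng):
    """One-step-ahead error on held-out ramps is below the copy-last-value
    baseline."""
    def ramp():
        start = rng.uniform(0.0, 0.4)
        slope = rng.uniform(0.02, 0.05)
        return start + slope * np.arange(12)

    train = [ramp() for _ in range(60)]
    test = [ramp() for _ in range(20)]
    model = TCNForecaster(epochs=250, batch_size=8, random_state=2).fit(train)
    err_model, err_persist = [], []
    for s in test:
        pred = model.predict([s[:-1]])[0]
        err_model.append((pred - s[-1]) ** 2)
        err_persist.append((s[-2] - s[-1]) ** 2)
    assert np.mean(err_model) < np.mean(err_persist)


def test_seeded_determinism():
    rng = np.random.default_rng(3)
    series = [rng.random(8) for _ in range(20)]
    a = TCNForecaster(epochs=20, random_state=5).fit(series)
    b = TCNForecaster(epochs=20, random_state=5).fit(series)
    assert a.loss_curve_ == b.loss_curve_
    for k in a.params_:
        assert np.array_equal(a.params_[k], b.params_[k])


def test_training_impossible_on_singletons():
    with pytest.raises(ValueError, match="length"):
        TCNForecaster().fit([np.array([0.5]), np.array([0.2])])
    with pytest.raises(ValueError):
        TCNForecaster().fit([])
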