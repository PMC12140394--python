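"""The combination g, the latent-state filter F and the filtering error."""

import numpy as np
import pytest

from idras.error_engine import (
    ModelState,
    batch_filtering_errors,
    combination_apply,
    filter_predict,
    filtering_error,
    init_model,
)


@pytest.fixture
def model(rng):
    return init_model(n_channels=2, T=3, b_y=2, g_hidden=(4,), enc_hidden=(4,),
                      drift_hidden=(4,), dt=0.5, rng=rng)


def test_constant_combination_returns_bias(model):
    net = model.theta.net
    for w in net.weights:
        w[...] = 0.0
    net.biases[-1][...] = 2.5
    z = np.random.default_rng(0).standard_normal((10, 2))
    out = combination_apply(z, model.theta)
    assert np.allclose(out, 2.5)


def test_single_linear_layer_weights():
    rng = np.random.default_rng(0)
    m = init_model(n_channels=2, T=2, g_hidden=(), dt=1.0, rng=rng)
    m.theta.net.weights[0][...] = np.array([[1.0], [1.0]])
    m.theta.net.biases[0][...] = 0.0
    assert combination_apply(np.array([2.0, 3.0]), m.theta) == pytest.approx(5.0)


def test_combination_matches_handcoded_forward_pass(model):
    """Independently hand-coded tanh MLP forward agrees with the module."""
    z = np.random.default_rng(1).standard_normal((7, 2))
    net = model.theta.net
    h = np.tanh(z @ net.weights[0] + net.biases[0])
    expect = (h @ net.weights[1] + net.biases[1])[:, 0]
    assert np.allclose(combination_apply(z, model.theta), expect)


def test_channel_mismatch_raises(model):
    with pytest.raises(ValueError, match="channels"):
        combination_apply(np.zeros(5), model.theta)
    with pytest.raises(ValueError, match="history length"):
        filter_predict(np.zeros(7), model.Theta, dt=0.5)


def _persistence_filter(m: ModelState):
    """Rig encoder/decoder so F copies the newest history value; w ≡ 0."""
    enc = m.Theta.encoder
    for w in enc.weights:
        w[...] = 0.0
    for b in enc.biases:
        b[...] = 0.0
    # single linear path: last history entry -> latent coord 0
    if len(enc.weights) == 1:
        enc.weights[0][-1, 0] = 1.0
    else:
        raise AssertionError("use enc_hidden=() for this rig")
    for w in m.Theta.drift.weights:
        w[...] = 0.0
    for b in m.Theta.drift.biases:
        b[...] = 0.0
    dec = m.Theta.decoder
    dec.weights[0][...] = 0.0
    dec.weights[0][0, 0] = 1.0
    dec.biases[0][...] = 0.0


def test_persistence_filter_predicts_last_value(rng):
    m = init_model(n_channels=1, T=4, b_y=2, enc_hidden=(), drift_hidden=(3,),
                   dt=0.1, rng=rng)
    _persistence_filter(m)
    hist = np.array([0.3, -1.2, 0.7, 2.0])
    assert filter_predict(hist, m.Theta, dt=0.1) == pytest.approx(2.0)


def test_static_mode_filter_is_exactly_zero(rng):
    m = init_model(n_channels=2, T=3, dt=1.0, static_mode=True, rng=rng)
    assert filter_predict(np.ones(3), m, dt=1.0) == 0.0
    # and the error reduces to the combination value itself
    w = np.random.default_rng(2).standard_normal((5, 4, 2))
    e = filtering_error(w, m)
    c = combination_apply(w[:, -1, :], m)
    assert np.array_equal(e, c)


def test_linear_drift_single_euler_step(rng):
    """w(y) = -y integrated with one explicit Euler step: y' = y(1 - dt)."""
    m = init_model(n_channels=1, T=2, b_y=2, enc_hidden=(), drift_hidden=(),
                   dt=0.25, rng=rng)
    _persistence_filter(m)
    m.Theta.drift.weights[0][...] = -np.eye(2)
    hist = np.array([0.0, 1.6])
    # encoder puts 1.6 into latent coord 0; Euler: 1.6 * (1 - 0.25) = 1.2
    assert filter_predict(hist, m.Theta, dt=0.25) == pytest.approx(1.6 * 0.75)


def test_rk4_matches_exact_linear_decay(rng):
    m = init_model(n_channels=1, T=2, b_y=2, enc_hidden=(), drift_hidden=(),
                   dt=0.25, integrator="rk4", rng=rng)
    _persistence_filter(m)
    m.Theta.drift.weights[0][...] = -np.eye(2)
    out = filter_predict(np.array([0.0, 1.0]), m.Theta, dt=0.25)
    assert out == pytest.approx(np.exp(-0.25), abs=1e-5)


def test_error_is_combination_minus_filter(model):
    """Compositional oracle: ℰ equals its two pieces computed separately."""
    w = np.random.default_rng(3).standard_normal((6, 4, 2))
    e = filtering_error(w, model)
    c_hist = np.stack([combination_apply(w[j, :3, :], model) for j in range(6)])
    c_k = combination_apply(w[:, 3, :], model)
    c_hat = filter_predict(c_hist, model.Theta, dt=model.dt)
    assert np.allclose(e, c_k - c_hat)


def test_constant_series_persistence_filter_zero_error(rng):
    m = init_model(n_channels=1, T=3, b_y=2, enc_hidden=(), drift_hidden=(2,),
                   dt=0.1, rng=rng)
    _persistence_filter(m)
    w = np.full((1, 4, 1), 0.37)
    # gauge identity: use raw gauge so c is constant and F persists it
    assert filtering_error(w, m)[0] == pytest.approx(0.0)


def test_autodiff_gradients_match_finite_differences(model):
    windows = np.random.default_rng(4).standard_normal((8, 4, 2))
    params = model.tensor_parameters()
    loss = batch_filtering_errors(windows, model, params=params).var()
    loss.backward()
    raw = model.parameters()
    rng = np.random.default_rng(5)

    def loss_np():
        return float(np.var(batch_filtering_errors(windows, model)))

    for pi in rng.choice(len(raw), size=6, replace=False):
        p = raw[pi]
        idx = tuple(rng.integers(0, s) for s in p.shape)
        h = 1e-5
        old = p[idx]
        p[idx] = old + h
        fp = loss_np()
        p[idx] = old - h
        fm = loss_np()
        p[idx] = old
        fd = (fp - fm) / (2 * h)
        ad = params[pi].grad[idx]
        assert np.isclose(fd, ad, rtol=1e-4, atol=1e-7)


def test_history_recomputed_from_current_theta(model):
    """Perturbing θ changes the filter's input sequence (end-to-end coupling)."""
    w = np.random.default_rng(6).standard_normal((5, 4, 2))
    e0 = batch_filtering_errors(w, model)
    model.theta.net.weights[0][0, 0] += 0.1
    e1 = batch_filtering_errors(w, model)
    assert not np.allclose(e0, e1)


def test_checkpoint_roundtrip(tmp_path, model, small_ts):
    model.c_mean, model.c_std = 0.3, 1.7
    model.z_mean = np.array([0.1, -0.2])
    model.z_std = np.array([1.1, 0.9])
    model.save(str(tmp_path / "ck.npz"), str(tmp_path / "ck.json"))
    back = ModelState.load(str(tmp_path / "ck.npz"), str(tmp_path / "ck.json"))
    w = np.random.default_rng(7).standard_normal((4, 4, 2))
    assert np.array_equal(filtering_error(w, model), filtering_error(w, back))
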