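"""Published nomogram transcription, ML regression fitting, and the network."""

import numpy as np
import pytest

from toricalc.nomogram import (
    LinearMapModel,
    fit_linear_map,
    fit_network,
    load_model,
    model_loglik,
    predict_rcp,
    published_nomogram,
    save_model,
    split_train_test,
)
from toricalc.powervector import PowerVector, mirror_for_left_eye

# Published coefficient sets, re-typed independently here to lock the
# package transcription digit for digit.
K_MATRIX = [
    [0.9458, 0.0332, -0.0104],
    [0.0009, 0.9135, -0.0711],
    [0.0129, 0.0315, 0.8557],
]
K_INTERCEPT = [2.5173, -0.1031, -0.5451]
TK_MATRIX = [
    [0.9523, 0.0360, 0.0011],
    [-0.0196, 0.8931, -0.0342],
    [0.0125, -0.0424, 0.8148],
]
TK_INTERCEPT = [2.1739, 0.9693, -0.4971]


def test_published_coefficients_exact():
    k = published_nomogram("keratometry")
    tk = published_nomogram("total_corneal_power")
    assert np.array_equal(k.matrix, np.array(K_MATRIX))
    assert np.array_equal(k.intercept, np.array(K_INTERCEPT))
    assert np.array_equal(tk.matrix, np.array(TK_MATRIX))
    assert np.array_equal(tk.intercept, np.array(TK_INTERCEPT))
    with pytest.raises(ValueError):
        published_nomogram("scheimpflug")


def test_zero_input_returns_intercept():
    zero = PowerVector(0.0, 0.0, 0.0)
    k = predict_rcp(published_nomogram("keratometry"), zero, "OD")
    tk = predict_rcp(published_nomogram("total_corneal_power"), zero, "OD")
    assert k.as_array() == pytest.approx(K_INTERCEPT, abs=0)
    assert tk.as_array() == pytest.approx(TK_INTERCEPT, abs=0)


def test_prediction_at_cohort_mean_matches_hand_dot_product():
    x = np.array([43.7843, -0.1401, -0.1152])
    expected = np.array(K_MATRIX) @ x + np.array(K_INTERCEPT)
    got = published_nomogram("keratometry").predict(PowerVector(*x))
    assert got.as_array() == pytest.approx(expected, abs=1e-12)


def test_identity_model_and_left_eye_symmetry():
    ident = LinearMapModel(np.eye(3), np.zeros(3))
    pv = PowerVector(43.0, 1.0, -0.4)
    assert predict_rcp(ident, pv, "OD") == pv
    model = published_nomogram("keratometry")
    os_pred = predict_rcp(model, pv, "OS")
    od_mirrored = mirror_for_left_eye(predict_rcp(model, mirror_for_left_eye(pv), "OD"))
    assert os_pred.as_array() == pytest.approx(od_mirrored.as_array(), abs=0)


# ------------------------------------------------------------------ fitting
def _simulate_linear(rng, n, A, b, sigma):
    X = np.column_stack(
        [rng.normal(43.8, 1.5, n), rng.normal(-0.14, 1.3, n), rng.normal(-0.12, 0.7, n)]
    )
    Y = X @ A.T + b + rng.normal(0, sigma, (n, 3))
    return X, Y


def test_fit_recovers_noiseless_linear_map_exactly():
    rng = np.random.default_rng(0)
    A = np.array(K_MATRIX)
    b = np.array(K_INTERCEPT)
    X, Y = _simulate_linear(rng, 50, A, b, 0.0)
    model, report = fit_linear_map(X, Y)
    assert model.matrix == pytest.approx(A, abs=1e-9)
    assert model.intercept == pytest.approx(b, abs=1e-8)
    assert report.mse_train == pytest.approx(0.0, abs=1e-16)


def test_fit_null_model_returns_mean():
    rng = np.random.default_rng(1)
    X = rng.normal(43, 1.5, (500, 3))
    Y = rng.normal(0.3, 0.1, (500, 3))  # independent of X
    model, _ = fit_linear_map(X, Y)
    assert model.matrix == pytest.approx(np.zeros((3, 3)), abs=0.02)
    assert model.intercept == pytest.approx(Y.mean(axis=0), abs=1.0)
    # predictions at the X centroid match the Y centroid regardless
    assert model.predict_array(X.mean(axis=0)[None])[0] == pytest.approx(
        Y.mean(axis=0), abs=0.02
    )


def test_fit_equivariant_under_recentring_of_inputs():
    rng = np.random.default_rng(5)
    A = np.array(K_MATRIX)
    X, Y = _simulate_linear(rng, 300, A, np.array(K_INTERCEPT), 0.2)
    shift = np.array([10.0, 1.0, -2.0])
    m1, _ = fit_linear_map(X, Y)
    m2, _ = fit_linear_map(X + shift, Y)
    assert m2.matrix == pytest.approx(m1.matrix, abs=1e-8)
    # same predictions on the same physical inputs
    assert m2.predict_array(X + shift) == pytest.approx(m1.predict_array(X), abs=1e-8)


def test_fit_rejects_degenerate_designs():
    with pytest.raises(ValueError):
        fit_linear_map(np.zeros((3, 3)), np.zeros((3, 3)))  # too few rows
    X = np.tile([43.0, 0.5, 0.1], (20, 1))  # rank-1 design
    with pytest.raises(np.linalg.LinAlgError):
        fit_linear_map(X, X.copy())


def test_coefficient_bias_shrinks_with_sample_size():
    A = np.array(K_MATRIX)
    b = np.array(K_INTERCEPT)
    errs = []
    for n in (500, 5000, 50000):
        rng = np.random.default_rng(99)
        X, Y = _simulate_linear(rng, n, A, b, 0.27)
        model, _ = fit_linear_map(X, Y)
        errs.append(np.max(np.abs(model.matrix - A)))
    assert errs[2] < errs[0]
    assert errs[2] < 0.01


# ----------------------------------------------------------------- loglik
def test_loglik_standard_normal_closed_form():
    rng = np.random.default_rng(2)
    n = 20000
    resid = rng.standard_normal((n, 1))
    # model=None treats Y - X as the residuals
    logl = model_loglik(None, np.zeros((n, 1)), resid)
    assert logl == pytest.approx(-n / 2 * (np.log(2 * np.pi) + 1), rel=0.01)


def test_loglik_decreases_with_residual_scale():
    rng = np.random.default_rng(3)
    resid = rng.standard_normal((500, 3))
    zeros = np.zeros((500, 3))
    assert model_loglik(None, zeros, 2 * resid) < model_loglik(None, zeros, resid)


# ------------------------------------------------------------------ split
def test_split_sizes_and_partition():
    records = list(range(442))
    train, test = split_train_test(records, 0.7, seed=4)
    assert (len(train), len(test)) == (309, 133)
    assert sorted(train + test) == records
    assert set(train).isdisjoint(test)
    t2, _ = split_train_test(records, 0.7, seed=4)
    assert t2 == train  # reproducible
    with pytest.raises(ValueError):
        split_train_test(records[:5], 0.7, seed=0)


# ---------------------------------------------------------------- network
def test_network_deterministic_and_json_roundtrip(tmp_path):
    rng = np.random.default_rng(6)
    X, Y = _simulate_linear(rng, 300, np.array(K_MATRIX), np.array(K_INTERCEPT), 0.2)
    net1, _ = fit_network(X, Y, seed=12, max_iter=200, n_iter_no_change=10)
    net2, _ = fit_network(X, Y, seed=12, max_iter=200, n_iter_no_change=10)
    for w1, w2 in zip(net1.weights, net2.weights):
        assert np.array_equal(w1, w2)  # bitwise identical under fixed seed
    assert net1.hidden_layer_sizes == (12, 8)

    path = tmp_path / "net.json"
    save_model(net1, path)
    loaded = load_model(path)
    assert loaded.predict_array(X) == pytest.approx(net1.predict_array(X), abs=0)

    lin, _ = fit_linear_map(X, Y)
    lpath = tmp_path / "reg.json"
    save_model(lin, lpath)
    assert load_model(lpath).predict_array(X) == pytest.approx(
        lin.predict_array(X), abs=0
    )


def test_network_requires_enough_data():
    X = np.zeros((10, 3))
    with pytest.raises(ValueError):
        fit_network(X, X.copy(), seed=0)
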