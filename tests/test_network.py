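"""Unit, oracle, and property tests for the network and its training rules.

The gradient-based update laws are checked against central finite
differences of the cost; the learning-rate stability results are checked by
brute-force grid evaluation and by the one-step error-contraction argument
for the weight-linear case.
"""

import math

import numpy as np
import pytest

from gfcmnn.errors import (
    DegenerateGradientError,
    DimensionError,
    DivergenceError,
    InvalidParamsError,
)
from gfcmnn.network import (
    NetworkParams,
    NetworkShape,
    TrainConfig,
    cost,
    delta_lyapunov,
    forward,
    gradient_factors,
    init_params,
    load_model,
    membership,
    one_hot_targets,
    optimal_rate,
    rate_bound,
    receptive_field,
    save_model,
    train,
    update_step,
)


def random_small_net(rng):
    """A random network with n_i<=3, n_j<=2, n_k<=3, n_o<=2."""
    shape = NetworkShape(
        n_i=int(rng.integers(1, 4)),
        n_j=int(rng.integers(1, 3)),
        n_k=int(rng.integers(1, 4)),
        n_o=int(rng.integers(1, 3)),
    )
    params = NetworkParams(
        shape=shape,
        means=rng.normal(0, 1, (shape.n_i, shape.n_j, shape.n_k)),
        variances=rng.uniform(0.5, 2.0, (shape.n_i, shape.n_j, shape.n_k)),
        weights=rng.normal(0, 1, (shape.n_j, shape.n_k, shape.n_o)),
    )
    I = rng.normal(0, 1, shape.n_i)
    d = rng.normal(0, 1, shape.n_o)
    return shape, params, I, d


class TestInitParams:
    def test_deterministic_under_seed(self):
        shape = NetworkShape(5, 4, 5, 5)
        cfg = TrainConfig(seed=42)
        a = init_params(shape, np.zeros(5), np.ones(5), cfg)
        b = init_params(shape, np.zeros(5), np.ones(5), cfg)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.variances, b.variances)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_shapes_for_medical_configuration(self):
        p = init_params(NetworkShape(5, 4, 5, 5, 5), np.zeros(5), np.ones(5),
                        TrainConfig(seed=0))
        assert p.means.shape == (5, 4, 5)
        assert p.variances.shape == (5, 4, 5)
        assert p.weights.shape == (4, 5, 5)

    def test_draw_ranges(self):
        shape = NetworkShape(2, 2, 2, 2)
        lows, highs = np.array([0.0, -1.0]), np.array([2.0, 1.0])
        for seed in range(50):
            cfg = TrainConfig(seed=seed, init_weight_scale=0.3)
            p = init_params(shape, lows, highs, cfg)
            assert np.all(np.abs(p.weights) <= 0.3)
            for i in range(2):
                assert np.all(p.means[i] >= lows[i])
                assert np.all(p.means[i] <= highs[i])
            assert np.all(p.variances > 0)

    def test_degenerate_range_widened(self):
        p = init_params(NetworkShape(1, 1, 2, 1, n_e=5), [0.5], [0.5],
                        TrainConfig(seed=0))
        assert p.input_high[0] - p.input_low[0] == pytest.approx(0.4)


class TestForwardPass:
    def test_membership_examples(self):
        assert membership(1.3, 1.3, 0.7) == 1.0
        assert membership(2.0, 1.0, 1.0) == pytest.approx(math.exp(-1))
        assert membership(0.2, 0.5, 0.9) == membership(0.8, 0.5, 0.9)
        with pytest.raises(InvalidParamsError):
            membership(0.0, 0.0, 0.0)

    def test_receptive_field_matches_scalar_loop(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            shape, params, I, _ = random_small_net(rng)
            r = receptive_field(I, params)
            for j in range(shape.n_j):
                for k in range(shape.n_k):
                    expected = 1.0
                    for i in range(shape.n_i):
                        expected *= membership(
                            I[i], params.means[i, j, k],
                            params.variances[i, j, k]
                        )
                    assert r[j, k] == pytest.approx(expected, rel=1e-12)
            assert np.all(r > 0) and np.all(r <= 1)

    def test_forward_matches_triple_loop(self):
        rng = np.random.default_rng(11)
        shape, params, I, _ = random_small_net(rng)
        O = forward(I, params)
        for o in range(shape.n_o):
            acc = 0.0
            for j in range(shape.n_j):
                for k in range(shape.n_k):
                    acc += params.weights[j, k, o] * receptive_field(
                        I, params)[j, k]
            assert O[o] == pytest.approx(acc, rel=1e-12)

    def test_forward_linear_in_weights(self):
        rng = np.random.default_rng(3)
        _, params, I, _ = random_small_net(rng)
        doubled = params.copy()
        doubled.weights = 2 * params.weights
        np.testing.assert_allclose(forward(I, doubled), 2 * forward(I, params),
                                   rtol=1e-12)

    def test_zero_weights_zero_output(self):
        rng = np.random.default_rng(4)
        _, params, I, _ = random_small_net(rng)
        params.weights[:] = 0.0
        np.testing.assert_array_equal(forward(I, params), 0.0)

    def test_input_length_checked(self):
        rng = np.random.default_rng(5)
        _, params, I, _ = random_small_net(rng)
        with pytest.raises(DimensionError):
            forward(np.append(I, 0.0), params)


class TestCost:
    def test_examples_and_symmetry(self):
        assert cost([1.0, 0.0], [0.0, 0.0]) == 0.5
        assert cost([0.3, -2.0], [0.3, -2.0]) == 0.0
        assert cost([1.0, 2.0], [0.5, 0.0]) == cost([0.5, 0.0], [1.0, 2.0])
        with pytest.raises(DimensionError):
            cost([1.0], [1.0, 2.0])


def finite_difference_grad(f, x0, step=1e-6):
    """Central finite differences of scalar f at flat array x0."""
    g = np.empty_like(x0)
    for idx in range(x0.size):
        xp, xm = x0.copy(), x0.copy()
        xp[idx] += step
        xm[idx] -= step
        g[idx] = (f(xp) - f(xm)) / (2 * step)
    return g


class TestGradients:
    def test_centered_input_zeroes_mean_variance_factors(self):
        shape = NetworkShape(2, 1, 2, 1)
        params = NetworkParams(
            shape=shape,
            means=np.full((2, 1, 2), 0.3),
            variances=np.ones((2, 1, 2)),
            weights=np.ones((1, 2, 1)),
        )
        I = np.full(2, 0.3)
        P_w, P_m, P_v = gradient_factors(I, params, 1)
        np.testing.assert_array_equal(P_m, 0.0)
        np.testing.assert_array_equal(P_v, 0.0)
        np.testing.assert_allclose(P_w, receptive_field(I, params))

    def test_factors_match_finite_differences(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            shape, params, I, _ = random_small_net(rng)
            for o in range(1, shape.n_o + 1):
                P_w, P_m, P_v = gradient_factors(I, params, o)

                def out_of(means=None, variances=None, weights=None):
                    q = params.copy()
                    if means is not None:
                        q.means = means.reshape(q.means.shape)
                    if variances is not None:
                        q.variances = variances.reshape(q.variances.shape)
                    if weights is not None:
                        q.weights = weights.reshape(q.weights.shape)
                    return forward(I, q)[o - 1]

                fd_m = finite_difference_grad(
                    lambda x: out_of(means=x), params.means.ravel().copy())
                fd_v = finite_difference_grad(
                    lambda x: out_of(variances=x),
                    params.variances.ravel().copy())
                np.testing.assert_allclose(P_m.ravel(), fd_m, rtol=1e-5,
                                           atol=1e-8)
                np.testing.assert_allclose(P_v.ravel(), fd_v, rtol=1e-5,
                                           atol=1e-8)


class TestUpdateStep:
    def test_zero_error_leaves_params_unchanged(self):
        rng = np.random.default_rng(23)
        shape, params, I, _ = random_small_net(rng)
        d = forward(I, params)  # zero error by construction
        out = update_step(I, d, params, TrainConfig())
        np.testing.assert_array_equal(out.weights, params.weights)
        np.testing.assert_array_equal(out.means, params.means)
        np.testing.assert_array_equal(out.variances, params.variances)

    def test_single_rule_weight_delta(self):
        shape = NetworkShape(1, 1, 1, 1)
        # r_11 = exp(-1) scaled setup: choose I - m = 0 so r = 1, then
        # rescale weight to make r*w produce error exactly 1 with r = 0.5.
        params = NetworkParams(
            shape=shape,
            means=np.array([[[0.0]]]),
            variances=np.array([[[1.0 / math.sqrt(math.log(2.0))]]]),
            weights=np.array([[[0.0]]]),
        )
        I = np.array([1.0])  # exp(-log 2) = 0.5 activation
        assert receptive_field(I, params)[0, 0] == pytest.approx(0.5)
        cfg = TrainConfig(eta_w=0.1, eta_m=0.0, eta_v=0.0)
        out = update_step(I, np.array([1.0]), params, cfg)
        assert out.weights[0, 0, 0] == pytest.approx(0.05, rel=1e-12)

    def test_deltas_descend_cost_via_finite_differences(self):
        rng = np.random.default_rng(29)
        cfg = TrainConfig(eta_w=0.07, eta_m=0.03, eta_v=0.02)
        for _ in range(10):
            shape, params, I, d = random_small_net(rng)
            out = update_step(I, d, params, cfg)

            def cost_of(means=None, variances=None, weights=None):
                q = params.copy()
                if means is not None:
                    q.means = means.reshape(q.means.shape)
                if variances is not None:
                    q.variances = variances.reshape(q.variances.shape)
                if weights is not None:
                    q.weights = weights.reshape(q.weights.shape)
                return cost(d, forward(I, q))

            fd_w = finite_difference_grad(
                lambda x: cost_of(weights=x), params.weights.ravel().copy())
            np.testing.assert_allclose(
                (out.weights - params.weights).ravel(), -cfg.eta_w * fd_w,
                rtol=1e-5, atol=1e-8)
            fd_m = finite_difference_grad(
                lambda x: cost_of(means=x), params.means.ravel().copy())
            np.testing.assert_allclose(
                (out.means - params.means).ravel(), -cfg.eta_m * fd_m,
                rtol=1e-5, atol=1e-8)
            fd_v = finite_difference_grad(
                lambda x: cost_of(variances=x),
                params.variances.ravel().copy())
            np.testing.assert_allclose(
                (out.variances - params.variances).ravel(), -cfg.eta_v * fd_v,
                rtol=1e-5, atol=1e-8)


class TestLearningRateTheory:
    def test_rate_bound_examples(self):
        assert rate_bound(np.array([1.0])) == 2.0
        assert rate_bound(np.array([1.0, 1.0])) == 1.0
        P = np.array([0.3, -0.4, 1.1])
        assert rate_bound(math.sqrt(2) * P) == pytest.approx(
            rate_bound(P) / 2)
        with pytest.raises(DegenerateGradientError):
            rate_bound(np.zeros(3))

    def test_optimal_rate_is_half_bound(self):
        assert optimal_rate(np.array([1.0])) == 1.0
        assert optimal_rate(np.array([1.0, 1.0])) == 0.5
        P = np.array([0.2, 0.9])
        assert optimal_rate(P) == pytest.approx(rate_bound(P) / 2)

    def test_delta_lyapunov_sign_structure(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            P = rng.normal(0, 1, rng.integers(1, 6))
            if np.allclose(P, 0):
                continue
            e = rng.normal(0, 2)
            bound = rate_bound(P)
            etas = np.linspace(bound / 101, bound * 100 / 101, 100)
            dV = np.array([delta_lyapunov(e, eta, P) for eta in etas])
            if e != 0:
                assert np.all(dV < 0)
            assert delta_lyapunov(e, bound, P) == pytest.approx(0.0, abs=1e-12)
            assert delta_lyapunov(e, bound * 1.5, P) >= 0.0
            assert delta_lyapunov(e, optimal_rate(P), P) == pytest.approx(
                -e**2 / 2)
            assert delta_lyapunov(e, 1e-12, P) == pytest.approx(0.0, abs=1e-9)

    def test_weight_step_contracts_error_inside_bound(self):
        """Single-sample, single-output, weight-only update: the new error is
        e(1 - eta ||r||^2), so it contracts for eta in (0, bound) and
        vanishes at the optimal rate."""
        rng = np.random.default_rng(37)
        for _ in range(10):
            shape, params, I, _ = random_small_net(rng)
            d = forward(I, params) + rng.normal(0, 1, shape.n_o)
            r = receptive_field(I, params)
            bound = rate_bound(r)
            for eta in (0.25 * bound, 0.5 * bound, 0.9 * bound):
                cfg = TrainConfig(eta_w=eta, eta_m=0.0, eta_v=0.0)
                out = update_step(I, d, params, cfg)
                e0 = d - forward(I, params)
                e1 = d - forward(I, out)
                assert np.all(np.abs(e1) <= np.abs(e0) + 1e-12)
                np.testing.assert_allclose(
                    e1, e0 * (1 - eta * float(np.sum(r**2))), atol=1e-10)
            cfg = TrainConfig(eta_w=optimal_rate(r), eta_m=0.0, eta_v=0.0)
            out = update_step(I, d, params, cfg)
            np.testing.assert_allclose(d - forward(I, out), 0.0, atol=1e-10)


class TestTrain:
    def test_one_hot_targets(self):
        D = one_hot_targets([2, 1, 3], 3)
        np.testing.assert_array_equal(
            D, [[0, 1, 0], [1, 0, 0], [0, 0, 1]])
        with pytest.raises(DimensionError):
            one_hot_targets([4], 3)

    def test_infinite_tolerance_stops_after_one_epoch(self):
        X = np.array([[0.1, 0.9], [0.8, 0.2]])
        cfg = TrainConfig(seed=1, cost_tol=np.inf)
        _, trace = train(X, [1, 2], NetworkShape(2, 2, 2, 2), cfg)
        assert trace.epochs_run == 1 and trace.converged

    def test_training_reduces_cost_and_is_deterministic(self):
        rng = np.random.default_rng(41)
        X = rng.uniform(0, 1, (4, 3))
        labels = [1, 2, 3, 1]
        shape = NetworkShape(3, 2, 3, 3)
        cfg = TrainConfig(seed=9, max_epochs=300, cost_tol=1e-4)
        p1, t1 = train(X, labels, shape, cfg)
        p2, t2 = train(X, labels, shape, cfg)
        assert t1.costs == t2.costs
        np.testing.assert_array_equal(p1.weights, p2.weights)
        assert t1.costs[-1] < t1.costs[0]

    def test_divergence_guard_raises(self):
        X = np.array([[0.0], [1.0]])
        # unit-width Gaussians keep every activation above exp(-1), so a
        # rate far beyond 2/||r||^2 must blow the cost past the guard
        cfg = TrainConfig(eta_w=1e3, eta_m=0.0, eta_v=0.0, seed=0,
                          max_epochs=50, variance_range=(1.0, 1.0))
        with pytest.raises(DivergenceError):
            train(X, [1, 2], NetworkShape(1, 1, 2, 2), cfg)

    def test_model_round_trip(self, tmp_path):
        X = np.array([[0.2, 0.4], [0.9, 0.1]])
        shape = NetworkShape(2, 2, 2, 2)
        cfg = TrainConfig(seed=3, max_epochs=5, cost_tol=0.0)
        params, _ = train(X, [1, 2], shape, cfg)
        path = tmp_path / "model.json"
        save_model(params, path, extra={"score_mode": "score2"})
        loaded, extras = load_model(path)
        np.testing.assert_allclose(loaded.weights, params.weights)
        np.testing.assert_allclose(loaded.means, params.means)
        assert extras["score_mode"] == "score2"
        I = np.array([0.5, 0.5])
        np.testing.assert_allclose(forward(I, loaded), forward(I, params))
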