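"""Network forward pass, Jacobian, LM machinery, training, label codec."""

import math

import numpy as np
import pytest

from facemyo.lmbp import (
    LabelCodec,
    NetworkLayout,
    NetworkWeights,
    TrainingConfig,
    forward,
    init_network,
    jacobian,
    lm_update,
    mse_error,
    predict,
    residuals,
    train_adam,
    train_lmbp,
)
from facemyo.synth_emg import ActionClass


def random_problem(seed, n_in=None, n_hid=None, n_out=None, m=None):
    rng = np.random.default_rng(seed)
    layout = NetworkLayout(
        n_input=n_in or int(rng.integers(1, 5)),
        n_hidden=n_hid or int(rng.integers(1, 5)),
        n_output=n_out or int(rng.integers(1, 4)),
    )
    net = init_network(layout, seed=seed)
    M = m or int(rng.integers(1, 7))
    X = rng.standard_normal((M, layout.n_input))
    Y = rng.uniform(0, 1, (M, layout.n_output))
    return net, X, Y


class TestInit:
    def test_same_seed_identical_weights(self):
        a = init_network(seed=5)
        b = init_network(seed=5)
        np.testing.assert_array_equal(a.to_vector(), b.to_vector())

    def test_default_layout_shapes(self):
        net = init_network(seed=0)
        assert net.W1.shape == (16, 12)
        assert net.b1.shape == (16,)
        assert net.W2.shape == (2, 16)
        assert net.b2.shape == (2,)
        assert net.n_params == 16 * 12 + 16 + 2 * 16 + 2

    def test_different_seeds_differ(self):
        a = init_network(seed=0)
        b = init_network(seed=1)
        assert np.max(np.abs(a.to_vector() - b.to_vector())) > 0


class TestForward:
    def test_zero_weights_give_half_everywhere(self):
        layout = NetworkLayout(n_input=3, n_hidden=4, n_output=2)
        net = NetworkWeights(layout, np.zeros((4, 3)), np.zeros(4),
                             np.zeros((2, 4)), np.zeros(2))
        O, H = forward(net, np.array([[1.0, -2.0, 3.0]]))
        np.testing.assert_array_equal(H, 0.5 * np.ones((1, 4)))
        np.testing.assert_array_equal(O, 0.5 * np.ones((1, 2)))

    def test_outputs_in_open_unit_interval(self, rng):
        net = init_network(seed=2)
        X = 100 * rng.standard_normal((20, 12))
        O, _ = forward(net, X)
        assert np.all(O > 0) and np.all(O < 1)

    def test_matches_hand_computed_two_node_network(self):
        # 1-1-1 network worked by hand: s1 = 2x - 1, h = sigmoid(s1),
        # s2 = 4h - 2, o = sigmoid(s2), evaluated at x = 1.
        layout = NetworkLayout(n_input=1, n_hidden=1, n_output=1)
        net = NetworkWeights(layout, np.array([[2.0]]), np.array([-1.0]),
                             np.array([[4.0]]), np.array([-2.0]))
        h_expected = 1 / (1 + math.exp(-1.0))
        o_expected = 1 / (1 + math.exp(-(4 * h_expected - 2)))
        O, H = forward(net, np.array([[1.0]]))
        assert H[0, 0] == pytest.approx(h_expected, rel=1e-12)
        assert O[0, 0] == pytest.approx(o_expected, rel=1e-12)

    def test_nan_input_rejected(self):
        net = init_network(seed=0)
        X = np.full((1, 12), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            forward(net, X)


class TestError:
    def test_outputs_equal_targets_zero_error(self):
        net, X, _ = random_problem(0)
        O, _ = forward(net, X)
        assert mse_error(net, X, O) == 0.0

    def test_half_residual_example(self):
        # one sample, output - target = (0.5, 0.5) -> E = 0.25
        layout = NetworkLayout(n_input=1, n_hidden=1, n_output=2)
        net = NetworkWeights(layout, np.zeros((1, 1)), np.zeros(1),
                             np.zeros((2, 1)), np.zeros(2))
        Y = np.array([[0.0, 0.0]])  # outputs are (0.5, 0.5)
        assert mse_error(net, np.array([[0.0]]), Y) == pytest.approx(0.25)

    def test_matches_direct_summation_oracle(self, rng):
        net, X, Y = random_problem(7, m=10)
        O, _ = forward(net, X)
        expected = 0.5 * sum(
            np.sum((O[i] - Y[i]) ** 2) for i in range(len(X))
        )
        assert mse_error(net, X, Y) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        net, X, Y = random_problem(1)
        with pytest.raises(ValueError):
            mse_error(net, X, Y[:, :-1] if Y.shape[1] > 1 else Y[:-1])


class TestJacobian:
    @pytest.mark.parametrize("seed", range(50))
    def test_gradient_matches_central_differences(self, seed):
        net, X, Y = random_problem(seed)
        J = jacobian(net, X)
        e = residuals(net, X, Y)
        grad = J.T @ e
        q = net.to_vector()
        h = 1e-6
        fd = np.empty_like(q)
        for p in range(len(q)):
            qp, qm = q.copy(), q.copy()
            qp[p] += h
            qm[p] -= h
            fd[p] = (
                mse_error(net.with_vector(qp), X, Y)
                - mse_error(net.with_vector(qm), X, Y)
            ) / (2 * h)
        denom = max(np.linalg.norm(fd), 1e-12)
        assert np.linalg.norm(grad - fd) / denom < 1e-5

    def test_zero_residuals_zero_gradient(self):
        net, X, _ = random_problem(3)
        O, _ = forward(net, X)
        grad = jacobian(net, X).T @ residuals(net, X, O)
        np.testing.assert_allclose(grad, 0, atol=1e-14)

    def test_linear_harness_recovers_least_squares_jacobian(self, rng):
        # Identity activations with W1 = I reduce the network to the
        # linear model o = W2 x + b2; with residuals e = output - target
        # the W2/b2 Jacobian block is the classical design matrix [X, 1].
        layout = NetworkLayout(n_input=3, n_hidden=3, n_output=1,
                               hidden_activation="identity",
                               output_activation="identity")
        net = NetworkWeights(layout, np.eye(3), np.zeros(3),
                             rng.standard_normal((1, 3)), np.zeros(1))
        X = rng.standard_normal((8, 3))
        J = jacobian(net, X)
        w2_cols = slice(3 * 3 + 3, 3 * 3 + 3 + 3)
        np.testing.assert_allclose(J[:, w2_cols], X, rtol=1e-12)
        np.testing.assert_allclose(J[:, -1], 1.0, rtol=1e-12)


class TestLmUpdate:
    def test_zero_residuals_zero_step(self, rng):
        J = rng.standard_normal((10, 4))
        dq = lm_update(J, np.zeros(10), mu=1e-3)
        np.testing.assert_allclose(dq, 0, atol=1e-14)

    def test_large_mu_gives_scaled_gradient_step(self, rng):
        J = rng.standard_normal((20, 5))
        e = rng.standard_normal(20)
        mu = 1e8
        dq = lm_update(J, e, mu)
        expected = -(J.T @ e) / mu
        rel = np.linalg.norm(dq - expected) / np.linalg.norm(expected)
        assert rel < 1e-6

    def test_tiny_mu_gives_gauss_newton_step(self, rng):
        # Full-rank linear least-squares: the Gauss-Newton step from q=0
        # with residual e = -y is the least-squares solution itself.
        A = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        dq = lm_update(A, -y, mu=1e-12)
        expected, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(dq, expected, rtol=1e-6)

    def test_non_positive_mu_rejected(self, rng):
        with pytest.raises(ValueError):
            lm_update(rng.standard_normal((4, 2)), np.zeros(4), mu=0.0)


class TestTrainLmbp:
    def test_xor_separable_for_most_seeds(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        Y = np.array([[0.0], [1.0], [1.0], [0.0]])
        layout = NetworkLayout(n_input=2, n_hidden=2, n_output=1)
        config = TrainingConfig(max_epochs=200, goal=1e-3)
        successes = 0
        for seed in range(10):
            net, trace = train_lmbp(init_network(layout, seed=seed), X, Y, config)
            if trace.final_error < 1e-3:
                successes += 1
        assert successes >= 9

    def test_converged_network_stops_immediately(self):
        net, X, _ = random_problem(4)
        O, _ = forward(net, X)
        trained, trace = train_lmbp(net, X, O)
        assert trace.n_epochs <= 1
        assert trace.termination in ("goal_reached", "update_tolerance")
        if trace.step_norms:
            assert trace.step_norms[-1] < 1e-6
        np.testing.assert_array_equal(trained.to_vector(), net.to_vector())

    def test_accepted_steps_strictly_decrease_error(self):
        net, X, Y = random_problem(11, m=20)
        _, trace = train_lmbp(net, X, Y, TrainingConfig(max_epochs=50))
        errors = [trace.initial_error] + trace.errors
        terminal_plateau = 1 if trace.termination == "update_tolerance" else 0
        diffs = np.diff(errors)
        # every accepted epoch decreases E; a terminal tolerance epoch
        # records the unchanged error
        assert np.all(diffs[: len(diffs) - terminal_plateau] < 0)

    def test_training_is_reproducible(self, fft_table):
        from facemyo.features import FeatureScaler

        table, y = fft_table
        X = FeatureScaler().fit_transform(table.to_numpy()[:48])
        Y = LabelCodec.encode(y[:48])
        runs = []
        for _ in range(2):
            net, trace = train_lmbp(
                init_network(seed=3), X, Y, TrainingConfig(max_epochs=40)
            )
            runs.append((trace.final_error, trace.n_epochs, net.to_vector()))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]
        np.testing.assert_array_equal(runs[0][2], runs[1][2])

    def test_full_training_reaches_100_percent_on_synthetic(self, fft_table):
        from facemyo.features import FeatureScaler

        table, y = fft_table
        X = FeatureScaler().fit_transform(table.to_numpy())
        net, _ = train_lmbp(
            init_network(seed=0), X, LabelCodec.encode(y),
            TrainingConfig(max_epochs=100),
        )
        pred = predict(net, X)
        assert all(p is t for p, t in zip(pred, y))


class TestTrainAdam:
    def test_zero_gradient_start_leaves_weights_unchanged(self):
        net, X, _ = random_problem(9)
        O, _ = forward(net, X)
        trained, _ = train_adam(net, X, O, TrainingConfig(max_epochs=5, goal=0.0))
        np.testing.assert_array_equal(trained.to_vector(), net.to_vector())

    def test_deterministic_under_fixed_seed(self):
        net, X, Y = random_problem(13, m=12)
        a, ta = train_adam(net, X, Y, TrainingConfig(max_epochs=30))
        b, tb = train_adam(net, X, Y, TrainingConfig(max_epochs=30))
        np.testing.assert_array_equal(a.to_vector(), b.to_vector())
        assert ta.errors == tb.errors

    def test_lmbp_reaches_lower_error_at_equal_budget(self):
        net, X, Y = random_problem(21, n_in=4, n_hid=6, n_out=2, m=40)
        config = TrainingConfig(max_epochs=100)
        _, trace_lm = train_lmbp(net, X, Y, config)
        _, trace_adam = train_adam(net, X, Y, config)
        assert trace_adam.final_error >= trace_lm.final_error


class TestLabelCodec:
    def test_paper_bit_assignments(self):
        assert tuple(LabelCodec.encode(ActionClass.FURROWING_BROW)) == (0, 0)
        assert tuple(LabelCodec.encode(ActionClass.RAISING_BROW)) == (0, 1)
        assert tuple(LabelCodec.encode(ActionClass.LEFT_SMIRKING)) == (1, 0)
        assert tuple(LabelCodec.encode(ActionClass.RIGHT_SMIRKING)) == (1, 1)

    def test_round_trip_all_actions(self):
        for action in ActionClass:
            bits = LabelCodec.encode(action)
            assert LabelCodec.decode_bits(bits) is action

    def test_predict_thresholds_outputs(self):
        # Force outputs near (0.9, 0.1) -> bits (1, 0) -> left smirking,
        # and (0.1, 0.2) -> bits (0, 0) -> furrowing brow.
        layout = NetworkLayout(n_input=1, n_hidden=1, n_output=2)

        def net_for(bias):
            return NetworkWeights(layout, np.zeros((1, 1)), np.zeros(1),
                                  np.zeros((2, 1)), np.asarray(bias, dtype=float))

        x = np.array([[0.0]])
        high, low = 3.0, -3.0  # sigmoid -> ~0.95 / ~0.05
        assert predict(net_for([high, low]), x) == [ActionClass.LEFT_SMIRKING]
        assert predict(net_for([low, low]), x) == [ActionClass.FURROWING_BROW]
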