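"""Gated recurrent cell, variance activation, analytic gradients and training."""

import numpy as np
import pytest
from scipy.special import expit

from varitrack.learner import (
    _BLOCKS,
    CellState,
    GradOptState,
    ModelParams,
    RecurrentVarianceClassifier,
    TrainConfig,
    abnormality_gradient,
    backward_batch,
    cell_step,
    forward_batch,
    forward_sequence,
    grad_gamma,
    init_params,
    loss,
    train,
    update_parameters,
    variance_activation,
    variance_layer,
)


def zero_params(F=2, H=2):
    p = init_params(F, H, rng=0)
    for name in _BLOCKS:
        setattr(p, name, np.zeros_like(getattr(p, name)))
    return p


class TestCellStep:
    def test_zero_weights_closed_form(self):
        p = zero_params()
        s = cell_step(p, np.array([0.3, -0.4]), CellState.zero(2))
        np.testing.assert_allclose(s.gate_i, 0.5)
        np.testing.assert_allclose(s.gate_d, 0.5)
        np.testing.assert_allclose(s.gate_b, 0.5)
        np.testing.assert_allclose(s.candidate, 0.0)
        np.testing.assert_allclose(s.c, 0.0)
        np.testing.assert_allclose(s.a, 0.0)

    def test_forget_open_input_closed_preserves_cell(self):
        p = zero_params()
        p.b_f = np.full(2, 30.0)   # forget gate ~= 1
        p.b_i = np.full(2, -30.0)  # input gate ~= 0
        state = CellState(a=np.zeros(2), c=np.array([0.7, -1.2]))
        out = cell_step(p, np.array([0.1, 0.2]), state)
        np.testing.assert_allclose(out.c, state.c, atol=1e-9)

    def test_matches_hand_unrolled_computation(self):
        rng = np.random.default_rng(77)
        p = init_params(2, 2, rng=rng)
        X = rng.normal(size=(3, 2))
        state = CellState.zero(2)
        a, c = np.zeros(2), np.zeros(2)
        for t in range(3):
            x = X[t]
            d = expit(p.W_fx @ x + p.W_fa @ a + p.W_fc @ c + p.b_f)
            i = expit(p.W_ix @ x + p.W_ia @ a + p.W_ic @ c + p.b_i)
            ch = np.tanh(p.W_cx @ x + p.W_ca @ a + p.b_c)
            c = i * ch + d * c
            b = expit(p.W_ox @ x + p.W_oa @ a + p.W_oc @ c + p.b_o)
            a = b * np.tanh(c)
            state = cell_step(p, x, state)
            np.testing.assert_allclose(state.a, a, atol=1e-12)
            np.testing.assert_allclose(state.c, c, atol=1e-12)

    def test_gates_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(5)
        p = init_params(3, 4, rng=rng)
        s = CellState.zero(4)
        for x in rng.normal(size=(20, 3)):
            s = cell_step(p, x, s)
            for g in (s.gate_i, s.gate_d, s.gate_b):
                assert np.all((g > 0) & (g < 1))

    def test_cell_state_bounded_by_step_count(self):
        rng = np.random.default_rng(6)
        p = init_params(3, 4, rng=rng)
        s = CellState.zero(4)
        for t, x in enumerate(rng.normal(size=(30, 3)), start=1):
            s = cell_step(p, x, s)
            assert np.max(np.abs(s.c)) <= t + 1e-12

    def test_shape_and_finite_errors(self):
        p = init_params(2, 2, rng=0)
        with pytest.raises(ValueError):
            cell_step(p, np.ones(3), CellState.zero(2))
        with pytest.raises(FloatingPointError):
            cell_step(p, np.array([np.nan, 0.0]), CellState.zero(2))


class TestVarianceActivation:
    def test_zero_maps_to_zero_for_any_gamma(self):
        for g in (0.0, 0.25, 5.0, -1.0):
            assert variance_activation(0.0, g) == 0.0

    def test_unit_leak_is_identity(self, rng):
        a = rng.normal(size=100)
        np.testing.assert_array_equal(variance_activation(a, 1.0), a)

    def test_negative_branch_arithmetic(self):
        assert variance_activation(-2.0, 0.25) == pytest.approx(-0.5)

    @pytest.mark.parametrize("gamma", [0.0, 0.25, 1.0])
    def test_two_layer_forms_agree_on_grid(self, gamma):
        a = np.linspace(-5, 5, 10001)
        np.testing.assert_array_equal(
            variance_activation(a, gamma), variance_layer(a, gamma)
        )

    def test_continuous_at_zero(self):
        eps = np.array([-1e-12, 0.0, 1e-12])
        out = variance_activation(eps, 0.25)
        assert np.all(np.abs(out) <= 1e-12)

    def test_positive_branch_gamma_independent(self):
        a = np.array([0.1, 2.0])
        np.testing.assert_array_equal(variance_layer(a, 0.0), variance_layer(a, 9.0))

    def test_pure_rectifier_limit(self):
        assert variance_layer(-1.0, 0.0) == 0.0

    def test_monotone_for_nonnegative_gamma(self, rng):
        a = np.sort(rng.normal(size=200))
        out = variance_activation(a, 0.3)
        assert np.all(np.diff(out) >= 0)


class TestForward:
    def test_zero_params_give_half_scores(self):
        p = zero_params()
        _, scores = forward_sequence(p, np.ones((4, 2)))
        np.testing.assert_allclose(scores, 0.5)

    def test_score_count_matches_length(self):
        p = init_params(3, 2, rng=1)
        _, scores = forward_sequence(p, np.zeros((7, 3)))
        assert scores.shape == (7,)
        assert np.all((scores > 0) & (scores < 1))

    def test_batch_matches_sequence_forward(self, rng):
        p = init_params(2, 3, rng=2)
        X = rng.normal(size=(2, 5, 2))
        cache = forward_batch(p, X)
        for b in range(2):
            states, scores = forward_sequence(p, X[b])
            np.testing.assert_allclose(cache.scores[b], scores, atol=1e-12)
            np.testing.assert_allclose(cache.A[b, -1], states[-1].a, atol=1e-12)

    def test_padding_does_not_change_valid_scores(self, rng):
        p = init_params(2, 3, rng=3)
        x = rng.normal(size=(4, 2))
        full = forward_batch(p, x[None])
        padded = np.zeros((1, 6, 2))
        padded[0, :4] = x
        mask = np.zeros((1, 6), dtype=bool)
        mask[0, :4] = True
        part = forward_batch(p, padded, mask)
        np.testing.assert_allclose(part.scores[0, :4], full.scores[0], atol=1e-12)


class TestLoss:
    def test_perfect_scores_zero(self):
        assert loss(np.array([0.0, 1.0]), np.array([0.0, 1.0])) == 0.0

    def test_half_scores_balanced_quarter(self):
        s = np.full(10, 0.5)
        y = np.array([0, 1] * 5, dtype=float)
        assert loss(s, y) == pytest.approx(0.25)

    def test_matches_brute_force_loop(self, rng):
        s = rng.uniform(0, 1, size=37)
        y = rng.integers(0, 2, size=37).astype(float)
        brute = sum((a - b) ** 2 for a, b in zip(s, y)) / 37
        assert loss(s, y) == pytest.approx(brute, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            loss(np.zeros(3), np.zeros(4))


class TestGradGamma:
    def test_zero_for_all_positive_preactivations(self):
        p = init_params(2, 2, rng=4)
        cache = forward_batch(p, np.zeros((1, 3, 2)))
        cache.A = np.abs(cache.A) + 0.1
        g = grad_gamma(cache, np.ones_like(cache.A))
        np.testing.assert_array_equal(g, np.zeros(2))

    def test_single_negative_unit_one_term(self):
        p = init_params(1, 1, rng=0)
        cache = forward_batch(p, np.zeros((1, 1, 1)))
        cache.A = np.array([[[-2.0]]])
        g = grad_gamma(cache, np.ones((1, 1, 1)))
        assert g[0] == pytest.approx(-2.0)

    def test_missing_cache_raises(self):
        with pytest.raises(RuntimeError):
            grad_gamma(None, np.zeros(1))


class TestGradientsAgainstFiniteDifferences:
    """The central oracle: every analytic gradient block equals central
    finite differences on seeded 2-unit / 3-step / 2-record instances."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("kind", ["mse", "xent"])
    def test_all_blocks(self, seed, kind):
        rng = np.random.default_rng(seed)
        p = init_params(2, 2, rng=rng)
        p.gamma = rng.uniform(0.1, 0.9, 2)
        X = rng.normal(size=(2, 3, 2))
        Y = rng.integers(0, 2, size=(2, 3)).astype(float)

        cache = forward_batch(p, X)
        grads = backward_batch(p, cache, Y, kind)

        h = 1e-6
        for name in _BLOCKS:
            flat = np.atleast_1d(getattr(p, name)).ravel()
            fd = np.empty(flat.size)
            for k in range(flat.size):
                orig = flat[k]
                flat[k] = orig + h
                lp = loss(forward_batch(p, X).scores, Y, kind)
                flat[k] = orig - h
                lm = loss(forward_batch(p, X).scores, Y, kind)
                flat[k] = orig
                fd[k] = (lp - lm) / (2 * h)
            analytic = np.atleast_1d(grads[name]).ravel()
            # atol 1e-8 is the oracle's own roundoff floor (~|R| * eps / h)
            np.testing.assert_allclose(analytic, fd, rtol=1e-5, atol=1e-8,
                                       err_msg=f"block {name}")

    def test_readout_gradient_one_step_hand_derivation(self):
        """1-step chain rule: dR/du = 2(s-y) s(1-s) F(a)."""
        rng = np.random.default_rng(9)
        p = init_params(2, 2, rng=rng)
        X = rng.normal(size=(1, 1, 2))
        Y = np.array([[1.0]])
        cache = forward_batch(p, X)
        s = cache.scores[0, 0]
        expected = 2 * (s - 1.0) * s * (1 - s) * cache.Fh[0, 0]
        du, db = abnormality_gradient(cache, Y)
        np.testing.assert_allclose(du, expected, atol=1e-12)
        assert db == pytest.approx(2 * (s - 1.0) * s * (1 - s))

    def test_zero_upstream_gives_zero_gradients(self):
        p = init_params(2, 2, rng=1)
        X = np.zeros((1, 2, 2))
        cache = forward_batch(p, X)
        grads = backward_batch(p, cache, cache.scores.copy())  # labels = scores
        for name in _BLOCKS:
            np.testing.assert_allclose(np.atleast_1d(grads[name]), 0.0, atol=1e-15)


class TestUpdateParameters:
    def test_zero_gradient_zero_momentum_fixed_point(self):
        p = init_params(2, 2, rng=2)
        before = p.copy()
        grads = {n: np.zeros_like(getattr(p, n)) for n in _BLOCKS}
        update_parameters(p, grads, GradOptState(), TrainConfig())
        for n in _BLOCKS:
            np.testing.assert_array_equal(getattr(p, n), getattr(before, n))

    def test_plain_gradient_descent_limit(self):
        """With no momentum and J >> c the step approaches lr * g."""
        p = init_params(1, 1, rng=0)
        cfg = TrainConfig(learning_rate=0.1, momentum=0.0, sq_decay=0.0, damping=1e-12)
        g = {n: np.ones_like(getattr(p, n)) for n in _BLOCKS}
        before = p.copy()
        update_parameters(p, g, GradOptState(), cfg)
        for n in _BLOCKS:
            np.testing.assert_allclose(
                getattr(before, n) - getattr(p, n), 0.1, rtol=1e-9
            )

    def test_matches_scripted_reference_loop(self):
        """10 scalar updates equal an independently coded reference loop."""
        cfg = TrainConfig(learning_rate=0.3, momentum=0.8, sq_decay=0.7, damping=0.05)
        rng = np.random.default_rng(11)
        gs = rng.normal(size=10)

        # reference loop, plain floats
        pref, m, J = 1.0, 0.0, 0.0
        for g in gs:
            m = 0.8 * m + 0.3 * g
            J = 0.7 * J + 0.3 * g * g
            pref -= m * J / (0.05 + J)

        p = init_params(1, 1, rng=0)
        p.b_out = np.array(1.0)
        opt = GradOptState()
        for g in gs:
            grads = {n: np.zeros_like(getattr(p, n)) for n in _BLOCKS}
            grads["b_out"] = np.array(g)
            update_parameters(p, grads, opt, cfg)
        assert float(p.b_out) == pytest.approx(pref, abs=1e-12)

    def test_accumulator_invariants(self):
        p = init_params(2, 2, rng=3)
        opt = GradOptState()
        rng = np.random.default_rng(0)
        for _ in range(5):
            grads = {n: rng.normal(size=getattr(p, n).shape) for n in _BLOCKS}
            update_parameters(p, grads, opt, TrainConfig())
        for n in _BLOCKS:
            assert np.all(opt.J[n] >= 0)

    def test_non_finite_gradient_names_block(self):
        p = init_params(2, 2, rng=4)
        grads = {n: np.zeros_like(getattr(p, n)) for n in _BLOCKS}
        grads["W_ia"] = np.full_like(p.W_ia, np.nan)
        with pytest.raises(FloatingPointError, match="W_ia"):
            update_parameters(p, grads, GradOptState(), TrainConfig())


class TestTrain:
    def make_toy(self):
        """Linearly separable one-feature toy: label = 1 iff input > 0.5."""
        rng = np.random.default_rng(21)
        X, Y = [], []
        for _ in range(6):
            x = rng.uniform(0, 1, size=(15, 1))
            X.append(x)
            Y.append((x[:, 0] > 0.5).astype(float))
        return X, Y

    def test_zero_epochs_leaves_params_unchanged(self):
        X, Y = self.make_toy()
        p = init_params(1, 2, rng=0)
        before = p.copy()
        trained, trace = train(p, X, Y, TrainConfig(epochs=0))
        assert len(trace) == 1
        for n in _BLOCKS:
            np.testing.assert_array_equal(getattr(trained, n), getattr(before, n))

    def test_separable_toy_reaches_full_accuracy(self):
        X, Y = self.make_toy()
        p = init_params(1, 2, rng=0)
        trained, trace = train(p, X, Y, TrainConfig(epochs=200, learning_rate=1.0))
        assert trace[-1] <= trace[0]
        correct = total = 0
        for x, y in zip(X, Y):
            _, scores = forward_sequence(trained, x)
            correct += int(np.sum((scores > 0.5) == (y > 0.5)))
            total += len(y)
        assert correct == total

    def test_same_seed_identical_loss_trace(self):
        X, Y = self.make_toy()
        t1 = train(init_params(1, 2, rng=5), X, Y, TrainConfig(epochs=20))[1]
        t2 = train(init_params(1, 2, rng=5), X, Y, TrainConfig(epochs=20))[1]
        assert t1 == t2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(init_params(1, 2, rng=0), [], [], TrainConfig())


class TestEstimator:
    def test_fit_predict_shapes_and_sklearn_protocol(self):
        X, Y = TestTrain().make_toy()
        clf = RecurrentVarianceClassifier(hidden_size=2, epochs=10)
        assert clf.get_params()["hidden_size"] == 2
        clf.set_params(epochs=5)
        clf.fit(X, Y)
        preds = clf.predict(X)
        assert len(preds) == len(X)
        assert all(p.shape == y.shape for p, y in zip(preds, Y))
        assert all(set(np.unique(p)) <= {0, 1} for p in preds)

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            RecurrentVarianceClassifier().predict([np.zeros((2, 1))])

    def test_model_json_round_trip(self, tmp_path):
        p = init_params(3, 2, rng=8)
        path = tmp_path / "model.json"
        p.save(path)
        q = ModelParams.load(path)
        for n in _BLOCKS:
            np.testing.assert_array_equal(getattr(p, n), getattr(q, n))
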