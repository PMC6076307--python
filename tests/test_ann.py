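"""Network forward pass, Levenberg–Marquardt training and model selection."""

import math

import numpy as np
import pytest

from edslung import ann
from edslung.errors import ConfigurationError, DataValidationError


def naive_forward(w: ann.NetworkWeights, x):
    """Independent double-loop oracle for the forward pass."""
    N, R = w.n_hidden, w.n_outputs
    ho = []
    for n in range(N):
        s = w.Hb[n]
        for i in range(w.n_inputs):
            s += w.Iw[i, n] * x[i]
        ho.append(math.tanh(s))
    y = []
    for r in range(R):
        s = w.Ob[r]
        for n in range(N):
            s += w.Hw[n, r] * ho[n]
        y.append(s)
    return np.array(ho), np.array(y)


class TestForward:
    def test_zero_network_outputs_zero(self):
        w = ann.NetworkWeights(np.zeros((5, 3)), np.zeros(3), np.zeros((3, 1)), np.zeros(1))
        tr = ann.forward(w, [0.2, 0.4, 0.6, 0.8, 1.0])
        assert np.all(tr.hidden == 0)
        assert tr.outputs[0] == 0

    def test_single_neuron_hand_value(self):
        w = ann.NetworkWeights(
            Iw=np.array([[1.0], [0.0], [0.0], [0.0], [0.0]]),
            Hb=np.zeros(1),
            Hw=np.array([[2.0]]),
            Ob=np.array([1.0]),
        )
        y = ann.forward(w, [0.5, 0.1, 0.9, 0.3, 0.7]).outputs[0]
        assert y == pytest.approx(2.0 * math.tanh(0.5) + 1.0)
        assert y == pytest.approx(1.9242343, abs=1e-6)

    def test_matches_naive_double_loop_oracle(self, rng):
        for _ in range(10):
            S, N, R = rng.integers(1, 6), rng.integers(1, 8), rng.integers(1, 4)
            w = ann.init_weights(int(S), int(N), int(R), rng, scale=2.0)
            x = rng.normal(size=int(S))
            tr = ann.forward(w, x)
            ho, y = naive_forward(w, x)
            np.testing.assert_allclose(tr.hidden, ho, rtol=1e-12)
            np.testing.assert_allclose(tr.outputs, y, rtol=1e-12)

    def test_hidden_activations_bounded(self, rng):
        w = ann.init_weights(5, 10, 1, rng, scale=50.0)
        tr = ann.forward(w, rng.normal(size=5) * 100)
        assert np.all(np.abs(tr.hidden) <= 1.0)

    def test_shape_mismatch_rejected(self, small_network):
        with pytest.raises(ConfigurationError):
            ann.forward(small_network, [0.1, 0.2])


class TestPredictClass:
    def _net_with_output(self, value):
        return ann.NetworkWeights(
            np.zeros((5, 1)), np.zeros(1), np.zeros((1, 1)), np.array([float(value)])
        )

    @pytest.mark.parametrize(
        "output, expected",
        [(3.4, "ASTHMA4"), (-0.2, "ASTHMA1"), (12.0, "INCONCLUSIVE"), (8.2, "NORMAL")],
    )
    def test_round_and_clamp(self, output, expected):
        w = self._net_with_output(output)
        assert ann.predict_class(w, [0.0] * 5) == expected


class TestMse:
    def test_zero_for_perfect_predictions(self):
        b = ann.TrainingBatch(np.zeros((3, 2)), np.array([1.0, 2, 3]))
        b.predictions = np.array([1.0, 2, 3])
        assert ann.mse(b) == 0.0

    def test_hand_value(self):
        b = ann.TrainingBatch(np.zeros((2, 2)), np.array([0.0, 0.0]))
        b.predictions = np.array([1.0, 2.0])
        assert ann.mse(b) == pytest.approx(2.5)

    def test_permutation_invariant(self, rng):
        t = rng.normal(size=9)
        p = rng.normal(size=9)
        perm = rng.permutation(9)
        b1 = ann.TrainingBatch(np.zeros((9, 1)), t)
        b1.predictions = p
        b2 = ann.TrainingBatch(np.zeros((9, 1)), t[perm])
        b2.predictions = p[perm]
        assert ann.mse(b1) == pytest.approx(ann.mse(b2))

    def test_unpopulated_predictions_error(self):
        with pytest.raises(DataValidationError):
            ann.mse(ann.TrainingBatch(np.zeros((2, 2)), np.zeros(2)))


class TestJacobian:
    def test_matches_central_finite_differences(self, rng):
        """Analytic residual Jacobian vs central differences, 1e-6 relative."""
        for R in (1, 3):
            w = ann.init_weights(4, 5, R, rng, scale=0.8)
            X = rng.uniform(0, 1, size=(6, 4))
            J = ann.residual_jacobian(w, X)
            theta = w.flatten()
            h = 1e-6
            J_fd = np.empty_like(J)
            for p in range(theta.size):
                tp = theta.copy()
                tp[p] += h
                tm = theta.copy()
                tm[p] -= h
                wp = ann.NetworkWeights.from_flat(tp, 4, 5, R)
                wm = ann.NetworkWeights.from_flat(tm, 4, 5, R)
                _, Yp = ann.forward_batch(wp, X)
                _, Ym = ann.forward_batch(wm, X)
                J_fd[:, p] = ((Yp - Ym) / (2 * h)).ravel()
            np.testing.assert_allclose(J, J_fd, rtol=1e-6, atol=1e-8)


class TestLmaTrain:
    def test_exactly_linear_target_solved_to_machine_precision(self, rng):
        """A target needing zero hidden contribution is linear least squares
        in (Hw, Ob); the damped Gauss–Newton loop must nail it."""
        X = rng.uniform(0, 1, size=(30, 3))
        batch = ann.TrainingBatch(X, np.full(30, -1.3))
        settings = ann.LmaSettings(mse_tol=1e-16, grad_tol=1e-14, max_iter=500)
        w, hist = ann.lma_train(batch, hidden_size=4, seed=0, settings=settings, restarts=1)
        assert hist.mse_per_iteration[-1] < 1e-10

    def test_accepted_step_mse_is_non_increasing(self, rng):
        X = rng.uniform(0, 1, size=(40, 5))
        t = rng.normal(size=40)
        _, hist = ann.lma_train(ann.TrainingBatch(X, t), hidden_size=3, seed=1)
        ms = hist.mse_per_iteration
        assert all(b <= a + 1e-12 for a, b in zip(ms, ms[1:]))

    def test_bit_identical_for_identical_seed(self, rng):
        X = rng.uniform(0, 1, size=(25, 5))
        t = rng.integers(0, 5, size=25).astype(float)
        batch = ann.TrainingBatch(X, t)
        w1, h1 = ann.lma_train(batch, hidden_size=4, seed=11, restarts=2)
        w2, h2 = ann.lma_train(batch, hidden_size=4, seed=11, restarts=2)
        assert np.array_equal(w1.flatten(), w2.flatten())
        assert h1.mse_per_iteration == h2.mse_per_iteration

    def test_large_damping_takes_small_gradient_steps(self, rng):
        """With enormous fixed lambda the update approximates -g/lambda."""
        X = rng.uniform(0, 1, size=(20, 2))
        t = rng.normal(size=20)
        w0 = ann.init_weights(2, 2, 1, np.random.default_rng(3))
        lam = 1e9
        r = ann._residuals(w0, X, t)
        J = ann.residual_jacobian(w0, X)
        g = J.T @ r
        delta = np.linalg.solve(J.T @ J + lam * np.eye(g.size), -g)
        np.testing.assert_allclose(delta, -g / lam, rtol=1e-4)


class TestKfold:
    def test_partition_covers_all_samples_exactly_once(self):
        plan = ann.kfold_plan(23, 5, seed=2)
        seen = np.concatenate([plan.test_indices(f) for f in range(5)])
        assert sorted(seen.tolist()) == list(range(23))
        sizes = [len(plan.test_indices(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_leave_one_out_degenerate_partition(self):
        plan = ann.kfold_plan(5, 5, seed=0)
        assert all(len(plan.test_indices(f)) == 1 for f in range(5))

    def test_same_seed_same_assignment(self):
        a = ann.kfold_plan(50, 10, seed=7).fold_assignments
        b = ann.kfold_plan(50, 10, seed=7).fold_assignments
        assert np.array_equal(a, b)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ConfigurationError):
            ann.kfold_plan(3, 10, seed=0)

    def test_cross_validate_tests_every_sample(self, rng):
        X = rng.uniform(0, 1, size=(30, 5))
        t = rng.integers(0, 3, size=30).astype(float)
        cv = ann.kfold_cross_validate(
            ann.TrainingBatch(X, t), k=3, hidden_size=2, seed=4,
            settings=ann.LmaSettings(max_iter=20),
        )
        assert len(cv.fold_test_mse) == 3
        assert cv.mean_test_mse == pytest.approx(np.mean(cv.fold_test_mse))
        assert np.all(cv.heldout_predictions >= 0)


class TestHiddenSizeSearch:
    def test_single_candidate_selected(self, rng):
        X = rng.uniform(0, 1, size=(20, 5))
        t = rng.integers(0, 3, size=20).astype(float)
        res = ann.hidden_size_search(
            ann.TrainingBatch(X, t), sizes=[3], k=2, seed=0,
            settings=ann.LmaSettings(max_iter=10),
        )
        assert res.selected_size == 3

    def test_parsimony_margin_prefers_smaller_architecture(self):
        # the marginally worse 14-neuron model wins over the best 17-neuron one
        table = [(17, 12.485), (14, 12.569)]
        assert ann.select_size(table, parsimony_margin=0.084) == 14
        assert ann.select_size(table, parsimony_margin=0.0) == 17

    def test_ties_resolve_to_smaller(self):
        assert ann.select_size([(20, 1.0), (5, 1.0)], parsimony_margin=0.0) == 5


class TestCodebook:
    def test_bijective_and_ordered(self):
        cb = ann.DEFAULT_CODEBOOK
        assert len(cb) == 10
        assert cb.code("ASTHMA1") == 0
        assert cb.code("INCONCLUSIVE") == 9
        assert all(cb.code(cb.name(i)) == i for i in range(10))

    def test_unknown_name_rejected(self):
        with pytest.raises(DataValidationError):
            ann.DEFAULT_CODEBOOK.code("EMPHYSEMA")

    def test_onehot_encoding(self):
        T = ann.encode_targets(["ASTHMA1", "NORMAL"], encoding="onehot")
        assert T.shape == (2, 10)
        assert T[0, 0] == 1 and T[1, 8] == 1 and T.sum() == 2
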