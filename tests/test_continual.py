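"""Fisher estimation, consolidation penalties, stability trajectories and
the task transition, against hand computations and closed forms."""

import numpy as np
import pytest

from zoneseg._autograd import Tensor
from zoneseg._nn import Adam, Module, Parameter
from zoneseg.continual import (ImportanceState, TrajectoryBuffer,
                               TransitionConfig, accumulate_fisher,
                               estimate_fisher, ewc_penalty, penalized_step,
                               penalty_term, vewc_penalty)


class ScalarModel(Module):
    """log-likelihood theta * c per sample -> per-sample gradient c."""

    def __init__(self, theta=0.0):
        self.theta = Parameter(np.array([theta]))


class TestFisher:
    def test_hand_example_gradients_one_and_three(self):
        model = ScalarModel()
        samples = [1.0, 3.0]
        fisher = estimate_fisher(
            model, samples,
            loglik_fn=lambda m, c: (m.theta * c).sum())
        assert fisher["theta"][0] == pytest.approx((1 + 9) / 2)  # = 5

    def test_disconnected_parameter_scores_zero(self):
        class TwoParam(Module):
            def __init__(self):
                self.used = Parameter(np.array([0.5]))
                self.unused = Parameter(np.array([0.5]))
        model = TwoParam()
        fisher = estimate_fisher(
            model, [1.0, 2.0],
            loglik_fn=lambda m, c: (m.used * c).sum() + (m.unused * 0.0).sum())
        assert np.all(fisher["unused"] == 0.0)
        assert np.all(fisher["used"] > 0.0)

    def test_bernoulli_logistic_matches_closed_form(self):
        """Empirical Fisher of a 2-parameter logistic model vs the analytic
        Bernoulli Fisher diag E[x_k^2 sigma(1-sigma)], within 5%.

        Design: 20 fixed covariate points, each replicated 25 times
        (N = 500); labels are stratified to the model's conditional
        frequencies so the check isolates estimator correctness from
        label-sampling noise."""
        w_true = np.array([0.8, -0.5])
        pts = np.linspace(-2.0, 2.0, 20)
        reps = 25
        N = 20 * reps
        X = np.repeat(np.column_stack([np.ones(20), pts]), reps, axis=0)
        p_true = 1.0 / (1.0 + np.exp(-X @ w_true))
        y = np.zeros(N)
        for j in range(20):
            n1 = int(round(reps * p_true[j * reps]))
            y[j * reps:j * reps + n1] = 1.0

        class Logistic(Module):
            def __init__(self):
                self.w = Parameter(w_true.copy())
        model = Logistic()

        def loglik(m, i):
            logit = (m.w * X[i]).sum()
            p = 1.0 / (1.0 + (-logit).exp())
            return (p.log() * y[i] + (1.0 - p).log() * (1.0 - y[i]))

        fisher = estimate_fisher(model, list(range(N)), loglik_fn=loglik)
        s = p_true * (1.0 - p_true)
        analytic = np.array([ (X[:, k] ** 2 * s).mean() for k in range(2)])
        assert np.all(np.abs(fisher["w"] - analytic) <= 0.05 * analytic
                      + 0.01)

    def test_accumulation_is_sample_weighted_average(self):
        prior = ImportanceState(theta_old={}, fisher={"w": np.array([2.0])},
                                n_samples=10)
        out = accumulate_fisher(prior, {"w": np.array([6.0])}, n_new=10)
        assert out["w"][0] == pytest.approx(4.0)


class TestPenalties:
    def _state(self, fisher, anchor, lam=2.0, stability=None):
        return ImportanceState(
            theta_old={"theta": np.asarray(anchor, dtype=float)},
            fisher={"theta": np.asarray(fisher, dtype=float)},
            stability=({"theta": np.asarray(stability, dtype=float)}
                       if stability is not None else {}),
            lambda_reg=lam)

    def test_zero_at_anchor(self):
        p = Parameter(np.array([0.3, -0.7]))
        state = self._state([1.0, 4.0], p.data.copy())
        assert ewc_penalty({"theta": p}, state).item() == 0.0
        assert vewc_penalty({"theta": p}, state).item() == 0.0

    def test_hand_evaluation_of_printed_formula(self):
        # lambda=2, F=(1,4), dtheta=(0.5,0.25) -> 1*(1*0.25+4*0.0625) = 0.5
        p = Parameter(np.array([0.5, 0.25]))
        state = self._state([1.0, 4.0], [0.0, 0.0], lam=2.0)
        assert ewc_penalty({"theta": p}, state).item() \
            == pytest.approx(0.5)
        # doubling lambda doubles the penalty
        assert ewc_penalty({"theta": p}, state, lambda_reg=4.0).item() \
            == pytest.approx(1.0)

    def test_vewc_hand_value_and_ewc_reduction(self):
        p = Parameter(np.array([0.5]))
        state = self._state([2.0], [0.0], lam=1.0, stability=[0.0])
        # lambda=1, I=(2,), dtheta=0.5 -> 1 * 2 * 0.25 = 0.5
        assert vewc_penalty({"theta": p}, state).item() \
            == pytest.approx(0.5)
        # S = 0 and the halved flag reproduce the EWC value exactly
        assert vewc_penalty({"theta": p}, state, halved=True).item() \
            == pytest.approx(ewc_penalty({"theta": p}, state).item())

    def test_penalty_is_differentiable_and_convex(self):
        p = Parameter(np.array([1.5]))
        state = self._state([2.0], [1.0], lam=3.0)
        pen = ewc_penalty({"theta": p}, state)
        pen.backward()
        # d/dtheta (lam/2) F (t - a)^2 = lam F (t - a) = 3*2*0.5
        assert p.grad[0] == pytest.approx(3.0)


class TestTrajectory:
    def test_constant_trajectory_zero_stability(self):
        p = Parameter(np.array([1.0]))
        buf = TrajectoryBuffer({"theta": p})
        for _ in range(5):
            buf.update({"theta": p})
        assert buf.finalize()["theta"][0] == 0.0

    def test_hand_trajectory_value(self):
        p = Parameter(np.array([0.0]))
        buf = TrajectoryBuffer({"theta": p})
        for v in (1.0, 0.5):                     # |1-0| + |0.5-1| = 1.5
            p.data = np.array([v])
            buf.update({"theta": p})
        assert buf.finalize()["theta"][0] == pytest.approx(1.5 / 2)

    def test_absolute_homogeneity(self):
        path = [0.0, 0.4, -0.2, 0.7]
        def stab(c):
            p = Parameter(np.array([path[0] * c]))
            buf = TrajectoryBuffer({"theta": p})
            for v in path[1:]:
                p.data = np.array([v * c])
                buf.update({"theta": p})
            return buf.finalize()["theta"][0]
        assert stab(-3.0) == pytest.approx(3.0 * stab(1.0))

    def test_frozen_parameters_excluded(self):
        p = Parameter(np.array([1.0]))
        p.frozen = True
        buf = TrajectoryBuffer({"theta": p})
        assert buf.finalize() == {}


class QuadraticModel(Module):
    def __init__(self, theta0=0.0):
        self.theta = Parameter(np.array([theta0]))

    def loss(self, a):
        d = self.theta - a
        return (d * d).sum()


def _converge(model, state, mode, lam, a, steps=3000, lr=0.02):
    cfg = TransitionConfig(mode=mode, eta=lr, rho=lr, lambda_reg=lam)
    opt = Adam(model.named_parameters(), lr=lr)
    for _ in range(steps):
        penalized_step(model, model.loss(a), state, cfg, opt)
    return float(model.theta.data[0])


class TestPenalizedOptimization:
    def test_quadratic_toy_matches_closed_form_minimizer(self):
        """min (t-a)^2 + (lam/2) F (t-b)^2 with F=1 has the stationary
        point (2a + lam*b) / (2 + lam)."""
        a, b, lam = 1.0, -0.5, 3.0
        model = QuadraticModel(0.0)
        state = ImportanceState(theta_old={"theta": np.array([b])},
                                fisher={"theta": np.array([1.0])},
                                lambda_reg=lam)
        theta = _converge(model, state, "ewc", lam, a)
        assert theta == pytest.approx((2 * a + lam * b) / (2 + lam),
                                      abs=1e-4)

    def test_no_penalty_matches_unpenalized_update(self):
        a = 0.7
        m1, m2 = QuadraticModel(0.2), QuadraticModel(0.2)
        state = ImportanceState(theta_old={"theta": np.array([0.0])},
                                fisher={"theta": np.array([1.0])},
                                lambda_reg=0.0)
        o1 = Adam(m1.named_parameters(), lr=0.01)
        penalized_step(m1, m1.loss(a), state, TransitionConfig(
            mode="ewc", lambda_reg=0.0), o1)
        o2 = Adam(m2.named_parameters(), lr=0.01)
        penalized_step(m2, m2.loss(a), None, TransitionConfig(mode="none"),
                       o2)
        assert m1.theta.data[0] == pytest.approx(m2.theta.data[0], abs=1e-12)

    def test_large_lambda_pins_parameters_to_anchor(self):
        a, b = 1.0, -0.5
        model = QuadraticModel(0.0)
        state = ImportanceState(theta_old={"theta": np.array([b])},
                                fisher={"theta": np.array([1.0])},
                                lambda_reg=1e6)
        theta = _converge(model, state, "ewc", 1e6, a)
        assert abs(theta - b) < 1e-2

    def test_mode_validation_and_missing_state(self):
        model = QuadraticModel()
        with pytest.raises(ValueError):
            penalty_term(model, None, TransitionConfig(mode="ewc"))
        with pytest.raises(ValueError):
            TransitionConfig(mode="bogus").validate()
        assert penalty_term(model, None,
                            TransitionConfig(mode="none")).item() == 0.0

    def test_importance_state_validation(self):
        with pytest.raises(ValueError):
            ImportanceState(theta_old={}, fisher={"w": np.array([-1.0])}
                            ).validate()
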