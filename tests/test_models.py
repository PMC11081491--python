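"""Generative rating models: enumeration, recursions, likelihood."""

import numpy as np
import pytest
from scipy.optimize import minimize

import wagework as ww
from wagework.models import (
    MECHANISMS,
    ModelSpec,
    ParamSet,
    RatedRound,
    enumerate_model_space,
    log_likelihood,
    log_likelihood_grad,
    predict_ratings,
    round_cost,
    simulate_ratings,
)
from wagework.process_model import CostComponents
from wagework.tasks import RATED_TASKS, TaskKind

COMPS = CostComponents(n_update=10, maintenance=2, n_interference=2,
                       n_response=5, n_miss=1, n_fa=1)


def make_rounds(n, tasks=RATED_TASKS, comps=COMPS, completed=True):
    return [
        RatedRound(task=tasks[i % len(tasks)], t=i + 1, completed=completed,
                   comps=comps if completed else None)
        for i in range(n)
    ]


def alpha_params(spec, sigma=0.5, alpha=0.5, init=2.0, cost=0.1, delta=0.0):
    kw = dict(
        spec=spec, sigma=sigma, alpha=alpha,
        inits={k.value: init for k in RATED_TASKS},
        costs={c: cost for c in spec.cost_set},
    )
    if spec.has_deltas:
        kw["deltas"] = {c: delta for c in spec.cost_set}
    return ParamSet(**kw)


class TestEnumeration:
    def test_default_two_classes_give_126(self):
        assert len(enumerate_model_space(("alpha", "delta"))) == 126

    def test_single_class_gives_63(self):
        assert len(enumerate_model_space(("alpha",))) == 63

    def test_names_round_trip(self):
        for spec in enumerate_model_space(MECHANISMS):
            assert ModelSpec.parse(spec.canonical_name) == spec

    def test_empty_class_set_rejected(self):
        with pytest.raises(ValueError):
            enumerate_model_space(())

    def test_empty_cost_set_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(mech="alpha", cost_set=())


class TestRoundCost:
    def test_single_term_sum(self):
        spec = ModelSpec.parse("alpha:update")
        p = alpha_params(spec, cost=0.5)
        assert round_cost(spec, p, COMPS, t=1, T=32) == pytest.approx(5.0)

    def test_linear_drift_zero_reduces_to_constant(self):
        lin = ModelSpec.parse("alpha_delta_linear:update+fa")
        const = ModelSpec.parse("alpha:update+fa")
        pl = alpha_params(lin, cost=0.3, delta=0.0)
        pc = alpha_params(const, cost=0.3)
        for t in (1, 16, 32):
            assert round_cost(lin, pl, COMPS, t, 32) == pytest.approx(
                round_cost(const, pc, COMPS, t, 32)
            )

    def test_exponential_drift_zero_is_constant(self):
        spec = ModelSpec.parse("alpha_delta_exp:update")
        p = alpha_params(spec, cost=0.4, delta=0.0)
        vals = {round_cost(spec, p, COMPS, t, 32) for t in (1, 7, 32)}
        assert len(vals) == 1

    def test_out_of_range_t_rejected(self):
        spec = ModelSpec.parse("alpha:update")
        with pytest.raises(ValueError):
            round_cost(spec, alpha_params(spec), COMPS, t=0, T=32)


class TestPredictRatings:
    def test_single_step_delta_rule(self):
        """init 2, experienced cost 4, learning rate 0.5 -> next mean 3."""
        spec = ModelSpec.parse("alpha:update")
        p = alpha_params(spec, alpha=0.5, init=2.0, cost=0.4)  # cost_r = 4
        rounds = make_rounds(2, tasks=(TaskKind.back2, TaskKind.back2))
        means = predict_ratings(spec, p, rounds)
        assert means[0] == pytest.approx(2.0)
        assert means[1] == pytest.approx(3.0)

    def test_zero_learning_rate_freezes_ratings(self):
        spec = ModelSpec.parse("alpha:update+fa")
        p = alpha_params(spec, alpha=0.0, init=2.5)
        means = predict_ratings(spec, p, make_rounds(12))
        assert np.allclose(means, 2.5)

    def test_skipped_rounds_leave_state_unchanged(self):
        spec = ModelSpec.parse("alpha:update")
        p = alpha_params(spec, alpha=0.7, init=2.0, cost=0.4)
        rounds = make_rounds(6, tasks=(TaskKind.back2,), completed=False)
        assert np.allclose(predict_ratings(spec, p, rounds), 2.0)

    @pytest.mark.parametrize("mech", MECHANISMS)
    def test_matches_independent_recursion(self, mech):
        """Trajectories equal a step-by-step oracle for every class."""
        rng = np.random.default_rng(31)
        if mech == "delta":
            spec = ModelSpec.parse("delta:update+interference")
        else:
            spec = ModelSpec(mech=mech, cost_set=("update", "interference"))
        for _ in range(30):
            vec = rng.normal(0, 1, spec.n_params)
            p = ParamSet.from_vector(spec, vec)
            rounds = []
            for i in range(32):
                done = bool(rng.random() < 0.7)
                comps = CostComponents(
                    int(rng.integers(8, 15)), 2, int(rng.integers(0, 4)),
                    int(rng.integers(0, 6)), int(rng.integers(0, 3)),
                    int(rng.integers(0, 3)),
                ) if done else None
                rounds.append(RatedRound(RATED_TASKS[rng.integers(3)], i + 1,
                                         done, comps))
            T = 32
            # oracle: naive recursion
            state = {k: p.init_for(k) for k in RATED_TASKS}
            expect = []
            a = p.effective_alpha
            for r in rounds:
                expect.append(state[r.task])
                if r.completed:
                    c = round_cost(spec, p, r.comps, r.t, T)
                    state[r.task] = state[r.task] + a * (c - state[r.task])
            assert np.allclose(predict_ratings(spec, p, rounds, T=T), expect)

    def test_geometric_convergence_to_constant_cost(self):
        """Repeating an identical round pulls the mean to its cost
        geometrically at rate (1 - alpha)."""
        spec = ModelSpec.parse("alpha:update")
        p = alpha_params(spec, alpha=0.3, init=1.0, cost=0.4)  # cost C = 4
        rounds = make_rounds(20, tasks=(TaskKind.back2,))
        means = predict_ratings(spec, p, rounds)
        gaps = np.abs(means - 4.0)
        assert np.allclose(gaps[1:] / gaps[:-1], 0.7)
        assert gaps[-1] < 1e-2

    def test_alpha_one_tracks_previous_cost(self):
        spec = ModelSpec.parse("alpha:update")
        p = alpha_params(spec, alpha=1.0, init=1.0, cost=0.25)
        rounds = make_rounds(5, tasks=(TaskKind.back1,))
        means = predict_ratings(spec, p, rounds)
        assert np.allclose(means[1:], 2.5)

    def test_delta_class_with_zero_drift_equals_alpha_one(self):
        dspec = ModelSpec.parse("delta:update+fa")
        aspec = ModelSpec.parse("alpha:update+fa")
        dp = ParamSet(spec=dspec, sigma=0.5, init=2.0,
                      costs={"update": 0.2, "fa": -0.3},
                      deltas={"update": 0.0, "fa": 0.0})
        ap = ParamSet(spec=aspec, sigma=0.5, alpha=1.0,
                      inits={k.value: 2.0 for k in RATED_TASKS},
                      costs={"update": 0.2, "fa": -0.3})
        rounds = make_rounds(15)
        assert np.allclose(
            predict_ratings(dspec, dp, rounds), predict_ratings(aspec, ap, rounds)
        )


class TestSimulateRatings:
    def test_seed_determinism(self):
        spec = ModelSpec.parse("alpha:update")
        p = alpha_params(spec)
        rounds = make_rounds(10)
        a = simulate_ratings(spec, p, rounds, np.random.default_rng(2))[1]
        b = simulate_ratings(spec, p, rounds, np.random.default_rng(2))[1]
        assert np.array_equal(a, b)

    def test_vanishing_noise_limit(self):
        spec = ModelSpec.parse("alpha:update")
        p = alpha_params(spec, sigma=1e-12)
        means, noisy = simulate_ratings(spec, p, make_rounds(10),
                                        np.random.default_rng(3))
        assert np.allclose(means, noisy, atol=1e-9)

    def test_noise_sd_matches_sigma(self):
        """Monte-Carlo: empirical SD of the injected noise within 3%."""
        spec = ModelSpec.parse("alpha:update")
        p = alpha_params(spec, sigma=0.8)
        rounds = make_rounds(10)
        rng = np.random.default_rng(4)
        devs = np.concatenate([
            np.subtract(*simulate_ratings(spec, p, rounds, rng)[::-1])
            for _ in range(1000)
        ])
        assert len(devs) == 10_000
        assert np.std(devs) == pytest.approx(0.8, rel=0.03)


class TestLogLikelihood:
    def test_zero_residuals_closed_form(self):
        spec = ModelSpec.parse("alpha:update")
        p = alpha_params(spec, sigma=0.7)
        rounds = make_rounds(12)
        means = predict_ratings(spec, p, rounds)
        ll = log_likelihood(spec, p.to_vector(), rounds, means)
        n = len(rounds)
        assert ll == pytest.approx(-n * (np.log(0.7) + 0.5 * np.log(2 * np.pi)))

    def test_larger_residuals_decrease_loglik(self):
        spec = ModelSpec.parse("alpha:update")
        p = alpha_params(spec, sigma=0.7)
        rounds = make_rounds(12)
        means = predict_ratings(spec, p, rounds)
        vec = p.to_vector()
        ll1 = log_likelihood(spec, vec, rounds, means + 0.2)
        ll2 = log_likelihood(spec, vec, rounds, means + 0.4)
        assert ll2 < ll1

    def test_nonfinite_ratings_rejected(self):
        spec = ModelSpec.parse("alpha:update")
        p = alpha_params(spec)
        rounds = make_rounds(3)
        with pytest.raises(ValueError):
            log_likelihood(spec, p.to_vector(), rounds, np.array([1, np.nan, 2.0]))

    @pytest.mark.parametrize("mech", MECHANISMS)
    def test_gradient_matches_finite_differences(self, mech):
        rng = np.random.default_rng(6)
        spec = ModelSpec(mech=mech, cost_set=("update", "maintenance", "fa"))
        rounds = make_rounds(20)
        ratings = rng.normal(2.5, 1.0, len(rounds))
        for _ in range(5):
            vec = rng.normal(0, 0.8, spec.n_params)
            _, grad = log_likelihood_grad(spec, vec, rounds, ratings)
            eps = 1e-6
            for j in range(spec.n_params):
                e = np.zeros(spec.n_params)
                e[j] = eps
                fd = (
                    log_likelihood(spec, vec + e, rounds, ratings)
                    - log_likelihood(spec, vec - e, rounds, ratings)
                ) / (2 * eps)
                assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_mle_recovers_generating_parameters(self):
        """Maximum likelihood on 500 simulated rounds lands near the truth.

        Update tallies vary across rounds so the learning rate is
        identified by how fast ratings chase the changing costs.
        """
        spec = ModelSpec.parse("alpha:update")
        truth = alpha_params(spec, sigma=0.4, alpha=0.3, init=2.0, cost=0.25)
        rng = np.random.default_rng(17)
        rounds = [
            RatedRound(
                RATED_TASKS[i % 3], i + 1, True,
                CostComponents(int(rng.integers(4, 15)), 2, 0, 4, 0, 0),
            )
            for i in range(500)
        ]
        _, noisy = simulate_ratings(spec, truth, rounds, np.random.default_rng(8))
        res = minimize(
            lambda v: tuple(-x for x in
                            log_likelihood_grad(spec, v, rounds, noisy)),
            truth.to_vector() + 0.3, jac=True, method="L-BFGS-B",
        )
        fit = ParamSet.from_vector(spec, res.x)
        assert fit.sigma == pytest.approx(truth.sigma, abs=0.05)
        assert fit.alpha == pytest.approx(truth.alpha, abs=0.08)
        assert fit.costs["update"] == pytest.approx(0.25, abs=0.03)
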