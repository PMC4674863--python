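"""Tests for the EM loop, M-step optimality and FDR selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize, minimize_scalar

import dereg
from dereg import (
    DataError,
    DeregulationScores,
    FitError,
    ModelParameters,
    deregulation_scores,
    e_step,
    enumerate_marginals,
    expected_complete_loglik,
    fdr_select,
    fit_em,
    initialize_parameters,
    m_step,
    simulate_dataset,
)
from dereg.factor_graph import SampleMarginals
from conftest import expression_from_rows, marginals_max_abs_diff, random_theta


def random_soft_marginals(net, rng) -> SampleMarginals:
    """Arbitrary valid soft marginals (only the fields the M-step reads)."""
    d3 = lambda: rng.dirichlet(np.ones(3))
    d2 = lambda: rng.dirichlet(np.ones(2))
    return SampleMarginals(
        regulator_s={g: d3() for g in net.regulators},
        target_s_a={g: d3() for g in net.targets},
        target_s_i={g: d3() for g in net.targets},
        target_s_r={g: d3() for g in net.targets},
        target_s={g: d3() for g in net.targets},
        target_d={g: d2() for g in net.targets},
    )


class TestEStep:
    def test_matches_enumeration_on_tree(self, toy_net, theta):
        rng = np.random.default_rng(0)
        row = rng.normal(size=len(toy_net.genes))
        X = expression_from_rows(row, toy_net)
        [marg] = e_step(toy_net, theta, X)
        exact = enumerate_marginals(toy_net, theta, row)
        assert marginals_max_abs_diff(marg, exact) < 1e-9

    def test_duplicated_samples_get_identical_marginals(self, loopy_net, theta):
        rng = np.random.default_rng(1)
        row = rng.normal(size=len(loopy_net.genes))
        X = expression_from_rows(np.vstack([row, row]), loopy_net)
        m0, m1 = e_step(loopy_net, theta, X)
        assert marginals_max_abs_diff(m0, m1) == 0.0

    def test_zero_epsilon_means_zero_deregulation_posterior(self, toy_net):
        theta = ModelParameters(
            np.full(3, 1 / 3), 0.0, np.array([-1, 0, 1.0]), np.full(3, 0.4)
        )
        rng = np.random.default_rng(2)
        X = expression_from_rows(rng.normal(size=(3, len(toy_net.genes))), toy_net)
        for marg in e_step(toy_net, theta, X):
            for g in toy_net.targets:
                assert marg.target_d[g][1] == pytest.approx(0.0, abs=1e-12)

    def test_marginals_carry_sample_ids(self, tiny_net, theta):
        X = expression_from_rows(np.zeros((2, 3)), tiny_net)
        marg = e_step(tiny_net, theta, X)
        assert [m.sample_id for m in marg] == ["s0", "s1"]


class TestMStep:
    def test_epsilon_is_mean_deregulation_posterior(self, tiny_net):
        rng = np.random.default_rng(3)
        marginals = []
        for _ in range(4):
            m = random_soft_marginals(tiny_net, rng)
            m.target_d["tg1"][:] = [0.5, 0.5]
            marginals.append(m)
        X = expression_from_rows(rng.normal(size=(4, 3)), tiny_net)
        theta = m_step(marginals, X, tiny_net)
        assert theta.epsilon == pytest.approx(0.5, abs=1e-12)

    def test_weighted_mean_and_variance(self, tiny_net):
        # two observations carry all the q(S=+1) weight, with values 2 and 4
        rng = np.random.default_rng(4)
        hard_plus = SampleMarginals(
            regulator_s={"tf1": np.array([0, 0, 1.0]), "tf2": np.array([0, 0, 1.0])},
            target_s_a={"tg1": np.array([0, 0, 1.0])},
            target_s_i={"tg1": np.array([0, 0, 1.0])},
            target_s_r={"tg1": np.array([0, 0, 1.0])},
            target_s={"tg1": np.array([0, 0, 1.0])},
            target_d={"tg1": np.array([1.0, 0.0])},
        )
        X = expression_from_rows(
            np.array([[2.0, 2.0, 2.0], [4.0, 4.0, 4.0]]), tiny_net
        )
        prev = random_theta(rng)
        theta = m_step([hard_plus, hard_plus], X, tiny_net, theta_prev=prev)
        assert theta.mu[2] == pytest.approx(3.0, abs=1e-12)
        assert theta.sigma[2] == pytest.approx(1.0, abs=1e-12)
        # unweighted states fall back to the previous parameters
        assert theta.mu[0] == prev.mu[0] and theta.sigma[1] == prev.sigma[1]

    def test_zero_weight_state_without_fallback_raises(self, tiny_net):
        hard = SampleMarginals(
            regulator_s={g: np.array([0, 0, 1.0]) for g in tiny_net.regulators},
            target_s_a={"tg1": np.array([0, 0, 1.0])},
            target_s_i={"tg1": np.array([0, 0, 1.0])},
            target_s_r={"tg1": np.array([0, 0, 1.0])},
            target_s={"tg1": np.array([0, 0, 1.0])},
            target_d={"tg1": np.array([1.0, 0.0])},
        )
        X = expression_from_rows(np.ones((1, 3)), tiny_net)
        with pytest.raises(FitError, match="zero posterior weight"):
            m_step([hard], X, tiny_net)

    def test_maximizes_expected_complete_loglik(self, loopy_net):
        """The closed form matches block-wise numerical optimization."""
        rng = np.random.default_rng(5)
        n = 5
        marginals = [random_soft_marginals(loopy_net, rng) for _ in range(n)]
        X = expression_from_rows(
            rng.normal(0, 2, size=(n, len(loopy_net.genes))), loopy_net
        )
        theta_hat = m_step(marginals, X, loopy_net)
        q_hat = expected_complete_loglik(marginals, X, loopy_net, theta_hat)

        theta_num = numeric_m_step(marginals, X, loopy_net)
        q_num = expected_complete_loglik(marginals, X, loopy_net, theta_num)
        assert q_hat >= q_num - 1e-6

    def test_beats_single_coordinate_perturbations(self, toy_net):
        rng = np.random.default_rng(6)
        marginals = [random_soft_marginals(toy_net, rng) for _ in range(3)]
        X = expression_from_rows(rng.normal(size=(3, len(toy_net.genes))), toy_net)
        theta_hat = m_step(marginals, X, toy_net)
        q_hat = expected_complete_loglik(marginals, X, toy_net, theta_hat)
        for delta in (1e-3, -1e-3):
            for attr in ("epsilon",):
                perturbed = ModelParameters(
                    theta_hat.alpha, theta_hat.epsilon + delta,
                    theta_hat.mu, theta_hat.sigma,
                )
                assert expected_complete_loglik(marginals, X, toy_net, perturbed) <= q_hat
            for j in range(3):
                mu = theta_hat.mu.copy()
                mu[j] += delta
                perturbed = ModelParameters(
                    theta_hat.alpha, theta_hat.epsilon, mu, theta_hat.sigma
                )
                assert expected_complete_loglik(marginals, X, toy_net, perturbed) <= q_hat


def numeric_m_step(marginals, X, net) -> ModelParameters:
    """Independent block-wise numerical maximizer of the EM objective."""

    def q_of(alpha=None, epsilon=None, mu=None, sigma=None):
        base = m_step(marginals, X, net)
        return expected_complete_loglik(
            marginals, X, net,
            ModelParameters(
                base.alpha if alpha is None else alpha,
                base.epsilon if epsilon is None else epsilon,
                base.mu if mu is None else mu,
                base.sigma if sigma is None else sigma,
            ),
        )

    def softmax(u):
        e = np.exp(u - u.max())
        return e / e.sum()

    res_a = minimize(
        lambda u: -q_of(alpha=softmax(np.r_[u, 0.0])),
        x0=np.zeros(2), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12},
    )
    alpha = softmax(np.r_[res_a.x, 0.0])
    res_e = minimize_scalar(
        lambda e: -q_of(epsilon=e), bounds=(1e-9, 1 - 1e-9), method="bounded",
        options={"xatol": 1e-12},
    )
    mu = np.empty(3)
    sigma = np.empty(3)
    base = m_step(marginals, X, net)
    for j in range(3):
        def neg(u, j=j):
            m = base.mu.copy()
            s = base.sigma.copy()
            m[j], s[j] = u[0], np.exp(u[1])
            return -q_of(mu=m, sigma=s)

        res = minimize(
            neg, x0=np.array([0.0, 0.0]), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        mu[j], sigma[j] = res.x[0], np.exp(res.x[1])
    return ModelParameters(alpha, float(res_e.x), mu, sigma)


class TestInitialization:
    def test_three_point_mixture_quantiles(self):
        k = 300
        pooled = np.r_[np.full(k, -1.0), np.full(k, 0.0), np.full(k, 1.0)]
        rng = np.random.default_rng(7)
        rng.shuffle(pooled)
        X = dereg.ExpressionMatrix(
            pooled.reshape(10, 90),
            tuple(f"s{i}" for i in range(10)),
            tuple(f"g{j}" for j in range(90)),
        )
        theta = initialize_parameters(X)
        np.testing.assert_allclose(theta.mu, [-1.0, 0.0, 1.0], atol=1e-9)
        assert theta.mu[0] <= theta.mu[1] <= theta.mu[2]

    def test_returns_valid_parameters(self):
        rng = np.random.default_rng(8)
        X = dereg.ExpressionMatrix(
            rng.normal(size=(5, 4)),
            tuple(f"s{i}" for i in range(5)),
            tuple(f"g{j}" for j in range(4)),
        )
        theta = initialize_parameters(X)
        assert abs(theta.alpha.sum() - 1) < 1e-12
        assert np.all(theta.sigma > 0)
        assert theta.mu[0] <= theta.mu[1] <= theta.mu[2]

    def test_constant_matrix_raises(self):
        X = dereg.ExpressionMatrix(
            np.full((3, 3), 2.5),
            ("s1", "s2", "s3"), ("g1", "g2", "g3"),
        )
        with pytest.raises(FitError, match="unidentifiable"):
            initialize_parameters(X)


class TestFitEM:
    def test_max_iter_one_runs_one_em_cycle(self, toy_net, theta):
        rng = np.random.default_rng(9)
        X, _ = simulate_dataset(toy_net, theta, 5, seed=9)
        th, marg, trace = fit_em(toy_net, X, theta, max_iter=1, tol=1e-12)
        assert trace.n_iterations == 1
        assert len(trace.records) == 2  # initial snapshot + one update

    def test_fixed_point_at_generating_parameters(self, theta):
        # at large n * G and small sigma the generating parameters are
        # close to an EM fixed point: few iterations, tiny drift
        net = dereg.generate_network(8, 12, max_act=2, max_inh=2, seed=10)
        theta_gen = dereg.default_simulation_theta(sigma=0.2, epsilon=0.05)
        X, _ = simulate_dataset(net, theta_gen, 30, seed=11)
        th, _, trace = fit_em(net, X, theta_gen, max_iter=30, tol=1e-4)
        assert trace.n_iterations < 30
        np.testing.assert_allclose(th.mu, theta_gen.mu, atol=0.1)

    def test_exact_loglik_nondecreasing_on_tree(self, toy_net, theta):
        X, _ = simulate_dataset(toy_net, theta, 6, seed=12)
        theta0 = initialize_parameters(X)
        _, _, trace = fit_em(
            toy_net, X, theta0, max_iter=8, tol=1e-10, track_loglik=True
        )
        lls = [r.loglik for r in trace.records]
        assert all(b - a >= -1e-9 for a, b in zip(lls, lls[1:]))

    def test_invalid_controls_raise(self, toy_net, theta):
        X, _ = simulate_dataset(toy_net, theta, 3, seed=13)
        with pytest.raises(FitError):
            fit_em(toy_net, X, theta, max_iter=0)
        with pytest.raises(FitError):
            fit_em(toy_net, X, theta, tol=0.0)


class TestDeregulationScores:
    def test_matches_enumeration_d_marginals(self, toy_net, theta):
        rng = np.random.default_rng(14)
        row = rng.normal(size=len(toy_net.genes))
        X = expression_from_rows(row, toy_net)
        scores = deregulation_scores(e_step(toy_net, theta, X))
        exact = enumerate_marginals(toy_net, theta, row)
        for j, g in enumerate(toy_net.targets):
            assert scores.scores[0, j] == pytest.approx(
                exact.target_d[g][1], abs=1e-9
            )

    def test_scores_within_unit_interval(self, loopy_net, theta):
        rng = np.random.default_rng(15)
        X = expression_from_rows(
            rng.normal(size=(4, len(loopy_net.genes))), loopy_net
        )
        scores = deregulation_scores(e_step(loopy_net, theta, X))
        assert np.all(scores.scores >= 0) and np.all(scores.scores <= 1)


class TestFdrSelect:
    def _scores(self, values):
        values = np.asarray(values, dtype=float)[None, :]
        return DeregulationScores(
            values, ("s1",), tuple(f"t{j}" for j in range(values.shape[1]))
        )

    def test_perfect_scores_have_zero_fdr(self):
        thr, sel, est = fdr_select(self._scores([1.0, 1.0]), 0.1)
        assert len(sel) == 2 and est == 0.0

    def test_all_selected_fdr_arithmetic(self):
        thr, sel, est = fdr_select(self._scores([0.9, 0.8, 0.7]), 0.25)
        assert len(sel) == 3
        assert est == pytest.approx((3 - 2.4) / 3, abs=1e-12)

    def test_boundary_prefix_selection(self):
        # (2 - 1.7)/2 = 0.15 exactly meets the target; (3 - 2.4)/3 = 0.2 does not
        thr, sel, est = fdr_select(self._scores([0.9, 0.8, 0.7]), 0.15)
        assert len(sel) == 2
        assert thr == pytest.approx(0.8)
        assert est == pytest.approx(0.15, abs=1e-9)

    def test_empty_selection(self):
        thr, sel, est = fdr_select(self._scores([0.5, 0.4]), 0.2)
        assert sel == set() and thr == 1.0 and est == 0.0

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 2.0])
    def test_rejects_invalid_target(self, bad):
        with pytest.raises(DataError):
            fdr_select(self._scores([0.9]), bad)

    def test_tie_handling_is_deterministic(self):
        scores = DeregulationScores(
            np.array([[0.8, 0.8], [0.8, 0.9]]), ("s1", "s2"), ("t1", "t2")
        )
        picks = [fdr_select(scores, 0.18)[1] for _ in range(3)]
        assert picks[0] == picks[1] == picks[2]

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
    )
    def test_estimated_fdr_nondecreasing_down_the_ranking(self, values):
        s = np.sort(np.asarray(values))[::-1]
        k = np.arange(1, len(s) + 1)
        est = (k - np.cumsum(s)) / k
        assert np.all(np.diff(est) >= -1e-12)
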