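"""Likelihood, priors, posterior target, DEzs sampler, diagnostics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from traitlv import (
    CommunitySample,
    LikelihoodConfig,
    PriorSpec,
    SyntheticScenario,
    TransferParams,
    ZConfig,
    gelman_rubin,
    log_posterior,
    make_target,
    multinomial_loglik,
    run_dezs,
    simulate_dataset,
    uniform_null_loglik,
)
from traitlv.errors import DimensionError, InvalidValueError, TraitLVError
from traitlv.inference import _reflect


class TestMultinomialLoglik:
    def test_two_outcomes_half_half(self):
        assert multinomial_loglik([1, 1], [0.5, 0.5]) == pytest.approx(
            math.log(0.5), abs=1e-12)

    def test_certain_outcome(self):
        assert multinomial_loglik([7, 0, 0], [1.0, 0.0, 0.0]) == 0.0

    def test_impossible_outcome_minus_inf(self):
        assert multinomial_loglik([1, 1], [1.0, 0.0]) == -np.inf

    def test_matches_scipy(self, rng):
        for _ in range(20):
            S = rng.integers(2, 6)
            p = rng.dirichlet(np.ones(S))
            counts = rng.multinomial(50, p)
            expected = stats.multinomial.logpmf(counts, 50, p)
            assert multinomial_loglik(counts, p) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("total,S", [(4, 3), (10, 4), (6, 2)])
    def test_enumeration_oracle(self, total, S, rng):
        """Brute-force enumeration: pmf sums to 1 and matches term by term."""
        p = rng.dirichlet(np.ones(S))
        acc = 0.0
        for combo in itertools.product(range(total + 1), repeat=S):
            if sum(combo) != total:
                continue
            # independent closed form via factorials
            log_ref = math.log(math.factorial(total))
            for x, pi in zip(combo, p):
                log_ref += x * math.log(pi) - math.log(math.factorial(x))
            assert multinomial_loglik(list(combo), p) == pytest.approx(
                log_ref, abs=1e-10)
            acc += math.exp(log_ref)
        assert acc == pytest.approx(1.0, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidValueError):
            multinomial_loglik([1, -1], [0.5, 0.5])
        with pytest.raises(InvalidValueError):
            multinomial_loglik([1, 1], [0.6, 0.6])
        with pytest.raises(DimensionError):
            multinomial_loglik([1, 1, 1], [0.5, 0.5])


class TestPriorSpec:
    def test_out_of_support_zero_density(self):
        prior = PriorSpec()
        v = prior.sample(np.random.default_rng(0), 1)[0]
        assert np.isfinite(prior.log_density(v))
        v_bad = v.copy()
        v_bad[0] = -0.2  # angle below range
        assert prior.log_density(v_bad) == -np.inf
        v_bad = v.copy()
        v_bad[6] = -0.1  # negative scale
        assert prior.log_density(v_bad) == -np.inf

    def test_samples_inside_support(self, rng):
        prior = PriorSpec()
        draws = prior.sample(rng, 200)
        lo, hi = prior.bounds()
        assert np.all(draws >= lo) and np.all(draws <= hi)
        assert all(np.isfinite(prior.log_density(v)) for v in draws)


@pytest.fixture(scope="module")
def setup():
    data = simulate_dataset(SyntheticScenario(S=12, J=4, seed=3))
    return data, PriorSpec()


class TestLogPosterior:

    def test_out_of_range_angle_minus_inf(self, setup):
        data, prior = setup
        vec = data.true_transfer.to_vector().copy()
        vec[0] = 3.2  # outside [0, pi]
        target = make_target(data.axes, data.sites, data.sample, prior)
        assert target(vec)[0] == -np.inf

    def test_posterior_is_likelihood_plus_prior(self, setup):
        data, prior = setup
        tp = data.true_transfer
        res = log_posterior(tp, data.axes, data.sites, data.sample, prior)
        assert res.log_posterior == pytest.approx(
            res.log_likelihood + res.log_prior, abs=1e-10)
        assert res.log_prior == pytest.approx(
            prior.log_density(tp.to_vector()), abs=1e-12)

    def test_duplicating_plots_doubles_likelihood_only(self, setup):
        data, prior = setup
        tp = data.true_transfer
        res1 = log_posterior(tp, data.axes, data.sites, data.sample, prior)
        doubled = CommunitySample(
            plot_id=np.concatenate([data.sample.plot_id, data.sample.plot_id]),
            species_id=data.sample.species_id,
            counts=np.vstack([data.sample.counts, data.sample.counts]),
        )
        from traitlv.model_core import SiteTable
        sites2 = SiteTable(
            plot_id=doubled.plot_id,
            theta=np.concatenate([data.sites.theta, data.sites.theta]))
        res2 = log_posterior(tp, data.axes, sites2, doubled, prior)
        assert res2.log_likelihood == pytest.approx(2 * res1.log_likelihood, rel=1e-12)
        assert res2.log_prior == pytest.approx(res1.log_prior, abs=1e-12)

    def test_ode_route_matches_analytic_composition(self, setup):
        """Dual route: ODE-based posterior vs fixed-point composition."""
        data, prior = setup
        tp = data.true_transfer
        res_a = log_posterior(tp, data.axes, data.sites, data.sample, prior,
                              LikelihoodConfig(equilibrium_method="analytic"))
        res_o = log_posterior(tp, data.axes, data.sites, data.sample, prior,
                              LikelihoodConfig(equilibrium_method="ode"))
        assert res_o.log_likelihood == pytest.approx(
            res_a.log_likelihood, abs=1e-3)

    def test_g_and_joint_cl_rescale_flat_directions(self, setup):
        """The likelihood is invariant to g and to shifting (b_c, b_l)
        together — the non-identifiabilities that justify fixing g and b_c."""
        data, prior = setup
        vec = data.true_transfer.to_vector()
        cfg0 = LikelihoodConfig()
        base = log_posterior(TransferParams.from_vector(vec, 3),
                             data.axes, data.sites, data.sample, prior, cfg0)
        # rescale g
        cfg_g = LikelihoodConfig(g_value=cfg0.g_value * 7.3)
        tp_g = TransferParams.from_vector(vec, 3, g_value=cfg_g.g_value)
        res_g = log_posterior(tp_g, data.axes, data.sites, data.sample, prior, cfg_g)
        assert res_g.log_likelihood == pytest.approx(base.log_likelihood, abs=1e-8)
        # shift b_c and b_l jointly (multiplies c and l by the same factor)
        delta = 0.9
        vec_s = vec.copy()
        vec_s[9] += delta  # b_l
        cfg_s = LikelihoodConfig(b_c_value=cfg0.b_c_value + delta)
        tp_s = TransferParams.from_vector(vec_s, 3, b_c_value=cfg_s.b_c_value)
        res_s = log_posterior(tp_s, data.axes, data.sites, data.sample, prior, cfg_s)
        assert res_s.log_likelihood == pytest.approx(base.log_likelihood, abs=1e-8)
        # shifting b_l alone does change the likelihood
        tp_one = TransferParams.from_vector(vec_s, 3)
        res_one = log_posterior(tp_one, data.axes, data.sites, data.sample, prior, cfg0)
        assert abs(res_one.log_likelihood - base.log_likelihood) > 0.1

    def test_single_species_single_plot_trivial(self):
        from traitlv.model_core import SiteTable
        from traitlv import generate_axes
        # two species, one of which cannot grow anywhere: p = (1, 0) wherever
        # only the first is viable; likelihood of sampling it n times is 0
        axes = generate_axes(4, 3, seed=0)
        prior = PriorSpec()
        tp = TransferParams(
            phi_theta_min=np.array([1.0, 0.5]), phi_l=np.array([1.0, 0.5]),
            phi_c=np.array([1.0, 0.5]), a_theta_min=0.0, b_theta_min=-5.0,
            a_l=0.0, b_l=-4.0, a_c=0.0)
        sites = SiteTable(plot_id=np.array(["p0"]), theta=np.array([0.0]))
        # all species identical => equal abundances p = 1/4
        sample = CommunitySample(plot_id=np.array(["p0"]),
                                 species_id=axes.species_id,
                                 counts=np.array([[2, 1, 0, 1]]))
        res = log_posterior(tp, axes, sites, sample, prior)
        assert res.log_likelihood == pytest.approx(
            multinomial_loglik([2, 1, 0, 1], np.full(4, 0.25)), abs=1e-9)


class TestRunDezs:
    def test_gaussian_target_moments(self):
        d = 3
        target = lambda x: float(-0.5 * x @ x)
        post = run_dezs(
            target, n_chains=2, steps=4000, seed=99, d=d,
            init_sampler=lambda rng, n: rng.normal(0, 2, size=(n, d)))
        draws = post.retained(0.5)
        assert np.all(np.abs(draws.mean(axis=0)) < 0.1)
        assert np.all(np.abs(draws.var(axis=0) - 1.0) < 0.15)

    def test_seed_reproducibility_bit_identical(self):
        d = 2
        target = lambda x: float(-0.5 * x @ x)
        kw = dict(n_chains=2, steps=500, seed=7, d=d,
                  init_sampler=lambda rng, n: rng.normal(0, 2, size=(n, d)))
        p1 = run_dezs(target, **kw)
        p2 = run_dezs(target, **kw)
        np.testing.assert_array_equal(p1.draws, p2.draws)
        np.testing.assert_array_equal(p1.log_posterior, p2.log_posterior)

    def test_uniform_box_marginals(self):
        """Sampling a uniform box target gives uniform marginals (KS)."""
        lo = np.zeros(2)
        hi = np.array([np.pi, 2 * np.pi])

        def target(x):
            if np.any(x < lo) or np.any(x > hi):
                return -np.inf
            return 0.0

        post = run_dezs(
            target, n_chains=2, steps=6000, seed=3, d=2, bounds=(lo, hi),
            init_sampler=lambda rng, n: rng.uniform(lo, hi, size=(n, 2)))
        draws = post.retained(0.5)
        sub = draws[:: max(1, draws.shape[0] // 400)]  # thin to ease dependence
        for j, width in enumerate(hi):
            ks = stats.kstest(sub[:, j] / width, "uniform")
            assert ks.pvalue > 0.01

    def test_all_minus_inf_start_raises(self):
        target = lambda x: -np.inf
        with pytest.raises(TraitLVError, match="finite"):
            run_dezs(target, n_chains=1, steps=10, seed=0, d=2,
                     init_sampler=lambda rng, n: rng.normal(size=(n, 2)))

    def test_reflection_stays_in_bounds(self):
        lo, hi = np.array([0.0]), np.array([1.0])
        x = _reflect(np.array([1.3]), lo, hi)
        assert x[0] == pytest.approx(0.7)
        x = _reflect(np.array([-2.3]), lo, hi)
        assert 0 <= x[0] <= 1


class TestGelmanRubin:
    def test_iid_chains_near_one(self, rng):
        chains = rng.normal(size=(2000, 4, 3))
        psrf, mpsrf = gelman_rubin(chains)
        assert np.all(psrf < 1.05)
        assert mpsrf < 1.05

    def test_shifted_chains_flagged(self, rng):
        chains = rng.normal(size=(500, 3, 2))
        chains[:, 0, :] += 5.0
        psrf, mpsrf = gelman_rubin(chains)
        assert np.all(psrf > 2.0) and mpsrf > 2.0

    def test_constant_chains_error(self):
        with pytest.raises(InvalidValueError):
            gelman_rubin(np.ones((100, 3, 2)))

    def test_matches_arviz(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = rng.normal(size=(800, 4, 2)) + rng.normal(size=(1, 4, 1)) * 0.2
        psrf, _ = gelman_rubin(chains)
        ref = arviz.rhat(arviz.convert_to_dataset(
            np.transpose(chains, (1, 0, 2))), method="identity")
        np.testing.assert_allclose(psrf, ref["x"].values, rtol=0.02)


class TestNullLoglik:
    def test_uniform_null_value(self):
        sample = CommunitySample(plot_id=np.array(["a"]),
                                 species_id=np.array(["s1", "s2"]),
                                 counts=np.array([[3, 1]]))
        expected = multinomial_loglik([3, 1], [0.5, 0.5])
        assert uniform_null_loglik(sample) == pytest.approx(expected)
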