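"""SIMM core: priors, likelihood, sampler behaviour on degenerate and
small cases, and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hairsimm.diagnostics import gelman_rubin, geweke
from hairsimm.mixing import MixingSpace, mixture_moments
from hairsimm.simm import (
    MCMCSettings,
    ModelSpec,
    MODEL_STRUCTURES,
    fit_mcmc,
    log_likelihood,
    prior_from_edec,
    summarize_posterior,
)


class TestPriorFromEdec:
    def test_uniform_edec_reduces_to_flat_dirichlet(self):
        spec = prior_from_edec([25.0, 25.0, 25.0, 25.0])
        np.testing.assert_allclose(spec.alpha, 1.0)

    def test_scaling_rule(self):
        spec = prior_from_edec([50.0, 25.0, 25.0])
        np.testing.assert_allclose(spec.alpha, [1.5, 0.75, 0.75])

    def test_zero_component_floored(self):
        spec = prior_from_edec([60.0, 40.0, 0.0])
        assert spec.alpha[2] == pytest.approx(0.01)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            prior_from_edec([50.0, -1.0])


def _space2(means, sds, conc):
    return MixingSpace(
        season=None, names=("a", "b"),
        means=np.asarray(means, float), sds=np.asarray(sds, float),
        conc=np.asarray(conc, float),
    )


class TestLogLikelihood:
    def test_observation_at_mixture_mean_unit_sd(self):
        """At the mean with total SD 1 per isotope the log-density is
        2 * (-0.5 * ln(2 pi))."""
        space = _space2([[0.0, 0.0], [0.0, 0.0]], np.zeros((2, 2)), np.ones((2, 2)))
        ll = log_likelihood(0.0, 0.0, [0.5, 0.5], space, sigma_res=(1.0, 1.0))
        assert ll == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)))

    def test_single_source_equals_normal_density(self):
        space = MixingSpace(
            season=None, names=("a",),
            means=np.array([[-26.7, 0.2]]), sds=np.array([[1.0, 2.0]]),
            conc=np.ones((1, 2)),
        )
        ll = log_likelihood(-25.9, 1.1, [1.0], space, sigma_res=(0.5, 0.5))
        expected = stats.norm.logpdf(-25.9, -26.7, np.hypot(1.0, 0.5)) + \
            stats.norm.logpdf(1.1, 0.2, np.hypot(2.0, 0.5))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_two_source_worked_case_matches_independent_density(self):
        """p=(0.5,0.5), q=(2,1), corrected means (0,3): mean 1.0; the process
        variance and density are recomputed here from first principles."""
        space = _space2(
            [[0.0, 0.0], [3.0, 3.0]], [[0.4, 0.4], [0.8, 0.8]],
            [[2.0, 2.0], [1.0, 1.0]],
        )
        p = np.array([0.5, 0.5])
        y = (1.7, 0.4)
        ll = log_likelihood(*y, p, space, sigma_res=(0.5, 0.5))
        w = p * np.array([2.0, 1.0])
        mean = (w @ np.array([0.0, 3.0])) / w.sum()
        pvar = (w**2 @ np.array([0.4, 0.8]) ** 2) / w.sum() ** 2
        sd = np.sqrt(pvar + 0.25)
        expected = stats.norm.logpdf(y[0], mean, sd) + stats.norm.logpdf(y[1], mean, sd)
        assert mean == pytest.approx(1.0)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        space = _space2([[0, 0], [3, 3]], np.zeros((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            log_likelihood(np.nan, 0.0, [0.5, 0.5], space)
        with pytest.raises(ValueError):
            log_likelihood(0.0, 0.0, [0.7, 0.7], space)


class TestDiagnostics:
    def test_identical_iid_chains_near_one(self):
        rng = np.random.default_rng(42)
        chains = rng.normal(0, 1, (2, 5000))
        assert 0.99 <= gelman_rubin(chains) <= 1.01

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(chains) > 5

    def test_degenerate_chains_warn_and_report_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert gelman_rubin(np.ones((3, 100))) == 1.0

    def test_hand_computed_rhat(self):
        chains = np.array([[0.0, 1.0, 2.0, 1.0], [1.0, 2.0, 3.0, 2.0]])
        n = 4
        w = chains.var(axis=1, ddof=1).mean()
        b_over_n = chains.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-12)

    def test_geweke_calibration_on_iid_chains(self):
        rng = np.random.default_rng(123)
        zs = [geweke(rng.normal(0, 1, 5000)) for _ in range(300)]
        assert np.mean(np.abs(zs) < 3) >= 0.99

    def test_geweke_detects_drift(self):
        drifting = np.linspace(0, 5, 2000) + np.random.default_rng(1).normal(0, 0.1, 2000)
        assert abs(geweke(drifting)) > 5

    def test_geweke_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke(np.zeros(10))


def _null_sections(space, p_true, sigma, n=40, seed=0):
    rng = np.random.default_rng(seed)
    mean, pvar = mixture_moments(p_true, space)
    y = rng.normal(mean, np.sqrt(pvar + sigma**2), size=(n, 2))
    return pd.DataFrame(
        {"bear_id": [f"b{i%5}" for i in range(n)], "sex": "F",
         "status": "non-management", "d13C": y[:, 0], "d15N": y[:, 1]}
    )


class TestFitMcmc:
    def test_single_source_posterior_is_degenerate(self):
        space = MixingSpace(
            season=None, names=("only",),
            means=np.array([[-24.0, 5.0]]), sds=np.array([[1.0, 1.0]]),
            conc=np.ones((1, 2)),
        )
        sections = _null_sections(space, np.ones(1), 0.3)
        res = fit_mcmc(
            sections, space, ModelSpec(), prior_from_edec([1.0]),
            MCMCSettings(chains=2, iterations=300, burn_in=100, thin=1),
            seed=0,
        )
        summary = summarize_posterior(res, min_draws=100)
        assert summary["mean"].iloc[0] == 1.0
        assert summary["sd"].iloc[0] == 0.0
        assert (summary["q2.5"].iloc[0], summary["q97.5"].iloc[0]) == (1.0, 1.0)

    def test_every_draw_on_simplex(self, space, scenario_sections):
        sdat = scenario_sections[scenario_sections["season"] == "autumn"]
        res = fit_mcmc(
            sdat, space, ModelSpec.from_label("Sex + BearID"), prior_from_edec([1] * 7),
            MCMCSettings(chains=2, iterations=600, burn_in=300, thin=1),
            seed=3,
        )
        pop = res.p_population()
        assert np.all(pop >= 0)
        np.testing.assert_allclose(pop.sum(axis=1), 1.0, atol=1e-12)
        for bear in res.bear_ids[:3]:
            pb = res.p_bear(bear)
            np.testing.assert_allclose(pb.sum(axis=1), 1.0, atol=1e-12)
        male = res.p_level("sex", "M")
        np.testing.assert_allclose(male.sum(axis=1), 1.0, atol=1e-12)

    def test_flat_prior_no_data_gives_uniform_means(self, space):
        """With alpha = 1 and the likelihood flattened (huge fixed residual
        SD), posterior means must approach 1/K."""
        p0 = np.full(7, 1.0 / 7)
        sections = _null_sections(space, p0, 0.5, n=10)
        res = fit_mcmc(
            sections, space, ModelSpec(), prior_from_edec([1.0] * 7),
            MCMCSettings(
                chains=3, iterations=12000, burn_in=6000, thin=3,
                sigma_res_fixed=(1e6, 1e6),
            ),
            seed=5,
        )
        pop = res.p_population()
        np.testing.assert_allclose(pop.mean(axis=0), 1.0 / 7, atol=0.03)

    def test_unknown_sex_bears_dropped_from_sex_models(self, space):
        sections = _null_sections(space, np.full(7, 1 / 7), 0.5, n=20)
        sections.loc[sections["bear_id"] == "b0", "sex"] = "unknown"
        res = fit_mcmc(
            sections, space, ModelSpec.from_label("Sex"), prior_from_edec([1] * 7),
            MCMCSettings(chains=2, iterations=200, burn_in=100, thin=1), seed=0,
        )
        assert res.n_dropped == 4
        assert "b0" not in res.bear_ids

    def test_seeded_runs_identical(self, space):
        sections = _null_sections(space, np.full(7, 1 / 7), 0.5, n=15)
        kw = dict(
            space=space, model=ModelSpec(), prior=prior_from_edec([1] * 7),
            settings=MCMCSettings(chains=2, iterations=400, burn_in=200, thin=2),
            seed=9,
        )
        a = fit_mcmc(sections, **kw)
        b = fit_mcmc(sections, **kw)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.pointwise_loglik, b.pointwise_loglik)


class TestSummaries:
    def test_uniform_grid_draws_quantiles(self, space):
        """Posterior summaries are plain moments/quantiles of the draws."""
        res = _fake_result(space)
        tab = summarize_posterior(res, min_draws=100)
        first = tab.iloc[0]
        draws = res.p_population()[:, 0]
        assert first["mean"] == pytest.approx(draws.mean())
        assert first["q2.5"] == pytest.approx(np.quantile(draws, 0.025))
        assert first["q97.5"] == pytest.approx(np.quantile(draws, 0.975))

    def test_permutation_invariance(self, space):
        res = _fake_result(space)
        shuffled = _fake_result(space)
        rng = np.random.default_rng(0)
        flat = shuffled.mu.reshape(-1, shuffled.mu.shape[-1])
        perm = rng.permutation(len(flat))
        shuffled.mu = flat[perm].reshape(shuffled.mu.shape)
        a = summarize_posterior(res, min_draws=100)
        b = summarize_posterior(shuffled, min_draws=100)
        pd.testing.assert_frame_equal(a, b)

    def test_min_draws_enforced(self, space):
        res = _fake_result(space, n=30)
        with pytest.raises(ValueError, match="draws"):
            summarize_posterior(res, min_draws=100)


def _fake_result(space, n=300):
    """A result whose mu draws are a deterministic grid."""
    from hairsimm.compositions import ilr
    from hairsimm.diagnostics import ConvergenceReport
    from hairsimm.simm import PosteriorResult

    rng = np.random.default_rng(1234)
    p = rng.dirichlet(np.ones(space.n_sources), size=n)
    mu = ilr(np.clip(p, 1e-9, None) / p.sum(axis=1, keepdims=True))
    return PosteriorResult(
        model=ModelSpec(), source_names=space.names, coef_labels=[],
        bear_ids=["b0"], bear_index=np.zeros(1, dtype=int),
        mu=mu[None, :, :], beta=np.zeros((1, n, 0, space.n_sources - 1)),
        u=None, sigma_res=np.full((1, n, 2), 0.5), sigma_u=None,
        pointwise_loglik=np.zeros((n, 1)),
        convergence=ConvergenceReport(), settings=MCMCSettings(
            chains=1, iterations=n, burn_in=0, thin=1
        ),
        seed=0, isotopes=("d13C", "d15N"), bear_X=np.zeros((1, 0)),
    )


def test_model_structure_labels_cover_the_seven():
    assert set(MODEL_STRUCTURES) == {
        "Null", "Sex", "Status", "BearID", "Sex + Status", "Sex + BearID",
        "Status + BearID",
    }
    for label in MODEL_STRUCTURES:
        assert ModelSpec.from_label(label).label == label
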