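import math

import numpy as np
import pytest
from scipy import stats

from iwrecords import (
    GammaPrior,
    IWDParams,
    MHConfig,
    PosteriorDraws,
    RecordSample,
    credible_interval,
    log_likelihood,
    log_posterior,
    log_prior,
    mh_sample,
    posterior_summary,
    prior_moments,
    sensitivity_table,
)
from iwrecords.bayes import summarize_chain
from iwrecords.model import InverseWeibullRecords

STD = IWDParams(1.0, 1.0)


class TestPrior:
    @pytest.mark.parametrize(
        "prior, expected",
        [
            (GammaPrior(3, 3, 3, 3), (1.0, 1 / 3, 1.0, 1 / 3)),
            (GammaPrior(1, 0.6, 1, 0.6), (5 / 3, 25 / 9, 5 / 3, 25 / 9)),
            (GammaPrior(1, 1, 1, 1), (1.0, 1.0, 1.0, 1.0)),
        ],
    )
    def test_prior_moments(self, prior, expected):
        np.testing.assert_allclose(prior_moments(prior), expected, rtol=1e-12)

    def test_log_prior_hand_value(self):
        # unit-exponential priors: log density is -phi - gamma up to constants
        assert log_prior(IWDParams(2.0, 3.0), GammaPrior(1, 1, 1, 1)) == pytest.approx(-5.0)

    def test_log_prior_differences_match_gamma_density(self):
        prior = GammaPrior(2.5, 1.5, 3.0, 0.7)
        p1, p2 = IWDParams(0.8, 2.0), IWDParams(3.0, 0.4)
        ref = (
            stats.gamma.logpdf(p1.phi, 2.5, scale=1 / 1.5)
            + stats.gamma.logpdf(p1.gamma, 3.0, scale=1 / 0.7)
            - stats.gamma.logpdf(p2.phi, 2.5, scale=1 / 1.5)
            - stats.gamma.logpdf(p2.gamma, 3.0, scale=1 / 0.7)
        )
        assert log_prior(p1, prior) - log_prior(p2, prior) == pytest.approx(ref, abs=1e-10)

    def test_log_prior_maximizer_is_gamma_mode(self):
        prior = GammaPrior(3.0, 2.0, 1.0, 1.0)
        phis = np.linspace(0.01, 5, 2000)
        vals = [log_prior(IWDParams(ph, 1.0), prior) for ph in phis]
        assert phis[np.argmax(vals)] == pytest.approx((3.0 - 1.0) / 2.0, abs=0.01)

    def test_nonpositive_params_give_minus_inf(self):
        assert log_prior(IWDParams(-1.0, 1.0), GammaPrior(1, 1, 1, 1)) == -math.inf

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            prior_moments(GammaPrior(0.0, 1, 1, 1))


class TestLogPosterior:
    def test_decomposition_identity(self, records_n20):
        prior = GammaPrior(3, 3, 3, 3)
        p = IWDParams(0.7, 1.4)
        assert log_posterior(records_n20, p, prior) - log_likelihood(records_n20, p) == (
            pytest.approx(log_prior(p, prior), abs=1e-10)
        )

    def test_flat_prior_argmax_matches_mle_argmax(self, records_n50):
        flat = GammaPrior(1.0, 1e-8, 1.0, 1e-8)
        phis = np.exp(np.linspace(math.log(0.05), math.log(20), 120))
        gams = np.exp(np.linspace(math.log(0.2), math.log(4), 120))
        lp = np.array(
            [[log_posterior(records_n50, IWDParams(ph, g), flat) for ph in phis] for g in gams]
        )
        ll = np.array(
            [[log_likelihood(records_n50, IWDParams(ph, g)) for ph in phis] for g in gams]
        )
        assert np.unravel_index(np.argmax(lp), lp.shape) == np.unravel_index(
            np.argmax(ll), ll.shape
        )

    def test_finite_on_positive_quadrant(self, records_n20):
        prior = GammaPrior(3, 3, 3, 3)
        for p in (IWDParams(0.01, 0.1), IWDParams(10.0, 3.0), IWDParams(1.0, 1.0)):
            assert math.isfinite(log_posterior(records_n20, p, prior))


class TestSampler:
    def test_prior_recovery_with_no_data(self):
        # empty likelihood: the chain must reproduce the prior moments
        prior = GammaPrior(3.0, 3.0, 2.0, 4.0)
        draws = mh_sample(RecordSample(np.empty(0)), prior, MHConfig(iterations=20000, seed=4))
        summ = posterior_summary(draws)
        m_phi, _, m_gam, _ = prior_moments(prior)
        assert abs(summ["phi"].estimate - m_phi) < 3 * max(summ["phi"].mc_error, 1e-3)
        assert abs(summ["gamma"].estimate - m_gam) < 3 * max(summ["gamma"].mc_error, 1e-3)

    def test_posterior_mean_matches_quadrature_oracle(self, records_n50):
        prior = GammaPrior(3, 3, 3, 3)
        from iwrecords.bayes import _make_log_posterior

        lp = _make_log_posterior(records_n50, prior)
        phis = np.linspace(0.05, 5, 400)
        gams = np.linspace(0.05, 5, 400)
        grid = np.array([[lp(ph, g) for ph in phis] for g in gams])
        w = np.exp(grid - grid.max())
        z = np.trapezoid(np.trapezoid(w, phis, axis=1), gams)
        oracle_phi = np.trapezoid(np.trapezoid(w * phis[None, :], phis, axis=1), gams) / z
        oracle_gam = np.trapezoid(np.trapezoid(w * gams[:, None], phis, axis=1), gams) / z
        draws = mh_sample(records_n50, prior, MHConfig(iterations=20000, seed=5))
        assert draws.phi.mean() == pytest.approx(oracle_phi, abs=0.02)
        assert draws.gamma.mean() == pytest.approx(oracle_gam, abs=0.02)

    def test_seed_determinism(self, records_n20):
        prior = GammaPrior(3, 3, 3, 3)
        cfg = MHConfig(iterations=2000, seed=9)
        a = mh_sample(records_n20, prior, cfg)
        b = mh_sample(records_n20, prior, cfg)
        np.testing.assert_array_equal(a.pairs, b.pairs)
        assert a.acceptance_rate == b.acceptance_rate

    def test_acceptance_rate_in_tuned_band(self, records_n50):
        draws = mh_sample(records_n50, GammaPrior(3, 3, 3, 3), MHConfig(iterations=5000, seed=1))
        assert 0.1 < draws.acceptance_rate < 0.9

    def test_shrinkage_toward_concentrated_prior_mean(self, records_n50):
        # priors of mean 1 with growing concentration pull the posterior mean
        # of phi monotonically toward 1 relative to the flattest fit
        cfg = MHConfig(iterations=8000, seed=2)
        gaps = []
        for c in (1.0, 20.0, 400.0):
            draws = mh_sample(records_n50, GammaPrior(c, c, c, c), cfg)
            gaps.append(abs(draws.phi.mean() - 1.0))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_too_few_iterations_rejected(self, records_n20):
        with pytest.raises(ValueError):
            mh_sample(records_n20, GammaPrior(1, 1, 1, 1), MHConfig(iterations=50))

    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError):
            MHConfig(iterations=1000, burn_in=1000).resolved_burn_in()


class TestSummaries:
    def test_constant_chain(self):
        s = summarize_chain(np.full(500, 2.0))
        assert s == (2.0, 0.0, 0.0, 2.0, 2.0, 2.0)

    def test_uniform_grid_chain(self):
        v = np.arange(1, 1001) / 1000.0
        s = summarize_chain(v)
        assert s.median == pytest.approx(0.5, abs=1e-3)
        assert s.q025 == pytest.approx(0.025, abs=2e-3)
        assert s.q975 == pytest.approx(0.975, abs=2e-3)

    def test_mc_error_bounded_by_sd(self, records_n20):
        draws = mh_sample(records_n20, GammaPrior(3, 3, 3, 3), MHConfig(iterations=3000, seed=3))
        for s in posterior_summary(draws).values():
            assert s.mc_error <= s.se
            assert s.q025 <= s.median <= s.q975

    def test_minimum_draw_count_enforced(self):
        d = PosteriorDraws(np.full((50, 2), 1.0), 0.4, MHConfig())
        with pytest.raises(ValueError):
            posterior_summary(d)

    def test_draw_positivity_enforced(self):
        with pytest.raises(ValueError):
            PosteriorDraws(np.array([[1.0, -1.0]]), 0.5, MHConfig())


class TestCredibleIntervals:
    def test_uniform_grid_interval(self):
        grid = np.arange(1, 1001) / 1000.0
        d = PosteriorDraws(np.column_stack([grid, grid]), 0.5, MHConfig())
        ci = credible_interval(d, 0.95)
        np.testing.assert_allclose(ci[:, 0], 0.025, atol=2e-3)
        np.testing.assert_allclose(ci[:, 1], 0.975, atol=2e-3)

    def test_contains_median(self, records_n20):
        draws = mh_sample(records_n20, GammaPrior(3, 3, 3, 3), MHConfig(iterations=3000, seed=6))
        ci = credible_interval(draws, 0.95)
        summ = posterior_summary(draws)
        assert ci[0, 0] <= summ["phi"].median <= ci[0, 1]
        assert ci[1, 0] <= summ["gamma"].median <= ci[1, 1]

    def test_level_domain(self, records_n20):
        draws = mh_sample(records_n20, GammaPrior(3, 3, 3, 3), MHConfig(iterations=2000, seed=7))
        with pytest.raises(ValueError):
            credible_interval(draws, 1.2)


class TestSensitivity:
    def test_table_structure(self, records_n20):
        priors = [GammaPrior(1, 1, 1, 1), GammaPrior(2, 2, 2, 2), GammaPrior(3, 3, 3, 3)]
        table = sensitivity_table(records_n20, priors, MHConfig(iterations=2000, seed=1))
        assert len(table) == 2 * len(priors)
        assert set(table["parameter"]) == {"phi", "gamma"}
        assert np.all(table["q2.5"] <= table["median"])
        assert np.all(table["median"] <= table["q97.5"])
        assert np.all(table["mc_error"] <= table["se"])

    def test_empty_prior_list_rejected(self, records_n20):
        with pytest.raises(ValueError):
            sensitivity_table(records_n20, [])


class TestResultsObject:
    def test_fit_bayes_summary(self, records_n20):
        res = InverseWeibullRecords(records_n20).fit_bayes(
            GammaPrior(3, 3, 3, 3), MHConfig(iterations=3000, seed=8)
        )
        summ = res.summary()
        assert list(summ.index) == ["phi", "gamma"]
        assert np.all(summ["2.5%"] <= summ["median"])
        ci = res.credible_interval(0.9)
        assert ci.shape == (2, 2)
        assert res.params.phi > 0 and res.params.gamma > 0
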