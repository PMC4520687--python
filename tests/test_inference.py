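import numpy as np
import pytest
from scipy.stats import norm

from thiodose import config
from thiodose.exceptions import EmptyGroupError
from thiodose.inference import (
    Band,
    ErrorParams,
    LogNormalPrior,
    MeasurementSeries,
    PosteriorSamples,
    adaptive_metropolis,
    build_group_prior,
    build_population_prior,
    fit_mle,
    fit_variational,
    gaussian_elbo_fit,
    lack_of_fit,
    log_likelihood,
    predictive_band,
    sample_posterior_mcmc,
)
from thiodose.pkmodel import DoseSchedule, PKParams, simulate_fast


def make_series(params, times, doses, sigma_add=10.0, sigma_prop=0.05, seed=0,
                patient_id="P"):
    rng = np.random.default_rng(seed)
    xm = simulate_fast(params, doses, np.asarray(times, float)).x_m
    sigma = sigma_add + sigma_prop * xm
    y = np.clip(xm + sigma * rng.standard_normal(xm.size), 0.0, None)
    return MeasurementSeries(patient_id, np.asarray(times, float), y, doses)


class TestLogLikelihood:
    def test_perfect_fit_unit_sigma(self, mean_params, daily_doses):
        times = np.array([7.0, 21.0])
        xm = simulate_fast(mean_params, daily_doses, times).x_m
        s = MeasurementSeries("P", times, xm, daily_doses)
        ll = log_likelihood(s, mean_params, ErrorParams(1.0, 0.0))
        assert ll == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)))

    def test_matches_term_by_term_formula(self, mean_params, daily_doses):
        times = np.array([7.0, 21.0, 35.0])
        y = np.array([100.0, 220.0, 230.0])
        s = MeasurementSeries("P", times, y, daily_doses)
        err = ErrorParams(8.0, 0.07)
        yhat = simulate_fast(mean_params, daily_doses, times).x_m
        sigma = err.sigma_add + err.sigma_prop * yhat
        expected = sum(norm.logpdf(yi, mi, si) for yi, mi, si in zip(y, yhat, sigma))
        assert log_likelihood(s, mean_params, err) == pytest.approx(expected)

    def test_two_points_sum_of_terms(self, mean_params, daily_doses):
        t1, t2 = np.array([7.0]), np.array([21.0])
        err = ErrorParams(5.0, 0.0)
        y1 = make_series(mean_params, t1, daily_doses, seed=1)
        y2 = make_series(mean_params, t2, daily_doses, seed=2)
        both = MeasurementSeries(
            "P", np.array([7.0, 21.0]), np.r_[y1.y, y2.y], daily_doses
        )
        assert log_likelihood(both, mean_params, err) == pytest.approx(
            log_likelihood(y1, mean_params, err) + log_likelihood(y2, mean_params, err)
        )


class TestMLE:
    def test_recovers_truth_from_dense_noise_free_data(self, mean_params):
        doses = DoseSchedule.daily(100.0, 56)
        times = np.arange(1.0, 57.0)
        xm = simulate_fast(mean_params, doses, times).x_m
        s = MeasurementSeries("P", times, xm, doses)
        params, err = fit_mle(s, seed=1)
        # the conversion/elimination pair dominates the output and is the
        # identifiable subset at this sampling density
        assert params.k_cm == pytest.approx(mean_params.k_cm, rel=0.01)
        assert params.k_me == pytest.approx(mean_params.k_me, rel=0.01)

    def test_optimum_at_least_as_good_as_truth(self, mean_params, daily_doses):
        s = make_series(mean_params, [7.0, 21.0, 35.0], daily_doses, seed=3)
        with pytest.warns(UserWarning):  # sparse series: nuisance params fixed
            params, err = fit_mle(s, seed=0)
        assert log_likelihood(s, params, err) >= log_likelihood(
            s, mean_params, ErrorParams(10.0, 0.05)
        ) - 1e-6

    def test_too_few_observations_rejected(self, mean_params, daily_doses):
        s = make_series(mean_params, [35.0], daily_doses)
        with pytest.raises(ValueError):
            fit_mle(s)


class TestMCMC:
    def test_conjugate_gaussian_posterior(self):
        # prior N(0,1), one observation y=2 with unit noise: posterior N(1, 1/2)
        def logpost(x):
            return -0.5 * x[0] ** 2 - 0.5 * (2.0 - x[0]) ** 2

        draws, diag = adaptive_metropolis(
            logpost, np.zeros(1), np.eye(1), n_draws=20000, seed=4
        )
        assert abs(draws.mean() - 1.0) < 0.07
        assert abs(draws.var() - 0.5) < 0.07
        assert diag["rhat"].max() < 1.05

    def test_no_data_returns_prior(self):
        # flat likelihood: the sampler must reproduce the prior moments
        mu, sd = 1.3, 0.6

        def logpost(x):
            return -0.5 * ((x[0] - mu) / sd) ** 2

        draws, _ = adaptive_metropolis(
            logpost, np.array([mu]), np.array([[sd**2]]), n_draws=20000, seed=5
        )
        assert draws.mean() == pytest.approx(mu, abs=0.06)
        assert draws.std() == pytest.approx(sd, abs=0.06)

    def test_posterior_contraction_with_more_data(self, mean_params, prior):
        doses = DoseSchedule.daily(100.0, 56)
        s4 = make_series(mean_params, [7.0, 21.0, 35.0, 56.0], doses, seed=6)
        t8 = [4.0, 7.0, 14.0, 21.0, 28.0, 35.0, 45.0, 56.0]
        s8 = make_series(mean_params, t8, doses, seed=6)
        p4 = sample_posterior_mcmc(s4, prior, n_draws=4000, seed=7)
        p8 = sample_posterior_mcmc(s8, prior, n_draws=4000, seed=7)
        sd4 = p4.sd()[2]
        sd8 = p8.sd()[2]
        assert sd8 <= sd4 * 1.15  # Monte-Carlo slack

    def test_seed_reproducible(self, mean_params, daily_doses, prior):
        s = make_series(mean_params, [7.0, 35.0, 56.0], daily_doses, seed=8)
        a = sample_posterior_mcmc(s, prior, n_draws=800, seed=9, n_chains=2)
        b = sample_posterior_mcmc(s, prior, n_draws=800, seed=9, n_chains=2)
        assert np.array_equal(a.draws, b.draws)


class TestVariational:
    def test_exact_gaussian_posterior_zero_kl(self):
        # when the target is itself Gaussian the bound is tight: exact moment
        # match and ELBO equal to the log-normalizer (zero KL)
        mu = np.array([0.5, -1.0])
        cov = np.array([[0.5, 0.2], [0.2, 0.8]])
        prec = np.linalg.inv(cov)
        _, logdet = np.linalg.slogdet(cov)
        lognorm = -0.5 * (2 * np.log(2 * np.pi) + logdet)

        def logpost(x):
            d = x - mu
            return lognorm - 0.5 * d @ prec @ d

        m, c, elbo, ok = gaussian_elbo_fit(
            logpost, np.zeros(2), np.eye(2), seed=0, n_mc=16, max_iter=400
        )
        assert ok
        assert np.allclose(m, mu, atol=1e-4)
        assert np.allclose(c, cov, atol=1e-3)
        assert elbo == pytest.approx(0.0, abs=1e-5)

    def test_elbo_below_quadrature_evidence(self):
        # 2-parameter non-Gaussian toy whose evidence is computable on a grid
        def logjoint(x):
            return (
                -0.5 * (x[0] ** 2 + x[1] ** 2)
                - 0.5 * (1.5 - x[0] * x[1]) ** 2
                - np.log(2 * np.pi)
            )

        g = np.linspace(-6, 6, 401)
        xx, yy = np.meshgrid(g, g)
        vals = np.exp(
            -0.5 * (xx**2 + yy**2) - 0.5 * (1.5 - xx * yy) ** 2 - np.log(2 * np.pi)
        )
        log_evidence = np.log(np.trapezoid(np.trapezoid(vals, g, axis=1), g))
        m, c, elbo, _ = gaussian_elbo_fit(
            logjoint, np.zeros(2), 0.5 * np.eye(2), seed=1, n_mc=64, max_iter=400
        )
        assert elbo <= log_evidence + 0.02  # small quasi-MC slack

    def test_moments_match_mcmc_on_synthetic_patient(self, prior):
        from thiodose.synthetic_data import generate_dataset

        series, _ = generate_dataset("D2", seed=5)
        s = series[0]
        post = sample_posterior_mcmc(s, prior, n_draws=12000, seed=1)
        vb = fit_variational(s, prior, seed=2, n_mc=32, max_iter=300)
        vbs = vb.posterior_samples(4000, np.random.default_rng(0))
        diff = np.abs(vbs.mean() - post.mean()) / post.sd()
        assert diff.max() < 0.2


class TestPooledPriors:
    def _posterior(self, shift, n=400, seed=0):
        rng = np.random.default_rng(seed)
        draws = np.exp(
            np.log([4.2, 3.8, 39.4 * shift, 15.0, 0.08, 10.0, 0.05])
            + 0.1 * rng.standard_normal((n, 7))
        )
        return PosteriorSamples(draws, np.ones(n))

    def test_single_patient_population_prior(self):
        post = self._posterior(1.0)
        pop = build_population_prior([post], [3])
        assert np.allclose(pop.mvn_mean, post.mean(), atol=1e-8)

    def test_mixture_weights_proportional_to_counts(self):
        p1, p2 = self._posterior(0.8, seed=1), self._posterior(1.2, seed=2)
        pop = build_population_prior([p1, p2], [1, 3])
        assert np.allclose(pop.weights, [0.25, 0.75])
        expected = 0.25 * p1.mean() + 0.75 * p2.mean()
        assert np.allclose(pop.mvn_mean, expected, atol=1e-10)

    def test_group_prior_partitions_draws(self):
        posts = [self._posterior(1.0, seed=i) for i in range(4)]
        acts = [8.0, 10.5, 12.0, 16.0]
        n = [2, 3, 1, 4]
        g1 = build_group_prior(posts, acts, n, (7.0, 9.0))
        g2 = build_group_prior(posts, acts, n, (9.0, 13.0))
        g3 = build_group_prior(posts, acts, n, (13.0, 30.0))
        total = sum(g.draws.shape[0] for g in (g1, g2, g3))
        assert total == sum(p.draws.shape[0] for p in posts)
        full = build_group_prior(posts, acts, n, (7.0, 30.0))
        pop = build_population_prior(posts, n)
        assert np.array_equal(full.draws, pop.draws)
        assert np.allclose(full.weights, pop.draw_weights)

    def test_empty_group_raises(self):
        posts = [self._posterior(1.0)]
        with pytest.raises(EmptyGroupError):
            build_group_prior(posts, [8.0], [2], (20.0, 22.0))

    def test_mixture_weights_normalized(self):
        posts = [self._posterior(1.0, seed=i) for i in range(3)]
        pop = build_population_prior(posts, [1, 2, 3])
        assert pop.draw_weights.sum() == pytest.approx(1.0)


class TestPredictiveBand:
    def _delta_posterior(self, theta7, n=200):
        return PosteriorSamples(np.tile(theta7, (n, 1)), np.ones(n))

    def test_level_one_spans_sample_range(self, mean_params, daily_doses):
        post = self._delta_posterior(np.r_[mean_params.theta(), 10.0, 0.05])
        band = predictive_band(post, daily_doses, [35.0], level=1.0, n_draws=300, seed=0)
        assert band.lo[0] < band.hi[0]

    def test_zero_noise_single_draw_collapses(self, mean_params, daily_doses):
        post = PosteriorSamples(
            np.r_[mean_params.theta(), 1e-12, 1e-12][None, :], np.ones(1)
        )
        times = np.array([7.0, 35.0])
        with pytest.warns(UserWarning):
            band = predictive_band(post, daily_doses, times, include_noise=False, seed=0)
        xm = simulate_fast(mean_params, daily_doses, times).x_m
        assert np.allclose(band.lo, xm) and np.allclose(band.hi, xm)

    def test_gaussian_predictive_matches_analytic_hpd(self, mean_params, daily_doses):
        sigma = 25.0
        post = self._delta_posterior(np.r_[mean_params.theta(), sigma, 1e-12], n=500)
        times = np.array([35.0])
        band = predictive_band(post, daily_doses, times, n_draws=6000, seed=1)
        xm = simulate_fast(mean_params, daily_doses, times).x_m[0]
        assert band.lo[0] == pytest.approx(xm - 1.96 * sigma, abs=0.12 * sigma)
        assert band.hi[0] == pytest.approx(xm + 1.96 * sigma, abs=0.12 * sigma)


class TestLackOfFit:
    def _band(self):
        t = np.arange(5.0)
        return Band(t, np.full(5, -1.0), np.full(5, 1.0), 0.95)

    def test_all_points_inside(self):
        res = lack_of_fit(np.arange(5.0), np.zeros(5), self._band())
        assert res.n_inside == res.n_total == 5

    def test_gross_misfit_rejected(self):
        t = np.arange(20.0)
        band = Band(t, np.full(20, -1.0), np.full(20, 1.0), 0.95)
        res = lack_of_fit(t, np.full(20, 5.0), band)
        assert res.n_inside == 0
        assert res.confidence == pytest.approx(1.0)
        assert not res.adequate

    def test_calibration_under_the_model(self):
        # points drawn from the predictive itself land inside the 95% HPD
        # about 95% of the time
        rng = np.random.default_rng(2)
        t = np.arange(50.0)
        band = Band(t, np.full(50, -1.96), np.full(50, 1.96), 0.95)
        fractions = []
        for _ in range(40):
            y = rng.standard_normal(50)
            res = lack_of_fit(t, y, band)
            fractions.append(res.n_inside / res.n_total)
        assert np.mean(fractions) == pytest.approx(0.95, abs=0.02)
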