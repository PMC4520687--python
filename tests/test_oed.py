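import numpy as np
import pytest

from thiodose.inference import (
    ErrorParams,
    LogNormalPrior,
    MeasurementSeries,
    PosteriorSamples,
    sample_posterior_mcmc,
)
from thiodose.oed import (
    DesignResult,
    expected_information_profile,
    fisher_information,
    output_sensitivities,
    select_sampling_time,
    select_sampling_time_from_arrays,
)
from thiodose.pkmodel import DoseSchedule, PKParams, simulate_fast


class TestSensitivities:
    def test_matches_central_finite_differences(self, mean_params, daily_doses):
        times = np.array([7.0, 21.0, 35.0, 56.0])
        names = ("k_ab", "k_el", "k_cm", "K", "k_me")
        S = output_sensitivities(mean_params, daily_doses, times, names)
        theta = mean_params.theta()
        for j in range(5):
            h = 1e-5 * theta[j]
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (
                simulate_fast(PKParams.from_theta(tp), daily_doses, times).x_m
                - simulate_fast(PKParams.from_theta(tm), daily_doses, times).x_m
            ) / (2 * h)
            scale = np.abs(fd).max()
            assert np.abs(S[:, j] - fd).max() / scale < 1e-3

    def test_zero_dose_zero_sensitivity(self, mean_params):
        S = output_sensitivities(mean_params, DoseSchedule(), np.array([5.0]), ("k_cm",))
        assert np.allclose(S, 0.0)

    def test_empty_subset_rejected(self, mean_params, daily_doses):
        with pytest.raises(ValueError):
            output_sensitivities(mean_params, daily_doses, [1.0], ())


class TestFisherInformation:
    def test_single_time_single_parameter(self):
        I = fisher_information(np.array([[3.0]]), ErrorParams(1.0, 0.0), np.array([10.0]))
        assert I.shape == (1, 1) and I[0, 0] == pytest.approx(9.0)

    def test_adding_measurements_never_decreases_det(self):
        rng = np.random.default_rng(0)
        err = ErrorParams(5.0, 0.05)
        S = rng.standard_normal((6, 2))
        yhat = rng.uniform(50, 300, 6)
        dets = [
            np.linalg.det(fisher_information(S[:k], err, yhat[:k])) for k in (2, 4, 6)
        ]
        assert dets[0] <= dets[1] + 1e-12 <= dets[2] + 1e-11

    def test_matches_directly_assembled_matrix(self):
        S = np.array([[1.0, 2.0], [0.5, -1.0], [2.0, 0.0]])
        yhat = np.array([100.0, 200.0, 150.0])
        err = ErrorParams(10.0, 0.1)
        sig = 10.0 + 0.1 * yhat
        expected = sum(
            np.outer(S[t], S[t]) / sig[t] ** 2 for t in range(3)
        )
        assert np.allclose(fisher_information(S, err, yhat), expected)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        S = rng.standard_normal((5, 2))
        yhat = rng.uniform(10, 100, 5)
        err = ErrorParams(3.0, 0.02)
        perm = rng.permutation(5)
        a = np.linalg.det(fisher_information(S, err, yhat))
        b = np.linalg.det(fisher_information(S[perm], err, yhat[perm]))
        assert a == pytest.approx(b, rel=1e-10)


class TestProfileSelection:
    def test_fraction_zero_strictly_increasing_takes_last(self):
        t = np.arange(1.0, 11.0)
        assert select_sampling_time_from_arrays(t, t**2, 0.0) == 10.0

    def test_flat_profile_takes_earliest(self):
        t = np.arange(1.0, 11.0)
        assert select_sampling_time_from_arrays(t, np.ones(10), 0.05) == 1.0

    def test_plateau_takes_earliest_plateau_day(self):
        t = np.arange(1.0, 61.0)
        info = np.minimum(t / 30.0, 1.0)  # plateau from day 30
        assert select_sampling_time_from_arrays(t, info, 0.0) == 30.0
        # 5% compromise admits slightly earlier days
        assert select_sampling_time_from_arrays(t, info, 0.05) == pytest.approx(28.5, abs=1.0)

    def test_reselect_from_design_result(self):
        res = DesignResult(np.arange(1.0, 6.0), np.array([1, 2, 3, 4, 4.0]), 4.0, 0.0, ("k_cm",))
        assert select_sampling_time(res, 0.0) == 4.0


class TestExpectedInformation:
    def _prior_draws(self, n, seed=0, spread=0.3):
        rng = np.random.default_rng(seed)
        base = np.log([4.2, 3.8, 39.4, 15.11, 0.08, 10.0, 0.05])
        return PosteriorSamples(
            np.exp(base + spread * rng.standard_normal((n, 7))), np.ones(n)
        )

    def test_single_draw_profile_equals_that_draw(self, mean_params, daily_doses):
        post = PosteriorSamples(
            np.r_[mean_params.theta(), 10.0, 0.05][None, :], np.ones(1)
        )
        days = np.array([10.0, 35.0, 60.0])
        res = expected_information_profile(post, days, daily_doses, ("k_cm",), n_draws=5, seed=0)
        S = output_sensitivities(mean_params, daily_doses, days, ("k_cm",))
        yhat = simulate_fast(mean_params, daily_doses, days).x_m
        expected = (S[:, 0] / (10.0 + 0.05 * yhat)) ** 2
        assert np.allclose(res.expected_information, expected, rtol=1e-8)

    def test_profile_increases_toward_steady_state(self, daily_doses):
        post = self._prior_draws(100)
        days = np.arange(1.0, 76.0, 2.0)
        res = expected_information_profile(post, days, daily_doses, ("k_cm",), n_draws=100, seed=1)
        ei = res.expected_information
        assert ei[5] > ei[0]
        assert ei[-1] > ei[len(ei) // 2] > ei[2]

    def test_exhaustive_scan_oracle_for_single_parameter(self, daily_doses):
        # D-optimality for one parameter reduces to maximizing the squared
        # noise-scaled sensitivity, verifiable by direct scan
        post = self._prior_draws(40, seed=3)
        days = np.arange(5.0, 76.0, 5.0)
        res = expected_information_profile(
            post, days, daily_doses, ("k_cm",), n_draws=40, seed=4,
            compromise_fraction=0.0,
        )
        scan = np.zeros(days.size)
        rng = np.random.default_rng(4)
        draws = post.resample(40, rng)
        for row in draws:
            p = PKParams.from_theta(row[:5])
            S = output_sensitivities(p, daily_doses, days, ("k_cm",))[:, 0]
            yhat = simulate_fast(p, daily_doses, days).x_m
            scan += (S / (row[5] + row[6] * yhat)) ** 2 / 40
        assert np.allclose(res.expected_information, scan, rtol=1e-6)
        assert res.chosen_time == days[np.argmax(scan)]

    def test_design_day_beats_early_day_for_estimation(self, daily_doses, prior):
        # one observation at the information-rich day yields a tighter k_cm
        # posterior than one taken in the first week, on average
        rng = np.random.default_rng(5)
        post = self._prior_draws(100, seed=6)
        days = np.arange(1.0, 76.0)
        res = expected_information_profile(post, days, daily_doses, ("k_cm",), n_draws=50, seed=7)
        t_star, t_early = res.chosen_time, 3.0
        wins = 0
        n_pat = 8
        for i in range(n_pat):
            theta = np.exp(
                np.log([4.2, 3.8, 39.4, 15.11, 0.08]) + 0.3 * rng.standard_normal(5)
            )
            p = PKParams.from_theta(theta)
            sds = {}
            for t in (t_star, t_early):
                xm = simulate_fast(p, daily_doses, np.array([t])).x_m
                sig = 10.0 + 0.05 * xm
                y = np.clip(xm + sig * rng.standard_normal(1), 0.0, None)
                series = MeasurementSeries(f"p{i}", np.array([t]), y, daily_doses)
                post_i = sample_posterior_mcmc(
                    series, prior, n_draws=1500, seed=100 + i, n_chains=2,
                    estimate=("k_cm",),
                    fixed={"k_ab": 4.2, "k_el": 3.8, "K": 15.11, "k_me": 0.08,
                           "sigma_add": 10.0, "sigma_prop": 0.05},
                )
                sds[t] = post_i.sd()[2]
            if sds[t_star] <= sds[t_early]:
                wins += 1
        assert wins >= n_pat - 2
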