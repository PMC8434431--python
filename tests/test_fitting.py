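"""Unit tests for linearization diagnostics and nonlinear fitting."""

import math

import numpy as np
import pytest

from weibull_release import (
    DomainError,
    FitError,
    NoiseModel,
    ReleaseProfile,
    SamplingSchedule,
    WeibullParams,
    compare_models,
    default_powerlaw_window,
    fit_weibull_cdf,
    generate_profile,
    goodness_of_fit,
    loglog_powerlaw_fit,
    weibull_cdf,
    weibull_inverse,
    weibull_plot_fit,
    weibull_plot_transform,
)
from conftest import make_noiseless_profile


class TestReleaseProfile:
    def test_sorts_points(self):
        prof = ReleaseProfile(times=[3.0, 1.0, 2.0], release=[9.0, 1.0, 4.0])
        assert list(prof.times) == [1.0, 2.0, 3.0]
        assert list(prof.release) == [1.0, 4.0, 9.0]

    def test_rejects_duplicates(self):
        with pytest.raises(DomainError):
            ReleaseProfile(times=[1.0, 1.0, 2.0], release=[1.0, 2.0, 3.0])

    def test_rejects_short(self):
        with pytest.raises(DomainError):
            ReleaseProfile(times=[1.0, 2.0], release=[1.0, 2.0])

    def test_rejects_negative(self):
        with pytest.raises(DomainError):
            ReleaseProfile(times=[-1.0, 1.0, 2.0], release=[0.0, 1.0, 2.0])
        with pytest.raises(DomainError):
            ReleaseProfile(times=[1.0, 2.0, 3.0], release=[-1.0, 1.0, 2.0])

    def test_plateau(self):
        prof = ReleaseProfile(times=[1, 2, 3], release=[1, 2, 5], m_inf_hint=7.5)
        assert prof.plateau == 7.5
        prof2 = ReleaseProfile(times=[1, 2, 3], release=[1, 2, 5])
        assert prof2.plateau == 5.0


class TestLoglogPowerlawFit:
    def test_exact_square_root_law(self):
        t = np.array([1.0, 4.0, 9.0, 16.0])
        prof = ReleaseProfile(times=t, release=2 * np.sqrt(t))
        fit = loglog_powerlaw_fit(prof)
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(math.log(2), abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 4

    def test_nanofiber_small_t_slope(self, nanofibers):
        # window chosen so (t/tau_k)**beta < 0.1, where the power-law limit
        # holds to ~5%; the observed log-log slope then tracks beta to ~5%
        prof = make_noiseless_profile(nanofibers, times=np.geomspace(0.05, 0.4, 12))
        fit = loglog_powerlaw_fit(prof)
        assert fit.slope == pytest.approx(0.71, abs=0.05 * 0.71)

    def test_colloid_small_t_slope(self, colloids):
        prof = make_noiseless_profile(colloids, times=np.geomspace(1.0, 8.0, 12))
        fit = loglog_powerlaw_fit(prof)
        assert fit.slope == pytest.approx(2.67, abs=0.05)

    def test_window_restriction(self, nanofibers):
        prof = make_noiseless_profile(nanofibers, times=np.geomspace(0.01, 80, 40))
        fit = loglog_powerlaw_fit(prof, window=(0.01, 0.4))
        assert fit.slope == pytest.approx(0.71, abs=0.05 * 0.71)
        assert fit.window[1] <= 0.4

    def test_zero_release_points_excluded(self):
        prof = ReleaseProfile(times=[1, 2, 3, 4, 5],
                              release=[0.0, 1.0, 1.41, 1.73, 2.0])
        fit = loglog_powerlaw_fit(prof)
        assert fit.n_points == 4

    def test_too_few_points(self):
        prof = ReleaseProfile(times=[1, 2, 3], release=[0.0, 0.0, 1.0])
        with pytest.raises(FitError):
            loglog_powerlaw_fit(prof)


class TestDefaultPowerlawWindow:
    def test_threshold_arithmetic(self):
        prof = ReleaseProfile(
            times=[1, 2, 4, 8, 16, 32],
            release=[2, 5, 12, 20, 26, 27.5],
            m_inf_hint=27.8,
        )
        # threshold 0.6 * 27.8 = 16.68; the initial run {2, 5, 12} qualifies
        lo, hi = default_powerlaw_window(prof)
        assert lo == 1.0
        assert hi == 4.0

    def test_all_below_threshold(self):
        prof = ReleaseProfile(times=[1, 2, 3], release=[1, 2, 3], m_inf_hint=100.0)
        assert default_powerlaw_window(prof) == (1.0, 3.0)

    def test_window_end_matches_inversion(self, colloids):
        prof = make_noiseless_profile(
            colloids, times=np.linspace(0.5, 80, 160)
        )
        _, hi = default_powerlaw_window(prof)
        t60 = weibull_inverse(0.6 * colloids.m_inf, colloids)
        assert abs(hi - t60) <= 0.5  # within one grid step

    def test_no_qualifying_points(self):
        prof = ReleaseProfile(times=[1, 2, 3], release=[90, 95, 99], m_inf_hint=100)
        with pytest.raises(FitError):
            default_powerlaw_window(prof, fraction=0.5)


class TestWeibullPlot:
    def test_known_point(self, colloids):
        t = colloids.tau_k
        m = colloids.m_inf * (1 - math.exp(-1))
        prof = ReleaseProfile(times=[t / 2, t, 2 * t],
                              release=[1.0, m, colloids.m_inf - 0.1])
        x, y, n_excl = weibull_plot_transform(prof, colloids.m_inf)
        assert n_excl == 0
        i = int(np.argmin(np.abs(x - math.log(t))))
        assert y[i] == pytest.approx(0.0, abs=1e-12)

    def test_collinear_for_exact_data(self, nanofibers):
        prof = make_noiseless_profile(nanofibers, times=np.arange(1.0, 81.0))
        fit = weibull_plot_fit(prof, nanofibers.m_inf)
        assert fit.slope == pytest.approx(0.71, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.beta0 == pytest.approx(nanofibers.beta, abs=1e-10)
        assert fit.tau_k0 == pytest.approx(nanofibers.tau_k, rel=1e-9)

    def test_exact_slope_any_params(self):
        p = WeibullParams(42.0, 3.3, 1.7)
        prof = make_noiseless_profile(p, times=np.geomspace(0.1, 20, 15))
        fit = weibull_plot_fit(prof, p.m_inf)
        assert fit.slope == pytest.approx(p.beta, rel=1e-9)

    def test_noisy_slope_within_band(self, colloids):
        # the double-log transform blows noise up near release -> 0 and
        # release -> plateau, so the noisy-data check trims to the
        # informative 10-90% fraction band
        prof = generate_profile(
            colloids, SamplingSchedule(kind="uniform", n_points=20),
            NoiseModel(sd=0.3, seed=99),
        )
        fit = weibull_plot_fit(prof, colloids.m_inf,
                               release_fraction_range=(0.1, 0.9))
        assert fit.slope == pytest.approx(colloids.beta, abs=0.2)

    def test_points_above_m_inf_excluded(self, colloids):
        prof = ReleaseProfile(times=[1, 5, 10, 20, 30],
                              release=[0.1, 1.0, 3.0, 8.0, 15.2])
        x, y, n_excl = weibull_plot_transform(prof, colloids.m_inf)
        assert n_excl == 1
        assert x.size == 4

    def test_too_few_transformable(self, colloids):
        prof = ReleaseProfile(times=[1, 2, 3], release=[0.0, 16.0, 16.0 + 1e-9])
        with pytest.raises((FitError, DomainError)):
            weibull_plot_transform(prof, 15.1)


class TestFitWeibullCdf:
    def test_noiseless_recovery(self, nanofibers):
        prof = make_noiseless_profile(nanofibers)
        fit = fit_weibull_cdf(prof, m_inf=nanofibers.m_inf)
        assert fit.converged
        assert fit.m_inf_fixed
        assert fit.params.tau_k == pytest.approx(10.51, abs=1e-6)
        assert fit.params.beta == pytest.approx(0.71, abs=1e-6)
        assert fit.residual_rmse == pytest.approx(0.0, abs=1e-8)
        assert "m_inf" not in fit.param_ses

    def test_noisy_recovery_seed1234(self, nanofibers):
        prof = generate_profile(
            nanofibers,
            SamplingSchedule(kind="log_spaced", n_points=25, t_max=80, t_min=0.25),
            NoiseModel(sd=0.5, seed=1234),
        )
        fit = fit_weibull_cdf(prof, m_inf=nanofibers.m_inf)
        assert fit.converged
        assert fit.params.beta == pytest.approx(0.71, abs=0.10)

    def test_free_m_inf(self, colloids):
        prof = make_noiseless_profile(colloids, times=np.geomspace(0.5, 150, 30))
        fit = fit_weibull_cdf(prof, free_m_inf=True)
        assert fit.converged
        assert not fit.m_inf_fixed
        assert "m_inf" in fit.param_ses
        assert fit.params.m_inf == pytest.approx(15.1, rel=1e-4)
        assert fit.params.beta == pytest.approx(2.67, rel=1e-4)

    def test_reorder_invariance(self, colloids):
        times = np.geomspace(0.5, 80, 20)
        release = weibull_cdf(times, colloids)
        rng = np.random.default_rng(0)
        perm = rng.permutation(20)
        a = fit_weibull_cdf(
            ReleaseProfile(times=times, release=release), m_inf=colloids.m_inf
        )
        b = fit_weibull_cdf(
            ReleaseProfile(times=times[perm], release=release[perm]),
            m_inf=colloids.m_inf,
        )
        assert a.params == b.params

    def test_weighted_fit(self, colloids):
        prof = make_noiseless_profile(colloids)
        fit = fit_weibull_cdf(prof, m_inf=colloids.m_inf,
                              weights=np.full(len(prof), 2.0))
        assert fit.params.beta == pytest.approx(colloids.beta, abs=1e-6)

    def test_point_count_requirements(self, colloids):
        # 3 points suffice with m_inf fixed, but not with m_inf free
        times = np.array([10.0, 25.0, 40.0])
        prof = ReleaseProfile(times=times, release=weibull_cdf(times, colloids))
        fit = fit_weibull_cdf(prof, m_inf=colloids.m_inf)
        assert fit.params.beta == pytest.approx(colloids.beta, abs=1e-5)
        with pytest.raises(FitError):
            fit_weibull_cdf(prof, free_m_inf=True)


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        obs = [1.0, 2.0, 3.0, 4.0]
        r2, rmse, aicc = goodness_of_fit(obs, obs, n_params=2)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0)

    def test_mean_prediction_gives_zero_r2(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _, _ = goodness_of_fit(obs, np.full(4, obs.mean()), n_params=1)
        assert r2 == pytest.approx(0.0)

    def test_zero_variance_r2_undefined(self):
        r2, _, _ = goodness_of_fit([2.0, 2.0, 2.0], [2.0, 2.1, 1.9], n_params=1)
        assert math.isnan(r2)

    def test_weibull_beats_higuchi_on_sigmoidal_data(self, colloids):
        prof = generate_profile(
            colloids, SamplingSchedule(kind="paperlike", n_points=20),
            NoiseModel(sd=0.3, seed=7),
        )
        cmp_ = compare_models(prof, candidates=("higuchi", "weibull"),
                              m_inf=colloids.m_inf)
        assert cmp_.records["weibull"].aicc < cmp_.records["higuchi"].aicc


class TestCompareModels:
    def test_zero_order_self_selection(self):
        t = np.linspace(1, 20, 15)
        prof = ReleaseProfile(times=t, release=1.5 * t)
        cmp_ = compare_models(prof, candidates=("zero_order", "higuchi", "power_law"))
        assert cmp_.best_model == "zero_order"

    def test_sigmoidal_selects_weibull(self, colloids):
        prof = generate_profile(
            colloids, SamplingSchedule(kind="paperlike", n_points=20),
            NoiseModel(sd=0.3, seed=7),
        )
        cmp_ = compare_models(prof, m_inf=colloids.m_inf)
        assert cmp_.best_model == "weibull"

    def test_single_candidate(self, noiseless_nanofibers):
        cmp_ = compare_models(noiseless_nanofibers, candidates=("higuchi",))
        assert cmp_.best_model == "higuchi"

    def test_unknown_candidate(self, noiseless_nanofibers):
        with pytest.raises(DomainError):
            compare_models(noiseless_nanofibers, candidates=("weibull", "nope"))

    def test_unknown_criterion(self, noiseless_nanofibers):
        with pytest.raises(DomainError):
            compare_models(noiseless_nanofibers, criterion="bic")

    def test_best_minimizes_criterion(self, noiseless_colloids):
        cmp_ = compare_models(noiseless_colloids, m_inf=15.1)
        best = cmp_.records[cmp_.best_model]
        assert all(best.aicc <= rec.aicc for rec in cmp_.records.values())


class TestConsistency:
    def test_recovery_improves_with_less_noise(self, nanofibers):
        sched = SamplingSchedule(kind="log_spaced", n_points=25, t_max=80, t_min=0.25)
        errors = []
        for sd in (2.0, 0.5, 0.05):
            errs = []
            for seed in (11, 12, 13, 14, 15):
                prof = generate_profile(nanofibers, sched, NoiseModel(sd=sd, seed=seed))
                fit = fit_weibull_cdf(prof, m_inf=nanofibers.m_inf)
                errs.append(abs(fit.params.beta - nanofibers.beta))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]
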