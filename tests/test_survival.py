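"""LQ survival: G-factor closed form vs quadrature, chaining, fits, thresholds."""

import numpy as np
import pytest
from scipy import integrate

from prrtdose.kinetics import KineticParams
from prrtdose.survival import (
    ChainedSurvival,
    FitFailureError,
    RadiobiologyParams,
    chain_intervals,
    fit_growth,
    fit_repair,
    growth_curve,
    lea_catcheside_G,
    minimal_effective_dose_rate,
    rbe,
    sample_alpha,
    survival,
    survival_map,
)
from prrtdose.synthetic import default_ground_truth


def g_oracle(kin: KineticParams, mu: float, t: float) -> float:
    """Independent double-integral evaluation of the protraction factor."""
    A, B = kin.r0 - kin.p, kin.p
    a, b = kin.lambda_e, kin.lambda_p

    def rate(tt):
        return A * np.exp(-a * tt) + B * np.exp(-b * tt)

    def outer(tp):
        inner, _ = integrate.quad(
            lambda ts: rate(ts) * np.exp(-mu * (tp - ts)), 0.0, tp,
            epsabs=1e-14, epsrel=1e-12, limit=300,
        )
        return rate(tp) * inner

    num, _ = integrate.quad(outer, 0.0, t, epsabs=1e-14, epsrel=1e-12, limit=300)
    d = A / a * (1 - np.exp(-a * t)) + B / b * (1 - np.exp(-b * t))
    return 2.0 * num / d**2


@pytest.fixture()
def kin():
    return KineticParams(r0=10.0, p=1.0, lambda_e=0.03, lambda_p=0.00434)


class TestLeaCatcheside:
    def test_no_repair_limit_is_one(self, kin):
        assert lea_catcheside_G(kin, 1e-12, 5000.0) == pytest.approx(1.0, abs=1e-4)

    def test_single_exponential_asymptote(self):
        """For P=0 and t→∞ the factor reduces to λe/(λe+μ)."""
        kin = KineticParams(r0=10.0, p=0.0, lambda_e=0.03)
        mu = 0.0116
        g = lea_catcheside_G(kin, mu, 1e6)
        assert g == pytest.approx(0.03 / (0.03 + mu), rel=1e-9)
        assert g == pytest.approx(g_oracle(kin, mu, 2000.0), rel=1e-4)

    def test_reference_case_matches_quadrature(self, kin):
        mu = 0.01155
        got = lea_catcheside_G(kin, mu, 120.0)
        assert got == pytest.approx(g_oracle(kin, mu, 120.0), rel=1e-6)

    def test_parameter_sweep_matches_quadrature(self):
        """Closed form ≡ double-integral quadrature over random kinetics."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            r0 = rng.uniform(1.0, 50.0)
            p = r0 * rng.uniform(0.0, 0.5)
            lam_e = rng.uniform(0.006, 0.1)
            mu = rng.uniform(0.002, 0.1)
            t = rng.uniform(5.0, 500.0)
            if min(abs(mu - lam_e), abs(mu - 0.00434)) < 1e-4:
                continue
            k = KineticParams(r0=r0, p=p, lambda_e=lam_e, lambda_p=0.00434)
            assert lea_catcheside_G(k, mu, t) == pytest.approx(
                g_oracle(k, mu, t), rel=1e-6
            )

    def test_monotone_nonincreasing_in_repair_rate(self, kin):
        mus = [1e-4, 1e-3, 0.01, 0.1, 1.0]
        gs = [lea_catcheside_G(kin, m, 200.0) for m in mus]
        assert all(g2 < g1 for g1, g2 in zip(gs, gs[1:]))
        assert all(0 < g <= 1 for g in gs)

    def test_near_degenerate_rates_fall_back_to_quadrature(self, kin):
        mu = kin.lambda_e + 1e-8  # inside the degeneracy guard
        got = lea_catcheside_G(kin, mu, 100.0)
        assert got == pytest.approx(g_oracle(kin, mu, 100.0), rel=1e-5)

    def test_invalid_inputs_rejected(self, kin):
        with pytest.raises(ValueError):
            lea_catcheside_G(kin, 0.01, 0.0)
        with pytest.raises(ValueError):
            lea_catcheside_G(kin, -1.0, 10.0)


class TestSurvival:
    def test_zero_dose_leaves_pure_repopulation(self):
        rad = RadiobiologyParams.from_half_times(0.14, 100.0, 60.0, 14.5)
        t = 48.0
        assert survival(rad, 0.0, 1.0, t) == pytest.approx(np.exp(rad.gamma * t))

    def test_linear_kill_at_reciprocal_alpha_dose(self):
        rad = RadiobiologyParams(alpha=0.25, alpha_beta_ratio=np.inf, mu=0.01)
        assert survival(rad, 1.0 / 0.25, 1.0, 10.0) == pytest.approx(np.exp(-1.0))

    def test_direct_evaluation(self):
        rad = RadiobiologyParams(alpha=0.14, alpha_beta_ratio=100.0, mu=0.0116,
                                 gamma=0.1 / 50.0)
        e = survival(rad, 3.0, 0.5, 50.0)
        expected = np.exp(0.1) * np.exp(-0.14 * 3.0 - 0.5 * 0.0014 * 9.0)
        assert e == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_dose_and_alpha(self):
        rad1 = RadiobiologyParams(0.14, 100.0, 0.0116)
        rad2 = RadiobiologyParams(0.264, 100.0, 0.0116)
        d = np.linspace(0, 10, 50)
        e1 = survival(rad1, d, 1.0, 0.0)
        assert np.all(np.diff(e1) < 0)
        assert np.all(survival(rad2, d[1:], 1.0, 0.0) < e1[1:])


class TestSurvivalMap:
    @pytest.fixture()
    def setup(self):
        truth = default_ground_truth()
        return truth.kinetics, truth.radiobiology

    def test_uniform_map_equals_average_approach(self, setup):
        kin, rad = setup
        r0 = np.full(100, 25.0)
        het = survival_map(r0, kin, rad, 48.0)
        avg = survival_map(r0, kin, rad, 48.0, average_approach=True)
        assert np.ptp(het.e) == 0.0
        assert het.e[0] == pytest.approx(avg.e[0], rel=1e-12)

    def test_zero_activity_gives_pure_repopulation(self, setup):
        kin, rad = setup
        res = survival_map(np.zeros(10), kin, rad, 48.0)
        np.testing.assert_allclose(res.e, np.exp(rad.gamma * 48.0))

    def test_heterogeneous_kill_exceeds_average_approach(self, setup):
        """Jensen: with a common G, mean log-survival of a heterogeneous
        dose map is at most the log-survival at the mean dose."""
        kin, rad = setup
        rng = np.random.default_rng(5)
        r0 = rng.lognormal(np.log(25.0), 0.6, 2000)
        het = survival_map(r0, kin, rad, 48.0)
        avg = survival_map(r0, kin, rad, 48.0, average_approach=True)
        assert np.log(het.e).mean() <= np.log(avg.e[0]) + 1e-12

    def test_average_approach_equals_scalar_pipeline(self, setup):
        kin, rad = setup
        rng = np.random.default_rng(6)
        r0 = rng.uniform(5, 50, 500)
        avg = survival_map(r0, kin, rad, 30.0, average_approach=True)
        scalar = survival_map(np.array([r0.mean()]), kin, rad, 30.0)
        assert avg.e[0] == pytest.approx(scalar.e[0], rel=1e-12)


class TestChaining:
    @pytest.fixture()
    def setup(self):
        truth = default_ground_truth()
        return truth.kinetics, truth.radiobiology

    def test_single_interval_preserves_distribution(self, setup):
        kin, rad = setup
        rng = np.random.default_rng(2)
        res = survival_map(rng.uniform(10, 40, 300), kin, rad, 48.0)
        chained = chain_intervals([res], n_samples=20000, seed=1)
        assert isinstance(chained, ChainedSurvival)
        assert chained.samples.mean() == pytest.approx(res.e.mean(), rel=0.02)
        assert set(np.round(np.unique(chained.samples), 12)).issubset(
            set(np.round(res.e, 12))
        )

    def test_zero_dose_course_is_point_mass_of_repopulation(self, setup):
        kin, rad = setup
        durations = [48.0, 72.0, 144.0, 72.0]  # the 0-2, 2-5, 5-11, 11-14 d split
        results = [survival_map(np.zeros(50), kin, rad, d) for d in durations]
        chained = chain_intervals(results, n_samples=1000, seed=3)
        expected = np.exp(rad.gamma * 14.0 * 24.0)
        np.testing.assert_allclose(chained.samples, expected, rtol=1e-12)

    def test_two_uniform_intervals_multiply_exactly(self, setup):
        kin, rad = setup
        r1 = survival_map(np.full(10, 20.0), kin, rad, 48.0)
        r2 = survival_map(np.full(10, 10.0), kin, rad, 72.0)
        chained = chain_intervals([r1, r2], n_samples=100, seed=0)
        np.testing.assert_allclose(chained.samples, r1.e[0] * r2.e[0], rtol=1e-12)

    def test_empty_interval_list_rejected(self):
        with pytest.raises(ValueError):
            chain_intervals([])

    def test_gaussian_alpha_widens_survival_dispersion(self, setup):
        """Radiosensitivity spread inflates outcome spread at a fixed map."""
        kin, _ = setup
        rad_fixed = RadiobiologyParams.from_half_times(0.14, 100.0, 60.0, 14.5)
        rad_gauss = RadiobiologyParams.from_half_times(0.14, 100.0, 60.0, 14.5,
                                                       alpha_sd=0.03)
        rng = np.random.default_rng(8)
        r0 = rng.lognormal(np.log(25.0), 0.3, 3000)
        alphas = sample_alpha(rad_gauss, r0.size, seed=9)
        fixed = survival_map(r0, kin, rad_fixed, 48.0)
        spread = survival_map(r0, kin, rad_gauss, 48.0, alpha_samples=alphas)
        assert spread.e.std() > fixed.e.std()


class TestGrowthFit:
    def test_pure_exponential_growth(self):
        t = np.linspace(0, 30, 10)
        v = 200.0 * np.exp(0.05 * t)
        fit = fit_growth(t, v)
        assert fit.td_days == pytest.approx(np.log(2) / 0.05, rel=1e-4)
        assert fit.k1 == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_piecewise_curve_recovered_to_4_digits(self):
        t = np.arange(0.0, 42.1, 3.0)
        v = growth_curve(t, 300.0, 0.12, 0.25, 0.1778, 3.0, 20.0)
        fit = fit_growth(t, v, t0_d=3.0)
        assert fit.k0 == pytest.approx(0.12, rel=1e-4)
        assert fit.k1 == pytest.approx(0.25, rel=1e-4)
        assert fit.k2 == pytest.approx(0.1778, rel=1e-4)
        assert fit.t1_d == pytest.approx(20.0, rel=1e-3)
        assert fit.v0 == pytest.approx(300.0, rel=1e-4)

    def test_doubling_time_recovered_from_truth(self):
        truth = default_ground_truth()
        t = np.arange(0.0, 42.1, 3.0)
        v = growth_curve(t, truth.v0_mm3, truth.k0_per_d, truth.k1_per_d,
                         truth.k2_per_d, truth.t0_d, truth.t1_d)
        fit = fit_growth(t, v, t0_d=truth.t0_d)
        assert fit.td_defined
        assert fit.td_days == pytest.approx(truth.td_days, rel=1e-4)

    def test_shrinking_forever_flags_undefined_doubling_time(self):
        t = np.arange(0.0, 42.1, 3.0)
        v = growth_curve(t, 300.0, 0.02, 0.30, 0.0, 3.0, 20.0)
        fit = fit_growth(t, v)
        assert not fit.td_defined
        assert np.isnan(fit.td_days)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_growth([0, 1, 2, 3, 4], [1, 2, 3, 4, 5])


class TestRepairFit:
    def test_noiseless_60h_half_life_recovered_exactly(self):
        t = np.array([0.0, 30.0, 60.0, 90.0, 120.0, 150.0])
        y = 8.0 * np.exp(-np.log(2) / 60.0 * t)
        fit = fit_repair(t, y)
        assert fit.t_mu_h == pytest.approx(60.0, rel=1e-6)
        assert fit.model == "decay"

    def test_flat_series_flagged_near_zero_rate(self):
        t = np.array([0.0, 30.0, 60.0, 90.0])
        fit = fit_repair(t, np.array([5.0, 5.0, 5.0, 5.0]))
        assert fit.flagged_flat

    def test_increasing_series_rejected(self):
        t = np.array([0.0, 30.0, 60.0, 90.0])
        with pytest.raises(FitFailureError):
            fit_repair(t, np.array([1.0, 2.0, 3.0, 4.0]))

    def test_poisson_counts_recover_within_10_percent(self):
        from prrtdose.synthetic import generate_foci_series

        truth = default_ground_truth()
        table = generate_foci_series(truth, [0, 30, 60, 90, 120, 150],
                                     n_cells=500, seed=0)
        fit = fit_repair(table["t_h"], table["foci_per_cell"])
        assert fit.t_mu_h == pytest.approx(60.0, rel=0.10)


class TestDoseRateThreshold:
    def test_linear_limit_is_gamma_over_alpha(self):
        rad = RadiobiologyParams(alpha=0.2, alpha_beta_ratio=np.inf, mu=0.0116,
                                 gamma=0.002)
        assert minimal_effective_dose_rate(rad) == pytest.approx(
            0.002 / 0.2 * 1000.0, rel=1e-9
        )

    def test_solution_satisfies_defining_balance(self):
        rad = RadiobiologyParams.from_half_times(0.14, 100.0, 60.0, 14.5)
        r = minimal_effective_dose_rate(rad) / 1000.0  # Gy/h
        kill = rad.alpha * r + 2.0 * rad.beta / rad.mu * r**2
        assert kill == pytest.approx(rad.gamma, rel=1e-6)

    def test_without_repopulation_rejected(self):
        rad = RadiobiologyParams(alpha=0.14, alpha_beta_ratio=100.0, mu=0.0116)
        with pytest.raises(ValueError):
            minimal_effective_dose_rate(rad)


class TestRBEAndAlphaSampling:
    def test_identical_alphas_give_unity(self):
        assert rbe(0.264, 0.264) == 1.0

    def test_internal_vs_external_reference_rounds_to_0_4(self):
        assert round(rbe(0.1, 0.264), 1) == 0.4

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            rbe(0.1, 0.0)

    def test_sample_mean_matches_at_large_n(self):
        rad = RadiobiologyParams(0.14, 100.0, 0.0116, alpha_sd=0.03)
        draws = sample_alpha(rad, 100_000, seed=1)
        # truncation at zero shifts the mean by < 1 SE at this mean/sd ratio
        se = 0.03 / np.sqrt(100_000)
        assert abs(draws.mean() - 0.14) < 3 * se + 0.001
        assert draws.min() >= 0.0
        np.testing.assert_array_equal(draws, sample_alpha(rad, 100_000, seed=1))
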