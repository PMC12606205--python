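"""Inverse fitting: aggregation, power-law fit, a<->K conversion, rheometry."""

import math

import numpy as np
import pytest

from extruflow import (
    AggregatedSeries,
    PowerLawCurve,
    PowerLawFluid,
    aggregate_measurements,
    average_index,
    coefficient_from_consistency,
    consistency_from_coefficient,
    fit_fixed_n,
    fit_newtonian,
    fit_power_law,
    fit_rheometry,
    proportionality_coefficient,
    r_squared,
)
from extruflow.fitting import _optimal_a


def series_from_curve(a, n, pressures):
    """Noise-free aggregated series generated by d = a * dP^(1/2n)."""
    p = np.asarray(pressures, dtype=float)
    d = a * p ** (1 / (2 * n))
    return AggregatedSeries(pressures=p, d_mean=d, d_sd=np.zeros_like(p), m_lines=np.ones_like(p, dtype=int))


class TestAggregation:
    def test_line_mean_of_three_positions(self, tiny_dataset):
        series = aggregate_measurements(tiny_dataset)
        assert series.d_mean[0] == pytest.approx(0.32e-3, rel=1e-14)
        assert series.m_lines[0] == 1
        assert series.d_sd[0] == 0.0  # single line: sd undefined -> 0

    def test_unbalanced_lines_average_line_means_not_raw_widths(self, make_dataset):
        # line 1 has 3 positions, line 2 only 2: the per-pressure mean is the
        # mean of the two line means, not of the 5 raw widths
        ds = make_dataset(
            [
                (5e4, 1, 1, "start", 0.30e-3),
                (5e4, 1, 1, "middle", 0.33e-3),
                (5e4, 1, 1, "end", 0.30e-3),
                (5e4, 1, 2, "start", 0.40e-3),
                (5e4, 1, 2, "middle", 0.44e-3),
            ]
        )
        series = aggregate_measurements(ds)
        line1 = (0.30e-3 + 0.33e-3 + 0.30e-3) / 3
        line2 = (0.40e-3 + 0.44e-3) / 2
        assert series.d_mean[0] == pytest.approx((line1 + line2) / 2, rel=1e-14)
        assert series.m_lines[0] == 2
        raw_mean = np.mean([0.30e-3, 0.33e-3, 0.30e-3, 0.40e-3, 0.44e-3])
        assert series.d_mean[0] != pytest.approx(raw_mean, rel=1e-6)
        raw_series = aggregate_measurements(ds, convention="raw")
        assert raw_series.d_mean[0] == pytest.approx(raw_mean, rel=1e-14)
        assert raw_series.m_lines[0] == 5

    def test_repeats_pool_into_per_pressure_stats(self, make_dataset):
        ds = make_dataset(
            [(5e4, r, l, "middle", (0.3 + 0.01 * r + 0.001 * l) * 1e-3) for r in (1, 2) for l in (1, 2, 3)]
        )
        series = aggregate_measurements(ds)
        line_means = [(0.3 + 0.01 * r + 0.001 * l) * 1e-3 for r in (1, 2) for l in (1, 2, 3)]
        assert series.m_lines[0] == 6
        assert series.d_mean[0] == pytest.approx(np.mean(line_means), rel=1e-14)
        assert series.d_sd[0] == pytest.approx(np.std(line_means, ddof=1), rel=1e-12)


class TestPowerLawFit:
    def test_noiseless_recovery(self):
        pressures = np.linspace(6e4, 8e4, 20)
        series = series_from_curve(1.2e-18, 0.165, pressures)
        fit = fit_power_law(series)
        assert fit.n == pytest.approx(0.165, rel=1e-4)
        assert fit.a == pytest.approx(1.2e-18, rel=1e-4)
        assert fit.R2 == pytest.approx(1.0, abs=1e-10)

    def test_two_point_exponent_identity(self):
        # two exact points give n = ln(P2/P1) / (2 ln(d2/d1)); a 3rd point on
        # the same curve keeps the free fit well-posed and must reproduce it
        a_true, n_true = 5e-9, 0.42
        p = np.array([2e4, 5e4, 8e4])
        series = series_from_curve(a_true, n_true, p)
        d = series.d_mean
        n_closed = math.log(p[2] / p[0]) / (2 * math.log(d[2] / d[0]))
        assert n_closed == pytest.approx(n_true, rel=1e-12)
        fit = fit_power_law(series)
        assert fit.n == pytest.approx(n_closed, rel=1e-6)

    def test_optimizer_never_beaten_by_dense_grid(self, rng):
        """Profile-search SSR is within 1e-6 (relative) of a dense (a, n) grid."""
        for _ in range(5):
            n_true = rng.uniform(0.1, 1.2)
            a_true = 10 ** rng.uniform(-18, -6)
            p = np.sort(rng.uniform(2e4, 9e4, size=12))
            d = a_true * p ** (1 / (2 * n_true)) * (1 + 0.03 * rng.standard_normal(12))
            series = AggregatedSeries(
                pressures=p, d_mean=d, d_sd=np.zeros_like(p), m_lines=np.ones_like(p, dtype=int)
            )
            fit = fit_power_law(series)
            grid_ssr = min(_optimal_a(p, d, n)[1] for n in np.linspace(0.01, 2.0, 2000))
            assert fit.SSR <= grid_ssr * (1 + 1e-6)

    def test_needs_three_pressures(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_power_law(series_from_curve(1e-9, 0.5, [1e4, 2e4]))

    def test_reports_K_with_geometry(self, conical_22g):
        fluid = PowerLawFluid(n=0.165, K=560.0)
        U = 5e-3
        a = proportionality_coefficient(fluid, conical_22g, U)
        series = series_from_curve(a, fluid.n, np.linspace(6e4, 8e4, 10))
        fit = fit_power_law(series, nozzle=conical_22g, U=U)
        assert fit.K == pytest.approx(560.0, rel=1e-4)


class TestFixedNFits:
    def test_newtonian_exact_sqrt_data(self):
        series = series_from_curve(2e-6, 1.0, np.linspace(1e4, 9e4, 9))
        fit = fit_newtonian(series)
        assert fit.R2 == pytest.approx(1.0, abs=1e-12)
        assert fit.a == pytest.approx(2e-6, rel=1e-12)

    def test_newtonian_closed_form_equals_grid_search(self, rng):
        p = np.linspace(1e4, 9e4, 12)
        d = 2e-6 * np.sqrt(p) * (1 + 0.05 * rng.standard_normal(12))
        series = AggregatedSeries(
            pressures=p, d_mean=d, d_sd=np.zeros_like(p), m_lines=np.ones_like(p, dtype=int)
        )
        fit = fit_newtonian(series)
        a_grid = np.linspace(0.5 * fit.a, 1.5 * fit.a, 20001)
        x = np.sqrt(p)
        ssr_grid = ((d[None, :] - a_grid[:, None] * x[None, :]) ** 2).sum(axis=1)
        assert fit.a == pytest.approx(a_grid[np.argmin(ssr_grid)], rel=1e-4)
        assert fit.SSR <= ssr_grid.min() * (1 + 1e-12)

    def test_fixed_n_equals_newtonian_at_one(self, rng):
        p = np.linspace(1e4, 9e4, 8)
        d = 2e-6 * np.sqrt(p) * (1 + 0.02 * rng.standard_normal(8))
        series = AggregatedSeries(
            pressures=p, d_mean=d, d_sd=np.zeros_like(p), m_lines=np.ones_like(p, dtype=int)
        )
        f1 = fit_fixed_n(series, 1.0)
        f2 = fit_newtonian(series)
        assert f1.a == f2.a and f1.SSR == f2.SSR

    def test_fixing_true_n_recovers_K(self, conical_22g):
        fluid = PowerLawFluid(n=0.165, K=560.0)
        U = 5e-3
        a = proportionality_coefficient(fluid, conical_22g, U)
        series = series_from_curve(a, fluid.n, np.linspace(6e4, 8e4, 10))
        fit = fit_fixed_n(series, 0.165, nozzle=conical_22g, U=U)
        assert fit.K == pytest.approx(560.0, rel=1e-8)

    def test_fixed_at_free_optimum_matches_free_fit(self):
        series = series_from_curve(1.2e-18, 0.165, np.linspace(6e4, 8e4, 15))
        free = fit_power_law(series)
        fixed = fit_fixed_n(series, free.n)
        assert fixed.a == pytest.approx(free.a, rel=1e-12)
        assert fixed.SSR == pytest.approx(free.SSR, abs=1e-30)


class TestCoefficientConsistencyConversion:
    @pytest.mark.parametrize("n,K,U", [(0.165, 560.0, 5e-3), (0.457, 2959.6, 5e-3), (1.0, 1.0, 1e-2)])
    def test_round_trip_K_a_K(self, conical_22g, n, K, U):
        a = coefficient_from_consistency(K, n, conical_22g, U)
        assert consistency_from_coefficient(a, n, conical_22g, U) == pytest.approx(K, rel=1e-10)

    def test_doubling_K_scales_a(self, conical_22g):
        n, U = 0.165, 5e-3
        a1 = coefficient_from_consistency(560.0, n, conical_22g, U)
        a2 = coefficient_from_consistency(1120.0, n, conical_22g, U)
        assert a2 / a1 == pytest.approx(2 ** (-1 / (2 * n)), rel=1e-10)

    def test_straight_agrees_with_degenerate_cone(self):
        from extruflow import ConicalNozzle, StraightNozzle

        cone = ConicalNozzle(Di=4e-4, Do=4e-4, Lc=0.01)
        cyl = StraightNozzle(DN=4e-4, LN=0.01)
        a_cone = coefficient_from_consistency(100.0, 0.5, cone, 5e-3)
        a_cyl = coefficient_from_consistency(100.0, 0.5, cyl, 5e-3)
        assert a_cone == pytest.approx(a_cyl, rel=1e-14)


class TestGoodnessOfFit:
    def test_perfect_fit_r2_is_one(self):
        series = series_from_curve(1e-9, 0.5, [1e4, 4e4, 9e4])
        assert r_squared(series, PowerLawCurve(a=1e-9, n=0.5)) == pytest.approx(1.0, abs=1e-14)

    def test_mean_model_r2_is_zero(self):
        series = series_from_curve(1e-9, 0.5, [1e4, 4e4, 9e4])
        mean_value = float(np.mean(series.d_mean))
        assert r_squared(series, lambda p: np.full_like(np.asarray(p, float), mean_value)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_zero_sst_is_an_error(self):
        series = AggregatedSeries(
            pressures=np.array([1e4, 2e4]),
            d_mean=np.array([3e-4, 3e-4]),
            d_sd=np.zeros(2),
            m_lines=np.ones(2, dtype=int),
        )
        with pytest.raises(ValueError, match="total sum of squares"):
            r_squared(series, PowerLawCurve(a=1e-9, n=0.5))


class TestAverageIndex:
    def test_reported_index_triplet(self):
        # the three soft-colloid fits average to the headline shared index
        assert average_index([0.1694, 0.1654, 0.1635]) == pytest.approx(0.1661, abs=5e-5)

    def test_single_and_identical(self):
        assert average_index([0.42]) == 0.42
        assert average_index([0.3, 0.3, 0.3]) == pytest.approx(0.3, rel=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_index([])


class TestRheometry:
    def test_exact_power_law_recovery(self):
        g = np.geomspace(10, 1e4, 12)
        mu = 10.0 * g ** (0.5 - 1)
        n, K = fit_rheometry(g, mu)
        assert n == pytest.approx(0.5, rel=1e-12)
        assert K == pytest.approx(10.0, rel=1e-12)

    def test_constant_viscosity_is_newtonian(self):
        g = np.array([1.0, 10.0, 100.0])
        n, K = fit_rheometry(g, np.full(3, 3.0))
        assert n == pytest.approx(1.0, abs=1e-12)
        assert K == pytest.approx(3.0, rel=1e-12)

    def test_ols_matches_log_grid_search(self, rng):
        g = np.geomspace(10, 1e4, 15)
        mu = 20.0 * g ** (0.3 - 1) * np.exp(0.05 * rng.standard_normal(15))
        n_hat, K_hat = fit_rheometry(g, mu)

        def log_ssr(n, K):
            return np.sum((np.log(mu) - (np.log(K) + (n - 1) * np.log(g))) ** 2)

        best = min(
            ((n, K) for n in np.linspace(0.2, 0.4, 201) for K in np.geomspace(10, 40, 201)),
            key=lambda t: log_ssr(*t),
        )
        assert n_hat == pytest.approx(best[0], abs=2e-3)
        assert K_hat == pytest.approx(best[1], rel=2e-2)
        assert log_ssr(n_hat, K_hat) <= log_ssr(*best) * (1 + 1e-9)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            fit_rheometry([1.0, -2.0], [1.0, 1.0])
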