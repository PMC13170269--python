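"""Synthetic-data generators: growth law, kill curves, tradeoff cohorts, IO."""

import numpy as np
import pytest
from scipy import stats as sps

from thermolag.growth import logistic_od, preprocess, time_to_threshold
from thermolag.simulate import (
    GrowthModelParams,
    KillModelParams,
    TradeoffCohortParams,
    default_time_grid,
    generate_tradeoff_cohort,
    kill_mean_cfu,
    simulate_growth_curve,
    simulate_kill_curve,
    write_plate_tables,
)
from thermolag import io as tlio
from thermolag.stats import fit_tradeoff


class TestGrowthLaw:
    def test_flat_during_lag(self):
        od = logistic_od(
            [0.0, 1.0, 2.0],
            od_baseline=0.04,
            od_inoculum=0.01,
            lag_h=2.0,
            mu_per_h=0.3,
            capacity_od=1.0,
        )
        np.testing.assert_allclose(od, 0.05, rtol=1e-12)

    def test_zero_rate_is_constant(self):
        params = GrowthModelParams(mu_per_h=0.0, noise_sd=0.0, lag_h=0.0)
        curve = simulate_growth_curve(params, default_time_grid(12.0, 0.5))
        np.testing.assert_allclose(
            curve.od, params.od_baseline + params.od_inoculum, rtol=1e-12
        )

    def test_logistic_closed_form_value(self):
        """x0=0.01, K=1, mu=0.2, t=10 h: K x0 e^2 / (K - x0 + x0 e^2)."""
        expected = 1.0 * 0.01 * np.exp(2.0) / (1.0 - 0.01 + 0.01 * np.exp(2.0))
        od = logistic_od(
            [10.0],
            od_baseline=0.0,
            od_inoculum=0.01,
            lag_h=0.0,
            mu_per_h=0.2,
            capacity_od=1.0,
        )
        assert od[0] == pytest.approx(expected, rel=1e-12)
        assert od[0] == pytest.approx(0.0695, abs=5e-5)

    def test_noiseless_curves_monotone_and_bounded(self):
        for mu, lag in [(0.1, 0.0), (0.3, 4.0), (0.5, 10.0)]:
            params = GrowthModelParams(mu_per_h=mu, lag_h=lag, noise_sd=0.0)
            curve = simulate_growth_curve(params, default_time_grid(48.0, 0.25))
            assert np.all(np.diff(curve.od) >= 0)
            assert np.all(curve.od <= params.od_baseline + params.capacity_od + 1e-12)

    def test_seed_determinism(self):
        times = default_time_grid(24.0, 0.25)
        a = simulate_growth_curve(GrowthModelParams(seed=5), times)
        b = simulate_growth_curve(GrowthModelParams(seed=5), times)
        c = simulate_growth_curve(GrowthModelParams(seed=6), times)
        np.testing.assert_array_equal(a.od, b.od)
        assert not np.array_equal(a.od, c.od)

    def test_bad_time_grid_rejected(self):
        params = GrowthModelParams()
        with pytest.raises(ValueError):
            simulate_growth_curve(params, [0.0, 1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            simulate_growth_curve(params, [-1.0, 0.0, 1.0])


class TestKillCurve:
    def test_no_killing_is_flat(self):
        params = KillModelParams(n0_cfu_per_ml=1e8, k_per_min=0.0)
        sim = simulate_kill_curve(params, [0, 5, 10, 20])
        np.testing.assert_allclose(sim.cfu_per_ml, 1e8, rtol=1e-12)

    def test_one_half_life(self):
        params = KillModelParams(
            n0_cfu_per_ml=1e8, shoulder_min=0.0, k_per_min=np.log(2) / 5.0
        )
        sim = simulate_kill_curve(params, [5.0])
        assert sim.cfu_per_ml[0] == pytest.approx(5e7, rel=1e-12)

    def test_shoulder_then_exponential(self):
        params = KillModelParams(n0_cfu_per_ml=1e8, shoulder_min=2.0, k_per_min=0.3)
        sim = simulate_kill_curve(params, [0, 1, 2, 12])
        np.testing.assert_allclose(sim.cfu_per_ml[:3], 1e8, rtol=1e-12)
        assert sim.cfu_per_ml[3] == pytest.approx(1e8 * np.exp(-3.0), rel=1e-12)

    def test_log_mean_piecewise_linear(self):
        params = KillModelParams(shoulder_min=3.0, k_per_min=0.2)
        d = np.array([0.0, 1.0, 3.0, 5.0, 8.0, 13.0])
        logs = np.log(kill_mean_cfu(params, d))
        post = d >= 3.0
        slopes = np.diff(logs[post]) / np.diff(d[post])
        np.testing.assert_allclose(slopes, -0.2, rtol=1e-12)
        np.testing.assert_allclose(logs[d <= 3.0], logs[0], rtol=1e-12)

    def test_poisson_sampling_deterministic_given_seed(self):
        params = KillModelParams(seed=3)
        a = simulate_kill_curve(params, [0, 5, 10], dilution_factors=1e4)
        b = simulate_kill_curve(params, [0, 5, 10], dilution_factors=1e4)
        assert [p.colonies for p in a.points] == [p.colonies for p in b.points]
        assert len(a.points) == 9  # 3 durations x 3 replicates


class TestTradeoffCohort:
    def test_identity_line_without_noise(self):
        params = TradeoffCohortParams(
            n_strains=6, beta0=0.0, beta1=1.0, noise_sd=0.0, seed=1
        )
        cohort = generate_tradeoff_cohort(params)
        truth = cohort.truth_table()
        np.testing.assert_allclose(truth["p_35"], truth["p_hs"], rtol=1e-12)

    def test_refitting_noiseless_pairs_is_collinear(self):
        params = TradeoffCohortParams(n_strains=8, noise_sd=0.0, seed=2)
        cohort = generate_tradeoff_cohort(params)
        truth = cohort.truth_table()
        fit = fit_tradeoff(truth["p_hs"], truth["p_35"])
        assert fit.slope == pytest.approx(params.beta1, abs=1e-10)
        assert fit.intercept == pytest.approx(params.beta0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_slope_within_its_confidence_interval(self):
        """beta1 = -2.5, sd 0.05, n = 14: the fit's 95% CI covers truth."""
        params = TradeoffCohortParams(
            n_strains=14, beta1=-2.5, noise_sd=0.05, seed=42
        )
        cohort = generate_tradeoff_cohort(params)
        truth = cohort.truth_table()
        x = truth["p_hs"].to_numpy()
        y = truth["p_35"].to_numpy()
        res = sps.linregress(x, y)
        half_width = sps.t.ppf(0.975, len(x) - 2) * res.stderr
        assert abs(res.slope - (-2.5)) < half_width

    def test_pipeline_roundtrip_recovers_performances(self):
        """Extracted times-to-threshold reproduce each strain's P_HS and P_35."""
        params = TradeoffCohortParams(n_strains=6, noise_sd=0.0, seed=3)
        cohort = generate_tradeoff_cohort(params)
        by_strain = {s.strain: s for s in cohort.strains}
        for strain in cohort.strains:
            times = {}
            for curve in strain.curves:
                if curve.meta.replicate != 1:
                    continue
                pre = preprocess(curve, params.od_baseline)
                times[curve.meta.condition] = time_to_threshold(
                    pre, params.od_threshold
                )
            t_ref = times[tlio.COND_REFERENCE]
            truth = by_strain[strain.strain]
            # within one grid-interpolation step of the embedded times
            assert t_ref == pytest.approx(truth.t_ref_h, abs=params.dt_h)
            assert times[tlio.COND_HEATSHOCK] == pytest.approx(
                truth.t_hs_h, abs=params.dt_h
            )
            p_hs = t_ref / times[tlio.COND_HEATSHOCK]
            p_35 = t_ref / times[tlio.COND_ELEVATED]
            assert p_hs == pytest.approx(truth.p_hs, rel=0.02)
            assert p_35 == pytest.approx(truth.p_35, rel=0.02)

    def test_cohort_determinism_and_replicate_count(self):
        params = TradeoffCohortParams(n_strains=4, seed=9)
        a = generate_tradeoff_cohort(params)
        b = generate_tradeoff_cohort(params)
        assert len(a.curves()) == 4 * 3 * params.n_replicates
        np.testing.assert_array_equal(a.curves()[0].od, b.curves()[0].od)


class TestPlateTables:
    def test_three_point_curve_row_counts(self, tmp_path):
        from thermolag.growth import CurveMeta, GrowthCurve

        curve = GrowthCurve(
            [0.0, 1.0, 2.0], [0.1, 0.2, 0.3], CurveMeta(well="A1", strain="WT")
        )
        od_path, map_path = write_plate_tables([curve], tmp_path)
        od = np.loadtxt(od_path, delimiter=",", skiprows=1, usecols=(1, 2))
        assert od.shape == (3, 2)
        with open(map_path) as fh:
            assert len(fh.readlines()) == 2  # header + one well

    def test_roundtrip_identity(self, tmp_path):
        params = TradeoffCohortParams(n_strains=3, seed=4, od_noise_sd=0.002)
        cohort = generate_tradeoff_cohort(params)
        od_path, map_path = write_plate_tables(cohort.curves(), tmp_path)
        back = tlio.read_curves(od_path, map_path)
        assert len(back) == len(cohort.curves())
        original = {
            (c.meta.strain, c.meta.condition, c.meta.replicate): c
            for c in cohort.curves()
        }
        for curve in back:
            key = (curve.meta.strain, curve.meta.condition, curve.meta.replicate)
            # lossless up to CSV float formatting (last-ulp text truncation)
            np.testing.assert_allclose(curve.od, original[key].od, rtol=1e-12)
            np.testing.assert_allclose(curve.time_h, original[key].time_h, rtol=1e-12)

    def test_many_wells_row_arithmetic(self, tmp_path):
        from thermolag.growth import CurveMeta, GrowthCurve

        t = np.linspace(0, 10, 100)
        curves = [
            GrowthCurve(t, 0.1 + 0.001 * np.arange(100.0), CurveMeta(well=f"W{i}"))
            for i in range(96)
        ]
        od_path, _ = write_plate_tables(curves, tmp_path)
        with open(od_path) as fh:
            assert len(fh.readlines()) == 96 * 100 + 1

    def test_duplicate_wells_rejected(self, tmp_path):
        from thermolag.growth import CurveMeta, GrowthCurve

        curves = [
            GrowthCurve([0.0, 1.0], [0.1, 0.2], CurveMeta(well="A1")),
            GrowthCurve([0.0, 1.0], [0.1, 0.2], CurveMeta(well="A1")),
        ]
        with pytest.raises(ValueError, match="duplicate well"):
            write_plate_tables(curves, tmp_path)
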