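import numpy as np
import pandas as pd
import pytest

from phenoscale import (
    IrrigationPolicy,
    RatioSet,
    SubstrateSpec,
    aggregate_daily,
    build_reference_series,
    crop_fresh_weight,
    evaluate_series,
    fresh_weight_series,
    root_fresh_weight,
    water_weight,
)
from phenoscale.errors import EvaluationError, ParameterError
from phenoscale.simulate import (
    GrowthParams,
    SensorSimConfig,
    destructive_samples,
    simulate_growth,
    simulate_sensors,
)
from phenoscale.types import DailyAggregate, FreshWeightSeries


class TestWaterWeight:
    @pytest.mark.parametrize(
        "vwc,vol,expected",
        [(0.0, 10.0, 0.0), (0.5, 10.0, 5.0), (0.63, 12.5, 7.875)],
    )
    def test_definition_at_unit_density(self, vwc, vol, expected):
        assert water_weight(vwc, vol) == pytest.approx(expected)

    @pytest.mark.parametrize("vwc", [-0.1, 1.1])
    def test_domain_error(self, vwc):
        with pytest.raises(ParameterError):
            water_weight(vwc, 10.0)


class TestCropFreshWeight:
    def test_arithmetic_on_known_inputs(self):
        # system 3.000 kg, substrate dry 656.50 g, water 1.200 kg
        agg = DailyAggregate(1, 3.000, 1.200 / 12.0, 144, 36)
        substrate = SubstrateSpec(dry_weight=656.50, volume=12.0)
        assert crop_fresh_weight(agg, substrate) == pytest.approx(1.1435)

    def test_empty_crop_identity(self):
        substrate = SubstrateSpec(dry_weight=500.0, volume=10.0)
        agg = DailyAggregate(1, 0.5 + 6.0, 0.6, 144, 36)
        assert crop_fresh_weight(agg, substrate) == pytest.approx(0.0)

    def test_negative_result_is_flagged_not_clipped(self):
        substrate = SubstrateSpec(dry_weight=500.0, volume=10.0)
        aggs = [
            DailyAggregate(1, 0.2 + 6.0, 0.6, 144, 36),
            DailyAggregate(2, 9.0, 0.6, 144, 36),
        ]
        series = fresh_weight_series(aggs, substrate)
        assert series.crop_fresh_weight[0] == pytest.approx(-0.3)
        assert series.flagged.tolist() == [True, False]


class TestRootImputation:
    def test_zero_shoot_gives_zero_root(self):
        assert root_fresh_weight(0.0, RatioSet(0.2, 0.25)) == 0.0

    def test_hand_arithmetic(self):
        # 500 g shoot dry x RS 0.2 = 100 g root dry; / DF 0.25 = 400 g fresh
        assert root_fresh_weight(500.0, RatioSet(0.2, 0.25)) == pytest.approx(400.0)

    def test_simulator_round_trip_recovers_root_fresh(self):
        p = GrowthParams(rs_ratio=0.22, df_ratio=0.3)
        truth = simulate_growth(p, 40, seed=2)
        for t in truth[::10]:
            rf = root_fresh_weight(t.shoot_dry_weight, p.ratios)
            assert rf == pytest.approx(t.root_dry_weight / 0.3, rel=1e-12)


class TestReferenceSeries:
    def test_single_sample_addition(self):
        df = pd.DataFrame({"dat": [10], "shoot_fresh_kg": [1.0], "shoot_dry_g": [125.0]})
        ratios = RatioSet(0.2, 0.25)  # root fresh = 125*0.2/0.25 = 100 g
        out = build_reference_series(df, ratios)
        assert out.total_fresh_kg.iloc[0] == pytest.approx(1.1)
        assert out.n.iloc[0] == 1 and out.sd_kg.iloc[0] == 0.0

    def test_replicates_average(self):
        df = pd.DataFrame(
            {"dat": [5, 5, 5], "shoot_fresh_kg": [1.0, 1.2, 1.4], "shoot_dry_g": [0, 0, 0]}
        )
        out = build_reference_series(df, RatioSet(0.2, 0.25))
        assert len(out) == 1
        assert out.total_fresh_kg.iloc[0] == pytest.approx(1.2)

    def test_reference_tracks_simulated_truth_within_sampling_noise(self):
        p = GrowthParams()
        truth = simulate_growth(p, 90, seed=4)
        samples = destructive_samples(
            truth, p.ratios, [20, 40, 60, 80], n_replicates=6, noise_cv=0.05, seed=5
        )
        ref = build_reference_series(
            samples[["dat", "shoot_fresh_kg", "shoot_dry_g"]], p.ratios
        )
        by_dat = {t.dat: t.crop_fresh_weight for t in truth}
        for row in ref.itertuples():
            sd = max(row.sd_kg / np.sqrt(row.n), 0.01)
            assert abs(row.total_fresh_kg - by_dat[row.dat]) < 4 * sd + 0.05


class TestEvaluateSeries:
    def _series(self, dat, fw):
        return FreshWeightSeries(
            dat=np.array(dat), crop_fresh_weight=np.array(fw),
            water_weight=np.zeros(len(dat)),
        )

    def test_perfect_fit(self):
        ref = pd.DataFrame({"dat": [1, 2, 3], "total_fresh_kg": [1.0, 2.0, 3.0]})
        m = evaluate_series(self._series([1, 2, 3], [1.0, 2.0, 3.0]), ref)
        assert m["r2"] == 1.0 and m["rmse"] == 0.0 and m["n"] == 3

    def test_constant_estimate_nonpositive_r2(self):
        ref = pd.DataFrame({"dat": [1, 2, 3], "total_fresh_kg": [1.0, 2.0, 3.0]})
        m = evaluate_series(self._series([1, 2, 3], [2.0, 2.0, 2.0]), ref)
        assert m["r2"] <= 0.0

    def test_hand_computed_three_points(self):
        ref = pd.DataFrame({"dat": [1, 2, 3], "total_fresh_kg": [1.0, 3.0, 5.0]})
        m = evaluate_series(self._series([1, 2, 3], [1.0, 2.0, 4.0]), ref)
        assert m["r2"] == pytest.approx(0.75)
        assert m["rmse"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_insufficient_overlap_is_an_error(self):
        ref = pd.DataFrame({"dat": [9], "total_fresh_kg": [1.0]})
        with pytest.raises(EvaluationError):
            evaluate_series(self._series([9, 10], [1.0, 1.0]), ref)


class TestPipelineRecovery:
    def test_noiseless_equilibrium_recovers_truth_below_one_gram(
        self, truth_season, equilibrium_stream, substrate
    ):
        records, _ = equilibrium_stream
        series = fresh_weight_series(aggregate_daily(records), substrate)
        by_dat = {t.dat: t.crop_fresh_weight for t in truth_season}
        err_g = [
            abs(series.crop_fresh_weight[i] - by_dat[d]) * 1000.0
            for i, d in enumerate(series.dat)
        ]
        assert len(err_g) >= 100
        assert max(err_g) < 1.0

    def test_rmse_monotone_in_sensor_noise(self, truth_season, substrate, policy):
        rmses = []
        for sd_w, sd_v in [(0.0, 0.0), (0.02, 0.004), (0.05, 0.01), (0.15, 0.03)]:
            cfg = SensorSimConfig(weight_sd=sd_w, vwc_sd=sd_v)
            records = simulate_sensors(truth_season[:41], substrate, policy, cfg, seed=7)
            series = fresh_weight_series(aggregate_daily(records), substrate)
            by_dat = {t.dat: t.crop_fresh_weight for t in truth_season}
            resid = [
                series.crop_fresh_weight[i] - by_dat[d]
                for i, d in enumerate(series.dat)
            ]
            rmses.append(float(np.sqrt(np.mean(np.square(resid)))))
        assert all(a <= b + 1e-9 for a, b in zip(rmses, rmses[1:]))

    def test_moderate_noise_keeps_seasonal_r2_above_09(
        self, truth_season, substrate, policy
    ):
        cfg = SensorSimConfig(weight_sd=0.05, vwc_sd=0.01)
        records = simulate_sensors(truth_season, substrate, policy, cfg, seed=8)
        series = fresh_weight_series(aggregate_daily(records), substrate)
        truth_df = pd.DataFrame(
            {"dat": [t.dat for t in truth_season],
             "total_fresh_kg": [t.crop_fresh_weight for t in truth_season]}
        )
        m = evaluate_series(series, truth_df)
        assert m["r2"] >= 0.9
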