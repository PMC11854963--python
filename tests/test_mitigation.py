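import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import percentile_oracle
from parkdelta.errors import ConfigurationError
from parkdelta.background import remove_background_paired
from parkdelta.mitigation import (
    PeriodConfig,
    aggregate_by_period,
    assign_period,
    assign_sector,
    compute_deltas,
    diurnal_profile,
    percentile_rose,
)
from parkdelta.qaqc import run_cascade
from parkdelta.synthetic import SimConfig, simulate_pair, expected_period_pct


def paired_frame(road, park, hours=None, wd=None):
    n = len(road)
    hours = hours if hours is not None else range(n)
    df = pd.DataFrame({
        "hour_start": pd.to_datetime([f"2023-07-01 {h:02d}:00" for h in hours]),
    })
    for v in ("pm1", "pm25", "pm10", "temperature", "rh", "pressure"):
        df[f"road_{v}"] = road
        df[f"park_{v}"] = park
    if wd is not None:
        df["wd"] = wd
        df["ws"] = 1.0
    return df


class TestPeriodConfig:
    def test_fsp_table_boundaries(self):
        cfg = PeriodConfig.fsp()
        assert assign_period(10, cfg) == "daytime"
        assert assign_period(9, cfg) == "overnight"
        assert assign_period(19, cfg) == "evening"

    def test_cientec_table_boundaries(self):
        cfg = PeriodConfig.cientec()
        assert assign_period(16, cfg) == "evening"
        assert assign_period(8, cfg) == "daytime"
        assert assign_period(7, cfg) == "overnight"

    def test_malformed_partition_rejected(self):
        with pytest.raises(ConfigurationError):
            PeriodConfig({"overnight": set(range(10)), "daytime": set(range(10, 18)),
                          "evening": set(range(18, 23))})  # hour 23 missing
        with pytest.raises(ConfigurationError):
            PeriodConfig({"overnight": {0}, "daytime": {0}, "evening": {1}})

    def test_every_hour_has_exactly_one_period(self):
        for cfg in (PeriodConfig.fsp(), PeriodConfig.cientec()):
            labels = [assign_period(h, cfg) for h in range(24)]
            assert len(labels) == 24


class TestComputeDeltas:
    def test_arithmetic_and_percent(self):
        df = paired_frame([20.0], [15.0])
        out = compute_deltas(df)
        assert out["delta_pm25"].iloc[0] == 5.0
        assert out["pct_pm25"].iloc[0] == pytest.approx(25.0)

    def test_identical_sides_give_zero(self):
        df = paired_frame([10.0], [10.0])
        out = compute_deltas(df)
        assert out["delta_pm25"].iloc[0] == 0.0
        assert out["pct_pm25"].iloc[0] == 0.0

    def test_zero_road_value_pct_missing_delta_kept(self):
        df = paired_frame([0.0], [3.0])
        out = compute_deltas(df)
        assert out["delta_pm25"].iloc[0] == -3.0
        assert np.isnan(out["pct_pm25"].iloc[0])

    def test_role_swap_negates_every_delta(self, pipeline_thirty_days):
        _, joined, _, _ = pipeline_thirty_days
        swapped = joined.rename(columns=lambda c: (
            c.replace("park_", "TMP_").replace("road_", "park_").replace("TMP_", "road_")
        ))
        fwd = compute_deltas(joined)
        rev = compute_deltas(swapped)
        for v in ("pm1", "pm25", "pm10", "temperature"):
            np.testing.assert_allclose(
                rev[f"delta_{v}"], -fwd[f"delta_{v}"], atol=1e-12
            )


class TestAggregateByPeriod:
    def test_constructed_means(self):
        cfg = PeriodConfig.fsp()
        road = [10.0 + (2.0 if 10 <= h <= 18 else 0.0) for h in range(24)]
        park = [10.0] * 24
        deltas = compute_deltas(paired_frame(road, park), period_cfg=cfg)
        summary = aggregate_by_period(deltas, cfg)
        day = summary.query("period == 'daytime' and variable == 'pm25'")
        night = summary.query("period == 'overnight' and variable == 'pm25'")
        assert day["mean_delta"].iloc[0] == pytest.approx(2.0)
        assert night["mean_delta"].iloc[0] == pytest.approx(0.0)
        assert summary.query("variable == 'pm25'")["n_hours"].sum() == 24

    def test_single_hour_mean_is_identity(self):
        cfg = PeriodConfig.fsp()
        deltas = compute_deltas(paired_frame([12.0], [9.0], hours=[11]),
                                period_cfg=cfg)
        summary = aggregate_by_period(deltas, cfg)
        day = summary.query("period == 'daytime' and variable == 'pm25'")
        assert day["mean_delta"].iloc[0] == pytest.approx(3.0)
        assert day["n_hours"].iloc[0] == 1

    def test_group_means_match_bruteforce_oracle(self, pipeline_thirty_days):
        _, joined, _, _ = pipeline_thirty_days
        cfg = PeriodConfig.fsp()
        deltas = compute_deltas(joined, period_cfg=cfg)
        summary = aggregate_by_period(deltas, cfg)
        for _, row in summary.query("variable == 'pm25'").iterrows():
            expected = np.nanmean([
                d for d, p in zip(deltas["delta_pm25"], deltas["period"])
                if p == row["period"]
            ])
            assert row["mean_delta"] == pytest.approx(expected, nan_ok=True)

    def test_mitigation_recovery_against_closed_form(self, pipeline_thirty_days):
        cfg, joined, _, truth = pipeline_thirty_days
        periods = PeriodConfig.fsp()
        deltas = compute_deltas(joined, period_cfg=periods)
        summary = aggregate_by_period(deltas, periods)
        got = summary.query("period == 'daytime' and variable == 'pm25'")[
            "mean_pct"].iloc[0]
        expected = expected_period_pct(cfg, periods.hours["daytime"])
        assert got == pytest.approx(expected, abs=5.0)


class TestDiurnalProfile:
    def test_constant_series_flat_profile(self):
        df = pd.DataFrame({
            "hour_start": pd.date_range("2023-07-01", periods=48, freq="h"),
            "pm25": 7.0,
        })
        prof = diurnal_profile(df, ["pm25"])
        assert (prof["pm25"] == 7.0).all()

    def test_traffic_peaks_located(self):
        cfg = SimConfig(n_days=8)
        park, road, _, _ = simulate_pair(cfg, seed=4)
        paired, _ = run_cascade(park, road)
        prof = diurnal_profile(paired, ["road_pm25"])
        peak = int(prof["road_pm25"].idxmax())
        assert abs(peak - 8) <= 1  # morning rush hour

    def test_empty_input_all_missing(self):
        df = pd.DataFrame({"hour_start": pd.to_datetime([]), "pm25": []})
        prof = diurnal_profile(df, ["pm25"])
        assert len(prof) == 24
        assert prof["pm25"].isna().all()


class TestSectors:
    @pytest.mark.parametrize("wd,sector", [
        (0.0, 0), (90.0, 4), (230.0, 10), (348.75, 0), (348.74, 15),
        (11.25, 1), (359.9, 0),
    ])
    def test_center_convention(self, wd, sector):
        assert assign_sector(wd) == sector

    def test_partition_of_fine_grid(self):
        grid = np.arange(0.0, 360.0, 0.1)
        sectors = assign_sector(grid)
        assert sectors.min() == 0 and sectors.max() == 15
        # every direction lands in exactly one sector; all sectors hit
        assert set(np.unique(sectors)) == set(range(16))
        # sector widths are equal (225 grid steps of 0.1° each)
        counts = np.bincount(sectors)
        assert (counts == 225).all()


class TestPercentileRose:
    def test_constant_deltas_constant_percentiles(self):
        df = paired_frame([12.0] * 32, [9.0] * 32, hours=list(range(16)) * 2,
                          wd=np.repeat(np.arange(16) * 22.5, 2))
        rose = percentile_rose(compute_deltas(df))
        for lev in (10, 50, 99):
            np.testing.assert_allclose(rose[f"p{lev}"], 3.0)

    def test_matches_bruteforce_oracle(self, pipeline_thirty_days):
        _, joined, _, _ = pipeline_thirty_days
        deltas = compute_deltas(joined.loc[~joined["wind_missing"]])
        rose = percentile_rose(deltas)
        for _, row in rose.iterrows():
            vals = deltas.loc[deltas["sector"] == row["sector"], "delta_pm25"].dropna()
            if len(vals) == 0:
                assert row["n_hours"] == 0
                continue
            for lev in (10, 25, 50, 75, 90, 99):
                assert row[f"p{lev}"] == pytest.approx(
                    percentile_oracle(vals, lev / 100), rel=1e-12, abs=1e-12
                )

    def test_percentiles_nondecreasing_within_sector(self, pipeline_thirty_days):
        _, joined, _, _ = pipeline_thirty_days
        rose = percentile_rose(compute_deltas(joined.loc[~joined["wind_missing"]]))
        levels = [10, 25, 50, 75, 90, 99]
        for _, row in rose.iterrows():
            vals = [row[f"p{l}"] for l in levels]
            vals = [v for v in vals if not np.isnan(v)]
            assert vals == sorted(vals)

    def test_upwind_only_mitigation_maximizes_westerly_sectors(self):
        westerly = (10, 11, 12, 13, 14)  # SW through NW
        cfg = SimConfig(n_days=30, upwind_sectors=westerly, lod_rate=0,
                        rh_spike_rate=0, short_hour_rate=0,
                        discordant_hour_rate=0, unmatched_hour_rate=0)
        park, road, wind, _ = simulate_pair(cfg, seed=9)
        paired, _ = run_cascade(park, road)
        removed, _ = remove_background_paired(paired)
        from parkdelta.ingest import join_wind

        joined = join_wind(removed, wind)
        rose = percentile_rose(compute_deltas(joined))
        best = rose.loc[rose["mean_pct"].idxmax(), "sector"]
        assert best in westerly
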