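"""Driver aggregation, anomalies, collinearity screening, design matrix."""

import numpy as np
import pandas as pd
import pytest

from foodcast.features import (
    LagConfig,
    aggregate_fatalities,
    build_design,
    correlation_prune,
    dekad_index,
    dekad_of_year,
    expand_dekads_daily,
    feature_columns,
    monthly_price,
    ndvi_anomaly,
    rainfall_anomaly,
    ramadan_counter,
    vif_screen,
)

IDX = pd.date_range("2021-01-01", periods=60)


class TestFatalities:
    def test_no_events_all_zero(self):
        events = pd.DataFrame(
            {"area_id": ["a"], "date": ["2021-01-05"], "fatalities": [0]}
        )
        out = aggregate_fatalities(events, 7, index=IDX)
        assert (out.to_numpy() == 0).all()

    def test_single_event_covers_d_days(self):
        events = pd.DataFrame(
            {"area_id": ["a"], "date": ["2021-01-10"], "fatalities": [5]}
        )
        out = aggregate_fatalities(events, 7, index=IDX)["a"]
        assert (out.loc["2021-01-10":"2021-01-16"] == 5).all()
        assert out.loc["2021-01-09"] == 0
        assert out.loc["2021-01-17"] == 0

    def test_overlapping_events_sum(self):
        events = pd.DataFrame(
            {
                "area_id": ["a", "a"],
                "date": ["2021-01-10", "2021-01-12"],
                "fatalities": [5, 3],
            }
        )
        out = aggregate_fatalities(events, 7, index=IDX)["a"]
        assert out.loc["2021-01-12"] == 8

    def test_negative_counts_rejected(self):
        events = pd.DataFrame(
            {"area_id": ["a"], "date": ["2021-01-10"], "fatalities": [-1]}
        )
        with pytest.raises(ValueError):
            aggregate_fatalities(events, 7)


class TestPrices:
    def _prices(self, area_series):
        rows = []
        months = pd.date_range("2021-01-01", periods=6, freq="MS")
        for (area, market), series in area_series.items():
            for m, p in zip(months, series):
                rows.append((area, market, m, p))
        return pd.DataFrame(rows, columns=["area_id", "market", "month", "price"])

    def test_single_constant_market_normalises_to_one(self):
        df = self._prices({("a", "m1"): [100] * 6})
        out = monthly_price(df)
        assert np.allclose(out["a"], 1.0)

    def test_identical_markets_match_single_market(self):
        one = monthly_price(self._prices({("a", "m1"): [100, 110, 120, 115, 130, 140]}))
        two = monthly_price(
            self._prices(
                {
                    ("a", "m1"): [100, 110, 120, 115, 130, 140],
                    ("a", "m2"): [100, 110, 120, 115, 130, 140],
                }
            )
        )
        assert np.allclose(one["a"], two["a"])

    def test_constant_markets_at_different_levels_average_to_one(self):
        out = monthly_price(
            self._prices({("a", "m1"): [100] * 6, ("a", "m2"): [200] * 6})
        )
        assert np.allclose(out["a"], 1.0)

    def test_normalisation_is_causal(self):
        # changing later months must not change earlier normalised values
        base = self._prices({("a", "m1"): [100, 110, 120, 115, 130, 140]})
        bumped = base.copy()
        bumped.loc[bumped["month"] == bumped["month"].max(), "price"] = 999.0
        a = monthly_price(base)["a"]
        b = monthly_price(bumped)["a"]
        assert np.allclose(a.iloc[:-1], b.iloc[:-1])

    def test_daily_expansion_forward_fills(self):
        df = self._prices({("a", "m1"): [100, 200, 100, 100, 100, 100]})
        daily = monthly_price(df, index=pd.date_range("2021-02-01", "2021-02-10"))
        assert daily["a"].nunique() == 1


class TestAnomalies:
    def _dekads(self, values):
        idx = dekad_index(pd.Timestamp("2021-01-01"), pd.Timestamp("2021-12-31"))
        return pd.DataFrame({"a": values[: len(idx)]}, index=idx)

    def _baseline(self, value=20.0):
        return pd.DataFrame({"a": [value] * 36}, index=pd.Index(range(1, 37)))

    def test_rainfall_equal_to_baseline_gives_100(self):
        dek = self._dekads([20.0] * 36)
        out = rainfall_anomaly(dek, self._baseline(), span_dekads=3)
        assert np.allclose(out["a"].dropna(), 100.0)

    def test_doubled_rainfall_gives_200(self):
        dek = self._dekads([40.0] * 36)
        out = rainfall_anomaly(dek, self._baseline(), span_dekads=3)
        assert np.allclose(out["a"].dropna(), 200.0)

    def test_hand_computed_one_month_window(self):
        # dekads (10, 20, 30) against baseline (20, 20, 20): 100 * 60/60
        vals = [10.0, 20.0, 30.0] + [20.0] * 33
        out = rainfall_anomaly(self._dekads(vals), self._baseline(), span_dekads=3)
        assert out["a"].dropna().iloc[0] == pytest.approx(100.0)

    def test_zero_baseline_yields_missing(self):
        base = self._baseline()
        base.loc[1:3, "a"] = 0.0
        dek = self._dekads([20.0] * 36)
        with pytest.warns(UserWarning, match="zero historical baseline"):
            out = rainfall_anomaly(dek, base, span_dekads=3)
        assert out["a"].isna().iloc[2]

    def test_ndvi_anomaly_matches_per_dekad_ratio(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.1, 0.9, 36)
        base = self._baseline(0.5)
        out = ndvi_anomaly(self._dekads(vals), base)
        expected = 100.0 * vals / 0.5
        assert np.allclose(out["a"].to_numpy(), expected)

    def test_daily_expansion_repeats_dekad_values(self):
        dek = self._dekads([20.0] * 36)
        idx = pd.date_range("2021-03-01", "2021-03-31")
        daily = expand_dekads_daily(dek, idx)
        assert (daily.loc["2021-03-21":"2021-03-31", "a"] == 20.0).all()
        assert dekad_of_year(pd.Timestamp("2021-03-25")) == 9


class TestRamadan:
    INTERVALS = [(pd.Timestamp("2021-04-13"), pd.Timestamp("2021-05-12"))]

    def test_zero_far_from_ramadan(self):
        idx = pd.date_range("2021-01-01", "2021-12-31")
        out = ramadan_counter(idx, self.INTERVALS, d=7)
        assert out.loc["2021-02-01"] == 0
        assert out.loc["2021-05-20"] == 0  # 8 days after the end

    def test_full_length_at_last_day_with_wide_window(self):
        idx = pd.date_range("2021-01-01", "2021-12-31")
        out = ramadan_counter(idx, self.INTERVALS, d=40)
        assert out.loc["2021-05-12"] == 30  # the whole 30-day observance

    def test_ramp_up_during_ramadan(self):
        idx = pd.date_range("2021-01-01", "2021-12-31")
        out = ramadan_counter(idx, self.INTERVALS, d=7)
        assert out.loc["2021-04-15"] == 3  # three days in

    def test_ill_ordered_interval_rejected(self):
        idx = pd.date_range("2021-01-01", periods=10)
        with pytest.raises(ValueError):
            ramadan_counter(idx, [(idx[5], idx[2])], d=7)


class TestCorrelationPrune:
    def test_duplicated_series_drops_exactly_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        kept, dropped = correlation_prune(pd.DataFrame({"a": x, "b": x}))
        assert len(kept) == 1 and len(dropped) == 1
        assert set(kept) | set(dropped) == {"a", "b"}

    def test_independent_noise_pair_kept(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        kept, dropped = correlation_prune(df)
        assert kept == ["a", "b"] and dropped == []

    def test_greedy_rule_keeps_uncorrelated_third(self):
        rng = np.random.default_rng(2)
        n = 4000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)  # r(a,b) ~ 0.9
        c = rng.normal(size=n)  # near-zero correlation with both
        kept, dropped = correlation_prune(pd.DataFrame({"a": a, "b": b, "c": c}))
        assert "c" in kept
        assert len(dropped) == 1 and dropped[0] in {"a", "b"}

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(3)
        n = 800
        base = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "a": base,
                "b": 0.8 * base + 0.6 * rng.normal(size=n),
                "c": rng.normal(size=n),
                "d": rng.normal(size=n),
            }
        )
        kept, _ = correlation_prune(df)
        kept2, dropped2 = correlation_prune(df[kept])
        assert kept2 == kept and dropped2 == []

    def test_constant_series_warns_and_survives(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=100), "b": np.ones(100)})
        with pytest.warns(UserWarning, match="undefined correlations"):
            kept, dropped = correlation_prune(df)
        assert kept == ["a", "b"]


class TestVif:
    def test_orthogonal_features_unit_vif(self):
        a = np.array([1, 1, -1, -1, 1, 1, -1, -1], float)
        b = np.array([1, -1, 1, -1, 1, -1, 1, -1], float)
        u = np.array([1, -1, -1, 1, 1, -1, -1, 1], float)
        vif = vif_screen(pd.DataFrame({"a": a, "b": b, "u": u}))
        assert np.allclose(vif.to_numpy(), 1.0, atol=1e-10)

    def test_r2_half_gives_vif_two(self):
        a = np.array([1, 1, -1, -1, 1, 1, -1, -1], float)
        b = np.array([1, -1, 1, -1, 1, -1, 1, -1], float)
        u = np.array([1, -1, -1, 1, 1, -1, -1, 1], float)
        c = a + u  # regressing c on {a, b} explains exactly half its variance
        vif = vif_screen(pd.DataFrame({"a": a, "b": b, "c": c}))
        assert vif["c"] == pytest.approx(2.0, abs=1e-10)

    def test_duplicated_feature_flagged_unbounded(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        vif = vif_screen(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)}))
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])


class TestBuildDesign:
    def _inputs(self, n_days=120, n_areas=2, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.date_range("2021-01-01", periods=n_days)
        areas = [f"a{i}" for i in range(n_areas)]
        target = pd.DataFrame(
            rng.uniform(0.2, 0.6, (n_days, n_areas)), index=idx, columns=areas
        )
        driver = pd.DataFrame(
            rng.normal(size=(n_days, n_areas)), index=idx, columns=areas
        )
        return target, {"drv": driver}

    def test_lag_zero_feature_equals_reference_day_value(self):
        target, drivers = self._inputs()
        designs = build_design(
            target, None, drivers, None, LagConfig(target=(0,), rcsi=(), drivers=(0,)),
            horizons=[1],
        )
        d1 = designs[1]
        row = d1.loc[("a0", pd.Timestamp("2021-02-01"))]
        assert row["target_lag0"] == target.loc["2021-02-01", "a0"]
        assert row["y"] == target.loc["2021-02-02", "a0"]

    def test_temporal_identifiers_refer_to_forecast_date(self):
        target, drivers = self._inputs()
        designs = build_design(
            target, None, drivers, None, LagConfig(target=(0,), rcsi=(), drivers=(0,)),
            horizons=[10],
        )
        row = designs[10].loc[("a1", pd.Timestamp("2021-01-25"))]
        assert (row["day"], row["month"]) == (4.0, 2.0)  # Jan 25 + 10 = Feb 4

    def test_future_driver_shuffle_leaves_past_rows_unchanged(self):
        target, drivers = self._inputs(seed=7)
        cut = pd.Timestamp("2021-03-01")
        shuffled = {k: v.copy() for k, v in drivers.items()}
        rng = np.random.default_rng(99)
        tail = shuffled["drv"].loc[cut:].to_numpy()
        shuffled["drv"].loc[cut:] = rng.permutation(tail)
        lags = LagConfig(target=(0, 3), rcsi=(), drivers=(0, 5))
        a = build_design(target, None, drivers, None, lags, horizons=[3])[3]
        b = build_design(target, None, shuffled, None, lags, horizons=[3])[3]
        before = a.index.get_level_values("ref_date") < cut
        pd.testing.assert_frame_equal(a[before], b[before])

    def test_row_count_matches_counting_formula(self):
        n_days, n_areas, max_lag, h = 200, 3, 0, 5
        target, drivers = self._inputs(n_days=n_days, n_areas=n_areas)
        designs = build_design(
            target, None, drivers, None,
            LagConfig(target=(0,), rcsi=(), drivers=(0,)),
            horizons=[h],
        )
        # rows per horizon: areas x days with an observable target
        assert len(designs[h]) == n_areas * (n_days - h)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError, match="leak"):
            LagConfig(target=(-1,))

    def test_rows_with_missing_features_kept(self):
        target, drivers = self._inputs()
        designs = build_design(
            target, None, drivers, None,
            LagConfig(target=(0, 30), rcsi=(), drivers=()), horizons=[1],
        )
        d1 = designs[1]
        early = d1.loc[("a0", pd.Timestamp("2021-01-05"))]
        assert np.isnan(early["target_lag30"])  # kept, not dropped

    def test_statics_and_shared_series_broadcast(self):
        target, drivers = self._inputs()
        statics = pd.DataFrame(
            {
                "population": [1e5, 2e5],
                "total_area": [10.0, 20.0],
                "latitude": [1.0, 2.0],
                "longitude": [3.0, 4.0],
                "waterways": [0.0, 5.0],
            },
            index=pd.Index(["a0", "a1"], name="area_id"),
        )
        shared = pd.Series(
            np.arange(len(target.index), dtype=float), index=target.index
        )
        designs = build_design(
            target, None, {"ram": shared}, statics,
            LagConfig(target=(0,), rcsi=(), drivers=(0,)), horizons=[1],
        )
        d1 = designs[1]
        assert (d1.xs("a1", level="area_id")["population"] == 2e5).all()
        got = d1.loc[("a0", pd.Timestamp("2021-01-10")), "ram_lag0"]
        assert got == 9.0
        assert "y" not in feature_columns(d1)
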