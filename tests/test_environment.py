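"""VPD arithmetic, gap filling and daily covariate aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import npqdyn as nd
from npqdyn.environment import compute_vpd, daily_features, gap_fill, saturation_vapor_pressure


class TestVPD:
    def test_saturated_air_has_zero_deficit(self):
        assert np.isclose(compute_vpd(25.0, 100.0), 0.0)

    def test_reference_point_25C_50pct(self):
        es = saturation_vapor_pressure(25.0)
        assert np.isclose(es, 3.1667, atol=2e-3)
        assert np.isclose(compute_vpd(25.0, 50.0), 1.5834, atol=1e-3)

    def test_freezing_point_es(self):
        assert np.isclose(saturation_vapor_pressure(0.0), 0.6106)

    def test_out_of_range_humidity_rejected(self):
        with pytest.raises(ValueError):
            compute_vpd(25.0, 150.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        ta=st.floats(min_value=-20, max_value=45),
        dta=st.floats(min_value=0.1, max_value=5),
        rh=st.floats(min_value=0, max_value=99),
        drh=st.floats(min_value=0.1, max_value=1),
    )
    def test_monotone_in_temperature_and_humidity(self, ta, dta, rh, drh):
        assert compute_vpd(ta + dta, rh) > compute_vpd(ta, rh)
        if rh + drh <= 100:
            assert compute_vpd(ta, rh + drh) < compute_vpd(ta, rh)


class TestGapFill:
    def test_identity_when_no_gaps(self, weather_3wk):
        filled = gap_fill(weather_3wk)
        assert not filled["gap_filled"].any()
        np.testing.assert_allclose(filled["ta_c"], weather_3wk["ta_c"])

    def test_single_missing_value_is_midpoint(self, weather_3wk):
        w = weather_3wk.copy()
        w.loc[10, "ta_c"] = np.nan
        w.loc[9, "ta_c"], w.loc[11, "ta_c"] = 20.0, 22.0
        filled = gap_fill(w)
        assert np.isclose(filled.loc[10, "ta_c"], 21.0)
        assert filled.loc[10, "gap_filled"]

    def test_missing_timestamp_restored(self, weather_3wk):
        w = weather_3wk.drop(index=[5, 6]).reset_index(drop=True)
        filled = gap_fill(w)
        assert len(filled) == len(weather_3wk)
        assert filled["gap_filled"].sum() == 2

    def test_boundary_gap_extends_nearest(self, weather_3wk):
        w = weather_3wk.copy()
        w.loc[0, "ta_c"] = np.nan
        filled = gap_fill(w)
        assert np.isclose(filled.loc[0, "ta_c"], w.loc[1, "ta_c"])

    def test_excessive_gaps_rejected(self, weather_3wk):
        w = weather_3wk.copy()
        w.loc[: len(w) // 2, "ta_c"] = np.nan
        with pytest.raises(ValueError):
            gap_fill(w)


class TestDailyFeatures:
    def test_constant_series_gives_constants(self):
        times = pd.date_range("2021-07-01", "2021-07-06 23:30", freq="30min")
        w = pd.DataFrame(
            {"timestamp": times, "ta_c": 25.0, "rh_pct": 60.0, "fsd_wm2": 400.0, "precip_mm": 0.0}
        )
        feats = daily_features(w)
        assert np.allclose(feats["morning_Ta"], 25.0)
        assert np.allclose(feats["Ta_3day"].dropna(), 25.0)
        assert np.allclose(feats["morning_VPD"], compute_vpd(25.0, 60.0))

    def test_precip_day_before_enters_3day_sum(self):
        times = pd.date_range("2021-07-01", "2021-07-05 23:30", freq="30min")
        w = pd.DataFrame(
            {"timestamp": times, "ta_c": 25.0, "rh_pct": 60.0, "fsd_wm2": 400.0, "precip_mm": 0.0}
        )
        hit = w["timestamp"].eq(pd.Timestamp("2021-07-03 14:00"))
        w.loc[hit, "precip_mm"] = 5.0
        feats = daily_features(w).set_index("date")
        assert np.isclose(feats.loc["2021-07-04", "Precip_3day_sum"], 5.0)
        assert np.isclose(feats.loc["2021-07-04", "precip_to_10am"], 0.0)

    def test_three_day_window_excludes_current_day_by_default(self, weather_3wk):
        feats = daily_features(weather_3wk).set_index("date")
        w = weather_3wk.copy()
        w["date"] = pd.to_datetime(w["timestamp"]).dt.normalize()
        day = pd.Timestamp("2021-06-27")
        window = [day - pd.Timedelta(days=k) for k in (1, 2, 3)]
        expect = w[w["date"].isin(window)]["ta_c"].mean()
        assert np.isclose(feats.loc[day, "Ta_3day"], expect)

    def test_matches_independent_reaggregation(self, weather_3wk):
        """Row-for-row agreement with a hand-rolled oracle aggregation."""
        feats = daily_features(weather_3wk).set_index("date")
        w = weather_3wk.copy()
        w["vpd"] = compute_vpd(w["ta_c"], w["rh_pct"])
        w["date"] = w["timestamp"].dt.normalize()
        for day, grp in w.groupby("date"):
            morning = grp[grp["timestamp"].dt.strftime("%H:%M") == "10:00"].iloc[0]
            assert np.isclose(feats.loc[day, "morning_Ta"], morning["ta_c"])
            assert np.isclose(feats.loc[day, "morning_VPD"], morning["vpd"])
            to10 = grp[grp["timestamp"].dt.hour * 60 + grp["timestamp"].dt.minute <= 600]
            assert np.isclose(feats.loc[day, "precip_to_10am"], to10["precip_mm"].sum())

    def test_precip_mass_conserved(self, weather_3wk):
        feats = daily_features(weather_3wk)
        w = weather_3wk.copy()
        w["date"] = w["timestamp"].dt.normalize()
        w["mins"] = w["timestamp"].dt.hour * 60 + w["timestamp"].dt.minute
        remainder = w[w["mins"] > 600].groupby("date")["precip_mm"].sum()
        total = feats.set_index("date")["precip_to_10am"].add(remainder, fill_value=0.0).sum()
        assert np.isclose(total, weather_3wk["precip_mm"].sum())

    def test_timestamp_reserialization_invariance(self, weather_3wk):
        a = daily_features(weather_3wk)
        w = weather_3wk.copy()
        w["timestamp"] = w["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        b = daily_features(w)
        pd.testing.assert_frame_equal(a, b)

    def test_include_current_day_variant(self, weather_3wk):
        feats = daily_features(weather_3wk, include_current_day=True).set_index("date")
        w = weather_3wk.copy()
        w["date"] = w["timestamp"].dt.normalize()
        day = pd.Timestamp("2021-06-27")
        window = [day - pd.Timedelta(days=k) for k in (0, 1, 2)]
        expect = w[w["date"].isin(window)]["ta_c"].mean()
        assert np.isclose(feats.loc[day, "Ta_3day"], expect)

    def test_transformer_interface(self, weather_3wk):
        ext = nd.DailyFeatureExtractor()
        out = ext.fit_transform(weather_3wk)
        assert "morning_VPD" in out.columns
        with pytest.raises(ValueError):
            nd.DailyFeatureExtractor().fit(weather_3wk.drop(columns=["ta_c"]))
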