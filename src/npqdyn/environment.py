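"""Weather-record processing: vapor pressure deficit, gap filling and the
per-day covariates used by the statistics layer.

Input series are 30-minute station records with air temperature (ta_c, degC),
relative humidity (rh_pct, %), incoming shortwave radiation (fsd_wm2, W m-2)
and precipitation (precip_mm, mm per interval).  Daily covariates are the
10 a.m. values of Ta, VPD and Fsd, precipitation summed from midnight to
10 a.m., and 3-day aggregates (means; precipitation summed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "compute_vpd",
    "saturation_vapor_pressure",
    "gap_fill",
    "daily_features",
    "DailyFeatureExtractor",
    "ENV_FEATURES",
]

#: daily covariate columns, in output order
ENV_FEATURES = (
    "morning_Ta",
    "morning_VPD",
    "morning_Fsd",
    "precip_to_10am",
    "Ta_3day",
    "VPD_3day",
    "Fsd_3day",
    "Precip_3day_sum",
)

_VALUE_COLUMNS = ("ta_c", "rh_pct", "fsd_wm2", "precip_mm")


def saturation_vapor_pressure(ta_c):
    """Tetens saturation vapor pressure e_s (kPa) at air temperature degC."""
    ta = np.asarray(ta_c, dtype=float)
    if np.any(ta <= -237.3):
        raise ValueError("temperature out of the Tetens formula's domain")
    return 0.6106 * np.exp(17.27 * ta / (237.3 + ta))


def compute_vpd(ta_c, rh_pct):
    """Vapor pressure deficit (kPa): VPD = e_s - e_a with e_a = RH * e_s / 100."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    es = saturation_vapor_pressure(ta_c)
    ea = rh * es / 100.0
    return es - ea


def _as_weather_frame(weather: pd.DataFrame) -> pd.DataFrame:
    df = weather.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.sort_values("timestamp").reset_index(drop=True)


def gap_fill(weather: pd.DataFrame, cadence: str = "30min") -> pd.DataFrame:
    """Fill gaps in a 30-minute series by linear interpolation.

    Missing timestamps are restored on the regular cadence; missing values
    (including at restored timestamps) are linearly interpolated within each
    variable, with nearest-value extension at the series boundaries.  A
    boolean ``gap_filled`` column flags every record with at least one
    filled value.
    """
    df = _as_weather_frame(weather).set_index("timestamp")
    full_index = pd.date_range(df.index[0], df.index[-1], freq=cadence)
    df = df.reindex(full_index)
    missing = df[list(_VALUE_COLUMNS)].isna().any(axis=1)
    frac = float(missing.mean())
    if frac >= 0.25:
        raise ValueError(f"gap fraction {frac:.2f} >= 0.25; series not fillable")
    filled = df.copy()
    for col in _VALUE_COLUMNS:
        filled[col] = df[col].interpolate(method="time", limit_direction="both")
    filled["gap_filled"] = missing.to_numpy()
    filled.index.name = "timestamp"
    return filled.reset_index()


def daily_features(
    weather: pd.DataFrame,
    morning_hour: int = 10,
    window_days: int = 3,
    include_current_day: bool = False,
) -> pd.DataFrame:
    """Per-day environmental covariates from a gap-filled 30-minute series.

    morning_* are the values of the record at ``morning_hour`` (VPD computed
    per 30-min record before any aggregation); precip_to_10am sums intervals
    after midnight up to and including the morning record.  The 3-day
    aggregates cover the ``window_days`` complete calendar days preceding
    the day (means for Ta/VPD/Fsd, sum for precipitation); they are NaN for
    days without a full prior window.  Set ``include_current_day`` to end
    the window on the day itself instead.
    """
    df = _as_weather_frame(weather)
    df["vpd_kpa"] = compute_vpd(df["ta_c"], df["rh_pct"])
    df["date"] = df["timestamp"].dt.normalize()
    df["hour"] = df["timestamp"].dt.hour + df["timestamp"].dt.minute / 60.0

    day_means = df.groupby("date")[["ta_c", "vpd_kpa", "fsd_wm2"]].mean()
    day_precip = df.groupby("date")["precip_mm"].sum()
    all_days = day_means.index

    rows = []
    for day in all_days:
        day_df = df[df["date"] == day]
        morning = day_df[np.isclose(day_df["hour"], morning_hour)]
        if morning.empty:
            raise ValueError(f"no {morning_hour}:00 record on {day.date()} after gap fill")
        morning = morning.iloc[0]
        precip_morning = day_df.loc[day_df["hour"] <= morning_hour, "precip_mm"].sum()

        if include_current_day:
            window = pd.date_range(day - pd.Timedelta(days=window_days - 1), day, freq="D")
        else:
            window = pd.date_range(day - pd.Timedelta(days=window_days), day - pd.Timedelta(days=1), freq="D")
        have_window = all(d in all_days for d in window)
        if have_window:
            wdf = df[df["date"].isin(window)]
            ta3, vpd3, fsd3 = wdf["ta_c"].mean(), wdf["vpd_kpa"].mean(), wdf["fsd_wm2"].mean()
            pr3 = wdf["precip_mm"].sum()
        else:
            ta3 = vpd3 = fsd3 = pr3 = np.nan

        rows.append(
            {
                "date": day,
                "morning_Ta": morning["ta_c"],
                "morning_VPD": morning["vpd_kpa"],
                "morning_Fsd": morning["fsd_wm2"],
                "precip_to_10am": precip_morning,
                "Ta_3day": ta3,
                "VPD_3day": vpd3,
                "Fsd_3day": fsd3,
                "Precip_3day_sum": pr3,
            }
        )
    return pd.DataFrame(rows)


class DailyFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer view of :func:`daily_features` for pipeline composition.

    Stateless: ``fit`` only validates, ``transform`` maps a weather-record
    DataFrame to the per-day covariate table.
    """

    def __init__(self, morning_hour: int = 10, window_days: int = 3, include_current_day: bool = False, fill_gaps: bool = True):
        self.morning_hour = morning_hour
        self.window_days = window_days
        self.include_current_day = include_current_day
        self.fill_gaps = fill_gaps

    def fit(self, X, y=None):
        for col in ("timestamp", *_VALUE_COLUMNS):
            if col not in X.columns:
                raise ValueError(f"weather frame lacks column {col!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        weather = gap_fill(X) if self.fill_gaps else X
        return daily_features(
            weather,
            morning_hour=self.morning_hour,
            window_days=self.window_days,
            include_current_day=self.include_current_day,
        )
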