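"""Canopy timeseries construction and environmental correlation.

Builds regional and per-segment kelp canopy timeseries from dated
presence/absence maps — annual July–June or austral-season composites, with
sensors merged by an observation-count weighted mean — then tests linear
trends per series and correlates canopy with environmental drivers: a
temperature-derived synthetic nitrate proxy (linear model clipped at zero)
and annual climate indices, at lags of 0 or 1 year.

Trend and correlation inference use ordinary two-sided t-tests without
autocorrelation correction; see the methods note for the limitation this
implies for strongly autocorrelated series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geo_core import BinaryCanopyMap
from .timeseries_util import interval_label, july_june_year

__all__ = [
    "PIXEL_AREA_M2",
    "CanopyTimeseries",
    "NitrateModel",
    "TrendResult",
    "annual_composite",
    "trend_test",
    "segment_trend_map",
    "fit_nitrate_model",
    "annual_nitrate_from_sst",
    "lag_correlation",
    "segment_env_correlation",
]

#: Area of one 30 m Landsat-style pixel.
PIXEL_AREA_M2 = 900.0


@dataclass
class CanopyTimeseries:
    """Composited kelp canopy area by interval.

    ``table`` has one row per (interval, sensor) with columns
    (interval, sensor, n_obs, mean_area_m2); ``merged`` one row per interval
    with the observation-count weighted mean across sensors.  ``scope`` is
    'region' or a segment id.
    """

    table: pd.DataFrame
    merged: pd.DataFrame
    interval: str  # 'annual' | 'seasonal'
    scope: str = "region"

    def merged_series(self) -> pd.Series:
        return self.merged.set_index("interval")["merged_area_m2"]


@dataclass
class NitrateModel:
    """Linear synthetic-nitrate proxy ``N(T) = max(0, a + b*T)``.

    Fitted by least squares to in-situ temperature–nitrate pairs; negative
    predictions are clipped to zero (nitrate is a concentration).
    """

    intercept: float  # a, μmol/kg
    slope: float  # b, μmol/kg per °C
    rmse: float  # μmol/kg
    rmse_pct_range: float  # percent of observed nitrate range
    n_pairs: int

    def predict(self, temperature_c):
        raw = self.intercept + self.slope * np.asarray(temperature_c, dtype=float)
        return np.maximum(raw, 0.0)


@dataclass
class TrendResult:
    slope: float  # m² per interval
    p_value: float
    n: int
    scope: str = "region"


def annual_composite(maps: list[BinaryCanopyMap], interval: str = "annual",
                     scope: str = "region") -> CanopyTimeseries:
    """Composite dated presence maps into per-sensor interval means and a
    weighted multisensor merge.

    Per sensor per interval the canopy area is ``PIXEL_AREA_M2 * mean over
    scenes of kelp-pixel counts`` (missing pixels excluded per scene); the
    merged value weights each sensor's mean by its number of scenes, which
    equals the pooled per-scene mean.
    """
    if not maps:
        raise ValueError("need at least one map")
    rows = []
    for m in maps:
        if m.acquired_at is None:
            raise ValueError("every map needs an acquisition date")
        rows.append({
            "interval": interval_label(m.acquired_at, interval),
            "sensor": m.sensor or "unknown",
            "area_m2": m.kelp_pixel_count() * m.grid.pixel_size ** 2,
        })
    df = pd.DataFrame(rows)
    table = (df.groupby(["interval", "sensor"])
             .agg(n_obs=("area_m2", "size"), mean_area_m2=("area_m2", "mean"))
             .reset_index())
    merged = (table.assign(w=lambda d: d.n_obs * d.mean_area_m2)
              .groupby("interval")
              .apply(lambda g: pd.Series({
                  "merged_area_m2": g.w.sum() / g.n_obs.sum(),
                  "n_obs": int(g.n_obs.sum()),
              }), include_groups=False)
              .reset_index()
              .sort_values("interval", key=lambda s: s.astype(str))
              .reset_index(drop=True))
    return CanopyTimeseries(table=table, merged=merged, interval=interval,
                            scope=scope)


def trend_test(ts: CanopyTimeseries | pd.Series) -> TrendResult:
    """OLS linear trend of canopy area on interval index, two-sided t-test.

    A constant series has slope 0 and p = 1 by convention (the zero-variance
    t statistic is undefined); an exactly linear series gets p below 1e-12.
    """
    if isinstance(ts, CanopyTimeseries):
        series = ts.merged_series()
        scope = ts.scope
    else:
        series = ts
        scope = getattr(ts, "name", None) or "region"
    y = series.to_numpy(dtype=float)
    ok = ~np.isnan(y)
    y = y[ok]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 intervals with data")
    x = np.arange(len(series), dtype=float)[ok]
    if np.ptp(y) == 0:
        return TrendResult(slope=0.0, p_value=1.0, n=n, scope=str(scope))
    res = stats.linregress(x, y)
    p = res.pvalue
    if not np.isfinite(p):  # perfectly linear: t -> inf
        p = 0.0
    return TrendResult(slope=float(res.slope), p_value=float(max(p, 0.0)),
                       n=n, scope=str(scope))


def segment_trend_map(segment_series: dict, alpha: float = 0.01
                      ) -> tuple[float, float, pd.DataFrame]:
    """Per-segment trend tests; fractions of segments with significant
    (p < alpha) positive and negative trends, in percent."""
    if not segment_series:
        raise ValueError("need at least one segment series")
    rows = []
    for sid, series in segment_series.items():
        if isinstance(series, CanopyTimeseries):
            series = series.merged_series()
        tr = trend_test(series)
        rows.append({"segment_id": sid, "slope": tr.slope,
                     "p_value": tr.p_value, "n": tr.n,
                     "significant": tr.p_value < alpha})
    df = pd.DataFrame(rows)
    n = len(df)
    pct_pos = 100.0 * np.sum(df.significant & (df.slope > 0)) / n
    pct_neg = 100.0 * np.sum(df.significant & (df.slope < 0)) / n
    return float(pct_pos), float(pct_neg), df


def fit_nitrate_model(pairs: pd.DataFrame,
                      temp_col: str = "temperature_c",
                      nitrate_col: str = "nitrate_umol_kg") -> NitrateModel:
    """Least-squares linear fit of nitrate on temperature.

    RMSE is reported in μmol/kg and as a percentage of the observed nitrate
    range; predictions clip at zero.
    """
    t = pairs[temp_col].to_numpy(dtype=float)
    n = pairs[nitrate_col].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 temperature–nitrate pairs")
    if np.ptp(t) == 0:
        raise ValueError("temperature has zero variance; slope is undefined")
    res = stats.linregress(t, n)
    resid = n - (res.intercept + res.slope * t)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    rng = float(n.max() - n.min())
    return NitrateModel(intercept=float(res.intercept), slope=float(res.slope),
                        rmse=rmse,
                        rmse_pct_range=100.0 * rmse / rng if rng > 0 else np.nan,
                        n_pairs=len(t))


def annual_nitrate_from_sst(sst_monthly: pd.DataFrame, model: NitrateModel
                            ) -> pd.Series:
    """Annual (July–June) mean of monthly synthetic nitrate N(SST).

    Monthly SST is converted through the clipped linear model first, then
    averaged within each July–June interval (labeled by the June year).
    """
    df = sst_monthly.copy()
    df["nitrate"] = model.predict(df["sst_c"])
    df["interval"] = [
        july_june_year(pd.Timestamp(year=int(y), month=int(m), day=15))
        for y, m in zip(df["year"], df["month"])
    ]
    return df.groupby("interval")["nitrate"].mean()


def lag_correlation(canopy: pd.Series, driver: pd.Series, lag: int = 1
                    ) -> tuple[float, float, int]:
    """Pearson correlation of canopy(t) with driver(t - lag), t-test p-value.

    Series are aligned on their integer year index; at least 5 overlapping
    intervals are required.  ``lag`` is restricted to {0, 1} — with annual
    frond turnover, longer memory is not biologically plausible.
    """
    if lag not in (0, 1):
        raise ValueError("lag must be 0 or 1 year")
    c = pd.Series(canopy).dropna()
    d = pd.Series(driver).dropna()
    d_shifted = d.copy()
    d_shifted.index = d_shifted.index + lag
    joined = pd.concat([c, d_shifted], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 5:
        raise ValueError(f"only {n} overlapping intervals after lag; need >= 5")
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def segment_env_correlation(segment_series: dict, driver: pd.Series,
                            lag: int = 1, alpha: float = 0.01) -> pd.DataFrame:
    """Lag correlation of each segment's standardized canopy with a driver.

    Each segment's area series is z-scored over its observed intervals
    before correlation (which leaves Pearson r unchanged but matches how
    per-segment canopy extents are reported); significance at p < alpha.
    """
    rows = []
    for sid, series in segment_series.items():
        if isinstance(series, CanopyTimeseries):
            series = series.merged_series()
        s = pd.Series(series).dropna()
        if s.std(ddof=0) > 0:
            s = (s - s.mean()) / s.std(ddof=0)
        try:
            r, p, n = lag_correlation(s, driver, lag=lag)
        except ValueError:
            r, p, n = np.nan, np.nan, len(s)
        rows.append({"segment_id": sid, "r": r, "p_value": p, "n": n,
                     "significant": bool(p < alpha) if np.isfinite(p) else False})
    return pd.DataFrame(rows)
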