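"""Thermal-environment summaries from 4-hour interval soil data loggers.

Logger series (temperature 5 cm below the soil surface, six readings per
day) are reduced to daily means, then to cumulative degree days

    DD = sum over days of max(0, T_mean - T_base)

accumulated per month over a growing-season window (the default window
semantics run 1 November through 15 May).  Among-site differences are
tested by one-way ANOVA with plant microsites as replicates.  An optional
photoperiod multiplier (daylength from latitude and day of year via the
standard solar-declination formula) converts degree days into
photo-thermal units; it is off by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "daily_mean_temp",
    "degree_days",
    "site_anova",
    "daylength_hours",
]

READINGS_PER_DAY = 6
MIN_READINGS = 4


def daily_mean_temp(
    loggers: pd.DataFrame,
    min_readings: int = MIN_READINGS,
) -> pd.DataFrame:
    """Daily mean temperature per (site, microsite).

    ``loggers`` columns: site, microsite, timestamp, temp_C.  Days with
    fewer than ``min_readings`` of the nominal six 4-hourly readings are
    kept with a missing mean.
    """
    df = loggers.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    out = (
        df.groupby(["site", "microsite", "date"], as_index=False)
        .agg(tmean=("temp_C", "mean"), n_readings=("temp_C", "size"))
    )
    out.loc[out["n_readings"] < min_readings, "tmean"] = np.nan
    return out


def daylength_hours(latitude_deg: float, day_of_year) -> np.ndarray:
    """Daylength from latitude and day of year (solar declination formula)."""
    doy = np.asarray(day_of_year, dtype=float)
    decl = np.deg2rad(23.44) * np.sin(2 * np.pi * (284 + doy) / 365.0)
    lat = np.deg2rad(latitude_deg)
    cos_h = -np.tan(lat) * np.tan(decl)
    cos_h = np.clip(cos_h, -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_h)


def degree_days(
    daily: pd.DataFrame,
    base_temp: float = 0.0,
    start: str | pd.Timestamp | None = None,
    end: str | pd.Timestamp | None = None,
    photoperiod: bool = False,
    latitude_deg: float | None = None,
) -> pd.DataFrame:
    """Cumulative degree days per (site, microsite, month).

    Daily contributions are max(0, tmean - base_temp); missing daily means
    contribute nothing but are counted in ``n_missing``.  With
    ``photoperiod`` each day's contribution is weighted by daylength / 24
    (photo-thermal units), requiring ``latitude_deg``.
    """
    df = daily.copy()
    if start is not None:
        df = df[df["date"] >= pd.Timestamp(start)]
    if end is not None:
        df = df[df["date"] <= pd.Timestamp(end)]
    if df.empty:
        return pd.DataFrame(
            columns=["site", "microsite", "month", "cumulative_dd", "n_days", "n_missing", "base_temp"]
        )
    contrib = np.clip(df["tmean"] - base_temp, 0.0, None)
    if photoperiod:
        if latitude_deg is None:
            raise ValueError("photoperiod weighting requires latitude_deg")
        contrib = contrib * daylength_hours(latitude_deg, df["date"].dt.dayofyear) / 24.0
    df = df.assign(dd=contrib, month=df["date"].dt.to_period("M").astype(str))
    out = (
        df.groupby(["site", "microsite", "month"], as_index=False)
        .agg(
            cumulative_dd=("dd", "sum"),
            n_days=("dd", "size"),
            n_missing=("tmean", lambda s: int(s.isna().sum())),
        )
    )
    out["base_temp"] = base_temp
    return out


def site_anova(monthly_dd: pd.DataFrame) -> dict:
    """One-way ANOVA of whole-window cumulative degree days among sites,
    with microsites as replicates.  Returns F, df and p."""
    totals = (
        monthly_dd.groupby(["site", "microsite"], as_index=False)["cumulative_dd"].sum()
    )
    groups = [g["cumulative_dd"].to_numpy() for _, g in totals.groupby("site")]
    if len(groups) < 2:
        raise ValueError("need at least 2 sites")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 microsites per site")
    if np.ptp(np.concatenate(groups)) == 0:
        # all values identical: F is exactly 0 by definition
        return {"F": 0.0, "df_between": len(groups) - 1,
                "df_within": int(sum(len(g) for g in groups)) - len(groups), "p_value": 1.0}
    res = stats.f_oneway(*groups)
    return {
        "F": float(res.statistic),
        "df_between": len(groups) - 1,
        "df_within": int(sum(len(g) for g in groups)) - len(groups),
        "p_value": float(res.pvalue),
    }
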