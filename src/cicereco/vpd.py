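"""Vapor pressure deficit and per-leaf-area transpiration rates.

Saturation vapor pressure follows the Tetens approximation

    SVP(T) = 610.7 * 10^(7.5 T / (237.3 + T))   [Pa, T in deg C]

and VPD = (100 - RH)/100 * SVP.  Transpiration rate normalizes grams of
water transpired per interval by leaf area and interval length,
TR = (T / LA * 1000) / minutes, in mg cm^-2 min^-1.  Residual
transpiration is the per-pot residual from an ordinary least-squares
regression of total daytime transpiration on leaf area; pots that
transpire more than their canopy size predicts have positive residuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SVP_AT_0C_PA",
    "svp",
    "vpd",
    "transpiration_rate",
    "residual_transpiration",
    "summarize_vpd_experiment",
]

SVP_AT_0C_PA = 610.7
_TETENS_A = 7.5
_TETENS_B = 237.3


def svp(air_temp_c, literal: bool = False):
    """Saturation vapor pressure in Pascals at air temperature in deg C.

    ``literal=True`` evaluates the linear-in-T form 610.7 * 107.5 * T /
    (237.3 + T) for audit purposes only; the default is the Tetens
    power-of-ten form.
    """
    t = np.asarray(air_temp_c, dtype=float)
    if np.any(t <= -_TETENS_B):
        raise ValueError(f"air temperature must exceed {-_TETENS_B} deg C")
    if literal:
        out = SVP_AT_0C_PA * 107.5 * t / (_TETENS_B + t)
    else:
        out = SVP_AT_0C_PA * np.power(10.0, _TETENS_A * t / (_TETENS_B + t))
    return out if out.ndim else float(out)


def vpd(air_temp_c, relative_humidity_pct, literal: bool = False):
    """Vapor pressure deficit in Pascals: (100 - RH)/100 * SVP(T)."""
    rh = np.asarray(relative_humidity_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    out = (100.0 - rh) / 100.0 * svp(air_temp_c, literal=literal)
    return out if np.ndim(out) else float(out)


def transpiration_rate(transpiration_g, leaf_area_cm2, interval_min: float = 60.0):
    """Transpiration rate in mg cm^-2 min^-1: (T / LA * 1000) / minutes."""
    la = np.asarray(leaf_area_cm2, dtype=float)
    if np.any(la <= 0):
        raise ValueError("leaf area must be positive")
    if interval_min <= 0:
        raise ValueError("interval must be positive")
    out = np.asarray(transpiration_g, dtype=float) / la * 1000.0 / interval_min
    return out if np.ndim(out) else float(out)


def residual_transpiration(total_t_g, leaf_area_cm2) -> tuple[np.ndarray, float, float]:
    """Per-pot residuals of total transpiration regressed on leaf area.

    Returns (residuals, slope a, intercept b) with Residual T =
    Total T - (a * leaf_area + b).  Residuals sum to zero by the OLS
    normal equations.
    """
    t = np.asarray(total_t_g, dtype=float)
    la = np.asarray(leaf_area_cm2, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 pots")
    if np.allclose(la, la[0]):
        raise np.linalg.LinAlgError("leaf areas are constant: regression is singular")
    fit = stats.linregress(la, t)
    resid = t - (fit.slope * la + fit.intercept)
    return resid, float(fit.slope), float(fit.intercept)


def summarize_vpd_experiment(weighings: pd.DataFrame, leaf_areas: pd.DataFrame) -> pd.DataFrame:
    """Per-pot summary of a diurnal VPD-response experiment.

    ``weighings`` columns: pot, genotype, timestamp, weight_g, temp_C,
    RH_pct.  ``leaf_areas`` columns: pot, leaf_area_cm2.  Returns one row
    per pot with total transpiration over the weighing sequence, mean TR
    (per-minute, using actual interval lengths), mean VPD, leaf area and
    the residual transpiration across pots.
    """
    la_map = leaf_areas.set_index("pot")["leaf_area_cm2"]
    rows = []
    for pot, df in weighings.groupby("pot"):
        df = df.sort_values("timestamp")
        ts = pd.to_datetime(df["timestamp"])
        minutes = np.diff(ts.to_numpy()).astype("timedelta64[s]").astype(float) / 60.0
        w = df["weight_g"].to_numpy(dtype=float)
        t_int = w[:-1] - w[1:]
        la = float(la_map[pot])
        tr = transpiration_rate(t_int, la, interval_min=1.0) / minutes
        v = vpd(df["temp_C"].to_numpy(), df["RH_pct"].to_numpy())
        rows.append(
            {
                "pot": pot,
                "genotype": df["genotype"].iloc[0],
                "total_T_g": float(t_int.sum()),
                "mean_TR_mg_cm2_min": float(np.mean(tr)),
                "mean_VPD_Pa": float(np.mean(v)),
                "leaf_area_cm2": la,
            }
        )
    out = pd.DataFrame(rows)
    resid, slope, intercept = residual_transpiration(
        out["total_T_g"].to_numpy(), out["leaf_area_cm2"].to_numpy()
    )
    out["residual_T_g"] = resid
    out.attrs["regression"] = {"slope": slope, "intercept": intercept}
    return out
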