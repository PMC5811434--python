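"""Seed/soil color calibration and the seed-coat crypsis test.

Camera RGB channel means are first *linearized* against a set of six gray
reflectance standards imaged in the same session (the camera's radiance
response is modelled per channel as a power law, reflectance = a * m^b,
fit on log-log values), then *equalized* so that each channel reports the
same value on every gray standard.  The calibrated channels are reported as
LW/MW/SW (long/medium/short wave, i.e. derived from R/G/B).

Crypsis is tested on square-root-transformed 3-D Euclidean distances
between per-genotype seed color means and per-site soil color means: a
mixed-model ANOVA with a fixed native-vs-foreign contrast and a random
intercept for genotype (nested within population by unique labelling) asks
whether seeds are closer in color to their native site's soil than to
foreign soils.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import fit_lmm

__all__ = [
    "GRAY_STANDARD_COUNT",
    "OVEREXPOSURE_LIMIT",
    "Linearization",
    "CrypsisTestResult",
    "fit_linearization",
    "apply_linearization",
    "equalize_channels",
    "calibrate_table",
    "aggregate_colors",
    "build_distance_table",
    "crypsis_test",
]

GRAY_STANDARD_COUNT = 6
OVEREXPOSURE_LIMIT = 245.0
CHANNELS = ["R", "G", "B"]
CAL_CHANNELS = ["LW", "MW", "SW"]


@dataclass
class Linearization:
    """Per-channel power-law response model reflectance = gain * measured**exponent."""

    gain: np.ndarray        # shape (3,)
    exponent: np.ndarray    # shape (3,)
    r_squared: np.ndarray   # shape (3,), of the log-log least-squares fit
    monotone_warning: bool  # measured values not monotone in known reflectance


@dataclass
class CrypsisTestResult:
    fixed_effect: float     # native-minus-foreign contrast on sqrt-distance scale
    F_statistic: float
    df_num: int
    df_den: float
    p_value: float
    var_genotype: float
    var_residual: float
    n_obs: int
    n_genotypes: int


def _standards_arrays(standards: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if len(standards) != GRAY_STANDARD_COUNT:
        raise ValueError(
            f"expected exactly {GRAY_STANDARD_COUNT} gray standards, got {len(standards)}"
        )
    st = standards.sort_values("reflectance")
    refl = st["reflectance"].to_numpy(dtype=float)
    meas = st[CHANNELS].to_numpy(dtype=float)
    if np.any(meas <= 0):
        raise ValueError("gray-standard channel means must be strictly positive")
    if np.any(refl <= 0) or np.any(np.diff(refl) <= 0):
        raise ValueError("known reflectances must be positive and strictly increasing")
    return refl, meas


def fit_linearization(standards: pd.DataFrame) -> Linearization:
    """Fit the per-channel power-law camera response from one session's standards.

    ``standards`` needs columns ``standard_id``, ``reflectance`` and R/G/B
    channel means.  The fit is ordinary least squares of log(reflectance) on
    log(measured), channel by channel.
    """
    refl, meas = _standards_arrays(standards)
    monotone_warning = bool(np.any(np.diff(meas, axis=0) <= 0))
    if monotone_warning:
        warnings.warn("measured gray-standard values are not monotone in reflectance")
    logr = np.log(refl)
    gain = np.empty(3)
    expo = np.empty(3)
    r2 = np.empty(3)
    for c in range(3):
        logm = np.log(meas[:, c])
        A = np.column_stack([np.ones_like(logm), logm])
        coef, *_ = np.linalg.lstsq(A, logr, rcond=None)
        fitted = A @ coef
        ss_res = float(np.sum((logr - fitted) ** 2))
        ss_tot = float(np.sum((logr - logr.mean()) ** 2))
        gain[c] = np.exp(coef[0])
        expo[c] = coef[1]
        r2[c] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return Linearization(gain, expo, r2, monotone_warning)


def apply_linearization(rgb: np.ndarray, lin: Linearization) -> np.ndarray:
    """Map raw channel means (n, 3) onto the linear reflectance scale."""
    rgb = np.asarray(rgb, dtype=float)
    return lin.gain * np.power(rgb, lin.exponent)


def equalize_channels(linearized: np.ndarray, linearized_standards: np.ndarray) -> np.ndarray:
    """Divide each channel by its mean linearized value over the six standards.

    After this step all three channels report the identical value on every
    gray standard (up to the linearization fit residual).
    """
    linearized_standards = np.asarray(linearized_standards, dtype=float)
    means = linearized_standards.mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("zero or negative channel mean over the gray standards")
    return np.asarray(linearized, dtype=float) / means


def calibrate_table(colors: pd.DataFrame, standards: pd.DataFrame) -> pd.DataFrame:
    """Calibrate a raw color table session by session.

    ``colors`` columns: sample_id, kind, site, genotype, replicate, R, G, B,
    session.  ``standards`` columns: session, standard_id, reflectance,
    R, G, B.  Returns a copy of ``colors`` with LW/MW/SW columns appended.
    Records are always calibrated against their own session's standards.
    """
    raw = colors[CHANNELS].to_numpy(dtype=float)
    if np.any(raw >= OVEREXPOSURE_LIMIT):
        warnings.warn(
            f"raw channel means at or above {OVEREXPOSURE_LIMIT} detected: "
            "possible over-exposure"
        )
    out = colors.copy()
    for ch in CAL_CHANNELS:
        out[ch] = np.nan
    for session, idx in colors.groupby("session").indices.items():
        st = standards[standards["session"] == session]
        if st.empty:
            raise ValueError(f"no gray standards for session {session!r}")
        lin = fit_linearization(st)
        lin_std = apply_linearization(st[CHANNELS].to_numpy(dtype=float), lin)
        calibrated = equalize_channels(apply_linearization(raw[idx], lin), lin_std)
        out.loc[out.index[idx], CAL_CHANNELS] = calibrated
    return out


def aggregate_colors(
    calibrated: pd.DataFrame,
    expected_seed_reps: int = 5,
    expected_soil_reps: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average calibrated replicates into per-genotype seed means and per-site
    soil means.

    Seeds average the (nominally five) replicate measurements per genotype;
    soils average all aliquots and samples per site.  Replicate counts are
    reported; shortfalls are aggregated anyway with a warning.
    """
    if calibrated[CAL_CHANNELS].isna().any().any():
        raise ValueError("calibrated LW/MW/SW values missing; run calibrate_table first")
    seeds = calibrated[calibrated["kind"] == "seed"]
    soils = calibrated[calibrated["kind"] == "soil"]
    seed_means = (
        seeds.groupby(["genotype", "site"], as_index=False)
        .agg(**{ch: (ch, "mean") for ch in CAL_CHANNELS}, n_reps=("LW", "size"))
    )
    soil_means = (
        soils.groupby("site", as_index=False)
        .agg(**{ch: (ch, "mean") for ch in CAL_CHANNELS}, n_reps=("LW", "size"))
    )
    if (seed_means["n_reps"] < expected_seed_reps).any():
        warnings.warn("some genotypes have fewer seed replicates than expected")
    if (soil_means["n_reps"] < expected_soil_reps).any():
        warnings.warn("some sites have fewer soil measurements than expected")
    return seed_means, soil_means


def build_distance_table(
    seed_means: pd.DataFrame,
    soil_means: pd.DataFrame,
    populations: dict | pd.Series | None = None,
) -> pd.DataFrame:
    """One row per (genotype x soil site): 3-D Euclidean color distance.

    ``seed_means`` must carry the genotype's native site in its ``site``
    column.  ``populations`` optionally maps genotype -> population label
    (defaults to the native site).  Genotypes whose native site has no soil
    mean are excluded with a warning.  ``transformed_distance`` is the
    square root of the distance.
    """
    soil_sites = set(soil_means["site"])
    missing = sorted(set(seed_means["site"]) - soil_sites)
    if missing:
        warnings.warn(f"genotypes with no native-site soil excluded: sites {missing}")
        seed_means = seed_means[seed_means["site"].isin(soil_sites)]
    if seed_means.empty:
        raise ValueError("no genotype has a native-site soil mean")

    seed_xyz = seed_means[CAL_CHANNELS].to_numpy(dtype=float)
    soil_xyz = soil_means[CAL_CHANNELS].to_numpy(dtype=float)
    dist = np.sqrt(((seed_xyz[:, None, :] - soil_xyz[None, :, :]) ** 2).sum(axis=2))

    n_g, n_s = dist.shape
    genotype = np.repeat(seed_means["genotype"].to_numpy(), n_s)
    native = np.repeat(seed_means["site"].to_numpy(), n_s)
    compared = np.tile(soil_means["site"].to_numpy(), n_g)
    out = pd.DataFrame(
        {
            "genotype": genotype,
            "native_site": native,
            "compared_site": compared,
            "is_native": native == compared,
            "distance": dist.ravel(),
            "transformed_distance": np.sqrt(dist.ravel()),
        }
    )
    if populations is not None:
        out["population"] = out["genotype"].map(populations)
    else:
        out["population"] = out["native_site"]
    return out


def _design_matrix(distances: pd.DataFrame, grouping: str | None, site_effects: bool):
    n = len(distances)
    cols = [np.ones(n), distances["is_native"].to_numpy(dtype=float)]
    names = ["intercept", "is_native"]
    if site_effects:
        dummies = pd.get_dummies(distances["compared_site"], drop_first=True, dtype=float)
        for level in dummies.columns:
            cols.append(dummies[level].to_numpy())
            names.append(f"soil[{level}]")
    if grouping is not None:
        if grouping not in distances.columns:
            raise KeyError(f"grouping column {grouping!r} not in distance table")
        dummies = pd.get_dummies(distances[grouping], drop_first=True, dtype=float)
        for level in dummies.columns:
            cols.append(dummies[level].to_numpy())
            names.append(f"{grouping}[{level}]")
        for level in dummies.columns:
            cols.append(dummies[level].to_numpy() * cols[1])
            names.append(f"is_native:{grouping}[{level}]")
    return np.column_stack(cols), names


def crypsis_test(
    distances: pd.DataFrame,
    grouping: str | None = None,
    site_effects: bool = True,
    force_zero_variance: bool = False,
) -> CrypsisTestResult:
    """Mixed-model test of whether seeds match their native soil's color.

    Fits ``sqrt(distance) ~ is_native + soil_site (+ grouping +
    is_native:grouping)`` with a random intercept per genotype and returns
    the Wald F for the native/foreign contrast with Satterthwaite
    denominator df.  A negative fixed effect means native distances are
    smaller, i.e. crypsis.  ``site_effects`` absorbs the baseline distance
    level of each compared soil, which is shared by every genotype and
    would otherwise inflate the residual variance; it can be switched off
    to reproduce the bare native/foreign model.
    """
    d = distances
    if d["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes for the crypsis test")
    if d["is_native"].nunique() < 2:
        raise ValueError("design has no native/foreign contrast")
    y = d["transformed_distance"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite transformed distances")
    X, names = _design_matrix(d, grouping, site_effects)
    fit = fit_lmm(
        X, y, d["genotype"].to_numpy(), exog_names=names,
        force_zero_variance=force_zero_variance,
    )
    L = np.zeros(X.shape[1])
    L[1] = 1.0  # the is_native coefficient
    test = fit.contrast_test(L)
    return CrypsisTestResult(
        fixed_effect=test.estimate,
        F_statistic=test.F,
        df_num=test.df_num,
        df_den=test.df_den,
        p_value=test.p_value,
        var_genotype=fit.sigma2_group,
        var_residual=fit.sigma2_resid,
        n_obs=fit.n_obs,
        n_genotypes=fit.n_groups,
    )
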