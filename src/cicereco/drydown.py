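"""Dry-down drought physiology: transpiration, FTSW, NTR and curve traits.

A dry-down experiment tracks morning pot weights of water-stressed (WS) and
well-watered (WW) pots.  Daily transpiration is the weight drop between
successive mornings plus any water added between the two weighings.  The
fraction of transpirable soil water,

    FTSW = (weight_day_n - final_weight) / (initial_weight - final_weight),

indexes the stress level; the normalized transpiration ratio (NTR) rescales
each WS pot's transpiration by the same-day well-watered mean for its
genotype and then by the pot's own mean ratio over wet days (FTSW > 0.8) so
that the series starts near 1.  The NTR-vs-FTSW decline is summarized
either by a two-segment plateau regression (plateau at 1, linear decline
below a breakpoint) or by the inflection of a fourth-order polynomial fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DryDownSeries",
    "series_from_table",
    "PlateauFit",
    "NoBreakpointError",
    "NoInflectionError",
    "daily_transpiration",
    "ftsw",
    "ntr_table",
    "fit_plateau",
    "inflection_point",
    "drydown_traits",
    "trait_vs_aridity",
]

WET_FTSW_THRESHOLD = 0.8   # stage-2 NTR normalization window
TERMINATION_NTR = 0.1      # dry-down termination rule


class NoBreakpointError(RuntimeError):
    """All points lie on the plateau: no decline to fit."""


class NoInflectionError(RuntimeError):
    """No real second-derivative root inside the observed FTSW range."""


@dataclass
class DryDownSeries:
    """Morning-weight series of one pot."""

    pot_id: str
    genotype_id: str
    treatment: str                  # "WW" | "WS"
    days: np.ndarray                # integer day index, strictly increasing
    weights: np.ndarray             # grams, morning weighing
    water_added: np.ndarray         # grams added after each weighing
    leaf_area: float | None = None  # cm^2, end of experiment
    initial_weight: float | None = None
    final_weight: float | None = None

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        self.water_added = np.asarray(self.water_added, dtype=float)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.weights <= 0):
            raise ValueError("pot weights must be positive")
        if np.any(self.water_added < 0):
            raise ValueError("water additions cannot be negative")
        if self.initial_weight is None:
            self.initial_weight = float(self.weights[0])
        if self.final_weight is None:
            self.final_weight = float(self.weights.min())


def series_from_table(
    weights: pd.DataFrame,
    leaf_areas: pd.DataFrame | None = None,
) -> list[DryDownSeries]:
    """Build per-pot series from a long-format weight table.

    ``weights`` columns: pot, genotype, treatment, date, weight_g,
    water_added_g.  Days are counted from each pot's first weighing; the
    final weight defaults to the series minimum (the operational
    transpirable-water endpoint).
    """
    la_map = (
        leaf_areas.set_index("pot")["leaf_area_cm2"] if leaf_areas is not None else None
    )
    out = []
    for pot, df in weights.groupby("pot"):
        df = df.sort_values("date")
        dates = pd.to_datetime(df["date"])
        days = (dates - dates.iloc[0]).dt.days.to_numpy()
        out.append(
            DryDownSeries(
                pot_id=str(pot),
                genotype_id=str(df["genotype"].iloc[0]),
                treatment=str(df["treatment"].iloc[0]),
                days=days,
                weights=df["weight_g"].to_numpy(dtype=float),
                water_added=df["water_added_g"].to_numpy(dtype=float),
                leaf_area=float(la_map[pot]) if la_map is not None and pot in la_map.index else None,
            )
        )
    return out


def daily_transpiration(series: DryDownSeries) -> pd.DataFrame:
    """Per-day transpiration T_d = weight_d - weight_{d+1} + water_added_d.

    Gaps in the day sequence are flagged and not bridged; negative values
    (weighing error) are retained but flagged.
    """
    if len(series.weights) < 2:
        raise ValueError("need at least two daily weights")
    d = series.days
    t = series.weights[:-1] - series.weights[1:] + series.water_added[:-1]
    gap = np.diff(d) != 1
    t = np.where(gap, np.nan, t)
    if np.any(gap):
        warnings.warn(f"pot {series.pot_id}: day gaps detected; transpiration not computed across gaps")
    return pd.DataFrame(
        {
            "day": d[:-1],
            "transpiration": t,
            "negative_flag": ~np.isnan(t) & (t < 0),
            "gap_flag": gap,
        }
    )


def ftsw(series: DryDownSeries) -> pd.DataFrame:
    """FTSW per day; values outside [0, 1] are flagged, never silently clamped."""
    denom = series.initial_weight - series.final_weight
    if denom <= 0:
        raise ZeroDivisionError("initial weight must exceed final weight")
    f = (series.weights - series.final_weight) / denom
    return pd.DataFrame(
        {"day": series.days, "ftsw": f, "out_of_range": (f < 0) | (f > 1)}
    )


def ntr_table(pots: list[DryDownSeries], wet_threshold: float = WET_FTSW_THRESHOLD) -> pd.DataFrame:
    """NTR per WS pot per day, normalized in two stages.

    Stage 1: TR ratio = T_WS / mean(T_WW of the same genotype, same day);
    days with zero WW transpiration are excluded with a warning.  Stage 2:
    each pot's ratio series is rescaled by its own mean ratio over days with
    FTSW > ``wet_threshold`` so NTR starts near 1.  The returned frame has
    columns pot, genotype, day, ftsw, tr_ratio, ntr, terminated.
    """
    ws = [p for p in pots if p.treatment == "WS"]
    ww = [p for p in pots if p.treatment == "WW"]
    if not ws or not ww:
        raise ValueError("need both WS and WW pots")

    # WW mean transpiration per (genotype, day)
    ww_frames = []
    for p in ww:
        t = daily_transpiration(p)
        t["genotype"] = p.genotype_id
        ww_frames.append(t[["genotype", "day", "transpiration"]])
    ww_mean = (
        pd.concat(ww_frames)
        .dropna()
        .groupby(["genotype", "day"], as_index=False)["transpiration"]
        .mean()
        .rename(columns={"transpiration": "ww_mean"})
    )

    rows = []
    for p in ws:
        t = daily_transpiration(p)
        f = ftsw(p)
        ww_for_g = ww_mean[ww_mean["genotype"] == p.genotype_id][["day", "ww_mean"]]
        df = t.merge(f, on="day").merge(ww_for_g, on="day", how="left")
        zero_ww = df["ww_mean"] <= 0
        if zero_ww.any():
            warnings.warn(f"pot {p.pot_id}: days with zero WW transpiration excluded")
            df = df[~zero_ww]
        df = df.dropna(subset=["transpiration", "ww_mean"])
        df["tr_ratio"] = df["transpiration"] / df["ww_mean"]
        wet = df["ftsw"] > wet_threshold
        if not wet.any():
            warnings.warn(f"pot {p.pot_id}: no days with FTSW > {wet_threshold}; NTR left on ratio scale")
            scale = 1.0
        else:
            scale = df.loc[wet, "tr_ratio"].mean()
        df["ntr"] = df["tr_ratio"] / scale
        df["pot"] = p.pot_id
        df["genotype"] = p.genotype_id
        below = df["ntr"] < TERMINATION_NTR
        term_day = int(df.loc[below, "day"].iloc[0]) if below.any() else None
        df["terminated"] = below.cummax()
        df["termination_day"] = term_day
        rows.append(df[["pot", "genotype", "day", "ftsw", "tr_ratio", "ntr", "terminated", "termination_day"]])
    return pd.concat(rows, ignore_index=True)


@dataclass
class PlateauFit:
    breakpoint: float
    slope: float
    plateau: float
    rss: float
    n: int


def _plateau_sse(x, F, y, constrain_plateau):
    """Profile SSE over the slope (and plateau level) at breakpoint x."""
    below = F < x
    if below.sum() < 2:
        return np.inf, 0.0, 1.0
    dx = F[below] - x
    if constrain_plateau:
        plateau = 1.0
    else:
        above = ~below
        plateau = y[above].mean() if above.any() else 1.0
    r = y[below] - plateau
    # model below the breakpoint: y = plateau + s * (F - X), s > 0
    s = float(np.clip((r @ dx) / (dx @ dx), 0.0, None))
    resid_below = r - s * dx
    resid_above = y[~below] - plateau
    sse = float(resid_below @ resid_below + resid_above @ resid_above)
    return sse, s, plateau


def fit_plateau(
    ftsw_values: np.ndarray,
    ntr_values: np.ndarray,
    constrain_plateau: bool = True,
    floor: float | None = TERMINATION_NTR,
) -> PlateauFit:
    """Two-segment plateau regression of NTR on FTSW.

    Model: NTR = plateau for FTSW >= X; NTR = plateau - s * (X - FTSW) for
    FTSW < X, with s > 0.  The breakpoint X is located by a grid search over
    observed FTSW values and refined by bounded scalar minimization.  With
    ``constrain_plateau`` the plateau is pinned at 1 (the post-normalization
    level); otherwise it is the mean of the plateau-side points.  Points
    with NTR below ``floor`` (default: the 0.1 termination threshold, past
    which the experiment would have been stopped) are excluded so a
    near-zero transpiration tail cannot drag the decline segment.
    """
    F = np.asarray(ftsw_values, dtype=float)
    y = np.asarray(ntr_values, dtype=float)
    ok = np.isfinite(F) & np.isfinite(y)
    if floor is not None:
        ok &= y >= floor
    F, y = F[ok], y[ok]
    if F.size < 6:
        raise ValueError("need at least 6 (FTSW, NTR) points")
    order = np.argsort(F)
    F, y = F[order], y[order]

    candidates = np.unique(F)[2:-1]  # need >=2 points below, >=1 above
    if candidates.size == 0:
        raise NoBreakpointError("too few distinct FTSW values to place a breakpoint")
    sses = np.array([_plateau_sse(x, F, y, constrain_plateau)[0] for x in candidates])
    if not np.any(np.isfinite(sses)):
        raise NoBreakpointError("no candidate breakpoint with points on both sides")
    i = int(np.argmin(sses))
    lo = candidates[max(i - 1, 0)]
    hi = candidates[min(i + 1, candidates.size - 1)]
    if hi <= lo:
        x_hat = float(candidates[i])
    else:
        res = optimize.minimize_scalar(
            lambda x: _plateau_sse(x, F, y, constrain_plateau)[0],
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-10},
        )
        x_hat = float(res.x)
        if _plateau_sse(candidates[i], F, y, constrain_plateau)[0] < res.fun:
            x_hat = float(candidates[i])
    sse, s, plateau = _plateau_sse(x_hat, F, y, constrain_plateau)
    if s <= 1e-10:
        raise NoBreakpointError("no decline observed: all points lie on the plateau")
    return PlateauFit(breakpoint=x_hat, slope=s, plateau=plateau, rss=sse, n=int(F.size))


def inflection_point(
    ftsw_values: np.ndarray,
    ntr_values: np.ndarray,
    breakpoint: float | None = None,
    min_spread: float = 0.3,
) -> float:
    """FTSW at the second-derivative zero of a degree-4 polynomial fit.

    If several real roots fall inside the observed FTSW range, roots where
    the curvature crosses from positive to negative with increasing FTSW
    (third derivative negative: the shoulder of the decline) are preferred,
    and ties are broken by proximity to the plateau breakpoint (computed
    with :func:`fit_plateau` when not supplied; if that fails, the midpoint
    of the observed range anchors the tie-break).
    """
    F = np.asarray(ftsw_values, dtype=float)
    y = np.asarray(ntr_values, dtype=float)
    ok = np.isfinite(F) & np.isfinite(y)
    F, y = F[ok], y[ok]
    if F.size < 6:
        raise ValueError("need at least 6 points")
    if F.max() - F.min() <= min_spread:
        raise ValueError(f"FTSW spread must exceed {min_spread}")
    coef = np.polyfit(F, y, 4)  # highest power first
    c4, c3, c2 = coef[0], coef[1], coef[2]
    roots = np.roots([12 * c4, 6 * c3, 2 * c2])
    real = roots[np.abs(roots.imag) < 1e-8].real
    in_range = real[(real >= F.min()) & (real <= F.max())]
    if in_range.size == 0:
        raise NoInflectionError("no real second-derivative root in the observed FTSW range")
    if in_range.size == 1:
        return float(in_range[0])
    third = 24 * c4 * in_range + 6 * c3
    descending = in_range[third < 0]
    if descending.size == 1:
        return float(descending[0])
    if descending.size > 1:
        in_range = descending
    if breakpoint is None:
        try:
            breakpoint = fit_plateau(F, y).breakpoint
        except (NoBreakpointError, ValueError):
            breakpoint = 0.5 * (F.min() + F.max())
    return float(in_range[np.argmin(np.abs(in_range - breakpoint))])


def drydown_traits(pots: list[DryDownSeries]) -> pd.DataFrame:
    """Per-genotype NTR-curve traits: plateau breakpoint, slope, inflection,
    termination day.  WS replicates of a genotype are pooled before fitting."""
    table = ntr_table(pots)
    rows = []
    for genotype, df in table.groupby("genotype"):
        rec = {"genotype": genotype, "n_points": len(df)}
        try:
            fitres = fit_plateau(df["ftsw"].to_numpy(), df["ntr"].to_numpy())
            rec["breakpoint"] = fitres.breakpoint
            rec["slope"] = fitres.slope
        except (NoBreakpointError, ValueError) as e:
            warnings.warn(f"genotype {genotype}: plateau fit failed ({e})")
            rec["breakpoint"] = np.nan
            rec["slope"] = np.nan
        try:
            rec["inflection"] = inflection_point(
                df["ftsw"].to_numpy(), df["ntr"].to_numpy(),
                breakpoint=rec["breakpoint"] if np.isfinite(rec.get("breakpoint", np.nan)) else None,
            )
        except (NoInflectionError, ValueError):
            rec["inflection"] = np.nan
        term = df["termination_day"].dropna()
        rec["termination_day"] = term.iloc[0] if not term.empty else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def trait_vs_aridity(df: pd.DataFrame, trait: str = "breakpoint", aridity: str = "aridity") -> dict:
    """Pearson and Spearman correlation of a genotype trait with source-site
    aridity (precipitation / potential evapotranspiration)."""
    d = df[[trait, aridity]].dropna()
    if len(d) < 5:
        raise ValueError("need at least 5 genotypes with aridity values")
    if d[aridity].nunique() < 2 or d[trait].nunique() < 2:
        raise ValueError("correlation undefined for constant input")
    pr = stats.pearsonr(d[trait], d[aridity])
    sr = stats.spearmanr(d[trait], d[aridity])
    return {
        "n": int(len(d)),
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
    }
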