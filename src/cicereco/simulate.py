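"""Synthetic-data generators with planted, recoverable parameters.

Every generator is deterministic given (seed, config), emits tables in the
same schemas the analysis modules consume, and returns a machine-readable
``truth`` dict recording the planted parameters so the test suite can make
parameter-recovery assertions.  Default scales are deliberately small
(tens of genotypes, a few thousand SNPs, weeks of dry-down) so that full
simulation studies run in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drydown import DryDownSeries
from .popgen import GenotypeMatrix
from .soilpca import SOIL_VARIABLES
from .vpd import vpd as _vpd

__all__ = [
    "GRAY_REFLECTANCES",
    "ColorStudyConfig", "gen_color_study",
    "DryDownConfig", "gen_drydown", "gen_plateau_points", "plateau_curve",
    "VpdDayConfig", "gen_vpd_day",
    "LoggerConfig", "gen_logger",
    "SoilConfig", "gen_soil",
    "BioassayConfig", "gen_bioassay",
    "GenotypesConfig", "gen_genotypes",
]

# Neutral-patch reflectances in the style of a six-step gray scale,
# strictly increasing with standard id.
GRAY_REFLECTANCES = (0.031, 0.090, 0.198, 0.362, 0.591, 0.880)
STANDARD_IDS = (19, 20, 21, 22, 23, 24)


# ---------------------------------------------------------------------------
# seed/soil color study


@dataclass
class ColorStudyConfig:
    """Planted seed-soil crypsis study.

    ``delta`` in [0, 1] pulls each genotype's seed color from the global
    mean toward its native site's soil color: delta = 0 removes any
    seed-soil association (the null), delta = 1 with zero noise makes
    seeds identical in color to their native soil.
    """

    n_sites: int = 8
    n_genotypes: int = 20
    seed_reps: int = 5
    soil_samples: int = 5
    soil_reps: int = 3
    delta: float = 0.5
    camera_gamma: tuple[float, float, float] = (0.8, 1.0, 1.2)
    global_mean: tuple[float, float, float] = (0.42, 0.38, 0.33)
    site_sd: float = 0.08
    genotype_sd: float = 0.03
    replicate_sd: float = 0.01
    soil_sample_sd: float = 0.02
    soil_rep_sd: float = 0.01
    standards_noise_sd: float = 0.0


def _camera(reflectance: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Forward camera model: channel mean = 255 * reflectance**gamma,
    clipped under the over-exposure limit."""
    return np.minimum(255.0 * np.power(np.clip(reflectance, 1e-4, 0.93), gamma), 244.0)


def gen_color_study(config: ColorStudyConfig | None = None, seed: int = 0):
    """Returns (standards_df, colors_df, truth)."""
    cfg = config or ColorStudyConfig()
    if not 0.0 <= cfg.delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    if cfg.n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    gamma = np.asarray(cfg.camera_gamma, dtype=float)
    gm = np.asarray(cfg.global_mean, dtype=float)

    sites = [f"S{i + 1:02d}" for i in range(cfg.n_sites)]
    soil_site_mean = np.clip(
        gm + rng.normal(0.0, cfg.site_sd, size=(cfg.n_sites, 3)), 0.05, 0.90
    )
    native_idx = np.arange(cfg.n_genotypes) % cfg.n_sites
    seed_true = np.clip(
        gm + cfg.delta * (soil_site_mean[native_idx] - gm)
        + rng.normal(0.0, cfg.genotype_sd, size=(cfg.n_genotypes, 3)),
        0.05, 0.90,
    )

    std_refl = np.asarray(GRAY_REFLECTANCES)
    std_meas = _camera(std_refl[:, None] * np.ones(3), gamma)
    if cfg.standards_noise_sd > 0:
        std_meas = np.clip(std_meas + rng.normal(0, cfg.standards_noise_sd, std_meas.shape), 1.0, 244.0)
    standards = pd.DataFrame(
        {
            "session": 1,
            "standard_id": STANDARD_IDS,
            "reflectance": std_refl,
            "R": std_meas[:, 0],
            "G": std_meas[:, 1],
            "B": std_meas[:, 2],
        }
    )

    rows = []
    for g in range(cfg.n_genotypes):
        for rep in range(cfg.seed_reps):
            r = np.clip(seed_true[g] + rng.normal(0, cfg.replicate_sd, 3), 0.02, 0.90)
            m = _camera(r, gamma)
            rows.append(
                {
                    "sample_id": f"seed_G{g + 1:03d}_r{rep + 1}",
                    "kind": "seed",
                    "site": sites[native_idx[g]],
                    "genotype": f"G{g + 1:03d}",
                    "replicate": rep + 1,
                    "R": m[0], "G": m[1], "B": m[2],
                    "session": 1,
                }
            )
    for s in range(cfg.n_sites):
        for samp in range(cfg.soil_samples):
            sample_mean = np.clip(
                soil_site_mean[s] + rng.normal(0, cfg.soil_sample_sd, 3), 0.02, 0.90
            )
            for rep in range(cfg.soil_reps):
                r = np.clip(sample_mean + rng.normal(0, cfg.soil_rep_sd, 3), 0.02, 0.90)
                m = _camera(r, gamma)
                rows.append(
                    {
                        "sample_id": f"soil_{sites[s]}_s{samp + 1}_r{rep + 1}",
                        "kind": "soil",
                        "site": sites[s],
                        "genotype": "",
                        "replicate": rep + 1,
                        "R": m[0], "G": m[1], "B": m[2],
                        "session": 1,
                    }
                )
    colors = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "delta": cfg.delta,
        "camera_gamma": list(gamma),
        "sites": sites,
        "soil_site_means": soil_site_mean.tolist(),
        "genotype_native_site": {f"G{g + 1:03d}": sites[native_idx[g]] for g in range(cfg.n_genotypes)},
        "genotype_seed_colors": seed_true.tolist(),
    }
    return standards, colors, truth


# ---------------------------------------------------------------------------
# dry-down


def plateau_curve(ftsw, breakpoint: float, slope: float) -> np.ndarray:
    """Two-segment NTR(FTSW): 1 on the plateau, linear decline below the
    breakpoint, floored at 0."""
    f = np.asarray(ftsw, dtype=float)
    return np.clip(np.where(f >= breakpoint, 1.0, 1.0 + slope * (f - breakpoint)), 0.0, None)


@dataclass
class DryDownConfig:
    """Planted dry-down with per-genotype two-segment NTR curves.

    Breakpoints default to an even grid over 0.41-0.60, the trait range
    observed in wild accessions.  The water-stress schedule reproduces the
    partial-compensation protocol: pots may lose 50 g/day early and
    70 g/day late in the dry-down, with excess losses watered back.
    """

    n_genotypes: int = 20
    ww_reps: int = 2
    ws_reps: int = 2
    breakpoints: tuple | None = None      # default: linspace(0.41, 0.60)
    slope: float = 2.5
    initial_weight: float = 2000.0
    transpirable_water: float = 800.0     # grams; final weight = initial - this
    ww_deficit: float = 200.0             # WW kept within 200 g of field capacity
    ws_threshold_early: float = 50.0
    ws_threshold_late: float = 70.0
    potential_t_low: float = 60.0         # per-genotype potential transpiration range
    potential_t_high: float = 100.0
    max_days: int = 60
    transpiration_noise_cv: float = 0.0   # multiplicative noise on daily transpiration
    weighing_noise_sd: float = 0.0        # additive noise on recorded weights


def gen_drydown(config: DryDownConfig | None = None, seed: int = 0):
    """Returns (weights_df, pots, truth): a long-format weight table, the
    corresponding DryDownSeries objects (with true final weights), and the
    planted parameters."""
    cfg = config or DryDownConfig()
    if cfg.transpirable_water <= 0:
        raise ValueError("final weight must lie below initial weight")
    rng = np.random.default_rng(seed)
    n = cfg.n_genotypes
    bps = (
        np.asarray(cfg.breakpoints, dtype=float)
        if cfg.breakpoints is not None
        else np.linspace(0.41, 0.60, n)
    )
    if bps.size != n:
        raise ValueError("breakpoints length must match n_genotypes")
    final = cfg.initial_weight - cfg.transpirable_water
    t_pot = np.linspace(cfg.potential_t_low, cfg.potential_t_high, n)
    rng.shuffle(t_pot)

    pots: list[DryDownSeries] = []
    rows = []
    for g in range(n):
        gid = f"G{g + 1:03d}"
        for rep in range(cfg.ws_reps + cfg.ww_reps):
            is_ws = rep < cfg.ws_reps
            treatment = "WS" if is_ws else "WW"
            pot_id = f"{gid}_{treatment}{rep + 1}"
            w = cfg.initial_weight
            weights, added = [w], []
            for day in range(cfg.max_days):
                noise = (
                    rng.normal(1.0, cfg.transpiration_noise_cv)
                    if cfg.transpiration_noise_cv > 0 else 1.0
                )
                if is_ws:
                    f_true = (w - final) / cfg.transpirable_water
                    ntr_val = plateau_curve(f_true, bps[g], cfg.slope)
                    t = t_pot[g] * ntr_val * max(noise, 0.0)
                    thr = (
                        cfg.ws_threshold_early
                        if f_true > 0.5
                        else cfg.ws_threshold_late
                    )
                    add = max(0.0, t - thr)
                else:
                    t = t_pot[g] * max(noise, 0.0)
                    ntr_val = 1.0
                    floor = cfg.initial_weight - cfg.ww_deficit
                    add = max(0.0, floor - (w - t))
                w = w - t + add
                weights.append(w)
                added.append(add)
                if is_ws and ntr_val < 0.1:
                    break
            added.append(0.0)
            days = np.arange(len(weights))
            rec = np.asarray(weights)
            if cfg.weighing_noise_sd > 0:
                rec = rec + rng.normal(0, cfg.weighing_noise_sd, rec.shape)
            series = DryDownSeries(
                pot_id=pot_id, genotype_id=gid, treatment=treatment,
                days=days, weights=rec, water_added=np.asarray(added),
                initial_weight=cfg.initial_weight, final_weight=final,
            )
            pots.append(series)
            start = pd.Timestamp("2016-03-18")
            for d, (wt, ad) in enumerate(zip(rec, added)):
                rows.append(
                    {
                        "pot": pot_id, "genotype": gid, "treatment": treatment,
                        "date": (start + pd.Timedelta(days=d)).date().isoformat(),
                        "weight_g": wt, "water_added_g": ad,
                    }
                )
    weights_df = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "breakpoints": {f"G{g + 1:03d}": float(bps[g]) for g in range(n)},
        "slope": cfg.slope,
        "initial_weight": cfg.initial_weight,
        "final_weight": final,
        "potential_transpiration": {f"G{g + 1:03d}": float(t_pot[g]) for g in range(n)},
    }
    return weights_df, pots, truth


def gen_plateau_points(
    breakpoint: float,
    slope: float,
    n_points: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Directly sampled (FTSW, NTR) points from a two-segment curve, for
    breakpoint-recovery studies."""
    rng = np.random.default_rng(seed)
    f = np.linspace(0.02, 1.0, n_points)
    y = plateau_curve(f, breakpoint, slope)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, y.shape)
    return f, y


# ---------------------------------------------------------------------------
# diurnal VPD experiment


@dataclass
class VpdDayConfig:
    n_genotypes: int = 10
    pots_per_genotype: int = 3
    n_weighings: int = 7                      # 08:00-16:00
    base_rate: float = 0.006                  # g water per cm^2 leaf per kPa per hour
    leaf_area_low: float = 100.0
    leaf_area_high: float = 400.0
    temp_min: float = 18.0
    temp_max: float = 32.0
    rh_min: float = 25.0
    rh_max: float = 75.0
    high_residual_genotypes: tuple = (0,)     # indices with exaggerated high-VPD response
    high_residual_multiplier: float = 1.8
    noise_cv: float = 0.03
    initial_weight: float = 2500.0


def gen_vpd_day(config: VpdDayConfig | None = None, seed: int = 0):
    """Returns (weighings_df, leaf_areas_df, truth)."""
    cfg = config or VpdDayConfig()
    rng = np.random.default_rng(seed)
    hours = np.linspace(8.0, 16.0, cfg.n_weighings)
    frac = (hours - 8.0) / 8.0
    temp = cfg.temp_min + (cfg.temp_max - cfg.temp_min) * np.sin(np.pi * frac * 0.9)
    rh = cfg.rh_max - (cfg.rh_max - cfg.rh_min) * np.sin(np.pi * frac * 0.9)
    vpd_pa = _vpd(temp, rh)
    rows, la_rows = [], []
    hi = set(cfg.high_residual_genotypes)
    vpd_median = float(np.median(vpd_pa))
    for g in range(cfg.n_genotypes):
        gid = f"G{g + 1:03d}"
        for p in range(cfg.pots_per_genotype):
            pot_id = f"{gid}_P{p + 1}"
            la = float(rng.uniform(cfg.leaf_area_low, cfg.leaf_area_high))
            la_rows.append({"pot": pot_id, "genotype": gid, "leaf_area_cm2": la})
            w = cfg.initial_weight
            for i, h in enumerate(hours):
                ts = pd.Timestamp("2016-04-21") + pd.Timedelta(minutes=round(h * 60))
                rows.append(
                    {
                        "pot": pot_id, "genotype": gid, "timestamp": ts.isoformat(),
                        "weight_g": w, "temp_C": temp[i], "RH_pct": rh[i],
                    }
                )
                if i < cfg.n_weighings - 1:
                    interval_h = hours[i + 1] - hours[i]
                    mult = (
                        cfg.high_residual_multiplier
                        if g in hi and vpd_pa[i] > vpd_median else 1.0
                    )
                    t = cfg.base_rate * la * (vpd_pa[i] / 1000.0) * interval_h * mult
                    t *= max(rng.normal(1.0, cfg.noise_cv), 0.0) if cfg.noise_cv > 0 else 1.0
                    w -= t
    truth = {
        "seed": seed,
        "high_residual_genotypes": [f"G{g + 1:03d}" for g in sorted(hi)],
        "base_rate": cfg.base_rate,
    }
    return pd.DataFrame(rows), pd.DataFrame(la_rows), truth


# ---------------------------------------------------------------------------
# logger series / soils / bioassay


@dataclass
class LoggerConfig:
    n_sites: int = 6
    n_microsites: int = 5
    start: str = "2013-11-01"
    end: str = "2014-05-15"
    site_offsets: tuple | None = None  # deg C; default all zero (null)
    mean_temp: float = 8.0
    seasonal_amp: float = 8.0
    diurnal_amp: float = 4.0
    microsite_sd: float = 0.3
    noise_sd: float = 1.0


def gen_logger(config: LoggerConfig | None = None, seed: int = 0):
    """4-hourly soil-surface temperature series; returns (df, truth)."""
    cfg = config or LoggerConfig()
    rng = np.random.default_rng(seed)
    offsets = (
        np.asarray(cfg.site_offsets, dtype=float)
        if cfg.site_offsets is not None
        else np.zeros(cfg.n_sites)
    )
    if offsets.size != cfg.n_sites:
        raise ValueError("site_offsets length must match n_sites")
    times = pd.date_range(cfg.start, cfg.end, freq="4h")
    doy = times.dayofyear.to_numpy()
    hour = times.hour.to_numpy()
    seasonal = -cfg.seasonal_amp * np.cos(2 * np.pi * (doy - 15) / 365.0)
    diurnal = cfg.diurnal_amp * np.sin(2 * np.pi * (hour - 9) / 24.0)
    frames = []
    for s in range(cfg.n_sites):
        for m in range(cfg.n_microsites):
            micro = rng.normal(0, cfg.microsite_sd)
            temp = (
                cfg.mean_temp + offsets[s] + micro + seasonal + diurnal
                + rng.normal(0, cfg.noise_sd, times.size)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "site": f"S{s + 1:02d}",
                        "microsite": f"M{m + 1}",
                        "timestamp": times,
                        "temp_C": temp,
                    }
                )
            )
    truth = {"seed": seed, "site_offsets": offsets.tolist()}
    return pd.concat(frames, ignore_index=True), truth


@dataclass
class SoilConfig:
    n_sites: int = 8
    samples_per_site: int = 5
    site_sd: float = 0.25   # lognormal-scale site effects
    sample_sd: float = 0.12


# typical central values on each variable's measurement scale
_SOIL_SCALES = {
    "Cu": 2.0, "Zn": 1.5, "Fe": 3.0, "Ca": 120.0, "Mn": 0.8, "Na": 0.4,
    "K": 6.0, "Mg": 4.5, "N": 0.15, "organic_C": 1.8, "inorganic_C": 2.5,
    "total_C": 4.3, "S": 250.0, "lime_CaCO3": 18.0, "EC": 350.0,
    "P2O5": 45.0, "organic_matter": 3.0,
}


def gen_soil(config: SoilConfig | None = None, seed: int = 0):
    """Soil-chemistry table on the stated measurement scales; pH stays in
    (0, 14).  Returns (df, truth)."""
    cfg = config or SoilConfig()
    rng = np.random.default_rng(seed)
    rows = []
    site_effects = {}
    for s in range(cfg.n_sites):
        site = f"S{s + 1:02d}"
        eff = {v: rng.normal(0, cfg.site_sd) for v in _SOIL_SCALES}
        ph_site = rng.normal(7.6, 0.4)
        site_effects[site] = {**eff, "pH": ph_site}
        for k in range(cfg.samples_per_site):
            row = {"sample_id": f"{site}_s{k + 1}", "site": site}
            for v, scale in _SOIL_SCALES.items():
                row[v] = scale * np.exp(eff[v] + rng.normal(0, cfg.sample_sd))
            row["pH"] = float(np.clip(ph_site + rng.normal(0, 0.15), 3.5, 9.5))
            rows.append(row)
    df = pd.DataFrame(rows, columns=["sample_id", "site"] + SOIL_VARIABLES)
    truth = {"seed": seed, "site_effects": site_effects}
    return df, truth


@dataclass
class BioassayConfig:
    n_genotypes: int = 10
    replicates: int = 5                # five replications per accession
    baseline_gain: float = 60.0        # mg larval weight gain
    gain_cv: float = 0.15
    damage_mean: float = 4.5           # ordinal leaf damage rating, 1-9
    damage_sd: float = 0.8
    survival_p: float = 0.7
    hsi_shifts: dict = field(default_factory=dict)  # genotype index -> multiplier


def gen_bioassay(config: BioassayConfig | None = None, seed: int = 0):
    """Detached-leaf bioassay records; returns (df, truth)."""
    cfg = config or BioassayConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(cfg.n_genotypes):
        gid = f"G{g + 1:03d}"
        mult = cfg.hsi_shifts.get(g, 1.0)
        for rep in range(cfg.replicates):
            gain = cfg.baseline_gain * mult * np.exp(rng.normal(0, cfg.gain_cv))
            damage = int(np.clip(round(rng.normal(cfg.damage_mean, cfg.damage_sd)), 1, 9))
            survivors = int(rng.binomial(10, cfg.survival_p))
            rows.append(
                {
                    "genotype": gid, "replicate": rep + 1,
                    "weight_gain_mg": gain, "damage_rating": damage,
                    "survival": survivors / 10.0,
                }
            )
    truth = {
        "seed": seed,
        "hsi_shifts": {f"G{g + 1:03d}": m for g, m in cfg.hsi_shifts.items()},
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypesConfig:
    """Drifted populations from shared ancestral allele frequencies.

    ``scenario='tree'`` makes two clades ((P1,P2),(P3,P4)) with no gene
    flow, the null for f4.  ``scenario='admixture'`` makes sources A and B
    (drifted from the ancestor) and a target C that is an alpha/(1-alpha)
    frequency mixture of them, the alternative detected by a negative f3;
    ``scenario='unadmixed'`` drifts A, B and C independently, the f3 null.
    Drift is binomial resampling of ``drift_size`` chromosomes.
    """

    scenario: str = "tree"
    n_sites: int = 5000
    samples_per_pop: int = 10
    drift_size: int = 50
    alpha: float = 0.5
    mean_depth: float = 20.0
    contig: str = "Ca1"


def _drift(rng, p, size):
    return rng.binomial(size, p) / size


def gen_genotypes(config: GenotypesConfig | None = None, seed: int = 0):
    """Returns (GenotypeMatrix, truth)."""
    cfg = config or GenotypesConfig()
    if not 0.0 <= cfg.alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if cfg.n_sites < 200:
        raise ValueError("need at least 200 sites (two jackknife blocks)")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, cfg.n_sites)
    if cfg.scenario == "tree":
        clade12 = _drift(rng, anc, cfg.drift_size)
        clade34 = _drift(rng, anc, cfg.drift_size)
        pop_freqs = {
            "P1": _drift(rng, clade12, cfg.drift_size),
            "P2": _drift(rng, clade12, cfg.drift_size),
            "P3": _drift(rng, clade34, cfg.drift_size),
            "P4": _drift(rng, clade34, cfg.drift_size),
        }
    elif cfg.scenario == "admixture":
        a = _drift(rng, anc, cfg.drift_size)
        b = _drift(rng, anc, cfg.drift_size)
        pop_freqs = {"A": a, "B": b, "C": cfg.alpha * a + (1.0 - cfg.alpha) * b}
    elif cfg.scenario == "unadmixed":
        pop_freqs = {
            "A": _drift(rng, anc, cfg.drift_size),
            "B": _drift(rng, anc, cfg.drift_size),
            "C": _drift(rng, anc, cfg.drift_size),
        }
    else:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")

    names = list(pop_freqs)
    n_per = cfg.samples_per_pop
    G = np.empty((cfg.n_sites, n_per * len(names)), dtype=np.int8)
    samples, populations = [], {}
    for k, name in enumerate(names):
        cols = np.arange(k * n_per, (k + 1) * n_per)
        populations[name] = cols
        samples.extend(f"{name}_{i + 1:02d}" for i in range(n_per))
        G[:, cols] = rng.binomial(2, pop_freqs[name][:, None], (cfg.n_sites, n_per))
    depths = rng.poisson(cfg.mean_depth, G.shape).astype(np.int32)
    positions = np.arange(1, cfg.n_sites + 1) * 10  # strictly increasing
    matrix = GenotypeMatrix(
        contigs=np.full(cfg.n_sites, cfg.contig),
        positions=positions,
        genotypes=G,
        samples=samples,
        populations=populations,
        depths=depths,
    )
    truth = {
        "seed": seed,
        "scenario": cfg.scenario,
        "alpha": cfg.alpha if cfg.scenario == "admixture" else None,
        "drift_size": cfg.drift_size,
        "populations": names,
    }
    return matrix, truth


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a minimal biallelic VCF (GT:DP) readable by cyvcf2."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in pd.unique(matrix.contigs):
            length = int(matrix.positions[matrix.contigs == contig].max()) + 1000
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        depths = (
            matrix.depths
            if matrix.depths is not None
            else np.full(matrix.genotypes.shape, 20, dtype=np.int32)
        )
        for i in range(matrix.genotypes.shape[0]):
            calls = "\t".join(
                f"{gt_str[int(g)]}:{int(d)}"
                for g, d in zip(matrix.genotypes[i], depths[i])
            )
            fh.write(
                f"{matrix.contigs[i]}\t{int(matrix.positions[i])}\t.\tA\tT\t.\tPASS\t.\tGT:DP\t{calls}\n"
            )
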