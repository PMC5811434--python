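"""Replicated simulation studies over the full analysis pipeline.

Each routine here generates data with :mod:`cicereco.simulate`, pushes it
through the corresponding analysis stage end to end, and summarizes the
outcome over replicates (type-I error rate, power, parameter-recovery
coverage).  They back both the acceptance test suite and the standalone
acceptance script.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from . import bioassay, color, drydown, popgen, simulate

__all__ = [
    "CRYPSIS_DELTA_1P5_SD",
    "run_crypsis_pipeline",
    "crypsis_rejection_rate",
    "plateau_recovery_rate",
    "drydown_grid_rank_correlation",
    "f3_null_mean",
    "f3_admixture_detection_rate",
    "f4_null_exceedance_rate",
    "kw_shift_power",
]

# Mixing fraction for which the planted native-vs-foreign contrast on the
# sqrt-distance scale equals 1.5 residual SD under the default noise levels
# of ColorStudyConfig (measured once on a large pilot of the generator).
CRYPSIS_DELTA_1P5_SD = 0.41


def run_crypsis_pipeline(config: simulate.ColorStudyConfig, seed: int) -> color.CrypsisTestResult:
    """Generate one color study and run calibrate -> aggregate -> distances
    -> mixed-model crypsis test."""
    standards, colors, _ = simulate.gen_color_study(config, seed=seed)
    calibrated = color.calibrate_table(colors, standards)
    seed_means, soil_means = color.aggregate_colors(calibrated)
    distances = color.build_distance_table(seed_means, soil_means)
    return color.crypsis_test(distances)


def crypsis_rejection_rate(
    delta: float,
    n_reps: int,
    seed: int = 0,
    alpha: float = 0.05,
    n_genotypes: int = 20,
    n_sites: int = 8,
) -> float:
    """Fraction of replicate studies in which the crypsis test rejects."""
    cfg = simulate.ColorStudyConfig(delta=delta, n_genotypes=n_genotypes, n_sites=n_sites)
    ss = np.random.SeedSequence([seed, int(round(delta * 1000))])
    sub_seeds = ss.generate_state(n_reps)
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in sub_seeds:
            res = run_crypsis_pipeline(cfg, seed=int(s % 2**31))
            if res.p_value < alpha:
                hits += 1
    return hits / n_reps


def plateau_recovery_rate(
    noise_sd: float = 0.05,
    n_points: int = 30,
    n_reps: int = 200,
    seed: int = 0,
    tolerance: float = 0.05,
    slope: float = 2.5,
) -> float:
    """Fraction of noisy two-segment curves whose fitted breakpoint lands
    within ``tolerance`` of the planted value (drawn over the observed
    trait range 0.41-0.60)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        x_true = rng.uniform(0.41, 0.60)
        f, y = simulate.gen_plateau_points(
            x_true, slope, n_points=n_points, noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        try:
            fit = drydown.fit_plateau(f, y)
        except drydown.NoBreakpointError:
            continue
        if abs(fit.breakpoint - x_true) <= tolerance:
            hits += 1
    return hits / n_reps


def drydown_grid_rank_correlation(seed: int = 0, noise_cv: float = 0.03) -> float:
    """Spearman correlation of recovered vs planted breakpoints for a
    genotype grid spanning 0.41-0.60, run through the full dry-down
    pipeline (weights -> transpiration -> FTSW -> NTR -> plateau fit)."""
    cfg = simulate.DryDownConfig(transpiration_noise_cv=noise_cv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, pots, truth = simulate.gen_drydown(cfg, seed=seed)
        traits = drydown.drydown_traits(pots)
    traits["planted"] = traits["genotype"].map(truth["breakpoints"])
    ok = traits.dropna(subset=["breakpoint", "planted"])
    rho = stats.spearmanr(ok["breakpoint"], ok["planted"]).statistic
    return float(rho)


def _fstat_seeds(seed: int, n_runs: int, salt: int) -> np.ndarray:
    return np.random.SeedSequence([seed, salt]).generate_state(n_runs) % 2**31


def f3_null_mean(n_runs: int = 500, seed: int = 0, n_sites: int = 1000) -> float:
    """Mean f3 estimate when the target is unadmixed (independently drifted
    from the shared ancestor); non-negative in expectation."""
    cfg = simulate.GenotypesConfig(scenario="unadmixed", n_sites=n_sites)
    vals = []
    for s in _fstat_seeds(seed, n_runs, 11):
        matrix, _ = simulate.gen_genotypes(cfg, seed=int(s))
        vals.append(popgen.f3(matrix, "C", "A", "B").estimate)
    return float(np.mean(vals))


def f3_admixture_detection_rate(
    n_runs: int = 200,
    seed: int = 0,
    alpha: float = 0.5,
    drift_size: int = 5,
    n_sites: int = 5000,
) -> float:
    """Fraction of runs with f3(C; A, B) < 0 and |Z| > 3 under planted
    50/50 admixture with strong drift."""
    cfg = simulate.GenotypesConfig(
        scenario="admixture", alpha=alpha, drift_size=drift_size, n_sites=n_sites
    )
    hits = 0
    for s in _fstat_seeds(seed, n_runs, 13):
        matrix, _ = simulate.gen_genotypes(cfg, seed=int(s))
        res = popgen.f3(matrix, "C", "A", "B")
        if res.estimate < 0 and abs(res.z) > popgen.Z_SIGNIFICANCE:
            hits += 1
    return hits / n_runs


def f4_null_exceedance_rate(n_runs: int = 400, seed: int = 0, n_sites: int = 5000) -> float:
    """Fraction of tree-only simulations with |Z| > 3 for
    f4(P1, P2; P3, P4); should be a small false-positive rate."""
    cfg = simulate.GenotypesConfig(scenario="tree", n_sites=n_sites)
    hits = 0
    for s in _fstat_seeds(seed, n_runs, 17):
        matrix, _ = simulate.gen_genotypes(cfg, seed=int(s))
        res = popgen.f4(matrix, "P1", "P2", "P3", "P4")
        if abs(res.z) > popgen.Z_SIGNIFICANCE:
            hits += 1
    return hits / n_runs


def kw_shift_power(
    n_runs: int = 200,
    seed: int = 0,
    shift: float = 3.0,
    n_genotypes: int = 6,
    alpha: float = 0.05,
) -> float:
    """Power of the Kruskal-Wallis/Dunn pipeline to flag one genotype with
    a ``shift``-fold HSI increase (five replicates each), judged by any
    Bonferroni-significant Dunn comparison involving the shifted genotype."""
    shifted = n_genotypes - 1
    cfg = simulate.BioassayConfig(n_genotypes=n_genotypes, hsi_shifts={shifted: shift})
    gid = f"G{shifted + 1:03d}"
    hits = 0
    for s in _fstat_seeds(seed, n_runs, 19):
        records, _ = simulate.gen_bioassay(cfg, seed=int(s))
        res = bioassay.compare_genotypes(records)
        dn = res.dunn
        involved = dn[(dn["group_1"] == gid) | (dn["group_2"] == gid)]
        if res.p_value < alpha and (involved["p_bonferroni"] < alpha).any():
            hits += 1
    return hits / n_runs
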