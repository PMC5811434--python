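"""Pod-borer (Helicoverpa armigera) host suitability scoring.

The host suitability index per bioassay replicate is

    HSI = (larval weight gain / leaf damage rating) * larval survival

with survival expressed as the fraction of the ten released neonate larvae
that survive (integer counts are accepted and converted).  Low HSI marks a
poor host, i.e. a resistant genotype.  Genotypes are compared
nonparametrically with the Kruskal-Wallis H test (tie-corrected) and
Dunn's post hoc z tests with Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["hsi", "genotype_hsi_summary", "dunn_test", "compare_genotypes", "KWResult"]

LARVAE_RELEASED = 10


def hsi(weight_gain_mg, damage_rating, survival):
    """Host suitability index per replicate.

    ``survival`` may be a fraction in [0, 1] or an integer count of
    survivors out of the ten released larvae.
    """
    gain = np.asarray(weight_gain_mg, dtype=float)
    damage = np.asarray(damage_rating, dtype=float)
    surv = np.asarray(survival, dtype=float)
    if np.any(damage <= 0):
        raise ValueError("leaf damage rating must be positive")
    if np.any(gain < 0):
        raise ValueError("larval weight gain cannot be negative")
    surv = np.where(surv > 1, surv / LARVAE_RELEASED, surv)
    if np.any((surv < 0) | (surv > 1)):
        raise ValueError("survival must be a fraction in [0, 1] or a count of at most 10")
    out = gain / damage * surv
    return out if np.ndim(out) else float(out)


def genotype_hsi_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype mean, SD and n of the per-replicate HSI.

    ``records`` columns: genotype, weight_gain_mg, damage_rating, survival.
    """
    df = records.copy()
    df["hsi"] = hsi(df["weight_gain_mg"], df["damage_rating"], df["survival"])
    return (
        df.groupby("genotype", as_index=False)
        .agg(hsi_mean=("hsi", "mean"), hsi_sd=("hsi", "std"), n=("hsi", "size"))
    )


def dunn_test(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z tests on joint ranks with tie-corrected variance
    and Bonferroni-adjusted p-values (capped at 1)."""
    names = list(samples)
    values = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    sizes = np.array([len(samples[g]) for g in names])
    ranks = stats.rankdata(values)
    n_total = values.size
    # tie correction: sum over tie groups of (t^3 - t)
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    sigma2_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(names))]
    )
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i, j in combinations(range(len(names)), 2):
        se = np.sqrt(sigma2_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_1": names[i],
                "group_2": names[j],
                "z": float(z),
                "p_value": float(p),
                "p_bonferroni": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class KWResult:
    H: float
    df: int
    p_value: float
    dunn: pd.DataFrame


def compare_genotypes(records: pd.DataFrame, value_col: str = "hsi") -> KWResult:
    """Kruskal-Wallis test across genotypes followed by Dunn's post hoc.

    ``records`` needs a genotype column plus either a precomputed value
    column or the raw HSI components.
    """
    df = records.copy()
    if value_col not in df.columns:
        df[value_col] = hsi(df["weight_gain_mg"], df["damage_rating"], df["survival"])
    groups = {g: sub[value_col].to_numpy(dtype=float) for g, sub in df.groupby("genotype")}
    if len(groups) < 2:
        raise ValueError("need at least 2 genotypes")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least 2 replicates per genotype")
    allvals = np.concatenate(list(groups.values()))
    if np.ptp(allvals) == 0:
        # all observations identical: H is 0 by construction
        return KWResult(0.0, len(groups) - 1, 1.0, dunn_test(groups))
    kw = stats.kruskal(*groups.values())
    return KWResult(float(kw.statistic), len(groups) - 1, float(kw.pvalue), dunn_test(groups))
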