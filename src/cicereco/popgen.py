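"""Population-genetic summaries: diversity, windowed Tajima's D,
depth-filtered heterozygosity, and f3/f4 admixture statistics with a
block jackknife.

Genotypes are biallelic alt-allele doses (0/1/2, -1 for missing) with
optional per-call read depth.  Tajima's D is computed in fixed-size
windows of the reference coordinate (default 100 bp) from the classical
estimators: pi (mean pairwise differences), Watterson's theta_W = S / a1,
and D = (pi - theta_W) / sqrt(e1 S + e2 S (S - 1)).  Sites with missing
calls in the focal population are excluded so the haplotype count is
constant within a window; windows with fewer than three segregating sites
have D reported as missing.

f3(C; A, B) averages (c - a)(c - b) over sites and f4(P1, P2; P3, P4)
averages (p1 - p2)(p3 - p4), with standard errors from a delete-one block
jackknife over consecutive blocks of 100 SNPs; |Z| > 3 flags significance.
A significantly negative f3 indicates admixture in the target C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "WindowStat",
    "FStatResult",
    "allele_frequencies",
    "tajimas_d_windows",
    "heterozygosity",
    "block_jackknife",
    "f3",
    "f4",
]

DEFAULT_WINDOW_BP = 100
DEFAULT_BLOCK_SNPS = 100
MIN_SEGREGATING_FOR_D = 3
DEFAULT_MIN_DEPTH = 4
Z_SIGNIFICANCE = 3.0


@dataclass
class GenotypeMatrix:
    """Biallelic calls for samples grouped into populations.

    ``genotypes`` is (n_sites, n_samples) of alt-allele doses in
    {0, 1, 2} with -1 for missing; ``depths`` is the per-call read depth
    (or None).  Positions are 1-based and strictly increasing per contig.
    """

    contigs: np.ndarray    # (n_sites,) str
    positions: np.ndarray  # (n_sites,) int, 1-based
    genotypes: np.ndarray  # (n_sites, n_samples) int8
    samples: list[str]
    populations: dict[str, np.ndarray]  # name -> sample index array
    depths: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes)
        for contig in np.unique(self.contigs):
            pos = self.positions[self.contigs == contig]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {contig}")
        bad = ~np.isin(self.genotypes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype doses must be in {0, 1, 2} or -1 (missing)")

    def pop_index(self, population: str) -> np.ndarray:
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        return self.populations[population]

    @classmethod
    def from_vcf(cls, path: str, popmap: dict[str, str] | None = None) -> "GenotypeMatrix":
        """Read a biallelic VCF (with per-call DP) via cyvcf2.

        ``popmap`` maps sample name -> population; unmapped samples form a
        single population "ALL".
        """
        from cyvcf2 import VCF

        vcf = VCF(path, gts012=True)
        samples = list(vcf.samples)
        contigs, positions, rows, depth_rows = [], [], [], []
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            contigs.append(var.CHROM)
            positions.append(var.POS)
            gt = var.gt_types.astype(np.int8)  # 0/1/2 dose, 3 = unknown
            gt[gt == 3] = -1
            rows.append(gt)
            dp = var.format("DP")
            depth_rows.append(
                dp[:, 0].astype(np.int32) if dp is not None else np.full(len(samples), -1, np.int32)
            )
        genotypes = np.vstack(rows)
        depths = np.vstack(depth_rows)
        if np.all(depths < 0):
            depths = None
        if popmap is None:
            populations = {"ALL": np.arange(len(samples))}
        else:
            populations = {}
            for i, s in enumerate(samples):
                populations.setdefault(popmap.get(s, "ALL"), []).append(i)
            populations = {k: np.asarray(v) for k, v in populations.items()}
        return cls(
            contigs=np.asarray(contigs),
            positions=np.asarray(positions),
            genotypes=genotypes,
            samples=samples,
            populations=populations,
            depths=depths,
        )


def allele_frequencies(matrix: GenotypeMatrix, population: str) -> np.ndarray:
    """Per-site alt-allele frequency in a population (NaN where all calls
    are missing)."""
    idx = matrix.pop_index(population)
    if idx.size == 0:
        raise ValueError(f"population {population!r} is empty")
    g = matrix.genotypes[:, idx]
    called = g >= 0
    n_chrom = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_chrom > 0, alt / n_chrom, np.nan)


def _tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) for n haplotypes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


@dataclass
class WindowStat:
    contig: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    n_segregating: int
    pi: float
    theta_w: float
    tajimas_d: float  # NaN when undefined


def tajimas_d_windows(
    matrix: GenotypeMatrix,
    population: str | None = None,
    window_size: int = DEFAULT_WINDOW_BP,
    step: int | None = None,
) -> pd.DataFrame:
    """Windowed pi, Watterson's theta and Tajima's D.

    Windows tile the 1-based reference coordinate from position 1 in
    ``window_size`` steps (``step`` defaults to non-overlapping windows)
    and are reported 0-based half-open.  Only sites fully called in the
    population contribute.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    step = step or window_size
    if step <= 0:
        raise ValueError("step must be positive")
    idx = matrix.pop_index(population) if population else np.arange(len(matrix.samples))
    g = matrix.genotypes[:, idx]
    n = 2 * idx.size
    if n < 4:
        raise ValueError("need at least 4 haplotypes (2 diploids)")
    complete = np.all(g >= 0, axis=1)
    alt = g.sum(axis=1)

    a1, e1, e2 = _tajima_constants(n)
    rows = []
    for contig in pd.unique(matrix.contigs):
        on = (matrix.contigs == contig) & complete
        pos = matrix.positions[on]
        counts = alt[on]
        if pos.size == 0:
            continue
        last = int(pos.max())
        for w0 in range(0, last, step):
            w1 = w0 + window_size
            sel = (pos > w0) & (pos <= w1)  # 1-based positions in (w0, w1]
            c = counts[sel]
            seg = (c > 0) & (c < n)
            S = int(seg.sum())
            pi = float(np.sum(c * (n - c)) / (n * (n - 1) / 2.0))
            theta_w = S / a1
            if S >= MIN_SEGREGATING_FOR_D:
                var = e1 * S + e2 * S * (S - 1)
                d = (pi - theta_w) / np.sqrt(var)
            else:
                d = np.nan
            rows.append(
                {
                    "contig": contig, "start": w0, "end": w1,
                    "n_segregating": S, "pi": pi, "theta_w": theta_w,
                    "tajimas_d": d,
                }
            )
    return pd.DataFrame(rows)


def heterozygosity(
    matrix: GenotypeMatrix,
    population: str | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> float:
    """Fraction of heterozygous calls after discarding calls with read
    depth below ``min_depth`` (depth filtering guards against false
    heterozygotes at low coverage).  NaN when no call survives."""
    idx = matrix.pop_index(population) if population else np.arange(len(matrix.samples))
    g = matrix.genotypes[:, idx]
    ok = g >= 0
    if min_depth > 0:
        if matrix.depths is None:
            raise ValueError("depth filtering requested but no depths available")
        ok &= matrix.depths[:, idx] >= min_depth
    n_called = int(ok.sum())
    if n_called == 0:
        return float("nan")
    return float(((g == 1) & ok).sum() / n_called)


def block_jackknife(per_site: np.ndarray, block_size: int) -> tuple[float, float, int]:
    """Delete-one block jackknife over consecutive blocks.

    Returns (estimate, SE, n_blocks) where the estimate is the plain mean
    over sites and SE^2 = (B-1)/B * sum_j (theta_(j) - mean_j theta_(j))^2
    over the delete-one estimates theta_(j).  A trailing partial block is
    merged into the last full block.
    """
    h = np.asarray(per_site, dtype=float)
    n = h.size
    n_blocks = n // block_size
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    edges = [i * block_size for i in range(n_blocks)] + [n]
    total = h.sum()
    est = total / n
    loo = np.empty(n_blocks)
    for j in range(n_blocks):
        sl = slice(edges[j], edges[j + 1])
        nb = edges[j + 1] - edges[j]
        loo[j] = (total - h[sl].sum()) / (n - nb)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2)))
    return float(est), se, n_blocks


@dataclass
class FStatResult:
    kind: str
    populations: tuple
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_sites: int

    @property
    def significant(self) -> bool:
        return abs(self.z) > Z_SIGNIFICANCE


def _freq_stack(matrix: GenotypeMatrix, pops: tuple[str, ...]) -> np.ndarray:
    freqs = np.vstack([allele_frequencies(matrix, p) for p in pops])
    keep = ~np.isnan(freqs).any(axis=0)
    return freqs[:, keep]


def f3(
    matrix: GenotypeMatrix,
    target: str,
    source1: str,
    source2: str,
    block_size: int = DEFAULT_BLOCK_SNPS,
) -> FStatResult:
    """f3(target; source1, source2) with block-jackknife standard error."""
    c, a, b = _freq_stack(matrix, (target, source1, source2))
    h = (c - a) * (c - b)
    est, se, nb = block_jackknife(h, block_size)
    z = est / se if se > 0 else np.nan
    return FStatResult("f3", (target, source1, source2), est, se, float(z), nb, h.size)


def f4(
    matrix: GenotypeMatrix,
    p1: str,
    p2: str,
    p3: str,
    p4: str,
    block_size: int = DEFAULT_BLOCK_SNPS,
) -> FStatResult:
    """f4(P1, P2; P3, P4) with block-jackknife standard error.

    Antisymmetric in each pair: swapping P1 and P2 (or P3 and P4) flips
    the sign.
    """
    a1, a2, a3, a4 = _freq_stack(matrix, (p1, p2, p3, p4))
    h = (a1 - a2) * (a3 - a4)
    est, se, nb = block_jackknife(h, block_size)
    z = est / se if se > 0 else np.nan
    return FStatResult("f4", (p1, p2, p3, p4), est, se, float(z), nb, h.size)
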