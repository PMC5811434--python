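import numpy as np
import pytest

from cicereco.popgen import GenotypeMatrix


@pytest.fixture
def small_matrix():
    """5 diploid samples in two populations, 12 sites on one contig."""
    rng = np.random.default_rng(42)
    n_sites, n_samples = 12, 5
    g = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    depths = rng.integers(1, 30, size=(n_sites, n_samples)).astype(np.int32)
    return GenotypeMatrix(
        contigs=np.full(n_sites, "Ca1"),
        positions=np.arange(1, n_sites + 1) * 7,
        genotypes=g,
        samples=[f"s{i}" for i in range(n_samples)],
        populations={"P1": np.array([0, 1, 2]), "P2": np.array([3, 4])},
        depths=depths,
    )


def make_matrix(freq_rows: dict[str, list[float]], samples_per_pop: int, seed: int = 0):
    """Diploid genotypes sampled binomially from given per-population
    frequencies (one row of frequencies per population)."""
    rng = np.random.default_rng(seed)
    names = list(freq_rows)
    n_sites = len(next(iter(freq_rows.values())))
    g = np.empty((n_sites, samples_per_pop * len(names)), dtype=np.int8)
    populations, samples = {}, []
    for k, name in enumerate(names):
        cols = np.arange(k * samples_per_pop, (k + 1) * samples_per_pop)
        populations[name] = cols
        samples += [f"{name}_{i}" for i in range(samples_per_pop)]
        g[:, cols] = rng.binomial(
            2, np.asarray(freq_rows[name])[:, None], (n_sites, samples_per_pop)
        )
    return GenotypeMatrix(
        contigs=np.full(n_sites, "Ca1"),
        positions=np.arange(1, n_sites + 1),
        genotypes=g,
        samples=samples,
        populations=populations,
    )
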