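"""Diversity statistics and f-statistics against brute-force oracles."""

import numpy as np
import pytest

from cicereco import popgen, simulate
from cicereco.popgen import GenotypeMatrix

from conftest import make_matrix


# -- independent oracles ----------------------------------------------------


def oracle_pi_theta_d(genotypes: np.ndarray):
    """Loop-based textbook computation on fully-called diploid genotypes.

    Expands each diploid into two pseudo-haplotypes per site and counts
    pairwise differences over every chromosome pair and site.
    """
    n_sites, n_samples = genotypes.shape
    n = 2 * n_samples
    # haplotype alleles per site (order within a genotype is irrelevant for
    # unphased per-site counts)
    haps = np.zeros((n_sites, n), dtype=int)
    for s in range(n_sites):
        k = 0
        for g in genotypes[s]:
            alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(g)]
            haps[s, k], haps[s, k + 1] = alleles
            k += 2
    diffs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs += int(np.sum(haps[:, i] != haps[:, j]))
    n_pairs = n * (n - 1) // 2
    pi = diffs / n_pairs
    S = sum(1 for s in range(n_sites) if 0 < haps[s].sum() < n)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    theta_w = S / a1
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    d = (pi - theta_w) / np.sqrt(var) if S >= 3 else np.nan
    return S, pi, theta_w, d


def oracle_freq(genotypes: np.ndarray):
    out = []
    for row in genotypes:
        alt = tot = 0
        for g in row:
            if g >= 0:
                alt += int(g)
                tot += 2
        out.append(alt / tot if tot else np.nan)
    return np.array(out)


# -- allele frequencies -----------------------------------------------------


class TestAlleleFrequencies:
    def test_simple_calls(self):
        m = make_matrix({"A": [0.5]}, samples_per_pop=3)
        m.genotypes[0] = [0, 1, 2]
        assert popgen.allele_frequencies(m, "A")[0] == pytest.approx(0.5)

    def test_all_missing_is_nan(self, small_matrix):
        small_matrix.genotypes[0, :3] = -1
        f = popgen.allele_frequencies(small_matrix, "P1")
        assert np.isnan(f[0])

    def test_matches_loop_oracle(self, small_matrix):
        small_matrix.genotypes[3, 1] = -1
        for pop in ("P1", "P2"):
            idx = small_matrix.populations[pop]
            expected = oracle_freq(small_matrix.genotypes[:, idx])
            got = popgen.allele_frequencies(small_matrix, pop)
            assert np.allclose(got, expected, atol=1e-12, equal_nan=True)

    def test_unknown_population(self, small_matrix):
        with pytest.raises(KeyError):
            popgen.allele_frequencies(small_matrix, "nope")


# -- Tajima's D -------------------------------------------------------------


class TestTajimasD:
    def test_monomorphic_window(self):
        m = make_matrix({"A": [0.5] * 4}, samples_per_pop=4)
        m.genotypes[:] = 0
        w = popgen.tajimas_d_windows(m, "A", window_size=100)
        assert w["pi"].iloc[0] == 0.0
        assert w["n_segregating"].iloc[0] == 0
        assert np.isnan(w["tajimas_d"].iloc[0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            g = rng.integers(0, 3, size=(rng.integers(5, 50), rng.integers(2, 5))).astype(np.int8)
            m = GenotypeMatrix(
                contigs=np.full(g.shape[0], "c"),
                positions=np.arange(1, g.shape[0] + 1),
                genotypes=g,
                samples=[f"s{i}" for i in range(g.shape[1])],
                populations={"A": np.arange(g.shape[1])},
            )
            w = popgen.tajimas_d_windows(m, "A", window_size=10_000)
            S, pi, theta_w, d = oracle_pi_theta_d(g)
            assert w["n_segregating"].iloc[0] == S
            assert w["pi"].iloc[0] == pytest.approx(pi, abs=1e-10)
            assert w["theta_w"].iloc[0] == pytest.approx(theta_w, abs=1e-10)
            if S >= 3:
                assert w["tajimas_d"].iloc[0] == pytest.approx(d, abs=1e-10)

    def test_singleton_only_window_is_negative(self):
        g = np.zeros((5, 4), dtype=np.int8)
        g[:, 0] = 1  # five singleton hets on one sample
        m = GenotypeMatrix(
            contigs=np.full(5, "c"), positions=np.arange(1, 6), genotypes=g,
            samples=list("abcd"), populations={"A": np.arange(4)},
        )
        w = popgen.tajimas_d_windows(m, "A", window_size=100)
        assert w["tajimas_d"].iloc[0] < 0

    def test_window_tiling_and_coordinates(self):
        m = make_matrix({"A": [0.5] * 6}, samples_per_pop=4, seed=1)
        m.positions = np.array([5, 50, 100, 101, 150, 250])
        w = popgen.tajimas_d_windows(m, "A", window_size=100)
        assert list(w["start"]) == [0, 100, 200]
        assert list(w["end"]) == [100, 200, 300]
        # position 100 (1-based) belongs to the first window [0, 100)
        assert w["n_segregating"].iloc[0] == int(
            ((m.genotypes[:3].sum(axis=1) > 0) & (m.genotypes[:3].sum(axis=1) < 8)).sum()
        )

    def test_bad_window_size(self, small_matrix):
        with pytest.raises(ValueError):
            popgen.tajimas_d_windows(small_matrix, "P1", window_size=0)


# -- heterozygosity ---------------------------------------------------------


class TestHeterozygosity:
    def _matrix(self, genos, depths):
        g = np.array(genos, dtype=np.int8).reshape(-1, 1)
        d = np.array(depths, dtype=np.int32).reshape(-1, 1)
        return GenotypeMatrix(
            contigs=np.full(g.shape[0], "c"), positions=np.arange(1, g.shape[0] + 1),
            genotypes=g, samples=["s"], populations={"A": np.array([0])}, depths=d,
        )

    def test_low_depth_call_dropped(self):
        m = self._matrix([1, 1, 0], [2, 5, 10])
        assert popgen.heterozygosity(m, "A", min_depth=4) == pytest.approx(0.5)

    def test_all_homozygous(self):
        m = self._matrix([0, 2, 0], [9, 9, 9])
        assert popgen.heterozygosity(m, "A") == 0.0

    def test_min_depth_one_equals_unfiltered(self, small_matrix):
        unfiltered = popgen.heterozygosity(small_matrix, None, min_depth=0)
        assert popgen.heterozygosity(small_matrix, None, min_depth=1) == pytest.approx(unfiltered)

    def test_no_surviving_calls_is_nan(self):
        m = self._matrix([1], [1])
        assert np.isnan(popgen.heterozygosity(m, "A", min_depth=4))


# -- f statistics -----------------------------------------------------------


class TestFStatistics:
    def test_jackknife_closed_form_equal_blocks(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=400)
        est, se, nb = popgen.block_jackknife(h, 100)
        assert est == pytest.approx(h.mean(), abs=1e-12)
        loo = np.array([np.delete(h, slice(100 * j, 100 * (j + 1))).mean() for j in range(4)])
        expected_se = np.sqrt(3 / 4 * np.sum((loo - loo.mean()) ** 2))
        assert se == pytest.approx(expected_se, abs=1e-10)
        assert nb == 4

    def test_too_few_blocks(self):
        with pytest.raises(ValueError):
            popgen.block_jackknife(np.ones(150), 100)

    def test_f3_target_identical_to_source_is_zero(self):
        freqs = [0.1, 0.3, 0.5, 0.7, 0.9] * 80
        m = make_matrix({"C": freqs, "A": freqs, "B": list(np.roll(freqs, 1))}, 4, seed=2)
        m.genotypes[:, m.populations["A"]] = m.genotypes[:, m.populations["C"]]
        res = popgen.f3(m, "C", "A", "B", block_size=100)
        assert res.estimate == pytest.approx(0.0, abs=1e-15)

    def test_f3_small_table_matches_hand_computation(self):
        """Five frequencies per population, replicated into two exact
        blocks; (c-a)(c-b) averaged by hand."""
        a = np.array([0.2, 0.4, 0.6, 0.8, 0.5])
        b = np.array([0.3, 0.1, 0.9, 0.6, 0.5])
        c = np.array([0.2, 0.3, 0.7, 0.7, 0.5])
        # genotype doses that realize the frequencies exactly with 5 diploids
        def doses(freq):
            out = []
            for f in freq:
                total = round(f * 10)
                row = [2] * (total // 2) + [1] * (total % 2)
                row += [0] * (5 - len(row))
                out.append(row)
            return out

        rows = {"A": a, "B": b, "C": c}
        g = np.hstack([np.array(doses(rows[k]), dtype=np.int8) for k in ("A", "B", "C")])
        g = np.vstack([g, g])  # two identical blocks of 5 sites
        m = GenotypeMatrix(
            contigs=np.full(10, "c"), positions=np.arange(1, 11), genotypes=g,
            samples=[f"s{i}" for i in range(15)],
            populations={"A": np.arange(5), "B": np.arange(5, 10), "C": np.arange(10, 15)},
        )
        res = popgen.f3(m, "C", "A", "B", block_size=5)
        expected = np.mean((c - a) * (c - b))
        assert res.estimate == pytest.approx(expected, abs=1e-12)
        assert res.se == pytest.approx(0.0, abs=1e-12)  # identical blocks

    def test_f4_antisymmetry_and_degenerate_pair(self):
        matrix, _ = simulate.gen_genotypes(
            simulate.GenotypesConfig(scenario="tree", n_sites=600), seed=3
        )
        r1 = popgen.f4(matrix, "P1", "P2", "P3", "P4")
        r2 = popgen.f4(matrix, "P2", "P1", "P3", "P4")
        assert r1.estimate == pytest.approx(-r2.estimate, abs=1e-15)
        assert r1.se == pytest.approx(r2.se, abs=1e-12)
        # P1 against itself: zero identically
        matrix.populations["P1b"] = matrix.populations["P1"]
        assert popgen.f4(matrix, "P1", "P1b", "P3", "P4").estimate == 0.0

    def test_f3_unadmixed_nonnegative_in_expectation(self):
        mean = np.mean(
            [
                popgen.f3(
                    simulate.gen_genotypes(
                        simulate.GenotypesConfig(scenario="unadmixed", n_sites=400), seed=s
                    )[0],
                    "C", "A", "B",
                ).estimate
                for s in range(60)
            ]
        )
        assert mean > 0

    def test_f3_detects_planted_admixture(self):
        matrix, _ = simulate.gen_genotypes(
            simulate.GenotypesConfig(scenario="admixture", alpha=0.5, drift_size=5), seed=4
        )
        res = popgen.f3(matrix, "C", "A", "B")
        assert res.estimate < 0
        assert res.significant


# -- VCF round trip ---------------------------------------------------------


def test_vcf_round_trip(tmp_path):
    matrix, _ = simulate.gen_genotypes(
        simulate.GenotypesConfig(scenario="tree", n_sites=300), seed=5
    )
    matrix.genotypes[10, 3] = -1
    path = tmp_path / "g.vcf"
    simulate.write_vcf(matrix, str(path))
    popmap = {
        s: pop for pop, idx in matrix.populations.items()
        for s in np.asarray(matrix.samples)[idx]
    }
    back = popgen.GenotypeMatrix.from_vcf(str(path), popmap)
    assert np.array_equal(back.genotypes, matrix.genotypes)
    assert np.array_equal(back.positions, matrix.positions)
    assert np.array_equal(back.depths, matrix.depths)
    assert back.samples == matrix.samples
    for pop in matrix.populations:
        assert np.array_equal(np.sort(back.populations[pop]), matrix.populations[pop])
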