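"""Dry-down bookkeeping, NTR normalization and curve-trait extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cicereco import drydown, simulate
from cicereco.drydown import DryDownSeries


def _series(weights, added=None, treatment="WS", **kw):
    weights = np.asarray(weights, dtype=float)
    added = np.zeros_like(weights) if added is None else np.asarray(added, dtype=float)
    return DryDownSeries(
        pot_id="p1", genotype_id="g1", treatment=treatment,
        days=np.arange(len(weights)), weights=weights, water_added=added, **kw
    )


class TestTranspirationAndFtsw:
    def test_weight_drop_is_transpiration(self):
        t = drydown.daily_transpiration(_series([2000, 1950]))
        assert t["transpiration"].iloc[0] == pytest.approx(50.0)

    def test_water_added_counts(self):
        t = drydown.daily_transpiration(_series([2000, 2000], added=[30, 0]))
        assert t["transpiration"].iloc[0] == pytest.approx(30.0)

    def test_gap_not_bridged(self):
        s = _series([2000, 1950, 1900])
        s.days = np.array([0, 1, 3])
        with pytest.warns(UserWarning, match="gap"):
            t = drydown.daily_transpiration(s)
        assert np.isnan(t["transpiration"].iloc[1])

    def test_ws_threshold_compensation_in_generator(self):
        """The water-stress schedule adds back losses above the daily
        threshold, so recorded net losses never exceed it (noise-free)."""
        cfg = simulate.DryDownConfig(n_genotypes=3, ws_reps=1, ww_reps=1)
        _, pots, _ = simulate.gen_drydown(cfg, seed=0)
        for p in pots:
            if p.treatment != "WS":
                continue
            net = p.weights[:-1] - p.weights[1:]
            assert np.all(net <= max(cfg.ws_threshold_early, cfg.ws_threshold_late) + 1e-9)

    @pytest.mark.parametrize(
        "weight,expected", [(2000.0, 1.0), (1200.0, 0.0), (1600.0, 0.5)]
    )
    def test_ftsw_endpoints_and_midpoint(self, weight, expected):
        s = _series([2000.0, weight], initial_weight=2000.0, final_weight=1200.0)
        assert drydown.ftsw(s)["ftsw"].iloc[1] == pytest.approx(expected)

    def test_degenerate_denominator(self):
        s = _series([2000.0, 2000.0], initial_weight=2000.0, final_weight=2000.0)
        with pytest.raises(ZeroDivisionError):
            drydown.ftsw(s)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 50.0), min_size=3, max_size=12))
    def test_transpiration_conservation(self, additions):
        """Total transpiration equals total weight loss plus total water
        added, exactly, for any addition schedule."""
        rng = np.random.default_rng(1)
        added = np.asarray(additions)
        n = added.size
        weights = 2000.0 - np.cumsum(rng.uniform(0, 40, n)) + np.concatenate([[0], np.cumsum(added[:-1])])
        s = _series(weights, added=added)
        t = drydown.daily_transpiration(s)["transpiration"].to_numpy()
        total = weights[0] - weights[-1] + added[:-1].sum()
        assert t.sum() == pytest.approx(total, abs=1e-9)

    def test_ftsw_non_increasing_during_drydown(self):
        weights = np.linspace(2000, 1300, 15)
        s = _series(weights, initial_weight=2000.0, final_weight=1200.0)
        f = drydown.ftsw(s)["ftsw"].to_numpy()
        assert np.all(np.diff(f) <= 1e-12)


class TestNtr:
    def _pots(self):
        cfg = simulate.DryDownConfig(n_genotypes=2, ws_reps=1, ww_reps=2)
        return simulate.gen_drydown(cfg, seed=3)

    def test_matching_ww_transpiration_gives_unit_ntr(self):
        days = np.arange(8)
        w = 2000.0 - 50.0 * days
        ws = _series(w, treatment="WS", initial_weight=2000.0, final_weight=1000.0)
        ww = DryDownSeries(
            pot_id="p2", genotype_id="g1", treatment="WW",
            days=days, weights=w.copy(), water_added=np.zeros(8),
        )
        table = drydown.ntr_table([ws, ww])
        assert table["ntr"].to_numpy() == pytest.approx(np.ones(7))

    def test_termination_triggered_below_one_tenth(self):
        days = np.arange(4)
        ww = DryDownSeries(
            pot_id="ww", genotype_id="g1", treatment="WW", days=days,
            weights=np.array([2000.0, 1900, 1800, 1700]), water_added=np.zeros(4),
        )
        # WS transpires the WW mean early (FTSW high), then 5% of it
        ws = DryDownSeries(
            pot_id="ws", genotype_id="g1", treatment="WS", days=days,
            weights=np.array([2000.0, 1900.0, 1800.0, 1795.0]),
            water_added=np.zeros(4), initial_weight=2000.0, final_weight=1000.0,
        )
        table = drydown.ntr_table([ws, ww])
        assert table["termination_day"].iloc[0] == 2
        assert bool(table["terminated"].iloc[-1])

    def test_planted_curve_recovered_noise_free(self):
        cfg = simulate.DryDownConfig(n_genotypes=3, ws_reps=1, ww_reps=1)
        _, pots, truth = simulate.gen_drydown(cfg, seed=4)
        table = drydown.ntr_table(pots)
        for genotype, df in table.groupby("genotype"):
            planted = simulate.plateau_curve(
                df["ftsw"].to_numpy(), truth["breakpoints"][genotype], truth["slope"]
            )
            assert df["ntr"].to_numpy() == pytest.approx(planted, abs=1e-9)


class TestCurveTraits:
    def test_noiseless_breakpoint_exact(self):
        f, y = simulate.gen_plateau_points(0.4, 2.5, n_points=30)
        fit = drydown.fit_plateau(f, y)
        assert fit.breakpoint == pytest.approx(0.4, abs=1e-6)
        assert fit.slope == pytest.approx(2.5, rel=1e-6)

    def test_all_plateau_raises(self):
        f = np.linspace(0.3, 1.0, 10)
        with pytest.raises(drydown.NoBreakpointError):
            drydown.fit_plateau(f, np.ones_like(f))

    def test_unconstrained_plateau_level(self):
        f, y = simulate.gen_plateau_points(0.5, 2.0, n_points=30)
        fit = drydown.fit_plateau(f, y * 1.1, constrain_plateau=False, floor=None)
        assert fit.plateau == pytest.approx(1.1, rel=1e-6)
        assert fit.breakpoint == pytest.approx(0.5, abs=1e-6)

    def test_cubic_inflection_exact(self):
        f = np.linspace(0.1, 0.9, 20)
        y = (f - 0.5) ** 3 + 1.0
        assert drydown.inflection_point(f, y) == pytest.approx(0.5, abs=1e-6)

    def test_quadratic_has_no_inflection(self):
        f = np.linspace(0.1, 0.9, 20)
        with pytest.raises(drydown.NoInflectionError):
            drydown.inflection_point(f, 2.0 * f**2 + 1.0)

    def test_inflection_tracks_breakpoint(self):
        """Across noisy genotype curves the polynomial inflection ranks
        genotypes like the planted breakpoint does."""
        rng = np.random.default_rng(0)
        planted, recovered = [], []
        for _ in range(100):
            x = rng.uniform(0.41, 0.60)
            f, y = simulate.gen_plateau_points(
                x, 2.5, n_points=30, noise_sd=0.05, seed=int(rng.integers(2**31))
            )
            try:
                recovered.append(drydown.inflection_point(f, y))
            except drydown.NoInflectionError:
                continue
            planted.append(x)
        rho = stats.spearmanr(planted, recovered).statistic
        assert rho > 0.8

    @pytest.mark.parametrize("x_true", [0.55, 0.6])
    def test_breakpoint_and_inflection_agree_on_steep_curves(self, x_true):
        """When the decline is steep the transition is narrow and the two
        trait definitions coincide to within 0.08 FTSW."""
        f = np.linspace(0.02, 1.0, 80)
        y = simulate.plateau_curve(f, x_true, 12.0)
        bp = drydown.fit_plateau(f, y).breakpoint
        infl = drydown.inflection_point(f, y, breakpoint=bp)
        assert abs(bp - infl) <= 0.08

    def test_parameter_recovery_small_noise(self):
        """Planted (X, s) recovered with small bias at noise SD 0.02."""
        errs = []
        for seed in range(50):
            f, y = simulate.gen_plateau_points(0.5, 2.5, n_points=30, noise_sd=0.02, seed=seed)
            errs.append(drydown.fit_plateau(f, y).breakpoint - 0.5)
        assert abs(np.mean(errs)) < 0.01


class TestTraitVsAridity:
    def test_identity_gives_unit_correlation(self):
        df = pd.DataFrame({"breakpoint": np.linspace(0.4, 0.6, 8)})
        df["aridity"] = df["breakpoint"]
        res = drydown.trait_vs_aridity(df)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["spearman_rho"] == pytest.approx(1.0)

    def test_constant_aridity_rejected(self):
        df = pd.DataFrame({"breakpoint": np.linspace(0.4, 0.6, 8), "aridity": 0.5})
        with pytest.raises(ValueError, match="constant"):
            drydown.trait_vs_aridity(df)

    def test_permutation_null_is_uniform(self):
        """With the trait shuffled against aridity the p-values behave like
        a uniform draw (no spurious association)."""
        rng = np.random.default_rng(2)
        aridity = np.linspace(0.2, 0.8, 20)
        pvals = []
        for _ in range(200):
            df = pd.DataFrame({"breakpoint": rng.permutation(aridity), "aridity": aridity})
            pvals.append(drydown.trait_vs_aridity(df)["pearson_p"])
        # KS against uniform
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_series_from_table_round_trip():
    cfg = simulate.DryDownConfig(n_genotypes=2, ws_reps=1, ww_reps=1)
    weights_df, pots, _ = simulate.gen_drydown(cfg, seed=6)
    rebuilt = {s.pot_id: s for s in drydown.series_from_table(weights_df)}
    for p in pots:
        r = rebuilt[p.pot_id]
        assert r.weights == pytest.approx(p.weights)
        assert r.water_added == pytest.approx(p.water_added)
        assert r.treatment == p.treatment
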