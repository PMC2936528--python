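"""Pattern statistics: efficiencies, ranks, flanks, enrichment, stimulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cpgflank as cf
from cpgflank import patterns
from cpgflank.calling import MethylationCallMatrix, META_COLUMNS
from cpgflank.patterns import Flank


def _matrix_from_calls(calls: np.ndarray, sites=None, strand="top"):
    """Wrap a molecules x sites 0/1/NaN array into a passing call matrix."""
    n_mol, n_sites = calls.shape
    sites = sites if sites is not None else list(range(10, 10 + 3 * n_sites, 3))
    df = pd.DataFrame(
        {
            "molecule_id": [f"m{i}" for i in range(n_mol)],
            "strand": [strand] * n_mol,
            "dcm_class": ["NA"] * n_mol,
            "conversion_efficiency": [1.0] * n_mol,
            "pass_filter": [True] * n_mol,
        }
    )
    for j, s in enumerate(sites):
        df[str(s)] = calls[:, j]
    return MethylationCallMatrix("synthetic", list(sites), df)


def _table(effs, n=100):
    effs = np.asarray(effs, dtype=float)
    return pd.DataFrame(
        {
            "position": np.arange(len(effs)) * 3 + 10,
            "m": np.round(effs * n).astype(int),
            "n": n,
            "efficiency": effs,
        }
    )


class TestSiteEfficiencies:
    def test_counts_and_overall(self):
        calls = np.zeros((20, 2))
        calls[:, 0] = 1.0          # all methylated
        calls[:3, 1] = 1.0         # 3 of 20
        table = cf.site_efficiencies(_matrix_from_calls(calls), n_min=5)
        assert table["efficiency"].tolist() == [1.0, 0.15]
        assert table.attrs["overall"] == pytest.approx((20 + 3) / 40)

    def test_empty_stratum_is_an_error(self):
        matrix = _matrix_from_calls(np.ones((4, 2)))
        with pytest.raises(ValueError, match="strand=bottom"):
            cf.site_efficiencies(matrix, strand="bottom")

    def test_binomial_concentration_against_truth(self):
        """Estimated efficiencies concentrate around the planted per-site
        probabilities at the binomial rate (c=1, no maintenance)."""
        region = cf.generate_reference(400, 0.6, 30, seed=61)
        model = cf.build_preference_model("3A-like", 1.0)
        params = cf.SimulationParams(n_molecules=500, maintenance_efficiency=0.0,
                                     conversion_rate=1.0, seed=62)
        molecules, truth = cf.simulate_molecules(region, model, params)
        matrix = cf.call_clones([(m.fasta_header, m.read) for m in molecules], region)
        table = cf.site_efficiencies(matrix, strand="top")
        p = truth["sites"]["p_top"].to_numpy()
        e = table["efficiency"].to_numpy()
        n = table["n"].to_numpy()
        se = np.sqrt(p * (1 - p) / n)
        assert np.mean(np.abs(e - p) < 3 * se) >= 0.95


class TestRanks:
    @pytest.mark.parametrize("effs,expected", [
        ((0.3, 0.1, 0.2), [1.0, 3.0, 2.0]),
        ((0.3, 0.3, 0.1), [1.5, 1.5, 3.0]),
        ((0.2, 0.2, 0.2), [2.0, 2.0, 2.0]),
    ])
    def test_descending_average_ties(self, effs, expected):
        assert cf.rank_sites(_table(effs))["rank"].tolist() == expected

    def test_rank_sum_invariant(self):
        rng = np.random.default_rng(0)
        effs = rng.random(17)
        ranks = cf.rank_sites(_table(effs))["rank"]
        assert ranks.sum() == 17 * 18 / 2

    def test_relative_efficiencies_average_to_one(self):
        table = patterns.relative_efficiencies(_table([0.1, 0.2, 0.6]))
        assert table["relative_efficiency"].mean() == pytest.approx(1.0)


class TestRankCorrelation:
    def test_identical_and_reversed(self):
        t = _table([0.5, 0.4, 0.3, 0.2])
        assert cf.rank_correlation(t, t) == (pytest.approx(1.0), pytest.approx(1.0))
        rev = _table([0.2, 0.3, 0.4, 0.5])
        r, r2 = cf.rank_correlation(t, rev)
        assert r == pytest.approx(-1.0) and r2 == pytest.approx(1.0)

    def test_hand_pearson_on_ranks(self):
        # ranks A=(1,2,3,4) vs B=(2,1,3,4): r = 0.8, r^2 = 0.64
        a = _table([0.8, 0.6, 0.4, 0.2])
        b = _table([0.6, 0.8, 0.4, 0.2])
        r, r2 = cf.rank_correlation(a, b)
        assert r == pytest.approx(0.8) and r2 == pytest.approx(0.64)

    def test_degenerate_inputs(self):
        with pytest.warns(UserWarning):
            r, r2 = cf.rank_correlation(_table([0.1, 0.2]), _table([0.2, 0.1]))
        assert np.isnan(r)
        with pytest.warns(UserWarning):
            r, _ = cf.rank_correlation(_table([0.1] * 5), _table([0.1] * 5))
        assert np.isnan(r)


class TestFoldRange:
    def test_printed_ratio_pairs(self):
        """The highest/lowest ratios reproduce the printed 11- and 34-fold."""
        res = cf.fold_range(_table([0.285, 0.026], n=1000))
        assert res["fold"] == pytest.approx(10.96, abs=0.01)
        assert res["fold_int"] == 11
        res = cf.fold_range(_table([0.293, 0.0086], n=1000))
        assert res["fold"] == pytest.approx(34.07, abs=0.01)
        assert res["fold_int"] == 34

    def test_uniform_table(self):
        assert cf.fold_range(_table([0.2, 0.2, 0.2]))["fold"] == 1.0

    def test_zero_count_site_uses_haldane(self):
        table = _table([0.2, 0.0], n=50)
        res = cf.fold_range(table)
        assert res["fold"] == pytest.approx(0.2 / (0.5 / 51))


class TestSelectExtremes:
    def test_decile_sizes(self):
        hot, cold = cf.select_extremes(_table(np.linspace(0.9, 0.1, 48)), 0.10)
        assert len(hot) == 5 and len(cold) == 5 and not set(hot) & set(cold)
        hot, cold = cf.select_extremes(_table(np.linspace(0.9, 0.1, 10)), 0.10)
        assert len(hot) == 1 and len(cold) == 1

    def test_small_region_sets_stay_disjoint(self):
        hot, cold = cf.select_extremes(_table([0.5, 0.4, 0.3, 0.2, 0.1]), 0.5)
        assert len(hot) == 3 and len(cold) == 2 and not set(hot) & set(cold)

    def test_fraction_bounds(self):
        for bad in (0.0, 0.6, -0.1):
            with pytest.raises(ValueError):
                cf.select_extremes(_table([0.1, 0.2]), bad)


class TestFlanks:
    def test_extract_both_strands(self):
        region = cf.ReferenceRegion.from_sequence("w", "ATACGTCAAT")
        (top,) = cf.extract_flanks(region, [3], "top", 2)
        (bot,) = cf.extract_flanks(region, [3], "bottom", 2)
        assert top.sequence == "TACGTC" and bot.sequence == "GACGTA"

    def test_edge_sites_are_excluded_with_warning(self):
        region = cf.ReferenceRegion.from_sequence("e", "CGTTTACGTTT")
        with pytest.warns(UserWarning):
            flanks = cf.extract_flanks(region, [0, 6], "top", 2)
        assert [f.site for f in flanks] == [6]

    def test_orientation_flips_minority(self):
        flanks = [Flank(0, "top", "TACGTC")] * 9 + [Flank(1, "top", "GACGTA")]
        oriented, converged = cf.orient_flanks(flanks)
        assert converged
        assert [f.oriented_sequence for f in oriented] == ["TACGTC"] * 10

    def test_palindromes_keep_direct(self):
        flanks = [Flank(i, "top", "ACCGGT") for i in range(4)]
        oriented, converged = cf.orient_flanks(flanks)
        assert converged and all(f.orientation == "direct" for f in oriented)


class TestPositionEnrichment:
    def test_background_match_gives_null(self):
        flanks = ["AACGAA", "CCCGCC", "GGCGGG", "TTCGTT"]
        bg = dict.fromkeys("ACGT", 0.25)
        with pytest.warns(UserWarning):  # small flank set
            enr = cf.position_enrichment(flanks, bg)
        assert (enr["chi2"] == 0).all() and (enr["pvalue"] == 1).all()
        assert np.allclose(enr["ic_bits"], 0.0)

    def test_hand_chi_square_value(self):
        """O=15 of 20 vs q=0.25: X2 = 100/5 + 100/15 = 26.667, p ~ 2.4e-7,
        on the same side of significance as the exact binomial tail."""
        flanks = ["TACGAA"] * 15 + ["AACGAA"] * 5
        enr = cf.position_enrichment(flanks, dict.fromkeys("ACGT", 0.25))
        cell = enr[(enr["offset"] == -2) & (enr["base"] == "T")].iloc[0]
        assert cell["chi2"] == pytest.approx(26.6667, abs=1e-3)
        assert cell["pvalue"] == pytest.approx(2.418e-7, rel=1e-3)
        assert cell["direction"] == "enriched"
        p_exact = stats.binomtest(15, 20, 0.25).pvalue
        assert p_exact < 1e-4 and cell["pvalue"] < p_exact

    def test_perfect_conservation_is_two_bits(self):
        flanks = ["TACGAA"] * 12
        enr = cf.position_enrichment(flanks, dict.fromkeys("ACGT", 0.25))
        assert (enr.groupby("offset")["ic_bits"].first() == 2.0).all()

    def test_zero_background_for_observed_base(self):
        with pytest.raises(ValueError):
            cf.position_enrichment(["TACGAA"] * 6, {"A": 0.5, "C": 0.25, "G": 0.25, "T": 0.0})

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("ACGT"), min_size=6, max_size=30))
    def test_ic_bounds(self, bases):
        """0 <= IC <= 2 bits; 2 iff one base is fixed, 0 iff exactly uniform."""
        flanks = [f"A{b}CGAA" for b in bases]
        enr = cf.position_enrichment(flanks, dict.fromkeys("ACGT", 0.25))
        ic = float(enr[enr["offset"] == -1]["ic_bits"].iloc[0])
        assert 0.0 <= ic <= 2.0
        if len(set(bases)) == 1:
            assert ic == 2.0

    def test_pooled_background_properties(self, sim_bundle):
        bg = cf.pooled_background(sim_bundle["region"], 2)
        assert sum(bg.values()) == pytest.approx(1.0)
        assert bg["A"] == pytest.approx(bg["T"])  # both strands pooled
        assert bg["C"] == pytest.approx(bg["G"])


class TestStimulation:
    def test_identical_tables_fold_one(self):
        t = _table([0.1, 0.2, 0.3])
        with pytest.warns(UserWarning):
            stim = cf.fold_stimulation(t, t)
        assert np.allclose(stim["fold"], 1.0)
        assert np.isnan(stim.attrs["trend_rho"])

    def test_exact_saturation_gives_perfect_negative_trend(self):
        e = np.linspace(0.02, 0.5, 20)
        stim = cf.fold_stimulation(_table(e), _table(1 - (1 - e) ** 5))
        assert stim.attrs["trend_rho"] == pytest.approx(-1.0)
        assert stim.attrs["fold_range_after"] < stim.attrs["fold_range_before"]

    def test_simulated_negative_trend(self):
        """A planted DNMT3L run shows the inverse fold/baseline relation."""
        region = cf.generate_reference(400, 0.6, 30, seed=71)
        model = cf.build_preference_model("3A-like", 1.0)
        base = dict(n_molecules=300, maintenance_efficiency=0.0, conversion_rate=1.0)
        alone, _ = cf.simulate_molecules(
            region, model, cf.SimulationParams(seed=72, **base))
        with3l, _ = cf.simulate_molecules(
            region, model, cf.SimulationParams(seed=73, dnmt3l_exponent=4.0, **base))
        ta = cf.site_efficiencies(
            cf.call_clones([(m.fasta_header, m.read) for m in alone], region),
            strand="top")
        tb = cf.site_efficiencies(
            cf.call_clones([(m.fasta_header, m.read) for m in with3l], region),
            strand="top")
        stim = cf.fold_stimulation(ta, tb)
        assert stim.attrs["trend_rho"] < 0
        assert stim.attrs["trend_pvalue"] < 0.01

    def test_mismatched_sites_rejected(self):
        with pytest.raises(ValueError):
            cf.fold_stimulation(_table([0.1, 0.2]), _table([0.1, 0.2, 0.3]))


class TestGroupStimulationTest:
    def test_identical_groups(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        res = cf.group_stimulation_test(a, a)
        assert res["pvalue"] == pytest.approx(0.5)
        assert res["stars"] == "ns"

    def test_strong_stimulation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.05, 0.05, 30)
        b = rng.normal(0.15, 0.05, 30)
        res = cf.group_stimulation_test(a, b)
        assert res["pvalue"] < 0.001 and res["stars"] == "***"

    @pytest.mark.parametrize("p,stars", [
        (0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, "ns"),
    ])
    def test_star_categories(self, p, stars):
        assert patterns.significance_stars(p) == stars

    def test_degenerate_variance(self):
        with pytest.warns(UserWarning):
            res = cf.group_stimulation_test(np.full(5, 0.1), np.full(5, 0.1))
        assert np.isnan(res["pvalue"])


class TestStrandSymmetry:
    def test_identical_tables(self):
        t = _table([0.1, 0.3, 0.2, 0.4])
        assert cf.strand_symmetry(t, t)["r"] == pytest.approx(1.0)

    def test_maintained_simulation_is_symmetric(self, sim_bundle):
        top = cf.site_efficiencies(sim_bundle["matrix"], strand="top")
        bot = cf.site_efficiencies(sim_bundle["matrix"], strand="bottom")
        assert cf.strand_symmetry(top, bot)["r"] > 0.8

    def test_independent_strands_uncorrelated(self):
        """With mu=0 and per-strand de novo draws the two strands are
        independent; over ~160 sites the null correlation SE is ~0.08, so
        |r| < 0.2 is a 2.5-sigma check."""
        region = cf.generate_reference(1600, 0.65, 140, seed=81)
        model = cf.build_preference_model("null", 0.0)
        params = cf.SimulationParams(n_molecules=300, maintenance_efficiency=0.0,
                                     conversion_rate=1.0, seed=82)
        mols, _ = cf.simulate_molecules(region, model, params)
        matrix = cf.call_clones([(m.fasta_header, m.read) for m in mols], region)
        top = cf.site_efficiencies(matrix, strand="top")
        bot = cf.site_efficiencies(matrix, strand="bottom")
        assert abs(cf.strand_symmetry(top, bot)["r"]) < 0.2
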