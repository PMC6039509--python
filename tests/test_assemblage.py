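import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from riveredna.assemblage import (
    CatchTable,
    abundance_bias_test,
    cumulative_richness_test,
    diversity,
    pair_sites,
    richness_comparison,
    richness_trend,
    spearman_site_correlation,
    trend_free_sites,
)


class TestDiversity:
    def test_uniform_assemblage_is_maximum_entropy(self):
        d = diversity([0.25, 0.25, 0.25, 0.25])
        assert d.richness == 4
        assert d.shannon == pytest.approx(math.log(4), rel=1e-12)
        assert d.evenness == pytest.approx(1.0, rel=1e-12)

    def test_single_species(self):
        d = diversity([1.0])
        assert d.shannon == 0.0
        assert math.isnan(d.evenness)

    def test_direct_summation_oracle(self):
        p = [0.5, 0.3, 0.2]
        expected = -sum(x * math.log(x) for x in p)  # 1.02965...
        d = diversity(p)
        assert d.shannon == pytest.approx(expected, rel=1e-12)
        assert d.shannon == pytest.approx(1.0297, abs=1e-4)

    def test_permutation_invariance(self, rng):
        p = rng.dirichlet(np.ones(8))
        d1 = diversity(p)
        d2 = diversity(rng.permutation(p))
        assert d1.shannon == pytest.approx(d2.shannon, rel=1e-12)

    def test_evenness_one_iff_uniform(self, rng):
        nonuniform = diversity([0.7, 0.2, 0.1])
        assert nonuniform.evenness < 1.0
        uniform = diversity([1 / 3] * 3)
        assert uniform.evenness == pytest.approx(1.0, rel=1e-12)

    def test_all_zero_vector_raises(self):
        with pytest.raises(ValueError):
            diversity([0.0, 0.0])


class TestPairSites:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["site", "section", "reach_type", "km"])

    def test_least_distant_pair_wins(self):
        edna = self._frame([("E1", "A", "MC", 100.0)])
        tef = self._frame(
            [("T1", "A", "MC", 105.0), ("T2", "A", "MC", 102.0), ("T3", "A", "MC", 109.0)]
        )
        pairs = pair_sites(edna, tef)
        assert len(pairs) == 1
        assert pairs.iloc[0]["tef_site"] == "T2"
        assert pairs.iloc[0]["distance_km"] == pytest.approx(2.0)

    def test_single_candidate_returned(self):
        edna = self._frame([("E1", "A", "BPS", 50.0)])
        tef = self._frame([("T1", "A", "BPS", 53.0)])
        pairs = pair_sites(edna, tef)
        assert pairs.iloc[0].tolist()[:3] == ["A", "E1", "T1"]

    def test_reach_type_mismatch_skips_section(self):
        edna = self._frame([("E1", "A", "MC", 50.0)])
        tef = self._frame([("T1", "A", "BPS", 50.0)])
        assert len(pair_sites(edna, tef)) == 0

    def test_minimality_by_exhaustive_search(self, rng):
        rows_e = [(f"E{i}", "A", "MC", float(rng.uniform(0, 100))) for i in range(5)]
        rows_t = [(f"T{i}", "A", "MC", float(rng.uniform(0, 100))) for i in range(5)]
        pairs = pair_sites(self._frame(rows_e), self._frame(rows_t))
        best = min(abs(e[3] - t[3]) for e in rows_e for t in rows_t)
        assert pairs.iloc[0]["distance_km"] == pytest.approx(best)


class TestRichnessComparison:
    def test_identical_annual_values_give_p_one(self):
        per_loc, _ = richness_comparison({"L1": [20] * 10}, {"L1": 20})
        assert per_loc.iloc[0]["p_lower"] == 1.0

    def test_strictly_lower_annual_richness_highly_significant(self):
        # 10 annual values all below the eDNA value: exact one-sided
        # signed-rank p = 2**-10 < 0.001
        per_loc, _ = richness_comparison({"L1": [12, 14, 13, 15, 11, 16, 12, 13, 14, 15]}, {"L1": 28})
        assert per_loc.iloc[0]["p_lower"] == pytest.approx(2**-10, rel=1e-6)
        assert per_loc.iloc[0]["p_lower"] < 0.001

    def test_equal_cumulative_richness_not_significant(self):
        cum = {f"L{i}": 25 for i in range(8)}
        edna = {f"L{i}": 25 for i in range(8)}
        stat, p = cumulative_richness_test(cum, edna)
        assert p == 1.0

    def test_cross_location_test_needs_six_locations(self):
        with pytest.raises(ValueError):
            cumulative_richness_test({"L1": 20}, {"L1": 21})

    def test_short_series_excluded(self, caplog):
        per_loc, _ = richness_comparison({"L1": [20]}, {"L1": 25})
        assert len(per_loc) == 0


class TestAbundanceBias:
    @staticmethod
    def _tables(n_loc=16, n_sp=5, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"L{i}" for i in range(n_loc)]
        cols = [f"sp{j}" for j in range(n_sp)]
        base = rng.dirichlet(np.ones(n_sp), size=n_loc)
        return (
            pd.DataFrame(base, index=idx, columns=cols),
            pd.DataFrame(base.copy(), index=idx, columns=cols),
        )

    def test_equal_proportions_flag_nothing(self):
        e, c = self._tables()
        out = abundance_bias_test(e, c)
        assert not out["significant"].any()

    def test_planted_unidirectional_bias_flagged(self):
        e, c = self._tables()
        e["sp0"] = c["sp0"] + 0.01  # eDNA higher at all 16 locations
        out = abundance_bias_test(e, c).set_index("species")
        assert out.loc["sp0", "p"] == pytest.approx(2 * 0.5**16, rel=1e-9)
        assert out.loc["sp0", "significant"]
        assert out.loc["sp0", "direction"] == "edna"

    def test_sign_test_matches_exact_binomial(self):
        # planted k-of-n splits must reproduce the two-sided binomial p
        e, c = self._tables(n_loc=12)
        e["sp1"] = c["sp1"].copy()
        e.loc[e.index[:9], "sp1"] += 0.01
        e.loc[e.index[9:], "sp1"] -= 0.01
        out = abundance_bias_test(e, c).set_index("species")
        assert out.loc["sp1", "p"] == pytest.approx(
            sps.binomtest(9, 12, 0.5).pvalue, rel=1e-12
        )

    def test_rare_species_not_tested(self):
        e, c = self._tables(n_loc=16)
        e["rare"] = 0.0
        c["rare"] = 0.0
        e.loc[e.index[:3], "rare"] = 0.01
        out = abundance_bias_test(e, c)
        assert "rare" not in set(out["species"])


class TestSpearman:
    def test_concordant_ranks(self):
        e = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"))
        c = pd.Series([2, 4, 6, 8, 10, 12], index=list("abcdef"))
        rho, p = spearman_site_correlation(e, c)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        e = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"))
        c = pd.Series([6, 5, 4, 3, 2, 1], index=list("abcdef"))
        rho, _ = spearman_site_correlation(e, c)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        e = pd.Series(rng.integers(1, 500, size=6) + 0.0, index=list("abcdef"))
        c = pd.Series(rng.integers(1, 500, size=6) + 0.0, index=list("abcdef"))
        rho, _ = spearman_site_correlation(e, c)
        oracle = np.corrcoef(sps.rankdata(e), sps.rankdata(c))[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-10)

    def test_species_absent_from_both_excluded(self):
        e = pd.Series([0, 1, 2, 3, 4, 5], index=list("abcdef"))
        c = pd.Series([0, 2, 1, 4, 3, 6], index=list("abcdef"))
        rho_with, _ = spearman_site_correlation(e, c)
        rho_without, _ = spearman_site_correlation(e.drop("a"), c.drop("a"))
        assert rho_with == pytest.approx(rho_without)

    def test_too_few_species_raises(self):
        e = pd.Series([1, 2, 3], index=list("abc"))
        with pytest.raises(ValueError):
            spearman_site_correlation(e, e)

    def test_constant_vector_reports_missing(self):
        e = pd.Series([3, 3, 3, 3, 3], index=list("abcde"))
        c = pd.Series([1, 2, 3, 4, 5], index=list("abcde"))
        rho, p = spearman_site_correlation(e, c)
        assert math.isnan(rho) and math.isnan(p)


class TestRichnessTrend:
    def test_constant_series_has_no_trend(self):
        slope, p = richness_trend(range(2006, 2016), [18] * 10)
        assert slope == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_increasing_series_detected(self):
        years = list(range(2006, 2016))
        richness = [10, 12, 14, 16, 18, 20, 22, 24, 26, 28]
        slope, p = richness_trend(years, richness)
        assert slope > 0
        assert p < 0.01

    def test_trend_free_subset_returned(self):
        flat = pd.Series([15] * 10, index=range(2006, 2016))
        rising = pd.Series(range(10, 30, 2), index=range(2006, 2016))
        keep = trend_free_sites({"flat": flat, "rising": rising})
        assert keep == ["flat"]

    def test_needs_five_annual_values(self):
        with pytest.raises(ValueError):
            richness_trend([1, 2, 3], [4, 5, 6])


class TestCatchTable:
    @staticmethod
    def _table():
        catches = pd.DataFrame(
            {
                "site": ["A"] * 4 + ["A"] * 2,
                "year": [2006, 2006, 2007, 2007, 2008, 2008],
                "species": ["x", "y", "x", "z", "x", "y"],
                "count": [10, 5, 8, 2, 12, 6],
            }
        )
        effort = pd.DataFrame(
            {"site": ["A"] * 3, "year": [2006, 2007, 2008], "effort": [2.0, 2.0, 4.0]}
        )
        return CatchTable(catches=catches, effort=effort)

    def test_annual_and_cumulative_richness(self):
        t = self._table()
        assert t.annual_richness("A").tolist() == [2, 2, 2]
        assert t.cumulative_richness("A") == 3

    def test_mean_cpue_aggregation_order(self):
        # per-year CPUE first, then mean across years
        t = self._table()
        cpue = t.mean_cpue("A")
        assert cpue["x"] == pytest.approx((10 / 2 + 8 / 2 + 12 / 4) / 3)
        assert cpue["z"] == pytest.approx((0 + 2 / 2 + 0) / 3)

    def test_proportions_sum_to_one(self):
        p = self._table().proportions("A")
        assert p.sum() == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        catches = pd.DataFrame(
            {"site": ["A"], "year": [2006], "species": ["x"], "count": [-1]}
        )
        effort = pd.DataFrame({"site": ["A"], "year": [2006], "effort": [1.0]})
        with pytest.raises(ValueError):
            CatchTable(catches=catches, effort=effort)
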