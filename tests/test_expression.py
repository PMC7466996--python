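"""Expression statistics: normalization, E_g, delta, enrichment, GFP trend."""

import dataclasses
import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import burdenlab.expression as ex
import burdenlab.synth as synth


def _matrix(rows: dict, samples) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


class TestNormalizeLog2:
    def test_constant_row_maps_to_zero(self):
        m = _matrix({"g1": [5.0, 5.0, 5.0]}, ["a", "b", "c"])
        assert np.allclose(ex.normalize_log2(m), 0.0)

    def test_hand_arithmetic(self):
        # row (1,2,4): mean 7/3, normalized log2 values log2(3/7), log2(6/7),
        # log2(12/7)
        m = _matrix({"g1": [1.0, 2.0, 4.0]}, ["a", "b", "c"])
        out = ex.normalize_log2(m)
        assert np.allclose(out.loc["g1"],
                           np.log2([3 / 7, 6 / 7, 12 / 7]))

    def test_conditions_normalized_independently(self):
        m = _matrix({"g1": [1.0, 3.0, 10.0, 30.0]}, list("abcd"))
        cond = ["x", "x", "y", "y"]
        out = ex.normalize_log2(m, conditions=cond)
        back = 2.0 ** out
        assert back[["a", "b"]].mean(axis=1).iloc[0] == pytest.approx(1.0)
        assert back[["c", "d"]].mean(axis=1).iloc[0] == pytest.approx(1.0)

    def test_nonpositive_entry_names_gene(self):
        m = _matrix({"gBAD": [1.0, 0.0]}, ["a", "b"])
        with pytest.raises(ValueError, match="gBAD"):
            ex.normalize_log2(m)


class TestGrowthResponse:
    def _strains(self, growth):
        return pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(growth))],
                             "relative_growth_rate": growth})

    def test_exact_slope_recovery(self):
        growth = [1.0, 0.9, 0.8, 0.7]
        log2 = _matrix({"g1": [0.5 * g + 1 for g in growth],
                        "g2": [2.0] * 4}, [f"s{i}" for i in range(4)])
        prof = ex.growth_response(log2, self._strains(growth))
        assert prof.loc["g1", "E_g"] == pytest.approx(0.5)
        assert prof.loc["g2", "E_g"] == pytest.approx(0.0)

    def test_offset_invariance(self):
        growth = [1.0, 0.85, 0.7]
        samples = [f"s{i}" for i in range(3)]
        log2 = _matrix({"g1": [0.3, 0.1, -0.2]}, samples)
        shifted = log2 + 5.0
        a = ex.growth_response(log2, self._strains(growth))
        b = ex.growth_response(shifted, self._strains(growth))
        assert a.loc["g1", "E_g"] == pytest.approx(b.loc["g1", "E_g"])

    def test_sparse_gene_omitted(self):
        growth = [1.0, 0.9, 0.8, 0.7]
        samples = [f"s{i}" for i in range(4)]
        log2 = _matrix({"g1": [1, 2, 3, 4],
                        "g2": [1, np.nan, np.nan, 4]}, samples)
        prof = ex.growth_response(log2, self._strains(growth))
        assert "g2" not in prof.index and "g1" in prof.index


class TestSignatureCorrelation:
    def test_self_and_negation(self):
        p = pd.Series([1.0, -2.0, 0.5, 3.0], index=list("abcd"))
        assert ex.signature_correlation(p, p)[0] == pytest.approx(1.0)
        assert ex.signature_correlation(p, -p)[0] == pytest.approx(-1.0)

    def test_matches_brute_force_covariance(self):
        # hand-computable 5-gene instance
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 10.0], index=list("abcde"))
        b = pd.Series([2.0, 1.0, 5.0, 3.0, 8.0], index=list("abcde"))
        ac, bc = a - a.mean(), b - b.mean()
        brute = float((ac * bc).sum() /
                      np.sqrt((ac ** 2).sum() * (bc ** 2).sum()))
        r, n = ex.signature_correlation(a, b)
        assert n == 5 and r == pytest.approx(brute)

    def test_insufficient_overlap_rejected(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        with pytest.raises(ValueError):
            ex.signature_correlation(a, a)


class TestBurdenGrowthPlane:
    def test_mutant_identical_to_burden_profile(self, compendium):
        profile = compendium.signatures.iloc[:, 0]
        sigs = pd.DataFrame({"self": profile})
        plane = ex.burden_growth_plane(sigs, profile, compendium.growth_program)
        assert plane.loc["self", "r_burden"] == pytest.approx(1.0)

    def test_classes_separate_along_r_burden(self, catalog, small_config,
                                             compendium):
        expr, strains = synth.gen_burden_library(catalog, small_config)
        prof = ex.growth_response(ex.normalize_log2(expr), strains)
        plane = ex.burden_growth_plane(compendium.signatures, prof["E_g"],
                                       compendium.growth_program)
        merged = plane.join(compendium.mutants.set_index("mutant_id"))
        cap = merged.query("truth_class == 'capacity'")
        rest = merged.query("truth_class != 'capacity'")
        assert cap["r_burden"].min() > rest["r_burden"].max()
        # slow-growth mutants dominate the growth axis instead
        slow = merged.query("truth_class == 'slow_growth'")
        assert slow["r_growth"].min() > cap["r_growth"].max()

    def test_null_mutants_near_origin(self, compendium):
        nulls = compendium.mutants.query("truth_class == 'null'")["mutant_id"]
        capacity_like = compendium.signatures.iloc[:, 0]
        plane = ex.burden_growth_plane(compendium.signatures[nulls],
                                       capacity_like,
                                       compendium.growth_program)
        assert plane["r_burden"].abs().max() < 0.2
        assert plane["r_growth"].abs().max() < 0.2


class TestExpressionBias:
    def test_uniform_change_has_no_bias(self):
        abund = pd.Series(np.geomspace(0.1, 100, 50))
        change = pd.Series(0.7, index=abund.index)
        res = ex.expression_bias(change, abund)
        assert res.loc["all", "delta"] == pytest.approx(0.0, abs=1e-12)

    def test_burden_library_bias_negative_and_tata_accentuated(
            self, catalog, small_config):
        expr, _ = synth.gen_burden_library(catalog, small_config)
        change = ex.relative_change_vs_wt(expr, "copy00", "copy20")
        tata = catalog.set_index("gene_id")["is_tata"]
        abund = synth.wt_abundance(catalog, small_config)
        res = ex.expression_bias(change, abund, tata)
        assert res.loc["all", "delta"] < -3 * res.loc["all", "sem"]
        assert res.loc["TATA", "delta"] < res.loc["non-TATA", "delta"]

    def test_no_dead_time_no_bias(self, catalog, small_config):
        cfg = dataclasses.replace(small_config, dead_time_s=0.0)
        expr, _ = synth.gen_burden_library(catalog, cfg)
        change = ex.relative_change_vs_wt(expr, "copy00", "copy20")
        res = ex.expression_bias(change, synth.wt_abundance(catalog, cfg))
        assert abs(res.loc["all", "delta"]) < 3 * res.loc["all", "sem"]

    def test_abundance_rescaling_only_moves_intercept(self):
        rng = np.random.default_rng(0)
        abund = pd.Series(np.geomspace(0.1, 100, 40))
        change = pd.Series(-0.2 * np.log10(abund) + rng.normal(0, .05, 40),
                           index=abund.index)
        d1 = ex.expression_bias(change, abund).loc["all", "delta"]
        d2 = ex.expression_bias(change, abund * 2).loc["all", "delta"]
        assert d1 == pytest.approx(d2)


class TestPerMutantBias:
    def test_signs_by_mutant_class(self, catalog, small_config, compendium):
        expr, _ = synth.gen_burden_library(catalog, small_config)
        wt = expr["copy00"]
        growth = compendium.mutants.set_index("mutant_id")[
            "relative_growth_rate"]
        res = ex.per_mutant_bias(compendium.signatures, wt, growth)
        merged = res.join(compendium.mutants.set_index("mutant_id"),
                          rsuffix="_truth")
        cap = merged.query("truth_class == 'capacity'")
        null = merged.query("truth_class == 'null'")
        slow = merged.query("truth_class == 'slow_growth'")
        # losing capacity spares the saturated (abundant) genes: delta > 0
        assert (cap["delta"] > 3 * cap["sem"]).all()
        assert (null["delta"].abs() < 3 * null["sem"]).all()
        # slow growth alone does not produce an abundance-dependent bias
        assert slow["delta"].abs().mean() < cap["delta"].mean() / 5


class TestTopBottomSets:
    def _profile(self, eg_by_gene):
        return pd.DataFrame({"E_g": pd.Series(eg_by_gene)}).rename_axis(
            "gene_id")

    def test_three_gene_example(self):
        top, bottom = ex.top_bottom_sets(
            self._profile({"a": -1.0, "b": 0.0, "c": 2.0}), 1)
        assert top == ["c"] and bottom == ["a"]

    def test_disjoint_and_sized(self):
        rng = np.random.default_rng(1)
        prof = self._profile({f"g{i}": v for i, v in
                              enumerate(rng.normal(size=100))})
        top, bottom = ex.top_bottom_sets(prof, 30)
        assert len(top) == len(bottom) == 30
        assert not set(top) & set(bottom)

    def test_ties_break_lexicographically(self):
        top, bottom = ex.top_bottom_sets(
            self._profile({"b": 1.0, "a": 1.0, "c": -1.0, "d": -1.0}), 1)
        assert top == ["a"] and bottom == ["c"]

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            ex.top_bottom_sets(self._profile({"a": 1.0, "b": 2.0}), 2)


class TestEnrichment:
    def test_complete_overlap_small_universe(self):
        # universe 10, group 5, query 5, overlap 5: p = 1/C(10,5) = 1/252
        universe = set(range(10))
        res = ex.enrichment(set(range(5)), {"grp": set(range(5))}, universe)
        assert res.loc["grp", "p"] == pytest.approx(1 / 252)

    def test_query_equals_universe(self):
        universe = set(range(8))
        res = ex.enrichment(universe, {"grp": set(range(3))}, universe)
        assert res.loc["grp", "overlap"] == 3
        assert res.loc["grp", "p"] == pytest.approx(1.0)

    def test_zero_overlap_is_certain(self):
        res = ex.enrichment({0}, {"grp": {5}}, set(range(6)))
        # k = 0: the tail P(X >= 0) is 1 regardless of the group
        assert res.loc["grp", "p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("m_size", [5, 8, 10])
    def test_matches_exhaustive_enumeration(self, m_size):
        # independent oracle: enumerate every possible query draw
        universe = list(range(m_size))
        group = set(range(m_size // 2))
        for n in (1, m_size // 2, m_size - 1):
            query = set(universe[-n:])
            k = len(query & group)
            total = hits = 0
            for draw in itertools.combinations(universe, n):
                total += 1
                hits += len(set(draw) & group) >= k
            expected = Fraction(hits, total)
            res = ex.enrichment(query, {"grp": group}, set(universe))
            assert res.loc["grp", "p"] == pytest.approx(float(expected),
                                                        rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ex.enrichment(set(), {"grp": set()}, set())


class TestGfpRatioTrend:
    def _series(self, values):
        return pd.Series(values, index=[f"p{i}" for i in range(len(values))])

    def test_identical_libraries_show_no_increase(self):
        low = self._series(np.geomspace(300, 3000, 20))
        abund = self._series(np.geomspace(1, 100, 20))
        res = ex.gfp_ratio_trend(low, low, abund)
        assert res.mean_increase_pct == pytest.approx(0.0)
        assert np.allclose(res.table["ratio"], 1.0)

    def test_uniform_fifteen_percent_increase(self):
        low = self._series(np.geomspace(300, 3000, 20))
        abund = self._series(np.geomspace(1, 100, 20))
        res = ex.gfp_ratio_trend(1.15 * low, low, abund)
        assert res.mean_increase_pct == pytest.approx(15.0)

    def test_autofluorescent_proteins_excluded(self):
        low = self._series([150.0, 500.0, 900.0])
        high = 2.0 * low
        abund = self._series([1.0, 10.0, 100.0])
        res = ex.gfp_ratio_trend(high, low, abund,
                                 autofluorescence_threshold=200.0)
        assert not res.table.loc["p0", "informative"]
        assert res.n_informative == 2

    def test_all_dim_proteins_rejected(self):
        low = self._series([50.0, 80.0])
        with pytest.raises(ValueError):
            ex.gfp_ratio_trend(low, low, self._series([1.0, 2.0]))
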