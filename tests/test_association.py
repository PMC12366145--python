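"""Severity classes, Fisher association, gene discovery, set enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from famdev.association import (ThresholdConfig, classify_intellectual_functioning,
                                classify_srs_severity, compare_discovery,
                                discover_severe_genes, expressivity_profile,
                                fisher_association, flag_better_than_expected,
                                flag_severe, geneset_overlap)


class TestSrsSeverity:
    @pytest.mark.parametrize("score,expected", [
        (50.0, "normative"), (59.0, "normative"), (60.0, "mild_moderate"),
        (75.0, "mild_moderate"), (76.0, "severe"), (90.0, "severe")])
    def test_band_boundaries(self, score, expected):
        assert classify_srs_severity(score) == expected


class TestIntellectualFunctioning:
    def test_fsiq_decides_even_when_nviq_disagrees(self):
        assert classify_intellectual_functioning(69.0, 120.0, None) == ("ID", "FSIQ")

    def test_nviq_fallback(self):
        assert classify_intellectual_functioning(None, 100.0, None) == \
            ("higher_than_average", "NVIQ")

    def test_vabs_fallback(self):
        assert classify_intellectual_functioning(None, None, 65.0) == \
            ("ID", "VABS_total")

    def test_all_missing_unclassifiable(self):
        assert classify_intellectual_functioning(None, None, None) == \
            ("unclassifiable", "none")

    def test_middle_band(self):
        assert classify_intellectual_functioning(85.0, None, None) == \
            ("neither", "FSIQ")


class TestSevereFlags:
    def test_raw_threshold_inclusive(self):
        assert flag_severe(76.0, "raw")
        assert not flag_severe(75.9, "raw")

    def test_wfsd_threshold_inclusive(self):
        assert flag_severe(2.6, "wfsd")
        assert not flag_severe(2.59, "wfsd")

    def test_better_than_expected(self):
        assert flag_better_than_expected(1.99)
        assert not flag_better_than_expected(2.0)

    def test_threshold_equivalence_arithmetic(self):
        cfg = ThresholdConfig()
        assert cfg.check_consistency(population_mean=50.0, population_sd=10.0)


class TestFisher:
    def test_balanced_table_odds_ratio_one(self):
        severe = [True] * 20 + [False] * 20
        carrier = ([True] * 10 + [False] * 10) * 2
        res = fisher_association(severe, carrier)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_cross_product_odds_ratio(self):
        # table [[20, 5], [10, 10]] -> OR (20*10)/(5*10) = 4
        severe = [True] * 25 + [False] * 20
        carrier = [True] * 20 + [False] * 5 + [True] * 10 + [False] * 10
        res = fisher_association(severe, carrier)
        assert res.odds_ratio == pytest.approx(4.0)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_p_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 25, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            severe = [True] * (a + b) + [False] * (c + d)
            carrier = [True] * a + [False] * b + [True] * c + [False] * d
            res = fisher_association(severe, carrier)
            # two-sided Fisher p by direct enumeration of the hypergeometric
            n, K, N = a + b + c + d, a + c, a + b
            rv = hypergeom(n, K, N)
            support = np.arange(max(0, N + K - n), min(K, N) + 1)
            probs = rv.pmf(support)
            p_oracle = probs[probs <= rv.pmf(a) * (1 + 1e-9)].sum()
            assert res.p_value == pytest.approx(p_oracle, abs=1e-9)

    def test_transposed_table_reciprocal_odds(self):
        severe = [True] * 25 + [False] * 20
        carrier = [True] * 20 + [False] * 5 + [True] * 10 + [False] * 10
        res = fisher_association(severe, carrier)
        swapped = fisher_association(carrier, severe)
        # swapping the roles transposes the table; OR is unchanged,
        # inverting one flag inverts the OR
        assert swapped.odds_ratio == pytest.approx(res.odds_ratio)
        inverted = fisher_association(severe, [not c for c in carrier])
        assert inverted.odds_ratio == pytest.approx(1.0 / res.odds_ratio)

    def test_zero_cell_uses_haldane(self):
        severe = [True] * 5 + [False] * 10
        carrier = [True] * 5 + [False] * 10
        res = fisher_association(severe, carrier)
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1


class TestGeneDiscovery:
    def test_definition_specific_gene(self):
        # gene G carried by probands severe under wfsd but not raw
        genes = pd.DataFrame({"individual_id": ["p1", "p2"], "gene": ["G", "G"]})
        wfsd_severe = pd.Series({"p1": True, "p2": True})
        raw_severe = pd.Series({"p1": False, "p2": False})
        d_w = discover_severe_genes(genes, wfsd_severe, "wfsd")
        d_r = discover_severe_genes(genes, raw_severe, "raw")
        compare_discovery(d_w, d_r)
        assert d_w.genes == {"G": 2}
        assert d_w.unique_to_this == {"G"}
        assert d_r.genes == {}

    def test_non_severe_carriers_do_not_contribute(self):
        genes = pd.DataFrame({"individual_id": ["p1"], "gene": ["G"]})
        severe = pd.Series({"p1": False})
        assert discover_severe_genes(genes, severe).genes == {}

    def test_partition_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(23)
        gene_pool = [f"G{i}" for i in range(50)]
        rows = [(f"p{i}", rng.choice(gene_pool)) for i in range(200)]
        genes = pd.DataFrame(rows, columns=["individual_id", "gene"])
        ids = [f"p{i}" for i in range(200)]
        sev_a = pd.Series(rng.random(200) < 0.4, index=ids)
        sev_b = pd.Series(rng.random(200) < 0.4, index=ids)
        d_a = discover_severe_genes(genes, sev_a, "wfsd")
        d_b = discover_severe_genes(genes, sev_b, "raw")
        compare_discovery(d_a, d_b)
        ga, gb = set(d_a.genes), set(d_b.genes)
        assert d_a.unique_to_this == ga - gb
        assert d_b.unique_to_this == gb - ga
        assert d_a.shared == ga & gb
        assert (d_a.unique_to_this | d_b.unique_to_this | d_a.shared) == ga | gb

    def test_min_carriers_monotone(self):
        rng = np.random.default_rng(29)
        rows = [(f"p{i}", f"G{rng.integers(10)}") for i in range(100)]
        genes = pd.DataFrame(rows, columns=["individual_id", "gene"])
        severe = pd.Series(True, index=[f"p{i}" for i in range(100)])
        prev = None
        for k in (1, 2, 3, 5):
            cur = set(discover_severe_genes(genes, severe, min_carriers=k).genes)
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestExpressivity:
    def test_small_profile(self):
        df = pd.DataFrame({
            "id_class": ["ID", "ID", "higher_than_average", "neither"],
            "srs_class": ["severe", "severe", "normative", "mild_moderate"]})
        out = expressivity_profile(df).set_index(["axis", "class"])
        assert out.loc[("intellectual", "ID"), "proportion"] == 0.5
        assert out.loc[("intellectual", "higher_than_average"), "proportion"] == 0.25

    def test_all_unclassifiable_is_empty_for_id_axis(self):
        df = pd.DataFrame({"id_class": ["unclassifiable"] * 3,
                           "srs_class": [None] * 3})
        out = expressivity_profile(df)
        assert out.empty

    def test_planted_frequencies_recovered(self):
        rng = np.random.default_rng(31)
        n = 1000
        id_class = rng.choice(["ID", "higher_than_average", "neither"], n,
                              p=[0.45, 0.1, 0.45])
        srs = rng.choice(["normative", "mild_moderate", "severe"], n,
                         p=[0.1, 0.25, 0.65])
        out = expressivity_profile(pd.DataFrame({"id_class": id_class,
                                                 "srs_class": srs}))
        got = out.set_index(["axis", "class"])["proportion"]
        assert got[("intellectual", "ID")] == pytest.approx(0.45, abs=0.03)
        assert got[("srs_severity", "severe")] == pytest.approx(0.65, abs=0.03)


class TestGeneSetOverlap:
    def test_disjoint_sets(self):
        universe = {f"G{i}" for i in range(100)}
        res = geneset_overlap({"G1", "G2"}, {"t": {"G50", "G51"}}, universe)[0]
        assert res.overlap == 0
        assert res.log_odds_ratio <= 0
        assert res.p_value == pytest.approx(1.0)

    def test_identical_sets_minimal_p(self):
        universe = {f"G{i}" for i in range(100)}
        q = {f"G{i}" for i in range(10)}
        res = geneset_overlap(q, {"t": set(q)}, universe)[0]
        assert res.overlap == 10
        assert res.p_value == pytest.approx(
            hypergeom(100, 10, 10).pmf(10), rel=1e-9)

    def test_p_matches_hypergeometric_tail(self):
        rng = np.random.default_rng(37)
        universe = {f"G{i}" for i in range(200)}
        ulist = sorted(universe)
        for _ in range(20):
            q = set(rng.choice(ulist, rng.integers(5, 40), replace=False))
            t = set(rng.choice(ulist, rng.integers(5, 40), replace=False))
            res = geneset_overlap(q, {"t": t}, universe)[0]
            k = len(q & t)
            oracle = hypergeom(200, len(t), len(q)).sf(k - 1)
            assert res.p_value == pytest.approx(oracle, rel=1e-8)

    def test_bh_fdr_never_below_p_and_call_counts_monotone(self):
        rng = np.random.default_rng(41)
        universe = {f"G{i}" for i in range(200)}
        ulist = sorted(universe)
        targets = {f"t{j}": set(rng.choice(ulist, 30, replace=False))
                   for j in range(15)}
        q = set(rng.choice(ulist, 30, replace=False))
        res = geneset_overlap(q, targets, universe)
        for r in res:
            assert r.fdr >= r.p_value - 1e-12
        alpha = 0.05
        assert sum(r.fdr < alpha for r in res) <= sum(r.p_value < alpha for r in res)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            geneset_overlap({"G1"}, {"t": {"G1"}}, set())
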