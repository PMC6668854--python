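"""Stratified CMH statistics, max-statistic permutation, segregation screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hipgwas.io_formats import GenotypeMatrix
from hipgwas.region import (
    allele_tables,
    cmh_m2,
    gene_effect_rollup,
    max_m2_permutation,
    segregation_screen,
)


def _matrix(calls):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": ["9"] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "allele_a": ["A"] * m,
            "allele_b": ["G"] * m,
        }
    )
    return GenotypeMatrix([f"d{i}" for i in range(n)], snps, calls)


class TestCmh:
    def test_single_stratum_worked_example(self):
        # 60 * (20*20 - 10*10)^2 / 30^4 = 6.667
        res = cmh_m2([np.array([[20, 10], [10, 20]])])
        assert res.m2 == pytest.approx(6.6667, abs=1e-3)

    def test_identical_frequencies_give_zero(self):
        tables = [np.array([[10, 10], [20, 20]]), np.array([[5, 15], [10, 30]])]
        assert cmh_m2(tables).m2 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_stratum_equals_pearson(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 40, size=(2, 2))
        res = cmh_m2([t])
        chi2 = stats.chi2_contingency(t, correction=False)[0]
        assert res.m2 == pytest.approx(chi2, rel=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_hypergeometric_variant_matches_statsmodels(self, seed):
        from statsmodels.stats.contingency_tables import StratifiedTable

        rng = np.random.default_rng(seed)
        tables = [rng.integers(1, 30, size=(2, 2)) for _ in range(4)]
        res = cmh_m2(tables, variance="hypergeometric")
        st = StratifiedTable(np.stack(tables, axis=-1).astype(float))
        assert res.m2 == pytest.approx(st.test_null_odds(correction=False).statistic, rel=1e-8)

    def test_invariant_under_stratum_reordering(self):
        rng = np.random.default_rng(9)
        tables = [rng.integers(1, 30, size=(2, 2)) for _ in range(5)]
        a = cmh_m2(tables).m2
        b = cmh_m2(tables[::-1]).m2
        assert a == pytest.approx(b, rel=1e-12)

    def test_collapsing_identical_strata_leaves_m2_unchanged(self):
        t = np.array([[12, 8], [7, 13]])
        split = cmh_m2([t, t]).m2
        merged = cmh_m2([2 * t]).m2
        assert split == pytest.approx(merged, rel=1e-12)

    def test_zero_margin_strata_dropped(self):
        good = np.array([[20, 10], [10, 20]])
        empty = np.array([[0, 0], [5, 5]])
        res = cmh_m2([good, empty])
        assert res.n_strata_used == 1
        assert res.m2 == pytest.approx(cmh_m2([good]).m2)

    def test_all_strata_dropped_flagged(self):
        res = cmh_m2([np.array([[0, 0], [5, 5]])])
        assert res.n_strata_used == 0 and np.isnan(res.m2)


class TestMaxM2Permutation:
    def test_exhaustive_matches_brute_force_single_snp(self):
        g = np.array([[0], [1], [2], [2], [0], [1], [2], [0]], dtype=np.int8)
        y = np.array([1, 1, 0, 0, 1, 1, 0, 0])
        strata = np.array(["a"] * 4 + ["b"] * 4)
        gm = _matrix(g)
        dist, table = max_m2_permutation(gm, y, strata, seed=0)
        assert dist.exhaustive
        # independent enumeration: within-strata case assignments
        obs = cmh_m2(allele_tables(g[:, 0], y, strata)).m2
        maxes = []
        idx_a, idx_b = [0, 1, 2, 3], [4, 5, 6, 7]
        for ca in itertools.combinations(idx_a, int(y[idx_a].sum())):
            for cb in itertools.combinations(idx_b, int(y[idx_b].sum())):
                yy = np.zeros(8, dtype=int)
                yy[list(ca) + list(cb)] = 1
                maxes.append(cmh_m2(allele_tables(g[:, 0], yy, strata)).m2)
        maxes = np.array(maxes)
        expected = np.mean(maxes >= obs - 1e-12)
        assert table["p_fwer"].iloc[0] == pytest.approx(expected)

    def test_null_region_observed_max_inside_null_interval(self):
        hits = 0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n, m = 80, 30
            calls = rng.binomial(2, 0.4, size=(n, m)).astype(np.int8)
            y = np.array([1] * 40 + [0] * 40)
            strata = np.tile(["a", "b"], 40)
            dist, table = max_m2_permutation(
                _matrix(calls), y, strata, n_perm=300, seed=seed, exhaustive_limit=10
            )
            obs = np.nanmax(table["m2"])
            if dist.q2_5 <= obs <= dist.q97_5:
                hits += 1
        assert hits >= 9  # ~95% coverage, small-sample slack

    def test_fwer_p_dominates_single_snp_p(self):
        rng = np.random.default_rng(5)
        calls = rng.binomial(2, 0.4, size=(8, 3)).astype(np.int8)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        strata = np.array(["a"] * 8)
        gm = _matrix(calls)
        _dist, multi = max_m2_permutation(gm, y, strata, seed=0)
        for j in range(3):
            _d, single = max_m2_permutation(gm.subset(None, [j]), y, strata, seed=0)
            assert multi["p_fwer"].iloc[j] >= single["p_fwer"].iloc[0] - 1e-12

    def test_single_permutation_support(self):
        rng = np.random.default_rng(6)
        calls = rng.binomial(2, 0.4, size=(40, 2)).astype(np.int8)
        y = rng.integers(0, 2, 40)
        strata = np.array(["a"] * 40)
        _dist, table = max_m2_permutation(
            _matrix(calls), y, strata, n_perm=1, seed=0, exhaustive_limit=1
        )
        assert set(np.round(table["p_fwer"], 6)) <= {0.5, 1.0}


def _variant_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "effect_class", "case_carriers", "control_carriers"],
    )


class TestSegregationScreen:
    def test_boundary_delta_retained_and_excluded(self):
        variants = _variant_frame(
            [
                ("9", 100, "A", "G", "RAD51C", "upstream", 22, 0),
                ("9", 200, "C", "T", "GENE2", "upstream", 21, 0),
                ("9", 300, "G", "A", "GENE3", "nonsynonymous", 0, 23),
            ]
        )
        res = segregation_screen(variants)
        assert list(res.retained["gene"]) == ["RAD51C", "GENE3"]
        assert list(res.retained["delta"]) == [22, -23]

    def test_excluded_classes_dropped_regardless_of_delta(self):
        variants = _variant_frame(
            [
                ("9", 100, "A", "G", "X", "intronic", 24, 0),
                ("9", 200, "A", "G", "X", "intergenic", 24, 0),
                ("9", 300, "A", "G", "X", "synonymous", 24, 0),
                ("9", 400, "A", "G", "X", "splicing", 24, 0),
            ]
        )
        res = segregation_screen(variants)
        assert list(res.retained["effect_class"]) == ["splicing"]

    def test_empty_table_gives_empty_result(self):
        res = segregation_screen(_variant_frame([]))
        assert len(res.retained) == 0

    def test_invariant_to_row_order(self):
        rows = [
            ("9", 300, "G", "A", "B", "upstream", 23, 0),
            ("9", 100, "A", "G", "A", "splicing", 0, 24),
            ("9", 200, "C", "T", "C", "nonsynonymous", 22, 0),
        ]
        a = segregation_screen(_variant_frame(rows)).retained
        b = segregation_screen(_variant_frame(rows[::-1])).retained
        pd.testing.assert_frame_equal(a, b)


class TestGeneRollup:
    def test_single_variant_cell(self):
        variants = _variant_frame([("9", 1, "A", "G", "X", "nonsynonymous", 23, 0)])
        res = segregation_screen(variants)
        table = gene_effect_rollup(variants, res)
        assert table.loc["X", "nonsynonymous"] == 23

    def test_signed_summation(self):
        variants = _variant_frame(
            [
                ("9", 1, "A", "G", "X", "nonsynonymous", 23, 0),
                ("9", 2, "C", "T", "X", "nonsynonymous", 0, 22),
            ]
        )
        res = segregation_screen(variants)
        table = gene_effect_rollup(variants, res)
        assert table.loc["X", "nonsynonymous"] == 1

    def test_reproduces_reported_style_rows(self):
        # AATF: one segregating nonsynonymous (+23) and a small UTR3 (+4);
        # SCPEP1: control-enriched UTR3 (-24) plus sub-threshold downstream (-21)
        variants = _variant_frame(
            [
                ("9", 1, "A", "G", "AATF", "nonsynonymous", 23, 0),
                ("9", 2, "C", "T", "AATF", "UTR3", 4, 0),
                ("9", 3, "G", "A", "SCPEP1", "UTR3", 0, 24),
                ("9", 4, "T", "C", "SCPEP1", "downstream", 0, 21),
            ]
        )
        res = segregation_screen(variants)
        table = gene_effect_rollup(variants, res)
        assert table.loc["AATF", "nonsynonymous"] == 23
        assert table.loc["AATF", "UTR3"] == 4
        assert table.loc["SCPEP1", "UTR3"] == -24
        assert table.loc["SCPEP1", "downstream"] == -21
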