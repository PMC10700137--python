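"""Cross-clone bookkeeping, escapee criteria and exact-test oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from allelic import CrossInfo, Thresholds
from allelic.cross import (
    classify_cross_clone_consistency,
    cluster_allelic_fc,
    fisher_enrichment,
    haploinsufficiency_summary,
    identify_escapees,
    lost_allele,
)
from allelic.tables import AlleleCountTable

from conftest import make_suite_frames


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClusterAllelicFc:
    def test_separable_planting_recovered(self):
        rng = np.random.default_rng(0)
        a = np.column_stack([rng.normal(-3, 0.1, 40), rng.normal(0, 0.1, 40)])
        b = np.column_stack([rng.normal(0, 0.1, 40), rng.normal(-3, 0.1, 40)])
        mat = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(80)])
        labels = cluster_allelic_fc(mat, k=2, seed=1)
        assert labels.iloc[:40].nunique() == 1
        assert labels.iloc[40:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[40]

    def test_k_one_is_single_cluster(self):
        mat = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 4)))
        assert cluster_allelic_fc(mat, k=1, seed=0).nunique() == 1

    def test_seeded_determinism(self):
        mat = pd.DataFrame(np.random.default_rng(2).normal(size=(30, 4)))
        l1 = cluster_allelic_fc(mat, k=3, seed=5)
        l2 = cluster_allelic_fc(mat, k=3, seed=5)
        assert (l1 == l2).all()

    def test_k_exceeding_genes_rejected(self):
        mat = pd.DataFrame(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="k exceeds"):
            cluster_allelic_fc(mat, k=6)


# ---------------------------------------------------------------------------
# cross-clone consistency
# ---------------------------------------------------------------------------

def _calls(genes, category="bi_to_mono_A1"):
    return pd.DataFrame({"category": category}, index=pd.Index(genes, name="gene_id"))


class TestCrossCloneConsistency:
    cabl = CrossInfo("CaBl", "CAST", "BL6", "male")
    blca = CrossInfo("BlCa", "BL6", "CAST", "male")
    cabl_f = CrossInfo("CaBl_f", "CAST", "BL6", "female", xi_allele="a2")

    def test_reciprocal_maternal_loss_is_imprinting_like(self):
        # CaBl (CAST mother) loses a2 (=CAST=maternal);
        # BlCa (CAST father) loses a1 (=BL6=maternal)
        res = classify_cross_clone_consistency(
            _calls(["g"], "bi_to_mono_A1"),
            _calls(["g"], "bi_to_mono_A2"),
            self.cabl,
            self.blca,
            pd.Series({"g": "a2"}),
            pd.Series({"g": "a1"}),
        )
        row = res.loc["g"]
        assert row["mode"] == "reversed_allele"
        assert row["parental_origin_a"] == "maternal"
        assert row["parental_origin_b"] == "maternal"
        assert row["origin_consistent"]
        assert row["interpretation"] == "imprinting_like"

    def test_same_strain_allele_lost_is_same_allele(self):
        res = classify_cross_clone_consistency(
            _calls(["g"], "bi_to_mono_A2"),
            _calls(["g"], "bi_to_mono_A2"),
            self.cabl,
            self.blca,
            pd.Series({"g": "a1"}),
            pd.Series({"g": "a1"}),
        )
        assert res.loc["g", "mode"] == "same_allele"
        assert not res.loc["g", "origin_consistent"]

    def test_same_cross_reversal_is_random_monoallelic_like(self):
        res = classify_cross_clone_consistency(
            _calls(["g"], "bi_to_mono_A1"),
            _calls(["g"], "bi_to_mono_A2"),
            self.cabl,
            self.cabl_f,
            pd.Series({"g": "a2"}),
            pd.Series({"g": "a1"}),
        )
        assert res.loc["g", "mode"] == "reversed_allele"
        assert res.loc["g", "interpretation"] == "random_monoallelic_like"

    def test_argument_order_does_not_change_mode(self):
        args = (
            _calls(["g"], "bi_to_mono_A1"),
            _calls(["g"], "bi_to_mono_A2"),
            self.cabl,
            self.blca,
            pd.Series({"g": "a2"}),
            pd.Series({"g": "a1"}),
        )
        r1 = classify_cross_clone_consistency(*args)
        r2 = classify_cross_clone_consistency(
            args[1], args[0], args[3], args[2], args[5], args[4]
        )
        assert r1.loc["g", "mode"] == r2.loc["g", "mode"]
        assert r1.loc["g", "interpretation"] == r2.loc["g", "interpretation"]

    def test_non_bi_to_mono_genes_excluded(self):
        res = classify_cross_clone_consistency(
            _calls(["g"], "bi_to_bi_down"),
            _calls(["g"], "bi_to_mono_A1"),
            self.cabl,
            self.blca,
            pd.Series({"g": "a1"}),
            pd.Series({"g": "a1"}),
        )
        assert len(res) == 0

    def test_lost_allele_rule(self, small_suite, small_truth):
        lost = lost_allele(small_suite)
        bm2 = small_truth.index[small_truth["category"] == "bi_to_mono_A2"]
        assert (lost.loc[bm2].dropna() == "a1").all()
        assert (lost.loc[bm2] == "a1").mean() > 0.9


# ---------------------------------------------------------------------------
# escapees
# ---------------------------------------------------------------------------

def _x_table(xi_means, xa_means, n_wt=3):
    """Female-clone chrX table with Xi = a2 and exact WT means, sf = 1."""
    genes = [f"x{i}" for i in range(len(xi_means))]
    cols = [f"wt{i}" for i in range(n_wt)] + ["ko0", "ko1"]
    samples = pd.DataFrame(
        {
            "clone": "f",
            "condition": ["WT"] * n_wt + ["KO"] * 2,
            "replicate": [1, 2, 3, 1, 2][: n_wt + 2],
        },
        index=pd.Index(cols, name="sample_id"),
    )
    a2 = pd.DataFrame(
        {c: xi_means for c in cols}, index=genes
    )  # Xi allele constant across samples
    a1 = pd.DataFrame({c: xa_means for c in cols}, index=genes)
    total = a1 + a2
    gene_info = pd.DataFrame(
        {"chrom": "chrX", "tss": 1000, "strand": "+"}, index=genes
    )
    return AlleleCountTable(
        {"a1": a1.astype(int), "a2": a2.astype(int), "total": total.astype(int)},
        samples,
        gene_info,
    )


class TestEscapees:
    cross = CrossInfo("f", "CAST", "BL6", "female", xi_allele="a2")

    def test_rule_arithmetic(self):
        table = _x_table([15], [50])
        suite = make_suite_frames(["x0"], allele2_log2fc=[-1.0])
        layout, _ = table.allele_layout()
        suite.size_factors_allelic = pd.Series(1.0, index=layout.columns)
        res = identify_escapees(table, suite, self.cross)
        assert res.loc["x0", "xi_fraction"] == pytest.approx(15 / 65, abs=1e-6)
        assert bool(res.loc["x0", "is_escapee"])

    def test_low_xi_counts_never_escape(self):
        table = _x_table([8], [10])  # fraction 0.44 but counts below 10
        suite = make_suite_frames(["x0"])
        layout, _ = table.allele_layout()
        suite.size_factors_allelic = pd.Series(1.0, index=layout.columns)
        res = identify_escapees(table, suite, self.cross)
        assert not bool(res.loc["x0", "is_escapee"])

    def test_strict_lfc_defines_regulated(self):
        table = _x_table([15, 15], [50, 50])
        suite = make_suite_frames(["x0", "x1"], allele2_log2fc=[-2.5, -1.5])
        layout, _ = table.allele_layout()
        suite.size_factors_allelic = pd.Series(1.0, index=layout.columns)
        res = identify_escapees(table, suite, self.cross)
        assert bool(res.loc["x0", "is_msl2_regulated"])
        assert not bool(res.loc["x1", "is_msl2_regulated"])
        assert bool(res.loc["x1", "is_escapee"])

    def test_scaling_invariance(self):
        table = _x_table([20, 5], [60, 100])
        suite = make_suite_frames(["x0", "x1"])
        layout, _ = table.allele_layout()
        suite.size_factors_allelic = pd.Series(1.0, index=layout.columns)
        r1 = identify_escapees(table, suite, self.cross)
        scaled = AlleleCountTable(
            {k: v * 3 for k, v in table.counts.items()},
            table.samples,
            table.gene_info,
        )
        # normalization: tripling counts triples size factors
        suite.size_factors_allelic = pd.Series(3.0, index=layout.columns)
        r2 = identify_escapees(scaled, suite, self.cross)
        pd.testing.assert_series_equal(r1["is_escapee"], r2["is_escapee"])
        assert np.allclose(r1["xi_fraction"], r2["xi_fraction"])

    def test_male_clone_rejected(self):
        table = _x_table([15], [50])
        suite = make_suite_frames(["x0"])
        with pytest.raises(ValueError, match="XCI-informative"):
            identify_escapees(table, suite, CrossInfo("m", "CAST", "BL6", "male"))


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def two_sided_hypergeom_p(a, b, c, d):
    """Exact two-sided p: sum of probabilities <= that of the observed table
    over all tables with the same margins (independent enumeration oracle)."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    p_obs = hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p_x = hypergeom.pmf(x, n, row1, col1)
        if p_x <= p_obs * (1 + 1e-9):
            total += p_x
    return min(total, 1.0)


class TestFisherEnrichment:
    def test_balanced_table_is_null(self):
        universe = [f"g{i}" for i in range(20)]
        odds, p, table = fisher_enrichment(universe[:10], universe[5:15], universe)
        assert p == pytest.approx(1.0, abs=0.5)  # symmetric-ish table
        odds, p, table = fisher_enrichment(universe[:10], universe, universe)
        assert table[0, 1] == 0

    def test_perfect_association_hand_value(self):
        universe = [f"g{i}" for i in range(20)]
        odds, p, table = fisher_enrichment(universe[:10], universe[:10], universe)
        from math import comb

        assert np.allclose(table, [[10, 0], [0, 10]])
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)
        assert odds > 1

    def test_matches_enumeration_oracle_small_margins(self):
        for a, b, c, d in itertools.product(range(0, 8, 2), repeat=4):
            if a + b + c + d == 0:
                continue
            universe = [f"g{i}" for i in range(a + b + c + d)]
            query = universe[: a + b]
            anno = universe[:a] + universe[a + b : a + b + c]
            _, p, table = fisher_enrichment(query, anno, universe)
            assert np.allclose(table, [[a, b], [c, d]])
            assert p == pytest.approx(two_sided_hypergeom_p(a, b, c, d), rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_enrichment([], [], [])


class TestHaploinsufficiencySummary:
    def test_counts_on_constructed_sets(self):
        genes = [f"g{i}" for i in range(200)]
        calls = pd.DataFrame(
            {"category": ["bi_to_mono_A1"] * 50 + ["unclassified"] * 150},
            index=pd.Index(genes, name="gene_id"),
        )
        hi = pd.DataFrame(
            {"gene_id": genes[:40] + genes[100:160],
             "hi_score": [0.95] * 40 + [0.5] * 60,
             "triplosensitive": 0}
        )
        res = haploinsufficiency_summary(calls, hi, genes)
        assert res.loc["bi_to_mono_A1", "n_hi"] == 40
        assert res.loc["bi_to_mono_A1", "frac_hi"] == pytest.approx(0.8)
        assert res.loc["unclassified", "n_hi"] == 60
        assert res.loc["bi_to_mono_A1", "odds_ratio"] > 1

    def test_empty_hi_list_gives_zero_and_null_p(self):
        calls = pd.DataFrame(
            {"category": ["bi_to_mono_A1"] * 10},
            index=pd.Index([f"g{i}" for i in range(10)], name="gene_id"),
        )
        hi = pd.DataFrame({"gene_id": [], "hi_score": [], "triplosensitive": []})
        res = haploinsufficiency_summary(calls, hi, calls.index)
        assert res.loc["bi_to_mono_A1", "frac_hi"] == 0
        assert res.loc["bi_to_mono_A1", "fisher_p"] == pytest.approx(1.0)

    def test_duplicate_gene_ids_rejected(self):
        calls = pd.DataFrame({"category": ["x"]}, index=pd.Index(["g"], name="gene_id"))
        hi = pd.DataFrame(
            {"gene_id": ["g", "g"], "hi_score": [0.5, 0.6], "triplosensitive": [0, 0]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            haploinsufficiency_summary(calls, hi, ["g"])
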