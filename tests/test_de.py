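"""Normalization, dispersion, GLM and multiple-testing behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allelic import SimConfig, CrossInfo, simulate_experiment
from allelic.de import (
    LN2,
    adjust_bh,
    estimate_dispersions,
    estimate_size_factors,
    fit_nb_glm_wald,
    run_de_suite,
)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

class TestSizeFactors:
    def test_median_of_ratios_hand_example(self):
        m = pd.DataFrame([[10, 20], [30, 60], [50, 100]], columns=["s1", "s2"])
        sf = estimate_size_factors(m)
        assert sf.to_numpy() == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame([[5, 5], [9, 9], [100, 100]])
        assert estimate_size_factors(m).to_numpy() == pytest.approx([1.0, 1.0])

    def test_zero_count_gene_excluded_from_reference(self):
        m = pd.DataFrame([[0, 5], [10, 10]])
        assert estimate_size_factors(m).to_numpy() == pytest.approx([1.0, 1.0])

    def test_no_reference_gene_errors(self):
        m = pd.DataFrame([[0, 5], [10, 0]])
        with pytest.raises(ValueError, match="no common reference"):
            estimate_size_factors(m)

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.poisson(100, size=(50, 4)) + 1)
        sf = estimate_size_factors(m)
        m2 = m.copy()
        m2[0] = (m2[0] * 3).astype(int)
        sf2 = estimate_size_factors(m2)
        # ratios between factors are preserved up to the geomean rescale
        assert (sf2[0] / sf[0]) / (sf2[1] / sf[1]) == pytest.approx(3.0, rel=1e-6)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.poisson(50, size=(30, 5)) + 1)
        sf = estimate_size_factors(m)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersions:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=[f"s{i}" for i in range(len(rows[0]))])

    def test_method_of_moments_value(self):
        # one group, mean 100, sample variance 600 -> alpha = (600-100)/100^2
        vals = np.array([100.0, 80, 120, 90, 110, 100])
        vals = (vals - vals.mean()) + 100.0
        scale = np.sqrt(600.0 / vals.var(ddof=1))
        vals = (vals - 100.0) * scale + 100.0
        m = self._frame([vals])
        sf = pd.Series(1.0, index=m.columns)
        disp = estimate_dispersions(m, sf, ["g"] * 6)
        assert disp["alpha"].iloc[0] == pytest.approx(0.05, rel=1e-6)

    def test_poisson_like_variance_hits_floor(self):
        vals = np.array([90.0, 110, 95, 105, 100, 100])
        scale = np.sqrt(100.0 / vals.var(ddof=1))
        vals = (vals - 100.0) * scale + 100.0
        m = self._frame([vals])
        disp = estimate_dispersions(m, pd.Series(1.0, index=m.columns), ["g"] * 6)
        assert disp["alpha"].iloc[0] == pytest.approx(1e-8)

    def test_underdispersion_hits_floor(self):
        m = self._frame([[100, 100, 100, 100]])
        disp = estimate_dispersions(m, pd.Series(1.0, index=m.columns), ["g"] * 4)
        assert disp["alpha"].iloc[0] == pytest.approx(1e-8)

    def test_all_zero_gene_flagged(self):
        m = self._frame([[0, 0, 0, 0]])
        disp = estimate_dispersions(m, pd.Series(1.0, index=m.columns), ["g"] * 4)
        assert bool(disp["untestable"].iloc[0])

    def test_group_means_are_centered_out(self):
        # two groups with very different means but no within-group variance
        m = self._frame([[10, 10, 1000, 1000]])
        disp = estimate_dispersions(
            m, pd.Series(1.0, index=m.columns), ["a", "a", "b", "b"]
        )
        assert disp["alpha"].iloc[0] == pytest.approx(1e-8)


# ---------------------------------------------------------------------------
# the GLM
# ---------------------------------------------------------------------------

def _interaction_design():
    allele = np.repeat([0.0, 1.0], 4)
    cond = np.tile([0.0, 0.0, 1.0, 1.0], 2)
    return np.column_stack([np.ones(8), allele, cond, allele * cond])


class TestNbGlm:
    def test_flat_means_give_null_interaction(self):
        y = np.full(8, 100.0)
        fit = fit_nb_glm_wald(y, _interaction_design(), np.ones(8), 0.05)
        assert abs(fit.coefficients[3]) < 1e-6
        assert fit.p_values[3] > 0.99

    def test_poisson_limit_matches_log_ratio_of_means(self):
        # WT a1 = a2 = 100; KO a1 = 100, a2 = 25 -> interaction = -2
        y = np.array([100, 100, 100, 100, 100, 100, 25, 25], dtype=float)
        fit = fit_nb_glm_wald(y, _interaction_design(), np.ones(8), 1e-8)
        assert fit.coefficients[3] == pytest.approx(-2.0, abs=1e-3)

    def test_all_zero_group_is_capped_not_infinite(self):
        y = np.array([100, 100, 100, 100, 100, 100, 0, 0], dtype=float)
        fit = fit_nb_glm_wald(y, _interaction_design(), np.ones(8), 0.01)
        assert np.isfinite(fit.coefficients).all()
        assert fit.coefficients[3] == -12.0

    def test_balanced_large_counts_match_group_mean_ratios(self):
        rng = np.random.default_rng(2)
        means = {"wt1": 400.0, "wt2": 500.0, "ko1": 300.0, "ko2": 150.0}
        y = np.array(
            [means["wt1"]] * 2 + [means["ko1"]] * 2
            + [means["wt2"]] * 2 + [means["ko2"]] * 2
        )
        fit = fit_nb_glm_wald(y, _interaction_design(), np.ones(8), 1e-8)
        expect_a1 = np.log2(means["ko1"] / means["wt1"])
        expect_as = np.log2(
            (means["ko2"] / means["wt2"]) / (means["ko1"] / means["wt1"])
        )
        assert fit.coefficients[2] == pytest.approx(expect_a1, abs=1e-3)
        assert fit.coefficients[3] == pytest.approx(expect_as, abs=1e-3)

    def test_offsets_absorb_size_factors(self):
        # raw counts differ only through the 2x library size of odd samples
        y = np.array([200, 100, 200, 100, 200, 100, 200, 100], dtype=float)
        sf = np.tile([2.0, 1.0], 4)
        fit = fit_nb_glm_wald(y, _interaction_design(), sf, 1e-8)
        assert abs(fit.coefficients[2]) < 1e-3
        assert abs(fit.coefficients[3]) < 1e-3

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            fit_nb_glm_wald(np.ones(6), X, np.ones(6), 0.1)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_reference(p):
    """Brute-force BH: q_i = min_{j: p_j >= p_i} p_j * m / rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    best = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        q[i] = min(best, 1.0)
    return q


class TestAdjustBH:
    def test_hand_example(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_is_identity(self):
        assert adjust_bh([0.2]) == pytest.approx([0.2])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert adjust_bh(p)[perm] == pytest.approx(adjust_bh(p[perm]))

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(adjust_bh(p), bh_reference(p))

    def test_nan_propagates(self):
        q = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(0.02)  # m = 2 non-NaN tests

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_and_is_bounded(self, p):
        q = adjust_bh(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)


# ---------------------------------------------------------------------------
# the suite
# ---------------------------------------------------------------------------

class TestDESuite:
    def test_interaction_identity(self, small_suite):
        tested = small_suite.allele_specific["tested"]
        dev = (
            small_suite.allele_specific.loc[tested, "log2fc"]
            - (
                small_suite.allele2.loc[tested, "log2fc"]
                - small_suite.allele1.loc[tested, "log2fc"]
            )
        ).abs()
        assert dev.max() < 1e-6

    def test_planted_silencing_detected(self, small_suite, small_truth):
        bm = small_truth.index[small_truth["category"] == "bi_to_mono_A2"]
        sub1 = small_suite.allele1.loc[bm]
        frac = ((sub1["p"] < 0.01) & (sub1["log2fc"] < -2)).mean()
        assert frac >= 0.95

    def test_allele_relabel_flips_sign_keeps_p(self, small_table):
        from allelic.tables import AlleleCountTable

        swapped = AlleleCountTable(
            counts={
                "a1": small_table.counts["a2"],
                "a2": small_table.counts["a1"],
                "total": small_table.counts["total"],
            },
            samples=small_table.samples,
        )
        s1 = run_de_suite(small_table)
        s2 = run_de_suite(swapped)
        t = s1.allele_specific["tested"]
        assert np.allclose(
            s1.allele_specific.loc[t, "log2fc"],
            -s2.allele_specific.loc[t, "log2fc"],
            atol=1e-8,
        )
        assert np.allclose(
            s1.allele_specific.loc[t, "p"], s2.allele_specific.loc[t, "p"],
            atol=1e-10,
        )
        pd.testing.assert_frame_equal(s1.allele2.loc[t], s2.allele1.loc[t])

    def test_interaction_fit_equals_separate_allele_fit(self, small_table):
        """The shared 4-coefficient fit must reproduce a 2-coefficient fit on
        allele-1 counts alone (saturated design separability)."""
        suite = run_de_suite(small_table)
        layout, meta = small_table.allele_layout()
        sf = suite.size_factors_allelic
        a1_cols = meta.index[meta["allele"] == "a1"]
        genes = suite.genes[suite.allele1["tested"]][:25]
        is_ko = (meta.loc[a1_cols, "condition"] == "KO").to_numpy(float)
        X = np.column_stack([np.ones_like(is_ko), is_ko])
        group = (meta["condition"] + "." + meta["allele"]).to_numpy()
        disp = estimate_dispersions(layout.loc[genes], sf, group)
        for g in genes:
            fit = fit_nb_glm_wald(
                layout.loc[g, a1_cols].to_numpy(float),
                X,
                sf.loc[a1_cols].to_numpy(),
                disp.loc[g, "alpha"],
            )
            assert fit.coefficients[1] == pytest.approx(
                suite.allele1.loc[g, "log2fc"], abs=1e-5
            )

    def test_low_count_genes_untested_with_nan(self, small_table):
        counts = {k: v.copy() for k, v in small_table.counts.items()}
        for k in counts:
            counts[k].loc["dead_gene"] = 0
        from allelic.tables import AlleleCountTable

        t = AlleleCountTable(counts, small_table.samples)
        suite = run_de_suite(t)
        assert not suite.standard.loc["dead_gene", "tested"]
        assert np.isnan(suite.standard.loc["dead_gene", "p"])
        assert np.isnan(suite.allele_specific.loc["dead_gene", "q"])

    def test_single_replicate_condition_rejected(self, small_table):
        from allelic.tables import AlleleCountTable

        keep = small_table.samples.index[
            (small_table.samples["condition"] == "WT")
            | (small_table.samples["replicate"] == 1)
        ]
        t = AlleleCountTable(
            counts={k: v[keep] for k, v in small_table.counts.items()},
            samples=small_table.samples.loc[keep],
        )
        with pytest.raises(ValueError, match="replicates"):
            run_de_suite(t)
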