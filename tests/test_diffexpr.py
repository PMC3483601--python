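"""Normalization, dispersion estimation, the NB exact test and downstream calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from flysrna.diffexpr import (
    ContrastDesign,
    bh_adjust,
    classify_head_enrichment,
    ddct_fold_change,
    de_table,
    direction_concordance,
    estimate_dispersions,
    nb_exact_test,
    sample_correlation_qc,
    size_factors,
)
from flysrna.simulate import nb_null_matrix


def brute_force_bh(pvals):
    """Independent step-up oracle written from the definition."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * pvals[i] / rank))
        adj[i] = running
    return adj


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20]})
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_column_closed_form(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        s = size_factors(m)
        assert s["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert s["b"] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_zero_rows_do_not_change_factors(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        m2 = pd.concat([m, pd.DataFrame({"a": [0], "b": [0]})], ignore_index=True)
        assert np.allclose(size_factors(m), size_factors(m2))

    def test_no_all_positive_row_raises(self):
        m = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="size factors"):
            size_factors(m)


class TestEstimateDispersions:
    def test_recovers_alpha_point_two(self):
        m = nb_null_matrix(np.full(300, 500.0), 10, 0.2, seed=3)
        cols = list(m.columns)
        design = ContrastDesign(tuple(cols[:5]), tuple(cols[5:]))
        disp = estimate_dispersions(m, design)
        assert 0.1 <= np.median(disp["final"]) <= 0.4

    def test_poisson_data_gives_small_gene_wise(self):
        m = nb_null_matrix(np.full(300, 1000.0), 10, 0.0, seed=4)
        cols = list(m.columns)
        design = ContrastDesign(tuple(cols[:5]), tuple(cols[5:]))
        disp = estimate_dispersions(m, design)
        assert np.median(disp["gene_wise"]) <= 0.05

    def test_maximum_sharing_dominates_fit(self):
        m = nb_null_matrix(np.full(100, 200.0), 8, 0.1, seed=5)
        cols = list(m.columns)
        design = ContrastDesign(tuple(cols[:4]), tuple(cols[4:]))
        disp = estimate_dispersions(m, design, sharing_mode="maximum")
        assert (disp["final"] >= disp["fitted"] - 1e-12).all()
        assert (disp["final"] >= disp["gene_wise"] - 1e-12).all()

    def test_single_sample_groups_need_reference_controls(self):
        m = nb_null_matrix(np.full(50, 100.0), 2, 0.1, seed=6)
        design = ContrastDesign((m.columns[0],), (m.columns[1],))
        with pytest.raises(ValueError, match="reference control"):
            estimate_dispersions(m, design)


class TestNbExactTest:
    def test_balanced_split_has_p_one(self):
        assert nb_exact_test([50, 50], [50, 50], [1, 1], [1, 1], 0.1) == 1.0

    def test_poisson_limit_matches_binomial_conditional_test(self):
        for ka, kb in [(30, 70), (5, 20), (0, 10), (12, 12)]:
            p = nb_exact_test([ka], [kb], [1.0], [1.0], 0.0)
            expected = binomtest(ka, ka + kb, 0.5).pvalue
            assert p == pytest.approx(expected, abs=1e-6)

    def test_extreme_split_is_significant(self):
        assert nb_exact_test([0], [100], [1.0], [1.0], 0.1) < 0.01

    def test_empty_information_gives_p_one(self):
        assert nb_exact_test([0, 0], [0, 0], [1, 1], [1, 1], 0.1) == 1.0

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [2], [1.0], [1.0], -0.5)


class TestBHAdjust:
    def test_closed_form_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), brute_force_bh(p))

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(22)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDeTable:
    def test_fold_change_is_ratio_of_normalized_means(self):
        matrix = pd.DataFrame(
            {"a1": [292, 452], "b1": [966, 718]}, index=["gene1", "gene2"]
        )
        design = ContrastDesign(("a1",), ("b1",))
        de = de_table(
            matrix,
            design,
            sf=pd.Series({"a1": 1.0, "b1": 1.0}),
            dispersions=pd.Series({"gene1": 0.1, "gene2": 0.1}),
        )
        assert round(de.loc["gene1", "foldChange"], 2) == 3.31
        assert round(de.loc["gene2", "foldChange"], 2) == 1.59

    def test_identical_conditions_give_null_results(self):
        m = nb_null_matrix(np.full(60, 300.0), 12, 0.05, seed=8)
        cols = list(m.columns)
        design = ContrastDesign(tuple(cols[:3]), tuple(cols[3:6]), tuple(cols[6:]))
        de = de_table(m, design)
        assert (de["padj"] >= de["pval"] - 1e-15).all()
        assert (de["padj"] < 0.01).sum() == 0

    def test_zero_baseline_reports_infinite_fold_change(self):
        matrix = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 12], "b1": [30, 11], "b2": [25, 13]},
            index=["g1", "g2"],
        )
        design = ContrastDesign(("a1", "a2"), ("b1", "b2"))
        de = de_table(
            matrix, design,
            sf=pd.Series(1.0, index=matrix.columns),
            dispersions=pd.Series(0.1, index=matrix.index),
        )
        assert np.isinf(de.loc["g1", "foldChange"])

    def test_scale_invariance_of_normalization_and_fold_changes(self):
        # multiplying one column by c: its size factor grows c times relative
        # to every other (the geometric-mean reference spreads the constant as
        # c^(1/m) over all factors), normalized counts change only by a common
        # constant, and fold changes are untouched
        m = nb_null_matrix(np.full(80, 400.0), 8, 0.1, seed=9)
        cols = list(m.columns)
        design = ContrastDesign(tuple(cols[:2]), tuple(cols[2:4]), tuple(cols[4:]))
        scaled = m.copy()
        scaled[cols[0]] = scaled[cols[0]] * 3
        s1, s2 = size_factors(m), size_factors(scaled)
        assert s2[cols[0]] / s2[cols[1]] == pytest.approx(3 * s1[cols[0]] / s1[cols[1]])
        ratio = (scaled / s2) / (m / s1)
        assert np.allclose(ratio, ratio.iloc[0, 0])
        disp = pd.Series(0.1, index=m.index)
        de1 = de_table(m, design, dispersions=disp)
        de2 = de_table(scaled, design, dispersions=disp)
        assert np.allclose(de1["foldChange"], de2["foldChange"])


class TestQcAndClassification:
    def test_duplicated_control_sample_has_r_one(self):
        rng = np.random.default_rng(30)
        base = rng.uniform(10, 1000, size=100)
        m = pd.DataFrame({"s1": base, "s2": base, "s3": base * rng.uniform(0.9, 1.1, 100)})
        r = sample_correlation_qc(m, control_samples=["s1", "s2"])
        assert r["s1"] == pytest.approx(1.0)

    def test_anticorrelated_sample_has_negative_r(self):
        rng = np.random.default_rng(31)
        base = rng.uniform(10, 1000, size=200)
        noisy = base * rng.uniform(0.95, 1.05, 200)
        flipped = 2 * np.median(base) - base  # negated deviations from the center
        m = pd.DataFrame({"s1": base, "s2": noisy, "s3": flipped})
        r = sample_correlation_qc(m, control_samples=["s1", "s2"])
        assert r["s3"] < 0

    def test_homogeneous_replicates_correlate_above_0_99(self):
        # the QC regime: 12 replicates, 200 genes spanning four decades at
        # sequencing depth ~1e7 per library, moderate overdispersion
        rng = np.random.default_rng(32)
        means = np.exp(rng.uniform(np.log(100), np.log(1e6), 200))
        m = nb_null_matrix(means, 12, 0.05, seed=33)
        norm = m / size_factors(m)
        r = sample_correlation_qc(norm)
        assert (r > 0.99).all()

    def test_classification_by_ratio_direction(self):
        de = pd.DataFrame(
            {
                "foldChange": [0.5, 2.0, 0.4, 3.0],
                "pval": [0.001, 0.001, 0.5, 0.004],
                "padj": [0.004, 0.004, 0.8, 0.009],
            },
            index=["m1", "m2", "m3", "m4"],
        )
        enriched, depleted = classify_head_enrichment(de, threshold=0.01)
        assert enriched == ["m1"] and depleted == ["m2", "m4"]

    def test_planted_two_tissue_recovery(self):
        # 30 head-enriched / 70 head-depleted arms at 4-fold, 3 replicates:
        # recover >= 90% of the planted set at padj < 0.01
        rng = np.random.default_rng(40)
        n_genes = 200
        means = np.exp(rng.uniform(np.log(100), np.log(2000), n_genes))
        fold = np.ones((n_genes, 6))
        fold[:30, 3:] = 0.25  # body lower: head-enriched
        fold[30:100, 3:] = 4.0  # body higher: head-depleted
        m = nb_null_matrix(means, 6, 0.01, seed=41, fold=fold)
        cols = list(m.columns)
        design = ContrastDesign(tuple(cols[:3]), tuple(cols[3:]))
        de = de_table(m, design)
        enriched, depleted = classify_head_enrichment(de, threshold=0.01)
        sens_enr = len(set(enriched) & {f"gene{i+1}" for i in range(30)}) / 30
        sens_dep = len(set(depleted) & {f"gene{i+1}" for i in range(30, 100)}) / 70
        assert sens_enr >= 0.9 and sens_dep >= 0.9


class TestConcordanceAndDdct:
    def test_identical_ratio_vectors_fully_concordant(self):
        r = pd.Series({"a": 0.5, "b": 2.0, "c": 3.0})
        frac, n, ties = direction_concordance(r, r)
        assert frac == 1.0 and n == 3 and ties == 0

    def test_one_flip_among_ten(self):
        ids = [f"m{i}" for i in range(10)]
        r1 = pd.Series(2.0, index=ids)
        r2 = r1.copy()
        r2.iloc[0] = 0.5
        frac, _, _ = direction_concordance(r1, r2)
        assert frac == pytest.approx(0.9)

    def test_independent_ratios_concordant_about_half_the_time(self):
        rng = np.random.default_rng(50)
        ids = [f"m{i}" for i in range(4000)]
        r1 = pd.Series(np.exp(rng.normal(size=4000)), index=ids)
        r2 = pd.Series(np.exp(rng.normal(size=4000)), index=ids)
        frac, _, _ = direction_concordance(r1, r2)
        assert frac == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize(
        "ct_a, ct_b, norm_a, norm_b, expected",
        [
            (20.0, 20.0, [15.0, 16.0], [15.0, 16.0], 1.0),
            (20.0, 19.0, [15.0, 16.0], [15.0, 16.0], 2.0),
            (20.0, 18.0, [15.0, 16.0], [14.0, 15.0], 2.0),
        ],
    )
    def test_ddct_fold_change(self, ct_a, ct_b, norm_a, norm_b, expected):
        assert ddct_fold_change(ct_a, ct_b, norm_a, norm_b) == pytest.approx(expected)
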