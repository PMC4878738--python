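"""CPM rules, fold-change classification, TSS linkage, class comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chrombound.core_intervals import IntervalSet
from chrombound.expression_integration import (
    ExpressionTable,
    compare_expression_by_class,
    detect_transcripts,
    domain_expression_association,
    filter_transcripts,
    fold_change_classify,
    link_peaks_to_genes,
)
from chrombound.genome_bins import GeneModel
from chrombound.repressive_domains import RepressiveDomain
from chrombound.core_intervals import GenomicInterval

from conftest import rows_to_set
from oracles import rank_sum_exhaustive_p


def table_from_cpm(cpm_rows, genes=None):
    """Build a table whose CPM equals the given values (library size 1e6)."""
    df = pd.DataFrame(
        cpm_rows,
        index=genes or [f"g{i}" for i in range(len(cpm_rows))],
        columns=[f"s{j}" for j in range(len(cpm_rows[0]))],
    )
    lib = pd.Series(1e6, index=df.columns)
    return ExpressionTable(df, library_sizes=lib)


class TestExpressionTable:
    def test_cpm_columns_sum_to_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, (50, 4)).astype(float),
                              columns=list("abcd"))
        table = ExpressionTable(counts)
        assert np.allclose(table.cpm.sum(axis=0), 1e6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTable(pd.DataFrame({"a": [-1.0]}))


class TestDetectAndFilter:
    def test_median_rule(self):
        t = table_from_cpm([[0.5, 2.0, 3.0], [0.0, 0.0, 0.0], [0.9, 1.0, 1.1]])
        detected = detect_transcripts(t, 1.0)
        assert list(detected) == ["g0"]  # medians 2, 0, 1.0 (strict >)

    def test_min_samples_rule(self):
        t = table_from_cpm([[1.5, 1.2, 0.3, 2.0], [1.5, 0.2, 0.3, 0.4]])
        kept = filter_transcripts(t, 1.0, 3)
        assert list(kept) == ["g0"]

    def test_random_table_matches_predicate_oracle(self, rng):
        cpm = rng.uniform(0, 3, (500, 4))
        t = table_from_cpm(cpm.tolist())
        detected = set(detect_transcripts(t, 1.0))
        exp_detect = {f"g{i}" for i in range(500) if np.median(cpm[i]) > 1.0}
        assert detected == exp_detect
        kept = set(filter_transcripts(t, 1.0, 3))
        exp_keep = {f"g{i}" for i in range(500) if (cpm[i] > 1.0).sum() >= 3}
        assert kept == exp_keep

    def test_monotone_in_thresholds(self, rng):
        t = table_from_cpm(rng.uniform(0, 3, (200, 5)).tolist())
        d1 = set(detect_transcripts(t, 0.5))
        d2 = set(detect_transcripts(t, 1.5))
        assert d2 <= d1
        f1 = set(filter_transcripts(t, 1.0, 2))
        f2 = set(filter_transcripts(t, 1.0, 4))
        assert f2 <= f1


class TestFoldChange:
    def test_arithmetic_example(self):
        t = table_from_cpm([[10, 10, 25, 25]])
        cls = fold_change_classify(t, ["s0", "s1"], ["s2", "s3"], min_fold=2, pseudocount=0.5)
        # ratio = 25.5/10.5 = 2.43 > 2
        assert cls["g0"] == "up"

    def test_equal_means_unchanged(self):
        t = table_from_cpm([[10, 10, 10, 10]])
        cls = fold_change_classify(t, ["s0", "s1"], ["s2", "s3"])
        assert cls["g0"] == "unchanged"

    def test_random_table_matches_direct_arithmetic(self, rng):
        cpm = rng.uniform(0, 100, (300, 6))
        t = table_from_cpm(cpm.tolist())
        ga, gb = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        cls = fold_change_classify(t, ga, gb, min_fold=2, pseudocount=0.5)
        ratio = (cpm[:, 3:].mean(axis=1) + 0.5) / (cpm[:, :3].mean(axis=1) + 0.5)
        exp = np.where(ratio > 2, "up", np.where(ratio < 0.5, "down", "unchanged"))
        assert cls.tolist() == exp.tolist()

    def test_overlapping_groups_rejected(self):
        t = table_from_cpm([[1, 2]])
        with pytest.raises(ValueError):
            fold_change_classify(t, ["s0"], ["s0"])


class TestLinkPeaksToGenes:
    def test_distance_examples(self):
        peaks = rows_to_set([("chr1", 990, 1200)])
        genes = [GeneModel("chr1", "+", 2100, 9000, "near"),
                 GeneModel("chr1", "+", 5000, 9000, "far")]
        linked = link_peaks_to_genes(peaks, genes, d=1000,
                                     peak_classes=np.array(["invariant"]))
        assert linked.loc["near", "linked"]  # distance 900
        assert linked.loc["near", "gene_class"] == "invariant"
        assert not linked.loc["far", "linked"]
        assert linked.loc["far", "gene_class"] == "unlinked"

    def test_class_precedence_specific_wins(self):
        peaks = rows_to_set([("chr1", 900, 1100), ("chr1", 1200, 1400)])
        genes = [GeneModel("chr1", "+", 1000, 9000, "g")]
        linked = link_peaks_to_genes(
            peaks, genes, d=1000, peak_classes=np.array(["invariant", "specific"])
        )
        assert linked.loc["g", "gene_class"] == "specific"
        assert linked.loc["g", "classes"] == "invariant,specific"

    def test_random_instance_matches_tss_distance_oracle(self, rng):
        peak_rows = sorted(
            ("chr1", int(s), int(s) + 200) for s in rng.integers(0, 100_000, 100)
        )
        peaks = rows_to_set(peak_rows)
        genes = [
            GeneModel("chr1", "+", int(t), int(t) + 5_000, f"g{i}")
            for i, t in enumerate(rng.integers(0, 100_000, 50))
        ]
        linked = link_peaks_to_genes(peaks, genes, d=1000)
        for gene in genes:
            exp = any(
                max(0, s - gene.tss, gene.tss - e) <= 1000 for _, s, e in peak_rows
            )
            assert linked.loc[gene.gene_id, "linked"] == exp


class TestCompareExpression:
    def test_identical_distributions_large_p(self, rng):
        vals = rng.uniform(10, 1000, 100)
        t = table_from_cpm(np.column_stack([vals, vals]).tolist())
        classes = pd.Series(["a"] * 50 + ["b"] * 50, index=[f"g{i}" for i in range(100)])
        # identical marginal distributions via random split of one sample
        res = compare_expression_by_class(classes, t, classes=("a", "b"))
        assert res.p_value > 0.01

    def test_tiny_example_matches_exhaustive_permutation(self):
        x = [1.0, 3.0, 5.0, 7.0]
        y = [2.0, 4.0, 6.0, 20.0]
        t = table_from_cpm([[v] for v in x + y])
        classes = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"g{i}" for i in range(8)])
        res = compare_expression_by_class(classes, t, classes=("a", "b"))
        exact = stats.mannwhitneyu(
            np.log2(np.array(x) + 1), np.log2(np.array(y) + 1),
            alternative="two-sided", method="exact",
        )
        assert res.p_value == pytest.approx(exact.pvalue)
        # and both agree with brute-force enumeration of all 70 assignments
        brute = rank_sum_exhaustive_p(np.log2(np.array(x) + 1), np.log2(np.array(y) + 1))
        assert res.p_value == pytest.approx(brute)

    def test_rank_sum_invariant_to_monotone_transform(self, rng):
        a = rng.uniform(1, 100, 30)
        b = rng.uniform(1, 100, 30) * 2
        p1 = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        p2 = stats.mannwhitneyu(np.log2(a + 1), np.log2(b + 1), alternative="two-sided").pvalue
        assert p1 == pytest.approx(p2)

    def test_single_gene_class_skipped(self):
        t = table_from_cpm([[10], [20], [30]])
        classes = pd.Series(["a", "a", "b"], index=["g0", "g1", "g2"])
        res = compare_expression_by_class(classes, t, classes=("a", "b"))
        assert res.p_value is None
        assert "b" in res.skipped


class TestDomainExpressionAssociation:
    def test_membership_matches_point_in_interval_oracle(self, rng):
        doms = [
            RepressiveDomain(GenomicInterval("chr1", int(s), int(s) + 4_000))
            for s in sorted(rng.integers(0, 90_000, 8) * 10)
        ]
        genes = [
            GeneModel("chr1", "+", int(t), int(t) + 2_000, f"g{i}")
            for i, t in enumerate(rng.integers(0, 900_000, 200))
        ]
        cpm = rng.uniform(1, 100, (200, 2))
        t = table_from_cpm(cpm.tolist(), genes=[g.gene_id for g in genes])
        res = domain_expression_association(doms, genes, t)
        exp_in = {
            g.gene_id
            for g in genes
            if any(d.interval.start <= g.tss < d.interval.end for d in doms)
        }
        got_in = len(res.class_values.get("in_domain", []))
        assert got_in == len(exp_in)

    def test_all_genes_outside_comparison_skipped(self):
        genes = [GeneModel("chr1", "+", 100, 2_000, "g0"),
                 GeneModel("chr1", "+", 5_000, 8_000, "g1")]
        t = table_from_cpm([[10], [20]])
        res = domain_expression_association([], genes, t)
        assert res.p_value is None

    def test_planted_repression_recovered(self, rng):
        # in-domain genes 4-fold lower: direction and ~2 log2 magnitude
        doms = [RepressiveDomain(GenomicInterval("chr1", 0, 500_000))]
        genes = [
            GeneModel("chr1", "+", int(t), int(t) + 1_000, f"g{i}")
            for i, t in enumerate(
                list(rng.integers(0, 499_000, 300)) + list(rng.integers(600_000, 999_000, 300))
            )
        ]
        base = rng.uniform(400, 600, 600)
        base[:300] /= 4.0
        t = table_from_cpm([[v] for v in base], genes=[g.gene_id for g in genes])
        res = domain_expression_association(doms, genes, t)
        assert res.compared == ("outside", "in_domain")
        assert res.p_value < 1e-10
        assert res.median_difference == pytest.approx(-2.0, abs=0.15)
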