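import numpy as np
import pytest

from xallele import synthetic
from xallele.expression import (
    AllelicGeneExpression,
    DepthAdjustment,
    adjust_depth,
    classify_genes,
    count_gene_alleles,
    group_percent,
    xi_xa_ratio,
)
from xallele.genes import GeneModel
from xallele.reads import ClassifiedRead


def cread(read_id, chrom="chrX", start=0, n_ref=0, n_alt=0, strand="+"):
    return ClassifiedRead(
        read_id=read_id, chrom=chrom, start=start, length=100, strand=strand,
        mapq=60, genome_of_alignment="reference",
        n_ref_snps=n_ref, n_alt_snps=n_alt, n_other_snps=0,
    )


def expr(gene_id="g", xi=0.0, xa=0.0, total=0, rpkm=1.0, mapped=10_000_000):
    return AllelicGeneExpression(
        gene_id=gene_id, snp_reads_xi=xi, snp_reads_xa=xa, total_reads=total,
        rpkm=rpkm, total_mapped_reads=mapped,
    )


GENE = GeneModel("g", "chrX", "+", 1000, ((1000, 2000), (3000, 4000)), "X", "subject")


class TestCounting:
    def test_five_srpm_example(self):
        # 5 Xi SNP-reads in a 10 M library -> SRPM 5
        reads = [cread(f"r{i}", start=1100 + i, n_alt=1) for i in range(5)]
        out, _ = count_gene_alleles(
            reads, [GENE], xi_allele="alt", total_mapped_reads=10_000_000
        )
        assert out["g"].snp_reads_xi == 5
        assert out["g"].srpm_xi == pytest.approx(5.0)

    def test_intronic_read_excluded_by_default(self):
        reads = [cread("r0", start=2500, n_alt=1)]  # intron between the exons
        out, _ = count_gene_alleles(reads, [GENE], xi_allele="alt", total_mapped_reads=10**6)
        assert out["g"].total_reads == 0

    def test_include_introns_exception(self):
        reads = [cread("r0", start=2500, n_alt=1)]
        out, _ = count_gene_alleles(
            reads, [GENE], xi_allele="alt", total_mapped_reads=10**6,
            include_introns={"g"},
        )
        assert out["g"].snp_reads_xi == 1

    def test_zero_reads_gene_retained(self):
        out, _ = count_gene_alleles([], [GENE], xi_allele="alt", total_mapped_reads=10**6)
        assert out["g"].total_reads == 0
        assert out["g"].srpm_xi == 0.0

    def test_orientation_flips_xi_xa(self):
        reads = [cread("r0", start=1100, n_ref=1)]
        as_ref, _ = count_gene_alleles(reads, [GENE], xi_allele="ref", total_mapped_reads=10**6)
        as_alt, _ = count_gene_alleles(reads, [GENE], xi_allele="alt", total_mapped_reads=10**6)
        assert as_ref["g"].snp_reads_xi == 1 and as_ref["g"].snp_reads_xa == 0
        assert as_alt["g"].snp_reads_xi == 0 and as_alt["g"].snp_reads_xa == 1

    def test_opposite_strand_overlap_counted_in_both_and_flagged(self):
        g2 = GeneModel("g2", "chrX", "-", 1999, ((1000, 2000),), "X", "subject")
        reads = [cread("r0", start=1100, n_ref=1)]
        out, multi = count_gene_alleles(
            reads, [GENE, g2], xi_allele="ref", total_mapped_reads=10**6
        )
        assert multi == ["r0"]
        assert out["g"].total_reads == 1 and out["g2"].total_reads == 1

    def test_rpkm_definition(self):
        # 200 reads over 2 kb exon in a 1 M library -> 100 RPKM
        reads = [cread(f"r{i}", start=1000 + i % 900, n_ref=0) for i in range(200)]
        out, _ = count_gene_alleles(reads, [GENE], xi_allele="ref", total_mapped_reads=10**6)
        assert out["g"].rpkm == pytest.approx(100.0)


class TestDepthAdjustment:
    def test_paper_factor_rounds_to_1_06(self):
        adj = DepthAdjustment(mapped_a=22.3e6, mapped_b=23.7e6)
        assert round(adj.factor, 2) == 1.06

    def test_division_example(self):
        adj = DepthAdjustment(mapped_a=100.0, mapped_b=106.0)
        assert adj.adjust(106.0) == pytest.approx(100.0)

    def test_equal_depths_identity(self):
        adj = DepthAdjustment(mapped_a=5e6, mapped_b=5e6)
        assert adj.factor == 1.0
        e = adjust_depth({"g": expr(xi=7, xa=3, total=10)}, adj)["g"]
        assert e.adjusted_xi == 7 and e.adjusted_xa == 3

    def test_raw_counts_preserved(self):
        adj = DepthAdjustment(mapped_a=1e6, mapped_b=2e6)
        e = adjust_depth({"g": expr(xi=10, xa=4, total=14)}, adj)["g"]
        assert e.snp_reads_xi == 10
        assert e.adjusted_xi == pytest.approx(5.0)

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValueError):
            DepthAdjustment(mapped_a=0, mapped_b=1e6)


class TestRatio:
    def test_headline_ratio(self):
        assert xi_xa_ratio(expr(xi=16, xa=100)) == pytest.approx(0.16)

    def test_zero_xi(self):
        assert xi_xa_ratio(expr(xi=0, xa=50)) == 0.0

    def test_zero_xa_undefined(self):
        assert np.isnan(xi_xa_ratio(expr(xi=5, xa=0)))

    def test_uses_adjusted_when_available(self):
        e = adjust_depth({"g": expr(xi=32, xa=100)}, DepthAdjustment(1e6, 2e6))["g"]
        assert xi_xa_ratio(e) == pytest.approx(0.32)

    def test_simulated_skew_recovery(self, genome_pair, small_config, alignments):
        from xallele.reads import classify_alignments

        reference, snps = genome_pair
        classified = [
            r for r in classify_alignments(((a, "reference") for a in alignments), snps)
            if r.chrom == "chrX"
        ]
        whole_x = GeneModel(
            "x_locus", "chrX", "+", 0, ((0, len(reference["chrX"])),), "X", "subject"
        )
        out, _ = count_gene_alleles(
            classified, [whole_x], xi_allele="alt", total_mapped_reads=len(classified)
        )
        ratio = xi_xa_ratio(out["x_locus"])
        # Xi fraction 0.16 -> xi/xa = 0.16/0.84 = 0.190, binomial noise on ~700 reads
        assert ratio == pytest.approx(0.16 / 0.84, abs=0.05)


class TestClassification:
    def make_sets(self):
        genes = [
            GeneModel("x1", "chrX", "+", 0, ((0, 1000),), "X", "escape"),
            GeneModel("x2", "chrX", "+", 5000, ((5000, 6000),), "X", "subject"),
            GeneModel("x3", "chrX", "+", 9000, ((9000, 10000),), "X", "subject"),
            GeneModel("a1", "chr1", "+", 0, ((0, 1000),), "autosome", "unknown"),
        ]
        mapped = 10_000_000
        ex_a = {
            "x1": expr("x1", xi=10, xa=100, total=500, rpkm=3.0, mapped=mapped),
            "x2": expr("x2", xi=1, xa=200, total=400, rpkm=2.0, mapped=mapped),
            "x3": expr("x3", xi=0, xa=50, total=100, rpkm=0.5, mapped=mapped),
            "a1": expr("a1", xi=0, xa=0, total=800, rpkm=4.0, mapped=mapped),
        }
        ex_b = {
            "x1": expr("x1", xi=11, xa=105, total=520, rpkm=3.1, mapped=mapped),
            "x2": expr("x2", xi=1, xa=210, total=150, rpkm=0.9, mapped=mapped),
            "x3": expr("x3", xi=0, xa=60, total=120, rpkm=0.6, mapped=mapped),
            "a1": expr("a1", xi=0, xa=0, total=1600, rpkm=8.0, mapped=mapped),
        }
        return genes, ex_a, ex_b

    def test_rpkm_filter_excludes_low_genes(self):
        genes, a, b = self.make_sets()
        out = classify_genes(a, b, genes)
        assert "x3" not in out.subset1 + out.subset2
        assert set(out.calls["gene_id"]) == {"x1", "x2", "a1"}

    def test_srpm_subset_partition(self):
        genes, a, b = self.make_sets()
        out = classify_genes(a, b, genes)
        # x1 has srpm_xi = 10 reads / 10 M * 1e7 = 10 >= 5 -> subset1
        assert out.subset1 == ["x1"]
        assert out.subset2 == ["x2"]
        assert set(out.subset1).isdisjoint(out.subset2)

    def test_srpm_in_either_condition_qualifies(self):
        genes, a, b = self.make_sets()
        a["x2"] = expr("x2", xi=6, xa=200, total=400, rpkm=2.0)  # control only
        out = classify_genes(a, b, genes)
        assert "x2" in out.subset1

    def test_significant_doubling_called_up(self):
        genes, a, b = self.make_sets()
        out = classify_genes(a, b, genes)
        row = out.calls.set_index("gene_id").loc["a1"]
        assert row["fold_change"] == pytest.approx(2.0)
        assert row["direction@1.25"] == "up"
        assert row["direction@2"] == "unchanged"  # fold == cutoff, not >

    def test_down_call(self):
        genes, a, b = self.make_sets()
        out = classify_genes(a, b, genes)
        row = out.calls.set_index("gene_id").loc["x2"]
        assert row["fold_change"] == pytest.approx(150 / 400)
        assert row["direction@1.25"] == "down"

    def test_group_summary_percentages(self):
        # the paper-scale arithmetic: 33/342 -> 10%, 17/342 -> 5%
        assert group_percent(33, 342) == 10
        assert group_percent(17, 342) == 5

    def test_empty_expressed_set_errors(self):
        genes, a, b = self.make_sets()
        with pytest.raises(ValueError, match="expression filter"):
            classify_genes(a, b, genes, rpkm_min=100.0)

    def test_fold_change_depth_invariance(self):
        # multiplying both library depths by a constant leaves fold changes unchanged
        genes, a, b = self.make_sets()
        out1 = classify_genes(a, b, genes)
        for d in (a, b):
            for g in d.values():
                g.total_mapped_reads *= 3
        out2 = classify_genes(a, b, genes)
        np.testing.assert_allclose(out1.calls["fold_change"], out2.calls["fold_change"])


class TestParameterRecovery:
    def test_unbiased_xi_fraction_estimates(self):
        # simulated SNP-read pairs across genes at known Xi fractions
        rng = np.random.default_rng(17)
        for true_frac in (0.0, 0.05, 0.16, 0.5):
            estimates = []
            for _ in range(200):
                n = 100 * 20  # ~100x coverage over ~20 informative SNP sites
                xi = rng.binomial(n, true_frac)
                e = expr(xi=xi, xa=n - xi)
                ratio = xi_xa_ratio(e)
                estimates.append(ratio / (1 + ratio))  # back to a fraction
            assert abs(np.mean(estimates) - true_frac) < 0.01
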