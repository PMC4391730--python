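import numpy as np
import pandas as pd
import pysam
import pytest

from xallele import synthetic
from xallele.reads import (
    Category,
    FilterPolicy,
    classify_alignments,
    classify_read,
    filter_alignments,
    reconcile_dual_alignments,
)
from xallele.snps import SnpTable


def table(rows):
    return SnpTable(pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]))


HEADER = pysam.AlignmentHeader.from_references(["chr1", "chrX"], [100_000, 100_000])


def make_aln(
    name="r1", chrom="chr1", start=0, seq="ACGT" * 5, mapq=60, *,
    flag=0, cigar=None,
):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = HEADER.get_tid(chrom)
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = cigar or f"{len(seq)}M"
    return a


class TestFilter:
    def test_mapq_at_threshold_retained(self):
        assert len(filter_alignments([make_aln(mapq=30)], FilterPolicy(mapq_min=30))) == 1

    def test_mapq_below_threshold_dropped(self):
        assert filter_alignments([make_aln(mapq=29)], FilterPolicy(mapq_min=30)) == []

    def test_low_mapq_whitelisted_gene_retained(self):
        policy = FilterPolicy(mapq_min=30, low_mapq_whitelist={"geneA": ("chr1", 0, 50)})
        assert len(filter_alignments([make_aln(mapq=5, start=10)], policy)) == 1

    def test_low_mapq_outside_whitelist_dropped(self):
        policy = FilterPolicy(mapq_min=30, low_mapq_whitelist={"geneA": ("chr1", 0, 5)})
        assert filter_alignments([make_aln(mapq=5, start=10)], policy) == []

    def test_secondary_and_supplementary_dropped(self):
        assert filter_alignments([make_aln(flag=256), make_aln(flag=2048)], FilterPolicy()) == []

    def test_unmapped_only_warns(self):
        a = make_aln()
        a.is_unmapped = True
        with pytest.warns(UserWarning, match="unmapped"):
            assert filter_alignments([a], FilterPolicy()) == []

    def test_negative_mapq_min_rejected(self):
        with pytest.raises(ValueError):
            FilterPolicy(mapq_min=-1)


class TestClassify:
    def test_single_ref_snp(self):
        snps = table([("chr1", 5, "A", "G")])  # 0-based 4
        aln = make_aln(seq="TTTTATTTTT", start=0)
        assert classify_read(aln, snps).category is Category.REF

    def test_single_alt_snp(self):
        snps = table([("chr1", 5, "A", "G")])
        aln = make_aln(seq="TTTTGTTTTT", start=0)
        assert classify_read(aln, snps).category is Category.ALT

    def test_both_alleles_ambiguous(self):
        snps = table([("chr1", 2, "A", "G"), ("chr1", 8, "C", "T")])
        aln = make_aln(seq="TATTTTTTTT", start=0)  # pos1=A (ref), pos7=T (alt)
        r = classify_read(aln, snps)
        assert (r.n_ref_snps, r.n_alt_snps) == (1, 1)
        assert r.category is Category.AMBIGUOUS

    def test_no_snps_ambiguous(self):
        snps = table([("chr1", 500, "A", "G")])
        r = classify_read(make_aln(start=0), snps)
        assert r.category is Category.AMBIGUOUS
        assert (r.n_ref_snps, r.n_alt_snps, r.n_other_snps) == (0, 0, 0)

    def test_neither_allele_counts_as_other(self):
        snps = table([("chr1", 5, "A", "G")])
        aln = make_aln(seq="TTTTCTTTTT", start=0)  # C matches neither
        r = classify_read(aln, snps)
        assert r.n_other_snps == 1
        assert r.category is Category.AMBIGUOUS

    def test_other_base_does_not_disqualify_ref(self):
        snps = table([("chr1", 2, "A", "G"), ("chr1", 5, "A", "G")])
        aln = make_aln(seq="TATTCTTTTT", start=0)  # pos1 ref, pos4 neither
        r = classify_read(aln, snps)
        assert (r.n_ref_snps, r.n_other_snps) == (1, 1)
        assert r.category is Category.REF

    def test_chrom_absent_from_table_is_ambiguous(self):
        snps = table([("chrX", 5, "A", "G")])
        assert classify_read(make_aln(chrom="chr1"), snps).category is Category.AMBIGUOUS

    def test_soft_clipped_bases_never_count(self):
        # SNP at 0-based ref pos 2; the aligned base there is seq[4]='A' (ref
        # allele), while the clipped prefix holds alt-allele G's that must not count
        snps = table([("chr1", 3, "A", "G")])
        aln = make_aln(seq="GGGGATTTTT", start=2, cigar="4S6M")
        r = classify_read(aln, snps)
        assert (r.n_ref_snps, r.n_alt_snps, r.n_other_snps) == (1, 0, 0)
        assert r.category is Category.REF

    def test_deletion_skips_snp(self):
        snps = table([("chr1", 4, "A", "G")])  # 0-based 3
        aln = make_aln(seq="TTTTTT", start=0, cigar="3M2D3M")  # ref pos 3-4 deleted
        r = classify_read(aln, snps)
        assert (r.n_ref_snps, r.n_alt_snps, r.n_other_snps) == (0, 0, 0)

    def test_base_quality_floor(self):
        snps = table([("chr1", 5, "A", "G")])
        aln = make_aln(seq="TTTTATTTTT", start=0)
        aln.query_qualities = pysam.qualitystring_to_array("!" * 10)  # Q0 everywhere
        assert classify_read(aln, snps, min_baseq=20).category is Category.AMBIGUOUS
        assert classify_read(aln, snps, min_baseq=0).category is Category.REF


class TestSoftClipExplicit:
    def test_clip_over_snp_uninformative(self):
        # SNP at 0-based 1 falls inside the clipped prefix -> not evaluated
        snps = table([("chr1", 2, "A", "G")])
        aln = make_aln(seq="GAGGTTTTTT", start=4, cigar="4S6M")
        r = classify_read(aln, snps)
        assert (r.n_ref_snps, r.n_alt_snps, r.n_other_snps) == (0, 0, 0)


class TestReconcile:
    def test_passes_only_in_pseudo(self):
        res = reconcile_dual_alignments([make_aln(mapq=5)], [make_aln(mapq=60)], FilterPolicy())
        assert [(g, a.mapping_quality) for a, g in res.merged] == [("pseudo", 60)]

    def test_equal_mapq_same_locus_prefers_reference(self):
        res = reconcile_dual_alignments([make_aln(mapq=60)], [make_aln(mapq=60)], FilterPolicy())
        assert [g for _, g in res.merged] == ["reference"]

    def test_higher_mapq_wins(self):
        res = reconcile_dual_alignments([make_aln(mapq=60)], [make_aln(mapq=40)], FilterPolicy())
        assert [g for _, g in res.merged] == ["reference"]

    def test_fails_in_both_dropped(self):
        res = reconcile_dual_alignments([make_aln(mapq=5)], [make_aln(mapq=5)], FilterPolicy())
        assert res.merged == []

    def test_equal_mapq_discordant_coordinates_reported(self):
        res = reconcile_dual_alignments(
            [make_aln(mapq=60, start=0)], [make_aln(mapq=60, start=500)], FilterPolicy()
        )
        assert res.merged == []
        assert res.discordant == ["r1"]


class TestSimulationOracle:
    def test_perfect_classification_on_error_free_reads(self, genome_pair, small_config, sim_reads, alignments):
        _, snps = genome_pair
        reads, truth = sim_reads
        classified = classify_alignments(((a, "reference") for a in alignments), snps)
        assert len(classified) == len(reads)
        for r in classified:
            true_hap = truth.reads[r.read_id][0]
            if r.n_ref_snps + r.n_alt_snps >= 1:
                expected = Category.ALT if true_hap else Category.REF
                assert r.category is expected
            else:
                assert r.category is Category.AMBIGUOUS

    def test_partition_conserved(self, genome_pair, alignments):
        _, snps = genome_pair
        classified = classify_alignments(((a, "reference") for a in alignments), snps)
        by_cat = {c: 0 for c in Category}
        for r in classified:
            by_cat[r.category] += 1
        assert sum(by_cat.values()) == len(classified)

    def test_allele_swap_symmetry(self, genome_pair, alignments):
        _, snps = genome_pair
        fwd = classify_alignments(((a, "reference") for a in alignments), snps)
        rev = classify_alignments(((a, "reference") for a in alignments), snps.swapped())
        n = {c: sum(1 for r in fwd if r.category is c) for c in Category}
        m = {c: sum(1 for r in rev if r.category is c) for c in Category}
        assert n[Category.REF] == m[Category.ALT]
        assert n[Category.ALT] == m[Category.REF]
        assert n[Category.AMBIGUOUS] == m[Category.AMBIGUOUS]

    def test_errors_only_degrade_within_expected_bound(self):
        # with per-base errors, informative reads may flip to AMBIGUOUS (or
        # rarely across) at a rate bounded by the per-base error over SNPs
        cfg = synthetic.SimConfig(
            genome_length=30_000, n_chromosomes=1, coverage=10.0, error_rate=0.01, seed=21
        )
        ref, snps = synthetic.simulate_genome_pair(cfg)
        reads, truth = synthetic.simulate_reads(ref, snps, cfg)
        header = synthetic.alignment_header({c: len(s) for c, s in ref.items()})
        alns = synthetic.reads_to_alignments(reads, header)
        classified = classify_alignments(((a, "reference") for a in alns), snps)
        wrong = informative = 0
        for r in classified:
            n_covered = r.n_ref_snps + r.n_alt_snps + r.n_other_snps
            if n_covered == 0:
                continue
            informative += 1
            expected = Category.ALT if truth.reads[r.read_id][0] else Category.REF
            if r.category is not expected:
                wrong += 1
        # each read covers ~ read_length*snp_rate SNPs; a flip needs >=1 errored SNP base
        p_affected = 1 - (1 - cfg.error_rate) ** (cfg.read_length * cfg.snp_rate * 3)
        assert informative > 0
        assert wrong / informative <= p_affected + 0.02


class TestTaggedOutput:
    def test_tagged_sam_written(self, tmp_path, genome_pair, alignments):
        from xallele.reads import write_tagged_sam

        _, snps = genome_pair
        pairs = [(a, "reference") for a in alignments[:50]]
        classified = classify_alignments(pairs, snps)
        path = tmp_path / "tagged.sam"
        write_tagged_sam(pairs, classified, path)
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            recs = list(fh)
        assert len(recs) == 50
        assert all(r.get_tag("XL") in ("REF", "ALT", "AMBIGUOUS") for r in recs)
        assert all(r.get_tag("XG") == "reference" for r in recs)
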