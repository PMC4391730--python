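"""Alignment filtering and SNP-based allelic read classification.

Reads aligned to either haplotype genome are filtered on mapping quality
and segregated into three categories by the diagnostic SNP bases they
carry: REF (only reference-strain alleles), ALT (only alternate-strain
alleles) and AMBIGUOUS (no SNP covered, both allele classes present, or
only bases matching neither allele).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from xallele.snps import SnpTable


class Category(str, Enum):
    REF = "REF"
    ALT = "ALT"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class ClassifiedRead:
    """An alignment annotated with its allelic category."""

    read_id: str
    chrom: str
    start: int  # 0-based leftmost aligned base
    length: int  # aligned reference span
    strand: str
    mapq: int
    genome_of_alignment: str  # "reference" | "pseudo"
    n_ref_snps: int
    n_alt_snps: int
    n_other_snps: int

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def category(self) -> Category:
        if self.n_ref_snps >= 1 and self.n_alt_snps == 0:
            return Category.REF
        if self.n_alt_snps >= 1 and self.n_ref_snps == 0:
            return Category.ALT
        return Category.AMBIGUOUS


@dataclass(frozen=True)
class FilterPolicy:
    """Retention policy for alignments.

    ``low_mapq_whitelist`` maps exempt gene ids to (chrom, start, end)
    intervals; reads overlapping any of them are retained regardless of
    MAPQ (used for genes whose exons share sequence with another locus).
    """

    mapq_min: int = 30
    require_unique: bool = True
    low_mapq_whitelist: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")

    def _whitelisted(self, chrom: str, start: int, end: int) -> bool:
        for wchrom, wstart, wend in self.low_mapq_whitelist.values():
            if wchrom == chrom and start < wend and end > wstart:
                return True
        return False


def filter_alignments(
    alignments: Iterable[pysam.AlignedSegment],
    policy: FilterPolicy = FilterPolicy(),
) -> list[pysam.AlignedSegment]:
    """Keep mapped, primary, non-supplementary alignments passing MAPQ.

    A read overlapping a whitelisted gene interval is kept even below
    the MAPQ threshold.  Emits a warning when every input record was
    unmapped.
    """
    kept: list[pysam.AlignedSegment] = []
    saw_any = False
    saw_mapped = False
    for aln in alignments:
        saw_any = True
        if aln.is_unmapped:
            continue
        saw_mapped = True
        if aln.is_secondary or aln.is_supplementary:
            continue
        if aln.mapping_quality >= policy.mapq_min or policy._whitelisted(
            aln.reference_name, aln.reference_start, aln.reference_end
        ):
            kept.append(aln)
    if saw_any and not saw_mapped:
        warnings.warn("input contained only unmapped reads; nothing retained")
    return kept


def classify_read(
    read: pysam.AlignedSegment,
    snps: SnpTable,
    *,
    genome_of_alignment: str = "reference",
    min_baseq: int = 0,
) -> ClassifiedRead:
    """Classify one retained alignment by its bases at covered SNPs.

    Only aligned (CIGAR-matched) bases are evaluated; soft-clipped bases
    never count.  A base equal to the ref allele increments n_ref_snps,
    equal to the alt allele n_alt_snps, matching neither n_other_snps
    (uninformative).  Reads on chromosomes absent from the SNP table
    cover no SNPs and are AMBIGUOUS.
    """
    chrom = read.reference_name
    start, end = read.reference_start, read.reference_end
    pos, ref_alleles, alt_alleles = snps.in_interval(chrom, start, end)
    n_ref = n_alt = n_other = 0
    if len(pos):
        lookup = {int(p): (r, a) for p, r, a in zip(pos, ref_alleles, alt_alleles)}
        seq = read.query_sequence
        quals = read.query_qualities
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            alleles = lookup.get(rpos)
            if alleles is None:
                continue
            if min_baseq and quals is not None and quals[qpos] < min_baseq:
                continue
            base = seq[qpos].upper()
            if base == alleles[0]:
                n_ref += 1
            elif base == alleles[1]:
                n_alt += 1
            else:
                n_other += 1
    return ClassifiedRead(
        read_id=read.query_name,
        chrom=chrom,
        start=start,
        length=end - start,
        strand="-" if read.is_reverse else "+",
        mapq=read.mapping_quality,
        genome_of_alignment=genome_of_alignment,
        n_ref_snps=n_ref,
        n_alt_snps=n_alt,
        n_other_snps=n_other,
    )


def classify_alignments(
    alignments: Iterable[tuple[pysam.AlignedSegment, str]],
    snps: SnpTable,
    *,
    min_baseq: int = 0,
) -> list[ClassifiedRead]:
    """Classify (alignment, genome_label) pairs; see :func:`classify_read`."""
    return [
        classify_read(aln, snps, genome_of_alignment=genome, min_baseq=min_baseq)
        for aln, genome in alignments
    ]


@dataclass
class DualAlignmentResult:
    """Outcome of merging per-genome alignment streams: one record per read."""

    merged: list[tuple[pysam.AlignedSegment, str]]
    discordant: list[str]  # read ids dropped for equal-MAPQ coordinate conflicts


def reconcile_dual_alignments(
    aln_ref: Iterable[pysam.AlignedSegment],
    aln_pseudo: Iterable[pysam.AlignedSegment],
    policy: FilterPolicy = FilterPolicy(),
) -> DualAlignmentResult:
    """Merge reference- and pseudo-genome alignments into one record per read.

    A read passing the filter in at least one genome is kept once.  When
    it passes in both, the higher-MAPQ alignment wins; on an exact MAPQ
    tie the coordinates must agree (the two genomes share coordinates)
    and the reference-genome record is used.  Ties with disagreeing
    coordinates go to the discordant report and the read is dropped.
    """
    ref_by_id = {a.query_name: a for a in filter_alignments(aln_ref, policy)}
    pseudo_by_id = {a.query_name: a for a in filter_alignments(aln_pseudo, policy)}
    merged: list[tuple[pysam.AlignedSegment, str]] = []
    discordant: list[str] = []
    for read_id, ref_aln in ref_by_id.items():
        pseudo_aln = pseudo_by_id.pop(read_id, None)
        if pseudo_aln is None:
            merged.append((ref_aln, "reference"))
        elif pseudo_aln.mapping_quality > ref_aln.mapping_quality:
            merged.append((pseudo_aln, "pseudo"))
        elif pseudo_aln.mapping_quality < ref_aln.mapping_quality:
            merged.append((ref_aln, "reference"))
        else:
            same_locus = (
                ref_aln.reference_name == pseudo_aln.reference_name
                and ref_aln.reference_start == pseudo_aln.reference_start
            )
            if same_locus:
                merged.append((ref_aln, "reference"))
            else:
                discordant.append(read_id)
    merged.extend((a, "pseudo") for a in pseudo_by_id.values())
    return DualAlignmentResult(merged=merged, discordant=discordant)


def write_classified_tsv(reads: Sequence[ClassifiedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tchrom\tstart\tlength\tstrand\tmapq\tgenome\t"
            "n_ref_snps\tn_alt_snps\tn_other_snps\tcategory\n"
        )
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.length}\t{r.strand}\t{r.mapq}\t"
                f"{r.genome_of_alignment}\t{r.n_ref_snps}\t{r.n_alt_snps}\t{r.n_other_snps}\t"
                f"{r.category.value}\n"
            )


def write_tagged_sam(
    alignments: Sequence[tuple[pysam.AlignedSegment, str]],
    classified: Sequence[ClassifiedRead],
    path,
) -> None:
    """Write alignments with allele-category (XL) and genome (XG) tags."""
    if not alignments:
        raise ValueError("nothing to write")
    category_of = {r.read_id: r.category.value for r in classified}
    header = alignments[0][0].header
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln, genome in alignments:
            aln.set_tag("XL", category_of.get(aln.query_name, Category.AMBIGUOUS.value))
            aln.set_tag("XG", genome)
            out.write(aln)


def category_counts(reads: Iterable[ClassifiedRead]) -> dict[str, int]:
    counts = {c.value: 0 for c in Category}
    for r in reads:
        counts[r.category.value] += 1
    return counts
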