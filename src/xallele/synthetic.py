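"""Simulator for toy F1-hybrid datasets with ground truth.

Generates a two-haplotype genome pair (reference + SNP table), reads
with true haplotype tags emitted directly as alignments (no aligner),
TSS-anchored enrichment signal with an optional X-specific knockdown
effect, and per-nucleus Bernoulli association outcomes.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from xallele.genes import GeneModel
from xallele.pseudogenome import build_pseudogenome
from xallele.signalio import GenomicSignal
from xallele.snps import SnpTable

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated F1-hybrid experiment."""

    genome_length: int = 100_000
    n_chromosomes: int = 2  # chr1..chr(n-1) plus chrX
    snp_rate: float = 1 / 75
    read_length: int = 100
    coverage: float = 10.0
    allelic_skew: float = 0.5  # default alternate-haplotype fraction
    error_rate: float = 0.0
    seed: int = 0
    mapq: int = 60

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if not (0.0 <= self.snp_rate < 1.0):
            raise ValueError("snp_rate must be in [0, 1)")
        if not (0.0 <= self.allelic_skew <= 1.0):
            raise ValueError("allelic_skew must be in [0, 1]")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length < 1 or self.coverage < 0:
            raise ValueError("read_length must be >= 1 and coverage >= 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes)] + ["chrX"]


@dataclass
class GroundTruth:
    """Truth tags for everything the simulator emitted."""

    reads: dict[str, tuple[int, str, int]] = field(default_factory=dict)  # id -> (hap, chrom, pos)
    gene_ratios: dict[str, float] = field(default_factory=dict)
    nuclei: pd.DataFrame | None = None


def simulate_genome_pair(config: SimConfig) -> tuple[dict[str, str], SnpTable]:
    """Random reference genome plus a SNP table defining the second haplotype.

    SNP positions are Bernoulli(snp_rate) per base; the alternate allele
    is drawn uniformly from the three non-reference bases, so ref != alt
    at every SNP by construction.
    """
    rng = np.random.default_rng(config.seed)
    reference: dict[str, str] = {}
    rows = []
    for chrom in config.chrom_names:
        base_idx = rng.integers(0, 4, size=config.genome_length)
        seq = "".join(_BASES[base_idx])
        reference[chrom] = seq
        mask = rng.random(config.genome_length) < config.snp_rate
        positions = np.nonzero(mask)[0]
        shifts = rng.integers(1, 4, size=len(positions))
        for p, s in zip(positions, shifts):
            ref_b = seq[p]
            alt_b = _BASES[(base_idx[p] + s) % 4]
            rows.append((chrom, int(p) + 1, ref_b, alt_b))
    snps = SnpTable(pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]))
    return reference, snps


@dataclass(frozen=True)
class SimRead:
    """One simulated single-end read with its truth tag."""

    read_id: str
    chrom: str
    pos: int  # 0-based alignment start (true position)
    haplotype: int  # 0 = reference strain, 1 = alternate strain
    sequence: str
    mapq: int


def simulate_reads(
    reference: Mapping[str, str],
    snps: SnpTable,
    config: SimConfig,
    region_skew: Mapping[str, float] | None = None,
) -> tuple[list[SimRead], GroundTruth]:
    """Draw reads from the two haplotypes at per-chromosome skews.

    The number of reads per chromosome is coverage * length /
    read_length (rounded); each read's haplotype is Bernoulli with the
    chromosome's skew (probability of the alternate haplotype), its
    start uniform, and its sequence copied from the source haplotype
    with independent per-base substitution errors.
    """
    region_skew = dict(region_skew or {})
    for chrom in region_skew:
        if chrom not in reference:
            raise ValueError(f"region_skew names unknown chromosome {chrom}")
    for chrom, seq in reference.items():
        if config.read_length > len(seq):
            raise ValueError(f"read_length {config.read_length} exceeds {chrom} length {len(seq)}")
    pseudo = build_pseudogenome(reference, snps)
    rng = np.random.default_rng(config.seed + 1)  # independent of genome stream
    reads: list[SimRead] = []
    truth = GroundTruth()
    for chrom, seq in reference.items():
        skew = region_skew.get(chrom, config.allelic_skew)
        n_reads = round(config.coverage * len(seq) / config.read_length)
        haps = (rng.random(n_reads) < skew).astype(int)
        starts = rng.integers(0, len(seq) - config.read_length + 1, size=n_reads)
        for k in range(n_reads):
            source = pseudo[chrom] if haps[k] else seq
            frag = source[starts[k] : starts[k] + config.read_length]
            if config.error_rate > 0:
                err = np.nonzero(rng.random(config.read_length) < config.error_rate)[0]
                if len(err):
                    chars = list(frag)
                    for i in err:
                        cur = "ACGT".index(chars[i])
                        chars[i] = _BASES[(cur + rng.integers(1, 4)) % 4]
                    frag = "".join(chars)
            read_id = f"{chrom}_r{k:07d}"
            reads.append(SimRead(read_id, chrom, int(starts[k]), int(haps[k]), frag, config.mapq))
            truth.reads[read_id] = (int(haps[k]), chrom, int(starts[k]))
    return reads, truth


def alignment_header(chrom_lengths: Mapping[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_references(
        list(chrom_lengths.keys()), list(chrom_lengths.values())
    )


def reads_to_alignments(
    reads: Sequence[SimRead], header: pysam.AlignmentHeader
) -> list[pysam.AlignedSegment]:
    """Materialize simulated reads as alignment records at true coordinates."""
    out = []
    for r in reads:
        a = pysam.AlignedSegment(header)
        a.query_name = r.read_id
        a.query_sequence = r.sequence
        a.flag = 0
        a.reference_id = header.get_tid(r.chrom)
        a.reference_start = r.pos
        a.mapping_quality = r.mapq
        a.cigarstring = f"{len(r.sequence)}M"
        a.set_tag("XH", r.haplotype)
        a.set_tag("XP", r.pos)
        out.append(a)
    return out


def write_sam(reads: Sequence[SimRead], chrom_lengths: Mapping[str, int], path: str | Path) -> None:
    header = alignment_header(chrom_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in reads_to_alignments(reads, header):
            out.write(a)


def simulate_genes(
    n_x: int,
    n_autosomal: int,
    *,
    gene_length: int = 3000,
    spacing: int = 10_000,
    first_tss: int = 5_000,
    escape_fraction: float = 0.0,
    x_chrom: str = "chrX",
    autosome: str = "chr1",
    seed: int = 0,
) -> list[GeneModel]:
    """Evenly spaced single-exon genes with random strands.

    X-linked genes get xci_status "subject" except a leading
    ``escape_fraction`` which are "escape".  Spacing must exceed twice
    the metagene span so per-gene signal windows never overlap.
    """
    rng = np.random.default_rng(seed)
    genes = []
    n_escape = round(escape_fraction * n_x)
    for chrom, cls, n in ((x_chrom, "X", n_x), (autosome, "autosome", n_autosomal)):
        for i in range(n):
            anchor = first_tss + i * spacing
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tss, exons = anchor, ((anchor, anchor + gene_length),)
            else:
                tss, exons = anchor, ((anchor - gene_length + 1, anchor + 1),)
            status = "unknown"
            if cls == "X":
                status = "escape" if i < n_escape else "subject"
            genes.append(
                GeneModel(f"{cls}_gene_{i:05d}", chrom, strand, tss, exons, cls, status)
            )
    return genes


def simulate_enrichment(
    genes: Sequence[GeneModel],
    x_effect: float,
    seed: int = 0,
    *,
    bin_size: int = 100,
    span: int = 3000,
    mu_x: float = 3.0,
    mu_autosome: float = 1.0,
    mu_escape: float = 0.2,
    gene_sd: float = 0.5,
    bin_sd: float = 0.5,
) -> tuple[GenomicSignal, GenomicSignal]:
    """Paired control/knockdown enrichment signal around every TSS.

    Each gene draws a baseline level (X-subject genes high, escape genes
    low, autosomes intermediate); in the knockdown track the baseline of
    X-linked non-escape genes is multiplied by ``1 - x_effect`` while
    autosomes and escape genes are unchanged in expectation.  Per-bin
    noise is independent between the two tracks.
    """
    if not (0.0 <= x_effect <= 1.0):
        raise ValueError("x_effect must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_bins = 2 * span // bin_size
    ctrl: dict[str, list] = {}
    kd: dict[str, list] = {}
    for gene in genes:
        if gene.chrom_class == "X":
            mu = mu_escape if gene.xci_status == "escape" else mu_x
        else:
            mu = mu_autosome
        base = max(0.05, rng.normal(mu, gene_sd))
        affected = gene.chrom_class == "X" and gene.xci_status != "escape"
        base_kd = base * (1.0 - x_effect) if affected else base
        starts = gene.tss - span + bin_size * np.arange(n_bins)
        keep = starts >= 0
        starts = starts[keep]
        vals_c = base + rng.normal(0.0, bin_sd, size=n_bins)[keep]
        vals_k = base_kd + rng.normal(0.0, bin_sd, size=n_bins)[keep]
        ctrl.setdefault(gene.chrom, []).append((starts, vals_c))
        kd.setdefault(gene.chrom, []).append((starts, vals_k))

    def assemble(per_chrom: dict[str, list]) -> GenomicSignal:
        intervals = {}
        for chrom, parts in per_chrom.items():
            starts = np.concatenate([p[0] for p in parts])
            values = np.concatenate([p[1] for p in parts])
            intervals[chrom] = (starts, starts + bin_size, values)
        return GenomicSignal(intervals)

    return assemble(ctrl), assemble(kd)


def simulate_fish(n_nuclei: int, p_allele: float, ploidy: int = 2, seed: int = 0) -> pd.DataFrame:
    """Per-nucleus independent Bernoulli(p_allele) association per allele."""
    if not (0.0 <= p_allele <= 1.0):
        raise ValueError("p_allele must be in [0, 1]")
    rng = np.random.default_rng(seed)
    outcomes = rng.random((n_nuclei, ploidy)) < p_allele
    df = pd.DataFrame(
        outcomes, columns=[f"allele_{i}" for i in range(ploidy)]
    )
    df.insert(0, "nucleus_id", np.arange(n_nuclei))
    df["n_associated"] = outcomes.sum(axis=1)
    df["any_associated"] = outcomes.any(axis=1)
    return df
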