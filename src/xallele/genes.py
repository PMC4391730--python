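"""Gene models: TSS, strand, exons and chromosome class.

Genes are loaded from BED12 or from a simple TSV; internal coordinates
are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

ChromClass = Literal["X", "autosome"]
XciStatus = Literal["subject", "escape", "unknown"]


@dataclass(frozen=True)
class GeneModel:
    """One gene; ``exons`` are sorted non-overlapping 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]
    chrom_class: ChromClass = "autosome"
    xci_status: XciStatus = "unknown"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if self.exons:
            expect = self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1
            if self.tss != expect:
                raise ValueError(
                    f"{self.gene_id}: tss {self.tss} is not the 5' end of the "
                    f"first exon on strand {self.strand} (expected {expect})"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def tss_relative(self, pos: int) -> int:
        """Strand-oriented offset of a genomic position from the TSS."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


def read_genes(path: str | Path) -> list[GeneModel]:
    """Load genes from BED12 or TSV.

    BED12 columns follow the UCSC convention; chrom_class is inferred
    from the chromosome name ("X"/"chrX" -> X).  The TSV dialect has a
    header line: gene_id, chrom, strand, tss, exons (comma-separated
    start-end pairs), chrom_class, xci_status.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        return _read_tsv(path)
    return _read_bed12(path)


def _read_tsv(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            exons = tuple(
                tuple(int(x) for x in pair.split("-")) for pair in parts[idx["exons"]].split(",")
            )
            genes.append(
                GeneModel(
                    gene_id=parts[idx["gene_id"]],
                    chrom=parts[idx["chrom"]],
                    strand=parts[idx["strand"]],
                    tss=int(parts[idx["tss"]]),
                    exons=exons,
                    chrom_class=parts[idx["chrom_class"]] if "chrom_class" in idx else _infer_class(parts[idx["chrom"]]),
                    xci_status=parts[idx["xci_status"]] if "xci_status" in idx else "unknown",
                )
            )
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.rstrip("\n").split("\t")
            chrom, start, end, name, _score, strand = p[0], int(p[1]), int(p[2]), p[3], p[4], p[5]
            if len(p) >= 12:
                sizes = [int(x) for x in p[10].rstrip(",").split(",")]
                starts = [int(x) for x in p[11].rstrip(",").split(",")]
                exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            else:
                exons = ((start, end),)
            tss = start if strand == "+" else end - 1
            genes.append(
                GeneModel(name, chrom, strand, tss, exons, chrom_class=_infer_class(chrom))
            )
    return genes


def _infer_class(chrom: str) -> ChromClass:
    return "X" if chrom.removeprefix("chr").upper() == "X" else "autosome"


def write_genes_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\texons\tchrom_class\txci_status\n")
        for g in genes:
            exons = ",".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{exons}\t{g.chrom_class}\t{g.xci_status}\n"
            )
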