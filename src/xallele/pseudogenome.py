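"""Construct the alternate-strain pseudo-genome.

The pseudo-genome is the reference with the alternate allele substituted
at every SNP; because only single-base substitutions are allowed, both
genomes share coordinates exactly, which is what lets downstream stages
merge alignments against either genome without liftover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from xallele.snps import SnpTable


class SnpReferenceMismatch(ValueError):
    """A SNP's declared reference allele disagrees with the reference base."""


@dataclass
class SnpValidationReport:
    """Accumulated invariant violations of a SnpTable against a reference."""

    missing_chroms: list[str] = field(default_factory=list)
    out_of_bounds: list[tuple[str, int]] = field(default_factory=list)
    ref_mismatches: list[tuple[str, int, str, str]] = field(default_factory=list)  # chrom, pos, expected, found

    @property
    def ok(self) -> bool:
        return not (self.missing_chroms or self.out_of_bounds or self.ref_mismatches)

    def messages(self) -> list[str]:
        out = [f"chromosome {c} absent from reference" for c in self.missing_chroms]
        out += [f"SNP {c}:{p} beyond chromosome end" for c, p in self.out_of_bounds]
        out += [
            f"SNP {c}:{p} declares ref {decl} but reference has {found}"
            for c, p, decl, found in self.ref_mismatches
        ]
        return out


def validate_snps(reference: Mapping[str, str], snps: SnpTable) -> SnpValidationReport:
    """Check a SnpTable against a reference genome (report, never raise).

    Base comparison is case-insensitive.  Duplicate positions and
    non-SNV records are rejected at SnpTable construction, so the report
    covers the reference-dependent invariants only.
    """
    report = SnpValidationReport()
    for chrom in snps.chroms():
        if chrom not in reference:
            report.missing_chroms.append(chrom)
            continue
        seq = reference[chrom]
        pos0, ref_alleles, _alt = snps.for_chrom(chrom)
        for p, declared in zip(pos0, ref_alleles):
            if p >= len(seq):
                report.out_of_bounds.append((chrom, int(p) + 1))
            elif seq[p].upper() != declared:
                report.ref_mismatches.append((chrom, int(p) + 1, declared, seq[p]))
    return report


def build_pseudogenome(reference: Mapping[str, str], snps: SnpTable) -> dict[str, str]:
    """Substitute alternate alleles into the reference.

    Output preserves reference case except at substituted positions,
    which are emitted uppercase.  Any reference-allele mismatch or
    out-of-bounds SNP raises with the offending coordinate.
    """
    report = validate_snps(reference, snps)
    if not report.ok:
        raise SnpReferenceMismatch("; ".join(report.messages()))
    out: dict[str, str] = {}
    for chrom, seq in reference.items():
        pos0, _ref, alt = snps.for_chrom(chrom)
        if len(pos0) == 0:
            out[chrom] = seq
            continue
        chars = list(seq)
        for p, a in zip(pos0, alt):
            chars[p] = a
        out[chrom] = "".join(chars)
    return out
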