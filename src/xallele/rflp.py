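"""In-silico allele-discriminating restriction digest (RFLP).

Given an amplicon spanning a diagnostic SNP and an enzyme recognition
sequence, predict the fragment lengths each allele yields and report
whether the enzyme discriminates the alleles (a cut site created or
destroyed by the SNP).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Amplicon:
    """PCR product carrying one diagnostic SNP (reference-allele sequence)."""

    sequence: str
    snp_offset: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if not (0 <= self.snp_offset < len(seq)):
            raise ValueError("snp_offset outside amplicon")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"amplicon contains non-ACGT bases: {sorted(bad)}")
        if seq[self.snp_offset] != self.ref_allele.upper():
            raise ValueError(
                f"amplicon base at snp_offset is {seq[self.snp_offset]}, "
                f"not the declared ref allele {self.ref_allele}"
            )
        if self.ref_allele.upper() == self.alt_allele.upper():
            raise ValueError("ref and alt alleles are identical")

    @property
    def ref_sequence(self) -> str:
        return self.sequence.upper()

    @property
    def alt_sequence(self) -> str:
        seq = self.ref_sequence
        return seq[: self.snp_offset] + self.alt_allele.upper() + seq[self.snp_offset + 1 :]


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: IUPAC recognition site and top-strand cut offset."""

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self):
        site = self.recognition_site.upper()
        if len(site) < 4:
            raise ValueError(f"{self.name}: site must be >= 4 bases")
        bad = set(site) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC codes {sorted(bad)}")
        if not (0 <= self.cut_offset <= len(site)):
            raise ValueError(f"{self.name}: cut_offset outside site bounds")

    def _pattern(self, site: str) -> re.Pattern:
        return re.compile("".join(f"[{IUPAC[c]}]" for c in site.upper()))


def cut_positions(sequence: str, enzyme: Enzyme) -> list[int]:
    """Double-strand cut coordinates from scanning both strands.

    Each distinct occurrence interval of the recognition site is one
    cut event, even when a palindromic site matches both strands there.
    A forward-only occurrence at i cuts at ``i + cut_offset``, a
    reverse-only occurrence at ``i + len(site) - cut_offset``, and a
    both-strand (palindromic) occurrence at the site midpoint — a
    strand-symmetric convention, so reverse-complementing the sequence
    mirrors the cut list exactly.  Overlapping occurrences each count;
    cuts at the very ends produce no fragmentation and are dropped.
    """
    seq = sequence.upper()
    site = enzyme.recognition_site.upper()
    n = len(site)
    fwd_hits = set(_finditer_overlapping(enzyme._pattern(site), seq))
    rev_hits = set(_finditer_overlapping(enzyme._pattern(revcomp(site)), seq))
    cuts: set[int] = set()
    for i in fwd_hits | rev_hits:
        if i in fwd_hits and i in rev_hits:
            cuts.add(i + n // 2)
        elif i in fwd_hits:
            cuts.add(i + enzyme.cut_offset)
        else:
            cuts.add(i + n - enzyme.cut_offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def _finditer_overlapping(pattern: re.Pattern, seq: str) -> Iterable[int]:
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            return
        yield m.start()
        pos = m.start() + 1


def _fragments(length: int, cuts: Sequence[int]) -> list[int]:
    bounds = [0, *cuts, length]
    return [b - a for a, b in zip(bounds, bounds[1:])]


@dataclass(frozen=True)
class DigestResult:
    enzyme: str
    fragments_ref: tuple[int, ...]
    fragments_alt: tuple[int, ...]

    @property
    def discriminating(self) -> bool:
        return len(self.fragments_ref) != len(self.fragments_alt)


def digest(amplicon: Amplicon, enzyme: Enzyme) -> DigestResult:
    """Digest both allelic sequences; fragment lengths sum to amplicon length."""
    cuts_ref = cut_positions(amplicon.ref_sequence, enzyme)
    cuts_alt = cut_positions(amplicon.alt_sequence, enzyme)
    n = len(amplicon.sequence)
    return DigestResult(
        enzyme=enzyme.name,
        fragments_ref=tuple(_fragments(n, cuts_ref)),
        fragments_alt=tuple(_fragments(n, cuts_alt)),
    )


def resolvability(result: DigestResult) -> int:
    """Gel-resolvability proxy for a discriminating digest.

    The minimum distance between a fragment unique to one allele and the
    nearest fragment length of the other allele: the worst-separated
    diagnostic band limits whether the two digests can be told apart.
    """
    ref, alt = list(result.fragments_ref), list(result.fragments_alt)
    worst = None
    for own, other in ((ref, alt), (alt, ref)):
        diagnostic = [f for f in own if own.count(f) > other.count(f)]
        for f in diagnostic:
            nearest = min((abs(f - o) for o in other), default=f)
            worst = nearest if worst is None else min(worst, nearest)
    return worst if worst is not None else 0


def screen_enzymes(amplicon: Amplicon, enzymes: Sequence[Enzyme]) -> list[tuple[Enzyme, DigestResult]]:
    """Discriminating enzymes ranked by gel resolvability (best first)."""
    hits = []
    for enz in enzymes:
        res = digest(amplicon, enz)
        if res.discriminating:
            hits.append((enz, res))
    hits.sort(key=lambda pair: resolvability(pair[1]), reverse=True)
    return hits


def read_enzymes_tsv(path: str | Path) -> list[Enzyme]:
    """Load enzymes from a TSV of (name, recognition_site, cut_offset)."""
    enzymes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            name, site, off = line.rstrip("\n").split("\t")[:3]
            enzymes.append(Enzyme(name, site, int(off)))
    return enzymes
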