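"""Catalog of single-nucleotide differences between two haplotypes.

The :class:`SnpTable` is the basis of every allelic assignment in the
package: pseudo-genome substitution, read classification and allelic
expression all consume it.  Only single-base substitutions are modelled,
so coordinates are shared between the two haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Snp:
    """One single-nucleotide substitution; ``pos`` is 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str


class SnpTable:
    """Sorted, per-chromosome indexed table of SNVs.

    Positions are stored 1-based (VCF convention) in the public frame;
    internal lookups use 0-based arrays.  Construction enforces the type
    invariants: single-base alleles, ``ref != alt``, unique sorted
    positions per chromosome.
    """

    def __init__(self, records: pd.DataFrame | list[Snp] | None = None):
        if records is None:
            df = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        elif isinstance(records, pd.DataFrame):
            df = records[["chrom", "pos", "ref", "alt"]].copy()
        else:
            df = pd.DataFrame(
                [(s.chrom, s.pos, s.ref, s.alt) for s in records],
                columns=["chrom", "pos", "ref", "alt"],
            )
        if len(df):
            df["chrom"] = df["chrom"].astype(str)
            df["pos"] = df["pos"].astype(np.int64)
            df["ref"] = df["ref"].astype(str).str.upper()
            df["alt"] = df["alt"].astype(str).str.upper()
            self._check(df)
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self._df = df
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            self._index[str(chrom)] = (
                sub["pos"].to_numpy() - 1,  # 0-based
                sub["ref"].to_numpy(),
                sub["alt"].to_numpy(),
            )

    @staticmethod
    def _check(df: pd.DataFrame) -> None:
        bad_len = df[(df["ref"].str.len() != 1) | (df["alt"].str.len() != 1)]
        if len(bad_len):
            r = bad_len.iloc[0]
            raise ValueError(
                f"non-SNV record at {r.chrom}:{r.pos} ({r.ref}>{r.alt}); "
                "only single-base substitutions are supported"
            )
        bad_base = df[~df["ref"].isin(_BASES) | ~df["alt"].isin(_BASES)]
        if len(bad_base):
            r = bad_base.iloc[0]
            raise ValueError(f"non-ACGT allele at {r.chrom}:{r.pos} ({r.ref}>{r.alt})")
        same = df[df["ref"] == df["alt"]]
        if len(same):
            r = same.iloc[0]
            raise ValueError(f"ref == alt at {r.chrom}:{r.pos} ({r.ref})")
        if (df["pos"] < 1).any():
            raise ValueError("positions must be >= 1 (1-based)")
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            r = df[dup].iloc[0]
            raise ValueError(f"duplicate SNP position {r.chrom}:{r.pos}")

    # ------------------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """The underlying (chrom, pos, ref, alt) frame, pos 1-based."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[Snp]:
        for row in self._df.itertuples(index=False):
            yield Snp(row.chrom, int(row.pos), row.ref, row.alt)

    def chroms(self) -> list[str]:
        return list(self._index)

    def for_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(0-based positions, ref alleles, alt alleles) for one chromosome.

        Unknown chromosomes yield empty arrays, not an error.
        """
        if chrom in self._index:
            return self._index[chrom]
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=object), np.empty(0, dtype=object))

    def in_interval(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """SNPs whose 0-based position lies in [start, end)."""
        pos, ref, alt = self.for_chrom(chrom)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return pos[lo:hi], ref[lo:hi], alt[lo:hi]

    def swapped(self) -> "SnpTable":
        """Table with ref/alt alleles exchanged (haplotype flip)."""
        df = self._df.rename(columns={"ref": "alt", "alt": "ref"})
        return SnpTable(df)

    # ------------------------------------------------------------------
    @classmethod
    def read(cls, path: str | Path) -> "SnpTable":
        """Read a SNP table from a tab file or a minimal VCF.

        Accepts either a 4-column chrom/pos/ref/alt TSV (``#`` comments
        and an optional header allowed) or a VCF, in which case only
        CHROM/POS/REF/ALT are used and non-SNV records are rejected.
        """
        path = Path(path)
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("##"):
                    continue
                if line.startswith("#"):
                    continue  # header line (VCF #CHROM or TSV comment)
                parts = line.split("\t")
                if len(parts) >= 5 and parts[2] not in _BASES and len(parts[3]) >= 1:
                    # VCF: CHROM POS ID REF ALT ...
                    rows.append((parts[0], int(parts[1]), parts[3], parts[4]))
                else:
                    if parts[0].lower() in ("chrom", "chr", "chromosome"):
                        continue
                    rows.append((parts[0], int(parts[1]), parts[2], parts[3]))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        return cls(df)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tref\talt\n")
            for row in self._df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.ref}\t{row.alt}\n")
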