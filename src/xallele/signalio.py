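"""Piecewise-constant genomic signal with bedGraph I/O.

Enrichment ratios (e.g. log2 ChIP/input) are represented as sorted,
non-overlapping intervals per chromosome.  Interval gaps mean "no
probe/no signal" and are excluded from coverage-weighted means rather
than being imputed as zero.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np


class GenomicSignal:
    """Sorted non-overlapping (start, end, value) intervals per chromosome.

    Coverage-weighted means over arbitrary query windows are computed from
    prefix integrals, so batched queries are O(log n) each.
    """

    def __init__(self, intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="mergesort")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted interval")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping intervals")
            lengths = (ends - starts).astype(np.float64)
            # prefix integral of value*length and of covered length
            cum_i = np.concatenate([[0.0], np.cumsum(values * lengths)])
            cum_l = np.concatenate([[0.0], np.cumsum(lengths)])
            self._chroms[chrom] = (starts, ends, values, cum_i, cum_l)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]]) -> "GenomicSignal":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        return cls(
            {
                c: (
                    np.array([r[0] for r in rows]),
                    np.array([r[1] for r in rows]),
                    np.array([r[2] for r in rows]),
                )
                for c, rows in by_chrom.items()
            }
        )

    def chroms(self) -> list[str]:
        return list(self._chroms)

    def __len__(self) -> int:
        return sum(len(v[0]) for v in self._chroms.values())

    def _integrals(self, chrom: str, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Value-integral and covered-length from chromosome start to x."""
        starts, ends, values, cum_i, cum_l = self._chroms[chrom]
        k = np.searchsorted(starts, x, side="right") - 1
        k_cl = np.clip(k, 0, len(starts) - 1)
        inside = np.clip(np.minimum(x, ends[k_cl]) - starts[k_cl], 0, None).astype(np.float64)
        inside[k < 0] = 0.0
        base = np.where(k < 0, 0, k_cl)
        return cum_i[base] + values[k_cl] * inside * (k >= 0), cum_l[base] + inside * (k >= 0)

    def means(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Coverage-weighted mean and covered bases for each [start, end).

        Windows with no covered base get mean NaN and coverage 0; unknown
        chromosomes are treated as fully uncovered.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._chroms:
            return np.full(starts.shape, np.nan), np.zeros(starts.shape)
        i0, l0 = self._integrals(chrom, starts)
        i1, l1 = self._integrals(chrom, ends)
        cov = l1 - l0
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cov > 0, (i1 - i0) / np.where(cov > 0, cov, 1.0), np.nan)
        return mean, cov

    def mean(self, chrom: str, start: int, end: int) -> tuple[float, float]:
        m, c = self.means(chrom, np.array([start]), np.array([end]))
        return float(m[0]), float(c[0])

    def iter_intervals(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom, (starts, ends, values, _, _) in self._chroms.items():
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    # ------------------------------------------------------------------
    @classmethod
    def read_bedgraph(cls, path: str | Path) -> "GenomicSignal":
        records = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, value = line.split()[:4]
                records.append((chrom, int(start), int(end), float(value)))
        return cls.from_records(records)

    def write_bedgraph(self, path: str | Path, *, track_line: str | None = None) -> None:
        with open(path, "w") as fh:
            if track_line:
                fh.write(track_line.rstrip("\n") + "\n")
            for chrom, s, e, v in self.iter_intervals():
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
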