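"""TSS-anchored metagene profiles, gene-body summaries and shift tests.

Enrichment signal is treated as piecewise-constant; window means are
coverage-weighted and empty windows are excluded rather than
zero-imputed.  Minus-strand genes are mirrored so positive offsets are
always transcriptionally downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from xallele.genes import GeneModel
from xallele.signalio import GenomicSignal

# (window, step) presets for the two array dialects
DIALECTS = {"nimblegen": (500, 100), "agilent": (600, 200)}


@dataclass
class MetageneProfile:
    """Average enrichment as a function of TSS-relative offset."""

    offsets: np.ndarray  # window centers, strictly increasing
    mean_enrichment: np.ndarray  # NaN where no gene contributed
    n_genes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_enrichment": self.mean_enrichment, "n_genes": self.n_genes}
        )


def _gene_windows(gene: GeneModel, centers: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Genomic [start, end) windows for TSS-relative [c-half, c+half)."""
    if gene.strand == "+":
        starts = gene.tss + centers - half
        ends = gene.tss + centers + half
    else:
        # relative coord r maps to genomic tss - r; [lo, hi) -> [tss-hi+1, tss-lo+1)
        starts = gene.tss - (centers + half) + 1
        ends = gene.tss - (centers - half) + 1
    return starts, ends


def metagene_profile(
    signal: GenomicSignal,
    genes: Sequence[GeneModel],
    *,
    window: int = 500,
    step: int = 100,
    span: int = 3000,
    gene_weighted: bool = True,
) -> MetageneProfile:
    """Sliding-window average enrichment around the TSS ("end-analysis").

    For each offset on the grid -span..+span (step ``step``), the value
    is the mean over genes of the gene's coverage-weighted mean signal in
    the window of width ``window`` centred at that offset, in
    strand-oriented TSS-relative coordinates.  With
    ``gene_weighted=False`` the pooled (coverage-weighted across genes)
    mean is reported instead.
    """
    if step > window:
        raise ValueError("window must be >= step")
    if span < window:
        raise ValueError("span must be >= window")
    centers = np.arange(-span, span + 1, step)
    half = window // 2
    sums = np.zeros(len(centers))
    weights = np.zeros(len(centers))
    n_genes = np.zeros(len(centers), dtype=np.int64)
    any_signal = False
    for gene in genes:
        starts, ends = _gene_windows(gene, centers, half)
        means, cov = signal.means(gene.chrom, starts, ends)
        ok = cov > 0
        if not ok.any():
            continue
        any_signal = True
        n_genes[ok] += 1
        if gene_weighted:
            sums[ok] += means[ok]
            weights[ok] += 1.0
        else:
            sums[ok] += means[ok] * cov[ok]
            weights[ok] += cov[ok]
    if not any_signal:
        raise ValueError("no gene overlaps the signal; cannot build a profile")
    with np.errstate(invalid="ignore"):
        mean = np.where(weights > 0, sums / np.where(weights > 0, weights, 1.0), np.nan)
    return MetageneProfile(offsets=centers, mean_enrichment=mean, n_genes=n_genes)


def gene_body_enrichment(
    signal: GenomicSignal,
    genes: Sequence[GeneModel],
    *,
    lo: int = 1000,
    hi: int = 2000,
) -> pd.DataFrame:
    """Per-gene coverage-weighted mean signal over strand-aware [+lo, +hi).

    Genes with no covered base in the interval are omitted (their count
    is recorded in ``df.attrs['n_omitted']``); genes whose interval is
    only partially covered are kept and flagged ``truncated``.
    """
    rows = []
    omitted = 0
    centers = np.array([(lo + hi) // 2])
    half = (hi - lo) // 2
    for gene in genes:
        starts, ends = _gene_windows(gene, centers, half)
        starts = np.maximum(starts, 0)
        mean, cov = signal.means(gene.chrom, starts, ends)
        if cov[0] <= 0 or not np.isfinite(mean[0]):
            omitted += 1
            continue
        rows.append(
            (gene.gene_id, gene.chrom_class, gene.xci_status, float(mean[0]), float(cov[0]), cov[0] < hi - lo)
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom_class", "xci_status", "enrichment", "covered_bases", "truncated"]
    )
    df.attrs["n_omitted"] = omitted
    return df


@dataclass(frozen=True)
class ShiftTestResult:
    """Two-sample KS comparison of per-gene enrichment distributions."""

    ks_statistic: float
    p_value: float
    relative_change: float  # (mean_b - mean_a) / mean_a

    @property
    def percent_change(self) -> float:
        return 100.0 * self.relative_change


def shift_test(values_a: Iterable[float], values_b: Iterable[float]) -> ShiftTestResult:
    """Two-sample Kolmogorov-Smirnov test plus relative change of means."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"need >= 3 values per sample (got {len(a)} and {len(b)})")
    if np.array_equal(np.sort(a), np.sort(b)):
        ks, p = 0.0, 1.0
    else:
        res = stats.ks_2samp(a, b)
        ks, p = float(res.statistic), float(res.pvalue)
    change = (b.mean() - a.mean()) / a.mean()
    return ShiftTestResult(ks_statistic=ks, p_value=p, relative_change=float(change))


@dataclass
class ScatterSummary:
    """Paired per-gene table with per-class least-squares trend lines."""

    table: pd.DataFrame  # gene_id, a, b, chrom_class, xci_status
    trends: dict[str, tuple[float, float]]  # chrom_class -> (slope, intercept)


def scatter_summary(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    genes: Sequence[GeneModel],
) -> ScatterSummary:
    """Pair two gene-body summaries by gene id and fit OLS trends per class."""
    meta = {g.gene_id: (g.chrom_class, g.xci_status) for g in genes}
    a = summary_a.set_index("gene_id")["enrichment"]
    b = summary_b.set_index("gene_id")["enrichment"]
    shared = a.index.intersection(b.index)
    rows = [
        (gid, float(a[gid]), float(b[gid]), *meta.get(gid, ("autosome", "unknown")))
        for gid in shared
    ]
    table = pd.DataFrame(rows, columns=["gene_id", "a", "b", "chrom_class", "xci_status"])
    trends: dict[str, tuple[float, float]] = {}
    for cls, sub in table.groupby("chrom_class"):
        if len(sub) >= 2 and sub["a"].nunique() > 1:
            slope, intercept = np.polyfit(sub["a"], sub["b"], deg=1)
            trends[str(cls)] = (float(slope), float(intercept))
    return ScatterSummary(table=table, trends=trends)
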