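"""Gene-level allelic expression quantification and regulation calls.

SNP reads classified to a haplotype are counted per gene, mapped onto
Xi/Xa through an explicit strain-orientation setting, depth-adjusted
between libraries, expressed in SRPM (SNP reads per 10 million mapped
reads), and classified into up/down/unchanged regulation categories at
configurable fold cutoffs.

The significance flag is a documented stand-in for the original
pipeline's external differential-expression tool: a two-sided binomial
test on depth-weighted counts with Benjamini-Hochberg correction.  The
fold-change logic is the in-scope computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from xallele.genes import GeneModel
from xallele.reads import Category, ClassifiedRead

XiAllele = Literal["ref", "alt"]


@dataclass
class AllelicGeneExpression:
    """Per-gene allelic SNP-read counts and derived quantities."""

    gene_id: str
    snp_reads_xi: float
    snp_reads_xa: float
    total_reads: int
    rpkm: float
    total_mapped_reads: int
    condition: str = ""
    adjusted_xi: float | None = None
    adjusted_xa: float | None = None
    adjusted_total: float | None = None

    @property
    def srpm_xi(self) -> float:
        return self.snp_reads_xi * 1e7 / self.total_mapped_reads

    @property
    def srpm_xa(self) -> float:
        return self.snp_reads_xa * 1e7 / self.total_mapped_reads


@dataclass(frozen=True)
class DepthAdjustment:
    """Between-library sequencing-depth normalization.

    ``factor = mapped_b / mapped_a``; condition-b counts are divided by
    it so the two libraries are comparable at condition-a depth.
    """

    mapped_a: float
    mapped_b: float

    def __post_init__(self):
        if self.mapped_a <= 0 or self.mapped_b <= 0:
            raise ValueError("library totals must be positive")

    @property
    def factor(self) -> float:
        return self.mapped_b / self.mapped_a

    def adjust(self, raw_b: float) -> float:
        return raw_b / self.factor


def count_gene_alleles(
    reads: Iterable[ClassifiedRead],
    genes: Sequence[GeneModel],
    *,
    xi_allele: XiAllele,
    total_mapped_reads: int,
    include_introns: frozenset[str] | set[str] = frozenset(),
    condition: str = "",
) -> tuple[dict[str, AllelicGeneExpression], list[str]]:
    """Count allelic SNP reads per gene.

    A read contributes to a gene iff its 5' aligned base lies within the
    gene's exons — or anywhere in the gene body for genes listed in
    ``include_introns`` (used for genes whose informative SNPs are
    intronic).  REF/ALT categories are mapped to Xi/Xa by ``xi_allele``,
    the strain whose X is inactive.  Returns the per-gene table and the
    ids of reads assigned to more than one gene (opposite-strand
    overlaps), which are counted in every gene they hit.
    """
    if xi_allele not in ("ref", "alt"):
        raise ValueError("xi_allele must be 'ref' or 'alt'")
    counts = {g.gene_id: [0.0, 0.0, 0] for g in genes}  # xi, xa, total
    multi_hit: list[str] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    xi_cat = Category.REF if xi_allele == "ref" else Category.ALT
    xa_cat = Category.ALT if xi_allele == "ref" else Category.REF
    for r in reads:
        hits = []
        point = r.five_prime
        for g in by_chrom.get(r.chrom, ()):
            if g.gene_id in include_introns:
                inside = g.start <= point < g.end
            else:
                inside = any(s <= point < e for s, e in g.exons)
            if inside:
                hits.append(g)
        if len(hits) > 1:
            multi_hit.append(r.read_id)
        for g in hits:
            rec = counts[g.gene_id]
            rec[2] += 1
            if r.category == xi_cat:
                rec[0] += 1
            elif r.category == xa_cat:
                rec[1] += 1
    out = {}
    for g in genes:
        xi, xa, total = counts[g.gene_id]
        rpkm = total * 1e9 / (g.exon_length * total_mapped_reads) if total_mapped_reads else 0.0
        out[g.gene_id] = AllelicGeneExpression(
            gene_id=g.gene_id,
            snp_reads_xi=xi,
            snp_reads_xa=xa,
            total_reads=total,
            rpkm=rpkm,
            total_mapped_reads=total_mapped_reads,
            condition=condition,
        )
    return out, multi_hit


def adjust_depth(
    expr_b: Mapping[str, AllelicGeneExpression],
    adjustment: DepthAdjustment,
) -> dict[str, AllelicGeneExpression]:
    """Divide condition-b SNP-read counts by the depth factor (raw kept)."""
    if adjustment.factor <= 0:
        raise ValueError("depth factor must be positive")
    return {
        gid: replace(
            e,
            adjusted_xi=adjustment.adjust(e.snp_reads_xi),
            adjusted_xa=adjustment.adjust(e.snp_reads_xa),
            adjusted_total=adjustment.adjust(e.total_reads),
        )
        for gid, e in expr_b.items()
    }


def xi_xa_ratio(expr: AllelicGeneExpression) -> float:
    """Xi/Xa SNP-read ratio (adjusted counts when available); NaN if Xa=0."""
    xi = expr.adjusted_xi if expr.adjusted_xi is not None else expr.snp_reads_xi
    xa = expr.adjusted_xa if expr.adjusted_xa is not None else expr.snp_reads_xa
    if xa == 0:
        return float("nan")
    return xi / xa


@dataclass(frozen=True)
class RegulationCall:
    gene_id: str
    fold_change: float
    cutoff: float
    significant: bool

    @property
    def direction(self) -> str:
        if self.significant and self.fold_change > self.cutoff:
            return "up"
        if self.significant and self.fold_change < 1.0 / self.cutoff:
            return "down"
        return "unchanged"


def group_percent(n_changed: int, n_total: int) -> int:
    """Percentage a subgroup represents of its group, nearest integer."""
    if n_total <= 0:
        raise ValueError("group size must be positive")
    return int(round(100.0 * n_changed / n_total))


def _significance_binomial(
    raw_a: np.ndarray, raw_b: np.ndarray, mapped_a: float, mapped_b: float, alpha: float
) -> np.ndarray:
    """Two-sided binomial test per gene with Benjamini-Hochberg at alpha.

    Under no change, a read from the pooled pair of libraries comes from
    library b with probability mapped_b/(mapped_a+mapped_b).
    """
    p0 = mapped_b / (mapped_a + mapped_b)
    pvals = np.ones(len(raw_a))
    for i, (a, b) in enumerate(zip(raw_a, raw_b)):
        n = int(a + b)
        if n > 0:
            pvals[i] = stats.binomtest(int(b), n, p0).pvalue
    order = np.argsort(pvals)
    ranked = pvals[order]
    m = len(pvals)
    passed = ranked <= alpha * (np.arange(1, m + 1) / m)
    sig = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.nonzero(passed)[0])
        sig[order[: k + 1]] = True
    return sig


@dataclass
class GeneClassification:
    """Regulation calls plus group-level summaries and subset labels."""

    calls: pd.DataFrame  # gene_id, group, fold_change, significant, direction@cutoff...
    summary: pd.DataFrame  # group, cutoff, n, n_up, n_down, pct_up, pct_down
    subset1: list[str]  # expressed X genes with srpm_xi >= srpm_min in either condition
    subset2: list[str]  # remaining expressed X genes


def classify_genes(
    expr_a: Mapping[str, AllelicGeneExpression],
    expr_b: Mapping[str, AllelicGeneExpression],
    genes: Sequence[GeneModel],
    *,
    rpkm_min: float = 1.0,
    srpm_min: float = 5.0,
    cutoffs: Sequence[float] = (1.25, 1.5, 2.0),
    alpha: float = 0.05,
    srpm_on_adjusted: bool = False,
) -> GeneClassification:
    """Call per-gene regulation and summarize by group.

    The expressed set is genes with RPKM >= ``rpkm_min`` in either
    condition.  Expressed X-linked genes split into subset1 (Xi SRPM >=
    ``srpm_min`` in either condition) and subset2 (the rest); autosomal
    expressed genes form the third group.  Fold change is the
    depth-normalized b/a ratio of total gene reads; a call is
    up/down at a cutoff only when also significant.
    """
    meta = {g.gene_id: g for g in genes}
    expressed = [
        gid
        for gid in expr_a
        if gid in expr_b and max(expr_a[gid].rpkm, expr_b[gid].rpkm) >= rpkm_min
    ]
    if not expressed:
        raise ValueError("no gene passes the expression filter")

    def srpm_xi(e: AllelicGeneExpression) -> float:
        if srpm_on_adjusted and e.adjusted_xi is not None:
            return e.adjusted_xi * 1e7 / e.total_mapped_reads
        return e.srpm_xi

    subset1, subset2, autosomal = [], [], []
    for gid in expressed:
        if meta[gid].chrom_class == "X":
            if max(srpm_xi(expr_a[gid]), srpm_xi(expr_b[gid])) >= srpm_min:
                subset1.append(gid)
            else:
                subset2.append(gid)
        else:
            autosomal.append(gid)

    raw_a = np.array([expr_a[g].total_reads for g in expressed], dtype=float)
    raw_b = np.array([expr_b[g].total_reads for g in expressed], dtype=float)
    mapped_a = next(iter(expr_a.values())).total_mapped_reads
    mapped_b = next(iter(expr_b.values())).total_mapped_reads
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = (raw_b / mapped_b) / np.where(raw_a > 0, raw_a / mapped_a, np.nan)
    sig = _significance_binomial(raw_a, raw_b, mapped_a, mapped_b, alpha)

    group_of = {}
    for gid in subset1:
        group_of[gid] = "X_subset1"
    for gid in subset2:
        group_of[gid] = "X_subset2"
    for gid in autosomal:
        group_of[gid] = "autosome"

    calls = pd.DataFrame(
        {
            "gene_id": expressed,
            "group": [group_of[g] for g in expressed],
            "fold_change": fold,
            "significant": sig,
        }
    )
    for cutoff in cutoffs:
        calls[f"direction@{cutoff:g}"] = [
            RegulationCall(g, f, cutoff, s).direction if np.isfinite(f) else "unchanged"
            for g, f, s in zip(expressed, fold, sig)
        ]

    rows = []
    for group in ("X_subset1", "X_subset2", "autosome"):
        sub = calls[calls["group"] == group]
        n = len(sub)
        if n == 0:
            continue
        for cutoff in cutoffs:
            col = sub[f"direction@{cutoff:g}"]
            n_up = int((col == "up").sum())
            n_down = int((col == "down").sum())
            rows.append(
                (group, cutoff, n, n_up, n_down, group_percent(n_up, n), group_percent(n_down, n))
            )
    summary = pd.DataFrame(
        rows, columns=["group", "cutoff", "n", "n_up", "n_down", "pct_up", "pct_down"]
    )
    return GeneClassification(calls=calls, summary=summary, subset1=subset1, subset2=subset2)
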