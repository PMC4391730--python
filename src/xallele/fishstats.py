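"""Nucleolar-association statistics from per-nucleus FISH scoring.

Converts scoring tables into association frequencies with confidence
intervals, computes the diploid background expectation from a
haploid-equivalent (male) per-allele rate, and runs the comparison
tests: two-proportion chi-square, unpaired t on replicate frequencies,
and one-sample t of ratios against an expected value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CompareMethod = Literal["two_proportion_chi2", "unpaired_t_on_replicates", "one_sample_t_vs_expected"]


@dataclass(frozen=True)
class AssociationExperiment:
    """One scored experiment: nuclei with >=1 signal adjacent to the nucleolus."""

    label: str
    n_nuclei: int
    n_associated: int
    replicate: int | None = None

    def __post_init__(self):
        if not (0 <= self.n_associated <= self.n_nuclei):
            raise ValueError(f"{self.label}: 0 <= n_associated <= n_nuclei violated")
        if 0 < self.n_nuclei < 100:
            warnings.warn(f"{self.label}: fewer than 100 nuclei scored ({self.n_nuclei})")


@dataclass(frozen=True)
class FrequencyResult:
    fraction: float
    ci_low: float
    ci_high: float


def frequency(exp: AssociationExperiment, *, confidence: float = 0.95) -> FrequencyResult:
    """Association fraction with a Wilson score interval."""
    if exp.n_nuclei == 0:
        raise ValueError(f"{exp.label}: no nuclei scored")
    n, k = exp.n_nuclei, exp.n_associated
    p = k / n
    z = stats.norm.ppf(0.5 + confidence / 2)
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, float(center - half))
    hi = 1.0 if k == n else min(1.0, float(center + half))
    return FrequencyResult(fraction=p, ci_low=lo, ci_high=hi)


@dataclass(frozen=True)
class BackgroundModel:
    """Expected diploid background from a per-allele association rate.

    ``expected_additive`` is ploidy * p (capped at 1), the form used to
    double a male rate for female nuclei; ``expected_exact`` is
    1 - (1-p)^ploidy under independent alleles.  For ploidy 2 the
    additive form overestimates the exact one by exactly p^2.
    """

    p_allele: float
    ploidy: int
    expected_additive: float
    expected_exact: float


def background(p_allele: float, ploidy: int = 2) -> BackgroundModel:
    if not (0.0 <= p_allele <= 1.0):
        raise ValueError("p_allele must be in [0, 1]")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    return BackgroundModel(
        p_allele=p_allele,
        ploidy=ploidy,
        expected_additive=min(1.0, ploidy * p_allele),
        expected_exact=1.0 - (1.0 - p_allele) ** ploidy,
    )


@dataclass(frozen=True)
class CompareResult:
    statistic: float
    p_value: float
    method: str


def compare(
    a,
    b,
    method: CompareMethod = "two_proportion_chi2",
    *,
    expected: float = 1.0,
) -> CompareResult:
    """Compare two experiments or replicate sets.

    - ``two_proportion_chi2``: a, b are AssociationExperiments; Pearson
      chi-square on the 2x2 table without continuity correction.
    - ``unpaired_t_on_replicates``: a, b are sequences of replicate
      frequencies; two-tailed unpaired t-test.
    - ``one_sample_t_vs_expected``: a is a sequence of ratios tested
      against ``expected`` (default 1, i.e. no change); b is ignored.
    """
    if method == "two_proportion_chi2":
        table = np.array(
            [
                [a.n_associated, a.n_nuclei - a.n_associated],
                [b.n_associated, b.n_nuclei - b.n_associated],
            ]
        )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return CompareResult(float(chi2), float(p), method)
    if method == "unpaired_t_on_replicates":
        a, b = np.asarray(a, float), np.asarray(b, float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-tests need >= 2 replicates per group")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # constant input handled below
            stat, p = stats.ttest_ind(a, b)
        if np.isnan(stat):  # zero variance in both groups
            stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        return CompareResult(float(stat), float(p), method)
    if method == "one_sample_t_vs_expected":
        a = np.asarray(a, float)
        if len(a) < 2:
            raise ValueError("t-tests need >= 2 replicates")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p = stats.ttest_1samp(a, expected)
        if np.isnan(stat):
            stat, p = (0.0, 1.0) if a.mean() == expected else (np.inf, 0.0)
        return CompareResult(float(stat), float(p), method)
    raise ValueError(f"unknown method {method!r}")


def replicate_sem(fractions: Sequence[float]) -> float:
    """Standard error of the mean across replicate frequencies."""
    arr = np.asarray(fractions, float)
    if len(arr) < 2:
        raise ValueError("need >= 2 replicates for an s.e.m.")
    return float(arr.std(ddof=1) / np.sqrt(len(arr)))


def read_scores_tsv(path: str | Path) -> list[AssociationExperiment]:
    """Load a scoring table: label, replicate, n_nuclei, n_associated."""
    df = pd.read_csv(path, sep="\t")
    return [
        AssociationExperiment(
            label=str(r.label),
            n_nuclei=int(r.n_nuclei),
            n_associated=int(r.n_associated),
            replicate=int(r.replicate) if "replicate" in df.columns and not pd.isna(r.replicate) else None,
        )
        for r in df.itertuples(index=False)
    ]
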