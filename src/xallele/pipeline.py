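"""End-to-end demo pipeline on simulated data, with manifest accounting.

The pipeline wires the stages together: simulate a hybrid genome pair,
emit reads, build the pseudo-genome, filter + classify reads, window
them into allelic tracks, estimate the X skew, and simulate/score a
FISH experiment.  A manifest records per-stage record counts, the
config hash and package versions so each stage is auditable and
re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

import xallele
from xallele import expression, fastaio, fishstats, pseudogenome, reads as reads_mod, synthetic, tracks as tracks_mod
from xallele.expression import DepthAdjustment

logger = logging.getLogger("xallele")


@dataclass
class PipelineConfig:
    """Thresholds and simulation parameters for a demo run."""

    # simulation
    genome_length: int = 200_000
    n_chromosomes: int = 2
    snp_rate: float = 1 / 75
    read_length: int = 100
    coverage: float = 10.0
    xi_skew: float = 0.16  # alternate-haplotype fraction on chrX
    error_rate: float = 0.0
    seed: int = 0
    # orientation: which allele class is the inactive X
    xi_allele: str = ""  # "ref" or "alt"; must be declared explicitly
    # thresholds
    mapq_min: int = 30
    window: int = 100
    rpkm_min: float = 1.0
    srpm_min: float = 5.0
    fold_cutoffs: tuple[float, ...] = (1.25, 1.5, 2.0)
    metagene_dialect: str = "nimblegen"
    # FISH demo
    fish_nuclei: int = 1000
    fish_p_allele: float = 0.17

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "fold_cutoffs" in data:
            data["fold_cutoffs"] = tuple(data["fold_cutoffs"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """List every invariant violation; empty iff runnable."""
    problems = []
    if config.xi_allele not in ("ref", "alt"):
        problems.append("xi_allele (strain orientation) must be declared as 'ref' or 'alt'")
    if config.mapq_min < 0:
        problems.append("mapq_min must be >= 0")
    if config.window < 1:
        problems.append("window must be >= 1")
    if config.rpkm_min <= 0:
        problems.append("rpkm_min must be positive")
    if config.srpm_min <= 0:
        problems.append("srpm_min must be positive")
    if any(c <= 1.0 for c in config.fold_cutoffs):
        problems.append("fold cutoffs must exceed 1.0")
    if config.metagene_dialect not in ("nimblegen", "agilent"):
        problems.append("metagene_dialect must be 'nimblegen' or 'agilent'")
    if not (0.0 <= config.xi_skew <= 1.0):
        problems.append("xi_skew must be in [0, 1]")
    if config.genome_length <= 0:
        problems.append("genome_length must be positive")
    return problems


class LibraryManifest:
    """Per-replicate mapped-read accounting across conditions."""

    def __init__(self):
        self._libs: dict[str, dict[str, float]] = {}

    def add_library(self, condition: str, replicate: str, mapped_reads: float) -> None:
        if mapped_reads <= 0:
            raise ValueError("mapped_reads must be positive")
        self._libs.setdefault(condition, {})[replicate] = float(mapped_reads)

    def total_mapped(self, condition: str) -> float:
        if condition not in self._libs:
            raise KeyError(f"unknown condition {condition!r}")
        return sum(self._libs[condition].values())

    def depth_adjustment(self, condition_a: str, condition_b: str) -> DepthAdjustment:
        return DepthAdjustment(self.total_mapped(condition_a), self.total_mapped(condition_b))

    def to_dict(self) -> dict:
        return {
            cond: {"replicates": reps, "total_mapped": sum(reps.values())}
            for cond, reps in self._libs.items()
        }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the demo pipeline; returns the manifest (also written to disk)."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": xallele.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    sim = synthetic.SimConfig(
        genome_length=config.genome_length,
        n_chromosomes=config.n_chromosomes,
        snp_rate=config.snp_rate,
        read_length=config.read_length,
        coverage=config.coverage,
        allelic_skew=0.5,
        error_rate=config.error_rate,
        seed=config.seed,
    )

    logger.info("stage simulate: genome pair + reads")
    reference, snps = synthetic.simulate_genome_pair(sim)
    fastaio.write_fasta(reference, outdir / "reference.fa")
    snps.write(outdir / "snps.tsv")
    sim_reads, truth = synthetic.simulate_reads(
        reference, snps, sim, region_skew={"chrX": config.xi_skew}
    )
    chrom_lengths = {c: len(s) for c, s in reference.items()}
    synthetic.write_sam(sim_reads, chrom_lengths, outdir / "reads.sam")
    manifest["stages"]["simulate"] = {
        "n_snps": len(snps),
        "n_reads": len(sim_reads),
        "chrom_lengths": chrom_lengths,
    }

    logger.info("stage pseudogenome")
    pseudo = pseudogenome.build_pseudogenome(reference, snps)
    fastaio.write_fasta(pseudo, outdir / "pseudo.fa")
    manifest["stages"]["pseudogenome"] = {"n_substitutions": len(snps)}

    logger.info("stage classify")
    header = synthetic.alignment_header(chrom_lengths)
    alignments = synthetic.reads_to_alignments(sim_reads, header)
    policy = reads_mod.FilterPolicy(mapq_min=config.mapq_min)
    retained = reads_mod.filter_alignments(alignments, policy)
    classified = reads_mod.classify_alignments(((a, "reference") for a in retained), snps)
    reads_mod.write_classified_tsv(classified, outdir / "classified.tsv")
    counts = reads_mod.category_counts(classified)
    manifest["stages"]["classify"] = {
        "n_input": len(alignments),
        "n_retained": len(retained),
        "categories": counts,
    }

    logger.info("stage tracks")
    track = tracks_mod.count_windows(classified, config.window, chrom_lengths)
    for layer in ("total", "ref", "alt"):
        track.write_bedgraph(outdir / f"track_{layer}.bedgraph", layer)
    track.write_tsv(outdir / "windows.tsv")
    manifest["stages"]["tracks"] = {
        "window_size": config.window,
        "windowed_total": track.total_reads(),
    }

    logger.info("stage skew estimate")
    x_reads = [r for r in classified if r.chrom == "chrX"]
    n_ref = sum(1 for r in x_reads if r.category == reads_mod.Category.REF)
    n_alt = sum(1 for r in x_reads if r.category == reads_mod.Category.ALT)
    xi_count = n_ref if config.xi_allele == "ref" else n_alt
    xa_count = n_alt if config.xi_allele == "ref" else n_ref
    manifest["stages"]["skew"] = {
        "chrX_ref_reads": n_ref,
        "chrX_alt_reads": n_alt,
        "xi_fraction": xi_count / (xi_count + xa_count) if (xi_count + xa_count) else None,
        "true_xi_skew": config.xi_skew,
    }

    logger.info("stage fish")
    nuclei = synthetic.simulate_fish(
        config.fish_nuclei, config.fish_p_allele, ploidy=2, seed=config.seed + 2
    )
    nuclei.to_csv(outdir / "nuclei.tsv", sep="\t", index=False)
    exp = fishstats.AssociationExperiment(
        "demo", n_nuclei=len(nuclei), n_associated=int(nuclei["any_associated"].sum())
    )
    freq = fishstats.frequency(exp)
    model = fishstats.background(config.fish_p_allele, ploidy=2)
    manifest["stages"]["fish"] = {
        "n_nuclei": exp.n_nuclei,
        "n_associated": exp.n_associated,
        "frequency": freq.fraction,
        "expected_additive": model.expected_additive,
        "expected_exact": model.expected_exact,
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
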