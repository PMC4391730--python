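# xallele

Allele-specific analysis for F1-hybrid mouse genomes with skewed
X-chromosome inactivation. The package covers the full path from a
two-haplotype genome model to allele-resolved results:

- **`xallele.pseudogenome`** — build an alternate-strain pseudo-genome by
  substituting SNP alleles into the reference (coordinate-preserving,
  SNV-only), with a validation report.
- **`xallele.reads`** — filter alignments (MAPQ threshold, uniqueness,
  per-gene low-MAPQ whitelist), reconcile dual alignments against the
  reference and pseudo genomes, and segregate reads into REF / ALT /
  AMBIGUOUS by the diagnostic SNP bases they carry (CIGAR-aware;
  soft-clipped bases never count).
- **`xallele.tracks`** — 100-bp (configurable) windowed counts of total
  and per-allele reads, exported as bedGraph/TSV browser tracks.
- **`xallele.metagene`** — TSS-anchored sliding-window average enrichment
  profiles ("end-analysis", NimbleGen 500/100 and Agilent 600/200
  dialects), per-gene gene-body summaries over +1..+2 kb, two-sample KS
  shift tests, and per-class scatter trend lines.
- **`xallele.expression`** — gene-level allelic SNP-read counts, Xi/Xa
  orientation, SRPM (SNP reads per 10 M mapped), RPKM, between-library
  depth adjustment, and regulation calls at 1.25/1.5/2.0-fold cutoffs
  with group summaries (X subset1/subset2 by Xi-SRPM, autosomes).
- **`xallele.rflp`** — in-silico allele-discriminating restriction digest
  with IUPAC sites, both-strand scanning, fragment predictions per
  allele, and enzyme screening ranked by gel resolvability.
- **`xallele.fishstats`** — nucleolar-association frequencies with Wilson
  intervals, diploid background models (additive and exact), chi-square
  and t-test comparisons.
- **`xallele.synthetic`** — a simulator of toy F1-hybrid datasets
  (genome pair, SNP table, reads with ground-truth haplotype tags,
  TSS-anchored enrichment with an X-specific knockdown effect, FISH
  nuclei), so every stage is testable without external data.
- **`xallele.pipeline` / `xallele.cli`** — configuration validation and
  an end-to-end demo pipeline with a provenance manifest.

## CLI

Every stage is a subcommand of `xallele`:

```sh
xallele simulate --seed 1 --out demo/
xallele pseudogenome --ref ref.fa --snps snps.tsv --out pseudo.fa
xallele classify --ref-bam ref.sam --pseudo-bam pseudo.sam --snps snps.tsv --mapq 30 --out classified.tsv
xallele tracks --in reads.sam --snps snps.tsv --window 100 --out-prefix tracks/demo
xallele metagene --signal enrichment.bedgraph --genes genes.bed --dialect nimblegen --out profile.tsv
xallele expression --classified reads.sam --snps snps.tsv --genes genes.tsv \
    --xi-allele alt --total-mapped 10000000 --out expression.tsv
xallele rflp --amplicon amp.fa --snp-offset 120 --alt T --enzymes enzymes.tsv
xallele fish-stats --scores scores.tsv --background-from male
xallele run-all --config pipeline.yaml --out results/
```

`run-all` reads a YAML config whose keys mirror
`xallele.pipeline.PipelineConfig` (simulation parameters, thresholds,
and the mandatory `xi_allele: ref|alt` strain orientation); see
`docs/pipeline.example.yaml`.

File formats: FASTA genomes, tab-separated chrom/pos/ref/alt SNP tables
(minimal VCF also accepted), SAM alignments, bedGraph signal, BED12 or
TSV gene models, TSV scoring tables.

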