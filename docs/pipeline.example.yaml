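# Demo pipeline configuration (keys mirror xallele.pipeline.PipelineConfig)

# simulation
genome_length: 200000     # bases per chromosome
n_chromosomes: 2          # chr1 .. chr(n-1) plus chrX
snp_rate: 0.0133          # ~1 SNP per 75 bp
read_length: 100
coverage: 10.0
xi_skew: 0.16             # alternate-haplotype read fraction on chrX
error_rate: 0.0
seed: 1

# strain orientation: which allele class sits on the inactive X
xi_allele: alt            # "ref" or "alt" (mandatory)

# thresholds
mapq_min: 30
window: 100
rpkm_min: 1.0
srpm_min: 5.0
fold_cutoffs: [1.25, 1.5, 2.0]
metagene_dialect: nimblegen   # or "agilent"

# FISH demo
fish_nuclei: 1000
fish_p_allele: 0.17
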