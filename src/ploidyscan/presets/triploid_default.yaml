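# Default synthetic scenario: triploid sample, two reference-like haplophases
# plus one divergent haplophase, with a 600 kb segmental duplication of a
# reference-like haplophase on chr02 (a 1:10 linear scale-down of a
# megabase-scale chromosome-arm duplication) and window-aligned N-gap
# stretches that produce pseudo low-coverage artifacts.
#
# Divergence rates are chosen for statistical power at desk scale, not as
# estimates of any real cultivar's heterozygosity.
seed: 0
chromosomes:
  - [chr01, 2000000]
  - [chr02, 2000000]
  - [chr03, 2000000]
baseline_ploidy: 3
n_ref_like: 2
divergent_snv_rate: 0.005
shared_snv_rate: 0.002
ref_like_snv_rate: 0.0005
ref_mismatch_rate: 0.001
duplication: [chr02, 800000, 1400000, ref_like]
depth_per_copy: 20.0
depth_model: poisson
divergent_map_rate: 0.9
n_gap_intervals:
  - [chr01, 1200000, 1300000]
  - [chr03, 400000, 600000]
n_genes: 300
mean_cds_len: 1200
indel_rate: 0.0005
indel_max_len: 30
cds_mod3_enrichment: 3.0
fail_annotation_rate: 0.05
sample: sample1
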