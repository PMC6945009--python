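# Negative control: ordinary heterozygous diploid, no duplication, no CDS
# InDel mod-3 enrichment. AF spectrum should show a single peak near 1/2 and
# the mod-3 comparison should be null.
seed: 0
chromosomes:
  - [chr01, 2000000]
  - [chr02, 2000000]
  - [chr03, 2000000]
baseline_ploidy: 2
n_ref_like: 1
divergent_snv_rate: 0.005
shared_snv_rate: 0.0
ref_like_snv_rate: 0.0005
ref_mismatch_rate: 0.001
duplication: null
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
cds_mod3_enrichment: 1.0
fail_annotation_rate: 0.05
sample: sample1
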