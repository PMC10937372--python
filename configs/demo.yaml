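# Demo pipeline configuration: 2,000 SNVs over 50 Mb, 40 causal variants
# whose effects drift along ancestry axis 1, three planted z-score
# clusters, one enriched cell type and an outcome loading on the
# cluster-0 score. Runs end-to-end in a few seconds on one CPU.
seed: 1
outdir: demo_run
simulation:
  n_snvs: 2000
  snv_spacing: 25000
  n_causal: 40
  base_effect: 0.08
  axis_effects: [0.03, 0.0]
  missing_rate: 0.2
n_axes: 2
k_clusters: 3
cohort_size: 3000
outcome_effects:
  "0": 0.15
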