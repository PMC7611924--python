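# A 2,000-family fixture that runs the full pipeline in well under 2 minutes.
seed: 7
simulate:
  n_families: 2000
  n_snps: 150
  n_causal: 15
  shared_fraction: 0.5
  h2: [0.30, 0.30, 0.25]
  lifespan_years_lost: [2.0, 0.0, 0.5]
clump:
  p_thresh: 5.0e-8
  r2_thresh: 0.001
  window_bp: 1000000
fdr_q: 0.05
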