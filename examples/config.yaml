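# End-to-end synthetic run: strong planted effects, saturated proteomic
# detection, zero contamination -- all planted targets reach score 9.
simulation:
  n_genes: 800
  surface_fraction: 0.25
  n_planted: 40
  effect_delta: 3.0
  sigma: 1.0
  n_tumor: 10
  n_normal: 10
  detect_intercept: 20.0
  detect_slope: 0.0
  contamination_rate: 0.0
  seed: 123
stat: ordinary
p_max: 0.05
lfc_min: 1.5
min_score: 5
outdir: surfscore_out
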