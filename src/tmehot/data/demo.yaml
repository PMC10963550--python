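# Bundled fully synthetic demo run.
mode: synthetic
seed: 42
atlas:
  cells_per_cluster: 40
  n_genes: 800
  markers_per_cluster: 10
  marker_fold: 4.0
bulk:
  n_samples: 150
  noise_sd: 0.1
  tme_gene_slope: 2.0
  n_decoys: 29
survival:
  log_hr: -0.5
  baseline_rate: 0.03
  censor_rate: 0.1
markers:
  min_frac: 0.1
  min_log2fc: 0.25
  top_n: 15
ssgsea:
  alpha: 0.25
  normalize: true
scoring:
  nk_mode: celltype
  rescale_tam: true
screen:
  p_cor: 0.05
  p_cox: 0.05
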