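{
 "description": "edgeR 4.0 calcNormFactors(method='TMM') on tmm_input(seed=101)",
 "seed": 101,
 "n_genes": 200,
 "n_samples": 10,
 "factors": [
  0.980970774065,
  0.974842913951,
  0.952210932273,
  1.02299218273,
  0.978144524344,
  1.04720415342,
  0.965281533338,
  1.01479095317,
  1.00338688959,
  1.06627793644
 ]
}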