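# Example synthetic-dataset configuration for `tfcensus generate`.
n_genomes: 50
seed: 7
orf_range: [800, 6000]
lifestyle_mix:
  free-living: 0.48
  pathogen: 0.25
  extremophile: 0.21
  intracellular: 0.06
default_family:
  base_rate: 4.0
  size_slope: 0.8
  cd_pool_size: 10
  cd_concentration: 0.5
  p_monodomain: 0.32
families:
  LysR: {base_rate: 15.0, cd_pool_size: 12}
  TetR/AcrR: {base_rate: 16.0, cd_pool_size: 20}
  AraC/XylS: {base_rate: 9.0, cd_pool_size: 25, cd_concentration: 0.1}
  Fur: {base_rate: 1.8, cd_pool_size: 3, cd_concentration: 3.0, p_monodomain: 0.8}
  ArgR: {base_rate: 0.6, cd_pool_size: 3, cd_concentration: 3.0, p_monodomain: 0.8}
planted_enrichments:
  - [AraC/XylS, CD0003]
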