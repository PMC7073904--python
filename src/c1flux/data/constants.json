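{
  "biomass_per_od": 0.39,
  "cell_density": 300.0,
  "ph": 7.5,
  "c1_carbon_fraction": 0.023,
  "k_forward": 870000000.0,
  "thf_pool": 23.0,
  "formaldehyde_um": 100.0
}
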