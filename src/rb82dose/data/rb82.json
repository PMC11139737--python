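{
  "name": "Rb-82",
  "half_life_s": 76.0,
  "positron_yield": 0.95,
  "mean_energy_per_decay_MeV": 1.41,
  "photon_fraction": 0.0
}
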