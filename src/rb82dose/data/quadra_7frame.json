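{
  "frames": [[0, 30], [30, 60], [60, 90], [90, 120], [120, 180], [180, 270], [270, 420]],
  "reference_time_s": 0.0
}
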