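{
  "r_h": 0.35,
  "r_a": 0.30,
  "K_h": 2000.0,
  "K_a": 2000.0,
  "a": 0.8,
  "h": 1.2,
  "E_osi": 1.0
}
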