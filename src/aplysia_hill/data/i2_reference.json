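{
  "muscle": "I2 protractor (published reference values)",
  "F_mto_N": 0.15,
  "K_t": 5.0,
  "tau_s": 2.45,
  "tau_over_beta_s": 3.48
}
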