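{
  "F_mto": 1.61,
  "L_mto": 18.03,
  "L_0": 16.02,
  "L_st": 0.0,
  "K_t": 11.95,
  "A": [1.55, 7.90, 0.33, 8.33],
  "B": [7.44, -29.74, 37.17, -13.87],
  "Y": [5.44, -21.15, 25.16, -8.49],
  "C": [-1.89, 1.70, 0.75, 0.55],
  "l_pe_threshold": 0.87,
  "D": [-0.77, 0.07, 0.35, 0.07],
  "E": [0.84, 6.37, 1.69, 1.36, -5.07],
  "tau": 0.60,
  "beta": 0.15,
  "a0": 0.74,
  "g": 3.82
}
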