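{
  "x0": 0.08316,
  "xmax": 3.5,
  "mu_max": 0.0306,
  "y_xs": 1.1799,
  "alpha": 1.5371,
  "k_int": 1.2989,
  "y_ps": 1.8736,
  "ke": 2.560,
  "s0": 55.0,
  "p0": 1.4
}
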