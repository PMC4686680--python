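# Demo synthetic cohort: two inbred lines with the published length
# distributions, three trunk genes with injected scaling slopes.
lines:
  - {name: large, length_mean: 482.0, length_sd: 20.9}
  - {name: small, length_mean: 408.6, length_sd: 16.8, level_factors: {Kr: 0.85}}
domains:
  Kr:
    - anterior: {xi0: 0.44, slope: 0.0}
      posterior: {xi0: 0.62, slope: -0.05}
      amplitude: 100.0
  kni:
    - anterior: {xi0: 0.60, slope: -0.05}
      posterior: {xi0: 0.76, slope: -0.19}
      amplitude: 90.0
  gt:
    - anterior: {xi0: 0.72, slope: -0.10}
      posterior: {xi0: 0.84, slope: 0.05}
      amplitude: 80.0
classes: [nc13, T1, T2, T3, T4, T5, T6, T7, T8, T9]
n_per_class: 6
noise_sd: 3.0
background: 20.0
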