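{
  "isomer": "11-cis",
  "pair_distances": {
    "N15:E194_O": [6.49, 0.30],
    "N15:Y126_O": [3.14, 0.30],
    "N15:S199_O": [4.10, 0.30]
  },
  "contact_probs": {
    "M103": 0.392,
    "M99": 0.0
  },
  "n_waters_near": 5,
  "excitation_mean_protein": 2.42,
  "excitation_mean_vacuum": 2.31,
  "excitation_sd": 0.08,
  "oscillator_mean": 1.0
}
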