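{
  "lambdas": [0.0, 0.2, 0.4, 0.6, 0.8],
  "N": 100,
  "cs": [0.2],
  "n_connectivity": 3,
  "n_noise": 20
}
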