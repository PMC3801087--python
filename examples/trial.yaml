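# One erasing-protocol trial of the default single-unit network:
# ignite with a 56-Hz stimulus during 50-100 ms, then raise the
# background correlation level to 0.8 at 500 ms.
network:
  family: single_unit
  connectivity_seed: 7
  overrides: {}
schedule:
  duration: 1000.0
  dt: 0.1
  lam:
    E:
      - [0.0, 0.0]
      - [500.0, 0.8]
  stimuli:
    - population: E
      t_on: 50.0
      t_off: 100.0
      nu1: 56.0
      j1: 1.5
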