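strains:
  - label: resident
    alpha: 3.0e-6
    beta: 100.0
    tau: 15
    strategy: SX
environment:
  B0: 1000
  delta: 0.1
  seed: 1
experiment:
  name: steady
output:
  prefix: steady_default
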