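# single neutral-mutant invasions at one tenth of the default census
strains:
  - label: resident
    strategy: S
  - label: mutant
    strategy: S
environment:
  B0: 1000
  delta: 0.1
  seed: 7
experiment:
  name: fix
  trials: 1000000
  scale: 0.1        # B0 -> 100, alpha * 10, trials -> 100000
output:
  prefix: neutral_fix
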