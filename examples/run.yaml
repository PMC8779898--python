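# Example run configuration: a small membrane + protein system whose
# protein/membrane attraction toggles on at 0.2 T_max and off at 0.85 T_max.
box: [12, 12, 16]
counts: {major: 180, minor: 36, idp: 20, idp_backbone: 6}
epsilon: {ee: 0.68, em: 0.0}
engine: {dt: 0.02, seed: 1, steps: 20000}
density: 3.0
backend: reference
schedule:
  - {frac: 0.2, pair: E-H_B, epsilon: 0.8}
  - {frac: 0.85, pair: E-H_B, epsilon: 0.0}
output:
  interval: 1000
  observables: observables.csv
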