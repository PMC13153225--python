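# Standard testing condition with a refractoriness-style bias override.
preset: paper2026
overrides:
  e_k: -0.12
protocol:
  mode: pulses
  pulses:
    - [0.05, 1.0e-5, 0.02]   # t0 (s), amplitude (A), width (s)
seed: 0
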