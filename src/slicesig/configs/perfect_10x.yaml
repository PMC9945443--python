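# Demo: 10x tandem perfect-site reporter, MILI-like library.
seed: 7
guide:
  name: piR-synthetic
reporter:
  kind: perfect
  n_sites: 10
simulate:
  n_reads: 8000
  mature_mode: 26
  proportions:
    mature: 0.80
    pre: 0.08
    byproduct: 0.05
    phased: 0.0
    background: 0.07
scan:
  n_pool: 1000
  max_mm: 3
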