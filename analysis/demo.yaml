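# small demo configuration for `cidms run-all` (~10 s end to end)
library:
  n_molecules: 30000
sort:
  depth: 300000
landscape:
  shape: optimal
  wt_dgf: -1.6
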