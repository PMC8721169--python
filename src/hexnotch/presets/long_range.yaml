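# Long-range rule (e.g. signaling through cell protrusions): inhibition
# requires at least ten Delta-positive cells among the 18 neighbors at hex
# distance three, producing coarser spatial arrangements.
grid:
  n_rows: 20
  n_cols: 20
  boundary: cylindrical
rule:
  dist: 3
  theta: 10
run:
  seed: 1
  t_max: 300.0
  equilibrium_window: 25.0
output:
  directory: out/long_range
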