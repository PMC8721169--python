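# Small tissue with a two-neighbor quorum: inhibition requires at least two
# Delta-positive cells among the six nearest neighbors, giving a denser
# positive pattern.
grid:
  n_rows: 6
  n_cols: 6
  boundary: cylindrical
rule:
  dist: 1
  theta: 2
run:
  seed: 1
  t_max: 300.0
  equilibrium_window: 25.0
output:
  directory: out/quorum_two
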