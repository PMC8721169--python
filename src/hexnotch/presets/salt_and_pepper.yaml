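# Classic lateral inhibition: a cell is inhibited when at least one of its
# six nearest neighbors is Delta-positive.  Converges to a salt-and-pepper
# maximal-independent-set pattern.
grid:
  n_rows: 20
  n_cols: 20
  boundary: cylindrical
rule:
  dist: 1
  theta: 1
run:
  seed: 1
  t_max: 300.0
  equilibrium_window: 25.0
output:
  directory: out/salt_and_pepper
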