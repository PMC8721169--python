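# Lateral inhibition combined with a position-only morphogen: a linear
# Wnt-like gradient (0 in the top row, Wmax at the bottom) inhibits the
# transcriptional activity of nuclear NICD.  Where the gradient is strong,
# neighbor signaling can no longer repress Delta below the threshold and
# the rows stay uniformly Delta-positive (unresolved); the weak-gradient
# rows resolve into the usual salt-and-pepper pattern.
grid:
  n_rows: 20
  n_cols: 20
  boundary: cylindrical
rule:
  dist: 1
  theta: 1
wnt:
  Wmax: 10.0
  axis: row
params:
  KW: 4.0
run:
  seed: 1
  t_max: 300.0
  equilibrium_window: 25.0
output:
  directory: out/wnt_gradient
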