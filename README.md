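# hexnotch

Hybrid logic–ODE simulation of Delta–Notch lateral inhibition on
hexagonal cell grids.

## The scientific problem

During epithelial development, neighboring cells adopt alternating fates
through *lateral inhibition*: a cell that expresses the Delta ligand
activates the Notch receptor on its neighbors, and active Notch signaling
represses Delta in those neighbors. The tissue-level outcome is a
"salt-and-pepper" mosaic in which no two Delta-positive cells touch and
every Delta-negative cell has at least one Delta-positive neighbor — a
maximal independent set of the cell-contact graph.

Simulating this at tissue scale poses a granularity trade-off. A full ODE
model of every cell and every intercellular coupling is quantitative but
stiff and hard to scale; purely logical (Boolean) models scale but lose
concentrations and real time. `hexnotch` implements a hybrid middle
ground:

- **Inside each cell** a six-species ODE cascade tracks cleaved Notch
  (cytoplasmic `NC`, nuclear `NN`), Hes repressor (mRNA `HNmRNA`,
  cytoplasmic and nuclear protein `HCp`, `HNp`) and the Delta ligand `D`.
- **Between cells** communication is discrete: each cell's Delta is
  binarized against a threshold `Th`, and a logical quorum rule over the
  hexagonal neighbor ring (e.g. "at least 1 of the 6 cells at distance 1
  is Delta-positive", or "at least 10 of the 18 at distance 3") switches
  the cell's ligand input `DE` between 0 and `DEmax`.

Because inter-cell inputs only change when some cell's Delta crosses the
threshold, the simulation is *event-driven*: cells are integrated
independently with frozen inputs until the earliest threshold crossing,
the logic matrix is refreshed, and integration resumes. This yields
quantitative trajectories and real (hour-valued) time at a fraction of
the cost of a monolithic tissue ODE. An optional positional field (a
soluble Wnt-like gradient) can additionally suppress Notch transcriptional
activity in a concentration-dependent way, pinning part of the grid in an
undifferentiated Delta-positive state.

## Worked example

Simulate a 6×6 cylindrical grid (lateral edges in contact) under the
nearest-neighbor rule, starting from random initial concentrations:

```python
import hexnotch as hx

cfg = hx.SimulationConfig(grid=hx.GridSpec(6, 6, "cylindrical"),
                          rule=hx.LogicRule(dist=1, theta=1),
                          seed=1, t_max=300.0)
res = hx.run(cfg)

print(res.termination)            # equilibrium
print(round(res.final_time, 2))   # 63.09
print(len(res.events))            # 204
print(res.final_logic)
```

```
[[0 0 0 1 0 0]
 [1 0 0 0 1 0]
 [0 0 0 1 0 0]
 [0 1 0 0 1 0]
 [1 0 0 1 0 0]
 [0 1 0 0 1 0]]
```

The run commits 204 threshold-crossing events and reaches a fixed pattern
at t ≈ 63.09 h. The first events are early down-crossings as the randomly
initialized Hes arm transiently represses Delta everywhere:

```python
[(e.time, tuple(e.cell), e.direction) for e in res.events[:3]]
# [(0.0317, (5, 4), 'down'), (0.0531, (5, 2), 'down'), (0.0691, (3, 2), 'down')]
```

The final pattern is a valid lateral-inhibition mosaic:

```python
from hexnotch.patterns import summarize
summarize(res.final_logic, cfg.grid, cfg.rule)
# PatternSummary(n_positive=10, fraction_positive=0.2778,
#                is_valid_lateral_inhibition=True,
#                min_pairwise_distance_between_positives=2.0)
```

10 of 36 cells end Delta-positive, no two positives are adjacent
(minimum pairwise hex distance 2), and every negative cell has a positive
neighbor.

### Command line

The same run via the CLI, using one of the bundled scenario presets:

```sh
hexnotch simulate --preset salt_and_pepper --outdir out/
hexnotch render out/delta_300.csv --out out/delta.png   # if snapshots requested
hexnotch summarize out/logic_final.csv --dist 1 --theta 1
```

`simulate` writes `events.csv`, `logic_final.csv`, per-snapshot
`delta_<time>.csv` matrices, `trajectories.csv`, `summary.json` and a
normalized `config_used.yaml` provenance copy. Presets:
`salt_and_pepper` (20×20, nearest-neighbor rule), `quorum_two` (6×6,
quorum of two), `long_range` (distance-3 ring, quorum of ten) and
`wnt_gradient` (20×20 with a positional gradient). Custom runs use a YAML
config with sections `grid`, `rule`, `params`, `wnt`, `init`, `run`,
`output` — see `src/hexnotch/presets/` for complete examples.

## Layout

- `src/hexnotch/hexgrid.py` — hexagonal lattice addressing, neighbor
  rings, bounded / cylindrical / toroidal boundaries
- `src/hexnotch/kinetics.py` — the six-species intracellular ODE cascade
- `src/hexnotch/logic.py` — Delta binarization, quorum rules, positional
  Wnt field
- `src/hexnotch/engine.py` — the event-driven hybrid simulation loop
- `src/hexnotch/patterns.py` — pattern validity checks and summaries
- `src/hexnotch/config.py`, `results_io.py`, `render.py`, `cli.py` —
  configuration files, result serialization, rendering, CLI
- `docs/methods.md` — model equations, parameter table, numerical choices
  and limitations
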