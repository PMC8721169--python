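# Methods

## Model

Each cell on a hexagonal grid carries a six-species ODE system describing
the Delta–Notch–Hes cascade. State variables (concentrations, arbitrary
units): cleaved Notch intracellular domain in cytoplasm `NC` and nucleus
`NN`, Hes mRNA `HNmRNA`, Hes protein in cytoplasm `HCp` and nucleus
`HNp`, and Delta ligand `D`. Inputs: the neighbor-dependent ligand level
`DE` and the positional field value `W` (both piecewise constant in
time). With `Notch_free = Ntot − NC − NN·VN/VC` (clipped at zero inside
the cleavage flux) and the Wnt inhibition factor
`σ(W) = KW^nW / (KW^nW + W^nW)`:

```
dNC/dt      = kcl·Notch_free·DE + (ktrP/VC)(NN − NC) − (ktrA/VC)·NC − muN·NC
dNN/dt      = (ktrP/VN)(NC − NN) + (ktrA/VN)·NC − muN·NN
dHNmRNA/dt  = σ(W)·ktH·NN^nH/(NN^nH + KH^nH) − muHmRNA·HNmRNA
dHCp/dt     = kHp·HNmRNA·(VN/VC) + (ktrP/VC)(HNp − HCp) − muHp·HCp
dHNp/dt     = −(ktrP/VN)(HNp − HCp) − muHp·HNp
dD/dt       = ktD·KD^nH/(KD^nH + HNp^nH) − muD·D
```

Ligand binding cleaves free Notch; nuclear Notch activates Hes
transcription (activating Hill term); nuclear Hes represses Delta
transcription (repressing Hill term). Time is measured in hours.

### Model assumptions

- Total Notch `Ntot` is conserved up to the explicit degradation terms;
  the free receptor pool is an algebraic function of `NC` and `NN`.
- Intercellular signaling is quantized: a cell presents either no ligand
  or the saturating level `DEmax` to its neighbors, decided by a logical
  quorum rule over the binarized Delta states on its neighbor ring
  ("at least `theta` of the cells at hex distance `dist` have
  `D ≥ Th`"). Additional weighted clauses at other distances are
  supported (`LogicRule.extra_clauses`).
- Between threshold crossings all logical inputs are frozen, so cells
  evolve independently; crossings are the only coupling events.
- The positional field is static in time (a fixed gradient), acting only
  through the multiplicative factor `σ(W)` on Hes transcription.
- Cells are identical (same parameters); heterogeneity enters only
  through random initial conditions.

## Parameters

All defaults are dimensionally consistent with concentrations in
arbitrary units and time in hours. They were chosen once, before any
pattern-level testing, to place the model in the canonical
lateral-inhibition operating regime, and were not tuned afterwards.

| name | default | unit | role / rationale |
|---|---|---|---|
| `VC` | 1.0 | volume | cytoplasm volume (reference) |
| `VN` | 0.5 | volume | nuclear volume; VN/VC scales nuclear transport |
| `Ntot` | 10.0 | conc. | total Notch pool; large enough not to limit cleavage |
| `kcl` | 2.0 | 1/(conc.·h) | ligand-induced cleavage rate |
| `ktrP` | 2.0 | vol/h | passive nuclear transport |
| `ktrA` | 4.0 | vol/h | active nuclear import of cleaved Notch |
| `muN` | 1.0 | 1/h | cleaved Notch degradation |
| `ktH` | 4.0 | conc./h | max Hes transcription |
| `KH` | 2.0 | conc. | Hes activation half-saturation (reached by `NN` under stimulation) |
| `muHmRNA` | 2.0 | 1/h | Hes mRNA turnover |
| `kHp` | 4.0 | 1/h | Hes translation |
| `muHp` | 1.0 | 1/h | Hes protein degradation |
| `ktD` | 8.0 | conc./h | max Delta transcription |
| `KD` | 0.5 | conc. | Delta repression half-saturation (well below stimulated `HNp`, giving strong repression) |
| `muD` | 2.0 | 1/h | Delta turnover |
| `DEmax` | 2.0 | conc. | saturating presented-ligand level |
| `Th` | 2.0 | conc. | Delta quantization threshold |
| `nH` | 2 | – | Hill coefficient (both Hill terms) |
| `KW` | 4.0 | conc. | Wnt inhibition half-saturation |
| `nW` | 2 | – | Wnt Hill coefficient |

The regime constraint is validated at construction: `Th < ktD/muD`, so an
unstimulated cell's Delta fixed point `D* = ktD/muD = 4.0` lies above the
threshold while the fully stimulated fixed point (`D ≈ 0.20` at these
defaults, computed in the tests) lies below it. The threshold therefore
separates the two cell fates, which is what makes the binarization
meaningful.

Closed forms used as test oracles: with no stimulation and `HNp = 0`,
Delta follows the scalar linear ODE `dD/dt = ktD − muD·D`, so
`D* = ktD/muD` and the threshold-crossing time from `D(0)=0` is
`t* = −(1/muD)·ln(1 − Th·muD/ktD)` (≈ 0.3466 h at the defaults).

### Initial conditions (synthetic data)

Initial states are drawn per cell and species from independent uniform
distributions (`numpy.random.default_rng(seed)`); defaults:

| species | range |
|---|---|
| `NC` | [0, 3.5] |
| `NN` | [0, 8.5] |
| `HNmRNA` | [0.8, 2.0] |
| `HCp` | [1.5, 2.7] |
| `HNp` | [1.2, 2.2] |
| `D` | [0, 4.0] |

The ranges span the biologically plausible region between the two
single-cell fixed points. The nonzero lower bounds on the Hes arm mean
every cell starts with enough repressor to transiently push Delta below
threshold, reproducing the characteristic trajectory in which the whole
grid passes through an all-Delta-negative ("naive") state before the
pattern resolves — this is asserted over a seed set in the acceptance
tests. What the generator emulates: random, uncorrelated cell states at
the onset of fate selection. What it does not emulate: spatially
correlated initial conditions, cell division/rearrangement, parameter
heterogeneity between cells, or measurement noise.

## Grid geometry

Cells are addressed as `(row, col)` in odd-r offset coordinates and
converted internally to axial coordinates
(`q = col − (row − (row & 1))//2`, `r = row`). Hex distance is
`(|dq| + |dr| + |dq + dr|)/2`. Neighbor rings are enumerated by the
standard lattice ring walk, then wrapped, deduplicated and filtered by
the wrapped distance. Boundary modes:

- `bounded` — rings are clipped at the edges;
- `cylindrical` — columns wrap (lateral borders in contact);
- `toroidal` — both directions wrap. Because odd-r row parity alternates,
  a consistent toroidal wrap requires an even row count and identifies
  `(q, r) ~ (q + n_rows/2, r − n_rows)`; distances take the minimum over
  the adjacent wrapped images.

An interior cell has exactly 6, 12 and 18 neighbors at distances 1, 2
and 3 — verified exactly in the tests for all boundary modes against an
O(n²) brute-force distance enumeration.

## Numerical choices

- **Event-driven loop.** Each epoch integrates the full stacked system
  with `scipy.integrate.solve_ivp` and a single terminal event on the
  max-envelope surface `h(t) = max_i (D_i − Th)·(−side_i) − offset_i`,
  where `side_i` is the cell's current logical value. Crossings within a
  relative simultaneity tolerance of 1e-9 are committed together (this
  preserves exact symmetries, e.g. two identical coupled cells crossing
  at the same instant).
- **Hysteresis band.** A cell that has just crossed sits exactly on
  `D = Th`; to prevent an immediate spurious re-trigger its event surface
  is offset by a band of 1e-6·Th until it leaves the band. Cells inside
  the band keep their logical value; all other cells' logic is the plain
  binarization of Delta at all times.
- **Solvers.** Default `RK45` with `rtol = 1e-6`, `atol = 1e-9` (the
  defaults are not stiff at tissue scale); `BDF`, `Radau` and `LSODA` are
  selectable, with a block-diagonal Jacobian sparsity pattern supplied to
  the implicit methods (cells are uncoupled within an epoch).
- **Equilibrium detection.** A run terminates at equilibrium when no
  event occurs for `equilibrium_window` hours (default 25) *and* the
  max-norm of the vector field is below 1e-4·ktD. The tolerance reflects
  the residual floor of the integrator at the default solver tolerances:
  demanding much less than ≈1e-5 relative residual would require
  tightening `rtol`/`atol` well past the accuracy that the event times
  themselves need. Runs that do not meet it stop at `t_max` with
  `termination = "t_max"`.
- **Verification strategy.** The engine is checked against a separately
  written monolithic brute-force simulator (stacked ODE system, one
  terminal scipy event per cell, manual input switching) on 1×1, 1×2 and
  2×2 tissues: event times agree to ~1e-6 relative and final logic
  matrices agree exactly at tight tolerances. The vector field is checked
  against an independent scalar transcription of the six equations to
  float rounding on 1000 random states.

## Design decisions on open modeling questions

- **Wnt functional form.** Concentration-dependent inhibition of Notch
  transcriptional activity is modeled as the multiplicative repressing
  Hill factor `σ(W)` on Hes transcription, with half-saturation `KW` and
  coefficient `nW`. Consequence: where `σ(W)` is small, Hes cannot
  accumulate, Delta stays near its unstimulated fixed point above
  threshold, and the cell is locked Delta-positive (undifferentiated)
  regardless of its neighbors — so a steep gradient splits the grid into
  a patterned low-Wnt region and a uniformly Delta-positive high-Wnt
  region, with a narrow transition zone.
- **Gradient shape.** The positional field is linear along one grid axis,
  0 at the first row (or column) and `Wmax` at the last.
- **Salt-and-pepper operationalization.** "Pattern completed" is defined
  as the maximal-independent-set condition of the rule's neighbor graph:
  no positive cell sees an inhibitory quorum, every negative cell does
  (cells pinned by the positional field can be exempted).
- **Problem sizes.** Tissue-scale runs use 20×20 grids with cylindrical
  boundaries; oracle comparisons use 1–4 cells; combinatorial checks use
  grids up to 10×10 in all three boundary modes.

## Limitations

- Near the Wnt transition zone, cells whose effective Delta fixed point
  lies close to `Th` can flip indefinitely (grazing oscillations); such
  runs terminate at `t_max` rather than at a strict equilibrium. This is
  a genuine feature of the quantized-coupling dynamics, not a solver
  artifact — the pattern away from the transition rows is stable.
- Long-range quorum rules (e.g. distance 3, quorum 10) can produce slowly
  evolving patterns with very many events; the engine reports whatever
  state holds at `t_max` without asserting it is a fixed pattern.
- Event times inherit the accuracy of the ODE solver and its root-finder;
  runs with thousands of events accumulate ordering uncertainty between
  near-simultaneous crossings on distinct cells.
- The model omits cell division, movement, delays, stochastic gene
  expression and ligand diffusion; the positional field is static.
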