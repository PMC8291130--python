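# Methods

This note documents the numerical method implemented in `popgrid`, the
choices made where the design was open, and what the bundled validation
does and does not demonstrate.

## The population density technique on a regular grid

A population of identical, unconnected-within-population point neurons
receiving Poisson spike trains is described by a probability density
ρ(v, w) over the 2D state space of one neuron.  The density evolves under
(i) the deterministic vector field **F** of the neuron model, (ii) a
shot-noise master equation for the Poisson input, and (iii) threshold-reset
dynamics.  One-dimensional models are embedded in 2D with an inert second
variable.

State space is truncated to a rectangle and discretised into `n_h` rows ×
`n_v` columns of identical cells; mass within a cell is treated as
uniformly distributed.  Cells are half-open, `[low, high)` in both
dimensions; a point exactly on the upper bound belongs to the last cell,
so binning is deterministic.

Per time step the operators are applied in a fixed order: deterministic
transition → reset/refractory redistribution → master equation → activity
readout.  All updates across a network are synchronous.

### Deterministic transition matrix

The four vertices of every cell are advanced by one Euler step of
duration `timestep` (optionally `substeps` sub-Euler steps for stiff
fields).  The transformed quadrilateral is split into two triangles along
a fixed diagonal (absolute areas, which also handles non-convex or
twisted quads), and each triangle is recursively bisected at the first
grid line crossing its bounding box until each piece lies inside a single
cell; pieces are binned by centroid.  The per-cell areas divided by the
quadrilateral area give the row of a sparse stochastic matrix.

Numerical details:

- Points within `1e-12` of a grid line are treated as on it, which
  guarantees termination of the recursion.
- Fractions below `1e-12` are dropped and the row renormalised; every row
  then sums to 1 within `1e-9` (checked, and re-checked when a matrix is
  read from file).
- Rows are computed independently, so generation is traversal-order
  independent (and trivially parallelisable).

**Boundary policy.**  Mass transported below the lower grid bounds is
pinned to the boundary cell; mass transported above the upper bounds wraps
to the opposite side.  Both indicate an undersized grid, produce
physically meaningless dynamics at the boundary, and are logged as
warnings.  The policy is applied at matrix-generation time so rows remain
stochastic and global mass is conserved exactly.

### Master equation

A spike on one connection causes an instantaneous jump *h* in either the
membrane potential (`efficacy_orientation="v"`) or the second variable
(`"h"`, e.g. a conductance).  On a regular grid the induced transition is
the same for every cell: offset `k = floor(|h|/s)·sign(h)` cells and a
two-target split `(1−f, f)` with `f = frac(|h|/s)`, `s` the cell size
along the jump.  Jump matrices are built in memory at run time from the
efficacy and the grid.

With input rates λ_k and jump matrices M_k, the density is advanced by
forward Euler on dρ/dt = Σ_k λ_k (M_k − I) ρ using `master_steps`
substeps per simulation step (default 10).  All inputs are combined into
one generator, so no operator-splitting order bias exists between
connections.  Negative excursions smaller than `1e-12` are clamped and
the mass renormalised; anything larger raises an error advising a higher
`master_steps`.  A fixed-step scheme was chosen over an adaptive
integrator for bit-reproducibility: two runs of the same configuration are
identical.

The Euler scheme has a known first-order bias: over a window T it
reproduces the shot-noise mean growth ν·h·T exactly (the split is
mean-preserving), while the variance growth ν·h²·T is underestimated by a
relative factor ≈ λΔ, with Δ the substep.  At the default settings
(λΔ ≈ 0.01) this is a 1% effect.

### Threshold-reset and refractory queues

Threshold cells are all cells whose column's lower edge is at or above
the lower edge of the column containing `threshold_v` (so mass jumped far
past threshold is captured too).  Each threshold cell maps to the cell in
the column containing `reset_v`, in the same row displaced by
`round(reset_shift_h / cell_height)` rows; a displaced row outside the
grid is pinned to the nearest edge row (a displaced reset is an adaptation
current, and wrapping it would be meaningless).

Each threshold cell owns a refractory queue.  Per step: the queues
advance, delivering mass to the mapped reset cells; then the mass now in
threshold cells is removed, counted as the fired mass (firing rate =
fired mass / dt), and pushed onto the queue heads.  With
`n = refractory_period / dt`, `alpha = frac(n)` and `L = max(ceil(n), 1)`,
a packet pushed at step t delivers `(1−alpha)` of its mass at step `t+L`
and `alpha` at step `t+L+1`; an integer-multiple refractory period
arrives in one step, and a zero refractory period re-injects on the next
step.  Queue contents count toward the global mass balance, which is
asserted to hold within `1e-9` at every step.

Mass in the queues is excluded from the average-membrane-potential
("AvgV") readout, which is the mass-weighted mean of cell-centre
potentials over the in-grid mass.

### Networks, delays, external inputs

Connections carry `num_connections × presynaptic activity` as the
effective Poisson rate.  Node types constrain efficacy signs (excitatory
→ ≥ 0, inhibitory → ≤ 0, neutral → any), validated at wiring and at XML
parse time.  Delays use the same interpolating queue as the refractory
mechanism; because the update is synchronous, a connection always has at
least one step of transport (`delay/dt + 1` steps in total).  External
inputs supplied per step through the stepping API are applied in the
current step when their declared delay is zero.

The simulation `t_step` must equal or be an integer multiple of each grid
node's own time step; in the latter case the node substeps internally
with the same inputs.

## XML dialect and file formats

The XML vocabulary covers `Simulation`, `WeightType`, `Algorithms`
(`RateAlgorithm`, `RateFunctor` with constant expressions,
`GridAlgorithm` with `GridAlgorithmGroup` as an alias), `Nodes`,
`Connections` (+`IncomingConnection`/`OutgoingConnection` for the
stepping API), `Reporting` (`Rate`, `Density`, `Display`) and
`SimulationRunParameter` (`master_steps` defaults to 10 when omitted).
Mesh-based and other legacy algorithm types are recognised and rejected
with an explicit "unsupported" error.  `Variable` elements define named
string defaults substituted textually anywhere in the document before
type checking; caller overrides (always strings) take precedence;
duplicate variable names are rejected.

Grid geometry and model parameters are stored in a versioned plain-text
`.model` header (optionally including the serialized reset mapping);
transition matrices in `.tmat` files with one `source target proportion`
line per entry at 17 significant digits, making the round trip bit-exact.
Both are validated on read (row sums, dt compatibility).

## The direct (Monte Carlo) reference simulator

N individual neurons are integrated with per-step Poisson event counts
per input (valid for rate·dt ≪ 1; warned otherwise), one Euler step of
the field per time step, threshold detection at step boundaries, reset
with the `reset_shift_h` displacement, and a refractory hold during which
neurons are frozen and ignore input — mirroring the queue semantics of
the density path.  Runs are reproducible for a fixed seed.  This
simulator shares no code with the density path beyond the model
definitions and serves as the finite-size ground truth.

What agreement with it shows: that the density method reproduces the
statistics of an ensemble of independent neurons under ideal Poisson
input with constant efficacies.  What it does not show: correctness for
correlated inputs, finite-size fluctuation effects (the density is an
infinite-population limit and its output is noise-free), conductance
waveforms, or state-dependent efficacies.

## Validation conditions and problem sizes

- **Stationary-rate comparison** (conductance-based model): drive
  1000 Hz × h = 0.05 on the conductance, grid (−72, −54) × (−0.2, 1.0) mV
  at 360 × 120, dt = 0.1 ms, 1.2 s simulated, rate averaged over the last
  0.3 s, against 10,000 directly simulated neurons.  The grid is chosen so
  threshold (−55), reset (−65) and the jump (5 cells) fall exactly on cell
  boundaries, removing the leading discretisation biases; dt was fixed by
  a convergence study (the reset path adds one step of dead time per
  spike, a rate deficit ≈ rate²·dt, which at 0.1 ms is below the Monte
  Carlo standard error).  Measured difference ≈ 0.1 Hz on ≈ 41.5 Hz.
- **Conservation**: a fully wired E-I conductance network (two grid
  populations at 100 × 100, two 800 Hz inputs, cross/self connections
  with 1 ms delay, 2 ms refractory), 1 s at dt = 1 ms; the per-node mass
  balance holds to ~1e-14, asserted against 1e-9.
- **Poisson oracle**: one-cell jumps at λt = 1 with 1000 Euler substeps
  reproduce the Poisson pmf to < 1e-3 per cell.
- **Izhikevich damping**: regular-spiking parameters (a=0.02, b=0.2,
  reset −65, u-jump 8) on (−80, 35) × (−16, 16) at 230 × 96, driven by
  100 kHz × 0.1 mV jumps (mean 10 mV/ms, variance 1000 mV²/s — a
  low-variance drive so the synchronous transient rings for several
  cycles before de-synchronising), dt = 0.1 ms with 50 master substeps,
  0.4 s simulated.  Successive smoothed rate peaks are non-increasing and
  the trace converges to a constant rate.

These sizes keep the full validation under a few minutes on one CPU;
larger grids/longer runs scale linearly in steps and in matrix nonzeros.

## Known limitations

- The truncation boundary policy (pin/wrap) is a bookkeeping device, not
  physics; grids must be sized so negligible mass reaches the bounds.
- Per-step cell splitting adds numerical diffusion proportional to cell
  size; fast-threshold models (e.g. exponential integrate-and-fire) need
  disproportionately fine grids for accurate rates.
- The fired mass is re-injected one step after harvest, an O(dt) dead
  time per spike visible at high firing rates and coarse time steps.
- Efficacies are constant per connection (no state-dependent jumps), input
  processes are Poisson, and vector fields must be autonomous.
- Time-varying inputs are supplied per step through the stepping API
  rather than as expression-valued rate algorithms.
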