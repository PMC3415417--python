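# Methods

`topomap` asks a single question: can a population of hippocampal place
cells convey the *topology* of an environment — how many connected pieces
and how many holes it has — purely through the temporal pattern of its
co-firing, and if so, how quickly and under what firing regimes?  This note
records the model, the parameter choices, the numerical machinery and the
limits of what the simulations show.

## The model

**Arenas.** Three 2 m × 2 m planar arenas with axis-aligned rectangular
holes: `A` (one 50 × 50 cm hole, Betti numbers (1, 1)), `B` (50 × 50 cm and
50 × 100 cm holes, (1, 2)) and `C` (two 180 × 80 cm slabs that leave only
narrow corridors, (1, 2)).  The published layouts fix hole *sizes* only;
the positions used here (A: centred; B: holes at x ≈ 0.55 m and 1.45 m;
C: slabs stacked vertically, leaving three ~10–20 cm corridors plus side
connectors) are configuration, not science, and can be overridden with a
custom environment spec.

**Behaviour.** The simulated animal is a correlated random walk sampled at
dt = 10 ms.  Speed follows a mean-reverting (OU) process with long-run mean
0.25 m/s clipped to [0, 0.5] m/s.  The heading turns each step by a draw
from an even two-component Gaussian mixture with modes ±30°·(dt/0.1 s) and
s.d. 20°·(dt/0.1 s) — a bimodal turning distribution as measured in
open-field tracking; both mixture parameters scale linearly with dt so the
per-step shape is dt-invariant.  Steps that would cross a wall or hole
trigger (i) a speed reduction by the factor `wall_brake` = 0.7 — a mild
thigmotaxis that reproduces the elevated occupancy observed along walls,
hole borders and corners — then (ii) up to 50 re-draws of the turn, then
(iii) specular reflection off the blocking wall.  Reflection, rather than
heading reversal, is what lets the walker round the corners of environment
C's 10 cm corridors; with reversal the bottom corridor is simply never
entered.  The free parameters of the walk (turn mixture, OU constants,
brake) are not printed in the source study; they were calibrated once
against its published summary statistics — mean speed 25 cm/s, ~10 min to
cover 80% of arena A at 3 cm resolution, boundary-elevated occupancy — and
then frozen.

**Ensembles.** A hippocampal "state" is (f̄, s̄, N): the mode of the peak
firing-rate distribution, the mode of the place-field size distribution,
and the cell count.  Rates and sizes are log-normal, parameterised by mode
and standard deviation (the unique log-normal with density peak at the mode
and the requested s.d. is solved by bisection on the shape parameter).
Field sizes along x and y are drawn independently (ellipsoidal fields);
centres are scattered uniformly over the *accessible* part of the arena.
The spreads grow with the modes through σ_f = a·√(f̄/Hz) Hz and
σ_s = b·√(s̄/cm) cm with a = 1.2, b = 1.7.  At the reference state
(20 Hz, 60 cm) this gives σ_f ≈ 5.4 Hz and σ_s ≈ 13 cm — right-skewed
distributions whose bulk matches recorded place-cell statistics (typical
rates 10–20 Hz, fields of a few tens of cm).

Two design choices here deserve emphasis, because the alternatives fail in
an instructive way.  First, a *linear* spread law (σ_s = b·s̄) puts a
sizeable fraction of cells at arena-scale field sizes; such a cell is
active in essentially every coactivity window, and any always-active vertex
"cones" the complex — every co-firing pair it joins acquires a filling
triangle — forcing b1 = 0 from the first minutes in every seed.  Under that
law the model can never report a hole, so the square-root law (which keeps
the stated "wider spread for higher modes" monotonicity and the fitted
coefficients) was adopted.  Second, the sampled size s is interpreted as
the full field extent with Gaussian σ = s/6 (the ±3σ region).  A more
aggressive σ = s/4 convention makes a 70 cm field span the 50 cm hole of
arena A outright, collapsing the reported success band to 50–60 cm; σ = s/6
reproduces the published band (success at 50–80 cm, failure at ≥90 cm).

**Spiking.** Each cell is an inhomogeneous Poisson process with rate
λ_i(x) = f_i · exp(−(x−x0)²/2σ_x² − (y−y0)²/2σ_y²), sampled by Bernoulli
thinning per 10 ms step (error O(λ·dt) ≈ 0.4% at 40 Hz) with uniform jitter
within the step.  Each cell has its own child RNG stream, so a cell's train
does not depend on which other cells are present.

**Coactivity and the temporal complex.** Time is partitioned into
consecutive ε = 0.25 s windows (two theta cycles); a cell is active in a
window if it fires ≥ m = 1 spikes there.  Every subset of jointly active
cells (up to dimension `max_dim` = 2) spans a simplex whose entry value is
the end time of the earliest such window.  The complex only grows
(retained-memory assumption: all co-firing since t = 0 counts); there is no
forgetting.  A sliding (half-overlapping) window mode exists behind a flag.

## Homology machinery

All homology is simplicial with Z/2 coefficients, so orientations drop out
and boundary matrices are 0/1.  Three independent routes are implemented:

1. **Rank–nullity Betti numbers** (`betti_numbers`): dense Gaussian
   elimination over GF(2); b_k = #k-simplices − rank ∂_k − rank ∂_{k+1}.
   This is the brute-force oracle.
2. **Persistence barcodes** (`persistence`): the standard column-reduction
   algorithm in filtration order, one dimension at a time, with columns as
   integer bitsets.  Ties in entry value are broken by (dimension,
   lexicographic vertices); the barcode is invariant to that choice and the
   number of infinite dimension-k bars equals b_k of the final complex.
   Zero-length bars are recorded and can be suppressed.
3. **Incremental (b0, b1) traces** (`temporal_betti_trace`): b0 by
   union-find over coactivity edges processed chronologically; b1 from
   b1 = E − (V − b0) − rank ∂_2, with rank ∂_2 accumulated per window from
   *cone triangles* only.  Within a window whose active set is A, every
   triangle boundary in the clique on A is a Z/2 sum of the boundaries of
   triangles (v0, i, j) rooted at a fixed v0 ∈ A, so only those O(|A|²)
   columns (not O(|A|³) triangles) need reduction.  For realistic windows
   (30–80 active cells) this is the difference between seconds and hours,
   and it is exact: the test suite checks it against route 2 on full
   complexes, and route 2 against route 1 on random filtered complexes.

The Čech nerve of a planar cover (used for the field-overlap picture and
the annulus fixtures) tests region intersections by dense 1 cm grid
sampling.

## Map-formation detection and sweeps

The Betti trace is evaluated at every window end; a trial succeeds if there
is a time t* after which (b0, b1) equals the arena's ground truth at every
window through the observation cap, and T_min is the earliest such t*.
Caps are 15 simulated minutes for single trials and 25 minutes for sweeps
(the published failure cap is not printed; these are declared defaults).
Each trial draws a fresh ensemble (new centres); the trajectory is fixed
per environment across a sweep.  Per-trial seeds derive from
(master_seed, grid indices, repetition) via `SeedSequence`, so trials are
order-independent and parallelisable.

The reference protocol sweeps f̄ over 2–40 Hz, s̄ over ~10–90 cm and N over
50–400 with 10 repetitions per state (10,000 trials).  The desk-scale
protocol used by the tests and the acceptance script runs a 4 × 4 × 3 grid
(f̄ ∈ {2, 10, 20, 40} Hz, s̄ ∈ {10, 20, 60, 90} cm, N ∈ {50, 150, 350})
with 3 repetitions — 144 trials per environment, about a minute each
environment on one CPU.  The learning region L is the set of states with
success fraction ≥ 0.8 and mean T_min ≤ T_cap; its stable core additionally
requires relative spread ξ = sd(T_min)/mean(T_min) < 0.3.  The 0.8
membership threshold is this package's choice (the source describes
reliability by dot size, not a cutoff).

## What the simulations do and do not show

The generator reproduces the study conditions, not real recordings: Poisson
spiking with stationary Gaussian rate maps, no theta rhythm, phase
precession, bursting, replay, out-of-field firing, or field plasticity; a
single fixed trajectory model; rectangular arenas only.  Passing tests
therefore show that the *pipeline* recovers the right topology under the
stated model, with realistic time constants — not that biological
hippocampus does so.  Known limitations:

* With m = 1 and unbounded Gaussian tails, any pair of fields co-fires
  eventually, so every loop is transient as t → ∞; results are meaningful
  relative to the declared observation caps.
* At mid-size ensembles (N ≈ 100–150) with f̄ ≈ 17–20 Hz the cover is
  marginal under the σ = s/6 convention: spurious loops can persist past
  the 25 min cap, so success there concentrates at higher rates (e.g.
  f̄ = 40 Hz, where N = 150 forms maps in ~3 min).  Reliability at fixed
  (f̄, s̄) still never decreases with N beyond sampling noise.
* Learning-region sizes on the desk-scale grid (48 states × 3 reps) are
  small counts and correspondingly noisy; environment comparisons at this
  scale are majority-of-seeds statements, not per-seed guarantees.
* Exact published T_min values (e.g. a 5.84 min example trial) depend on
  the original trajectory realisation and RNG and are not reproducible;
  the range claims (2–5 min at the reference state; coverage slower than
  map formation; B slowest of the three arenas) are.

## Numerical details

Log-normal mode/std inversion: bisection on v = σ_shape² of
(e^v − 1)e^{3v} = (std/mode)², monotone, to 1e-14 relative tolerance; the
std → 0 limit degenerates to a point mass at the mode.  Spatial bins are
3 cm; a bin is accessible iff its centre is.  Rates are evaluated only
within 6σ of a field centre (truncation error < 2·10⁻⁸ of the peak).
Trajectory positions at the step start drive the rate (left-endpoint rule),
matching the thinning discretisation; the spike-count oracle integrates the
same rule.  All randomness flows through `numpy` `Generator`/`SeedSequence`
objects; every public entry point is deterministic given its seed.
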