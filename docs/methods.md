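# Methods

## Model class

A GDDM is specified by five components, each an arbitrary function of the
decision-variable position `x`, time `t` (seconds), a task-condition mapping
(e.g. motion coherence) and a named parameter set with box constraints:

* drift `μ(x, t, …)` (position/s; default 0),
* noise `σ(x, t, …)` (position/√s; default 1, strictly positive),
* symmetric absorbing bounds `±B(t, …)` (default 1, strictly positive),
* initial distribution `X₀` over interior grid points (default: point mass
  at `x = 0`; must sum to 1 and lie strictly inside `(−B(0), B(0))`),
* an overlay chain transforming the solved first-passage distribution
  (non-decision shift with optional uniform across-trial width, uniform
  lapse mixture).

The process is Markov: drift and noise are evaluated once per (grid point,
timestep); variation within a step is ignored.  Dependence flags
(x-/t-dependence of drift/noise, t-dependence of the bound) are declared by
the model author and spot-checked by `validate_model`, which also verifies
noise positivity, bound positivity, initial-condition normalization and
support, and reports evaluator exceptions as violation records instead of
crashing.  The upper bound is labelled "correct" (choice code 1), the lower
"error" (code 0).

## Discretization and schemes

Positions are discretized as `{−B₀+Δx, …, 0, …, B₀−Δx}`; a requested Δx is
shrunk to the largest value for which `B₀/Δx` is an integer so that `x = 0`
is always a grid point (where the default point mass lives), and Δt is
shrunk so it divides the duration.  Writing `ν = DΔt/Δx²` and `χ = μΔt/Δx`
(unitless), one step of all three schemes is

    (I + (1−α) M) Pⁿ = (I − α M) Pⁿ⁻¹

with tridiagonal `M` (row j: diagonal `2ν_j`, super-diagonal
`−ν_{j+1} + χ_{j+1}/2`, sub-diagonal `−ν_{j−1} − χ_{j−1}/2`) and α = 1
(forward Euler, explicit), 0 (backward Euler) or ½ (Crank-Nicolson);
implicit steps are O(n) banded solves.  Coefficients are evaluated at
`t_{n−1}` (forward), `t_n` (backward) or `t_{n−1/2}` (CN); time-invariant
operators are built once and reused.

**Flux.** The per-step exit masses are fixed by the column sums of `M`:

    Δp_upper = (ν + χ/2)|_{B−Δx} · Q,    Δp_lower = (ν − χ/2)|_{−B+Δx} · Q,

evaluated on the scheme-consistent boundary state
`Q = α Pⁿ⁻¹ + (1−α) Pⁿ`.  With this convention
`ΣPⁿ⁻¹ = ΣPⁿ + Δp_upper + Δp_lower` holds identically, so total
probability is conserved to rounding for every scheme.  The state vector is
deliberately **not** clamped during propagation — clamping would inject
mass and break this identity; instead per-step fluxes are clamped at zero
(clamped totals tracked in the solution metadata) and verification raises
if the state dips below a per-scheme tolerance (10⁻¹² for the Euler
schemes, 10⁻⁵ for CN, whose residual startup ringing is discussed below).

**Stability.** Forward Euler requires `D·Δt/Δx² < ½`; `solve` refuses to
run it outside that region unless `allow_unstable=True` (the benchmark
sweeps use this to *record* divergence, detected as interior mass
exceeding 10).  The implicit schemes are unconditionally stable.

**Crank-Nicolson startup.** CN applied directly to a point-mass start
rings: high-frequency modes are propagated with amplification ≈ −1,
producing transient oscillating masses of order one.  The solver therefore
takes each of the first two steps as two half-Δt backward-Euler sub-steps
(Rannacher startup), which damps the non-smooth modes while keeping the
scheme's second-order global accuracy (measured log-log RMS-density-error
slope 1.60 on the Δx = Δt benchmark sweep, rounding to the nominal order
2).  In strongly advection-dominated meshes (cell Péclet number
`μΔx/D > 2`) centered differencing can still produce small negative
excursions; the verification tolerance of 10⁻⁵ flags anything beyond
residual ringing.

**Time-varying bounds** (backward Euler only; CN is refused because it
oscillates on free-boundary problems).  At each step the current bound
`B_n` generally falls between grid points `x_j < B_n < x_{j+1}`.  The state
is propagated separately on the inner system (interior `{−j…j}`) and the
outer system (`{−j−1…j+1}`), and the results combined with the linear
interpolation weights `w_out = (B_n − x_j)/Δx`, `w_in = (x_{j+1} − B_n)/Δx`
(`w_in + w_out = 1`); fluxes are the same weighted combination of each
system's boundary fluxes.  Mass that a shrinking bound strands outside a
system's domain is routed to the matching side's flux, weighted by that
system's weight, so conservation is exact.  The state lives on a master
grid fixed at t = 0 extended by one point per side (the outer system can
reach `±B(0)` while the bound is within one Δx of its start).  A bound
exactly on a grid point (within 10⁻¹²·Δx) uses a single system — a constant
bound run through this path reproduces the fixed-bound solver bitwise.
Bounds below Δx (no interior point) or above `B(0)` raise.

## Analytic fast path

Constant drift/noise, constant bounds and a centered point start admit the
classical large-time series for the two-barrier first-passage density; in
unit-noise variables (`a = 2B/σ`, start `z = a/2`, `m = μ/σ`):

    f₀(t) = (π/a²) e^{−mz − m²t/2} Σ_k k sin(kπz/a) e^{−k²π²t/(2a²)}

for the lower barrier and `f₀(t | a−z, −m)` for the upper.  Terms are added
until four consecutive terms contribute < 10⁻¹⁴ (the sine vanishes on every
other term for a centered start), capped at 10⁴ terms.  Bin mass is the
density at the bin midpoint × Δt, matching the unitless per-bin convention
of the numerical solvers; as a consequence a "single bin" run returns
midpoint density × duration, not the cumulative mass — cumulative
quantities should be read from fine-binned solutions.  Linearly collapsing
bounds, though they too admit a closed form, are routed to backward Euler;
the analytic path covers exactly the constant-coefficient case.  Solver
priority is analytic → Crank-Nicolson (fixed bounds) → backward Euler;
forward Euler and trial-wise simulation are never auto-selected.

## Overlays

The non-decision overlay shifts the distribution later by
`round(t_nd/Δt)` bins (bias < Δt/2); with width `s_T` the shift is averaged
over offsets in `[t_nd − s_T, t_nd + s_T]` stepping by Δt, dropping
negative offsets and renormalizing.  Mass shifted past the duration is
reclassified undecided, so the shift is mass-preserving.  The uniform
mixture returns `w ·(diffusion) + (1−w)·lapse` with the lapse mass spread
uniformly over `(0, t_dur]` and split evenly between choices — the fixed
`w = 0.95` used throughout the zoo distributes 0.05 total lapse mass, which
keeps the total at exactly 1 for any duration.  Overlay parameters may be
literals, parameter names, or callables of (conditions, parameters) — the
per-condition DDM uses the callable form for its per-coherence
non-decision times.

## Trial-wise simulation and sampling

`simulate_trials` integrates the SDE by Euler-Maruyama
(`x ← x + μΔt + σ√Δt·z`).  Checking `|x| ≥ B` only at step ends misses
within-step excursions and biases first-passage times upward by O(√Δt) — at
Δt = 10⁻³ this is large enough to fail a Kolmogorov–Smirnov comparison
against the solved distribution at N = 10⁴.  Each surviving step is
therefore additionally absorbed with the exact Brownian-bridge crossing
probability `exp(−2(B−x_old)(B−x_new)/(σ²Δt))` per side (the standard bias
correction for first-passage sampling; not a higher-order integrator).
The bare endpoint-checked scheme remains available via
`bridge_absorption=False`.  Trials still inside the bounds at `t_dur` are
undecided.  Overlays are applied at the trial level (delays added to RTs;
lapse trials relabelled with uniform RT and fair-coin choice).

`sample_from_solution` draws (bin, choice, undecided) cells from the solved
masses and places RTs uniformly within bins — bins being the finest
information available — which is how synthetic fitting fixtures are made
without trajectory simulation.  Histogram smoothing for the trajectory
benchmark evaluates every centered mean filter of width 1…500 (windows
truncated and renormalized at the edges) against a reference and keeps the
best; width 1 is the identity, so smoothing can never increase the error.

## Fitting

The likelihood of a trial is the per-second model density for its choice at
its RT, read from the solved distribution (density = bin mass/Δt at bin
midpoints, linearly interpolated; nearest-bin is available).  One solve per
distinct condition combination is cached per objective evaluation.
Undecided model mass is treated as censoring: it lowers the decided density
and is not renormalized away.  Because observed datasets contain only
decided trials, this objective slightly rewards parameter settings with
less undecided mass; on the synthetic recovery study below this appears as
a systematic ≈ −13% bias in the recovered bound height (within the ±15%
recovery tolerance), while drift and non-decision time recover closely.
A lapse mixture keeps the likelihood finite for outlier RTs; a zero-density
trial without one raises an error recommending a mixture rather than
returning −∞.  The MSE objective compares per-bin model masses with
per-condition empirical histograms.  Optimizers: differential evolution
(seeded, scipy defaults, finite bounds required) and Nelder-Mead (restarted
once from its best point).  Fits are deterministic given the seed and
report NLL and BIC = k·ln(n) + 2·NLL.

## Model zoo defaults

Coherence levels follow the random-dot-motion convention with
`C_max = 0.512` (constructor argument).  Defaults chosen where a value was
needed: per-level drifts `{0, 0.32, 0.64, 1.28, 2.56, 5.12}` (a shared
drift scale of 10 across the six standard coherences), `B0 = 1`,
`t_nd = 0.2 s`, drift variability `s_v = 0.5`, start-point half-width
`s_z = 0.1`, non-decision half-width `s_T = 0.05 s`, duration 2 s.  The
collapsing-bound GDDM uses drift `μ0·(C/C_max)^α − leak·x` and bound
`B0·e^{−t/τ}`.  Across-trial drift variability does not fit the
Fokker-Planck state space, so the full DDM discretizes `N(μ_j, s_v²)` at 11
points spanning ±3 s_v with renormalized normal weights, solves each and
mixes the solutions; the uniform start is laid onto grid cells with
overlap-proportional weights.  Parameter counts: 6 / 3 / 11 / 8 / 18 (the
fixed 0.95 lapse weight and `C_max` are constants, not fitted parameters).

## Benchmarks and problem sizes

Accuracy sweeps solve the constant benchmark model (μ = 2, σ = 1.5, B = 1,
2 s) and compare per-bin masses with the series solution resampled to the
method's own time grid.  Convergence orders are log-log least-squares
slopes of the RMS error on the **density** scale (bin mass/Δt): per-bin
masses carry a factor Δt, so a joint Δx = Δt sweep on the mass scale would
inflate the measured slope by one.  Measured: CN temporal slope 1.60 and
backward-Euler spatial slope 1.57 (at fixed Δt = 10⁻⁴, whose O(Δt) floor
slightly flattens the finest point), both rounding to the schemes' nominal
order 2.  Execution times are recorded with a monotonic clock around the
solve only and are reported, never asserted; the time × MSE product is a
tradeoff heuristic.  The empirical forward-Euler stable/unstable transition
is located by bisection on `D·Δt/Δx²` and brackets ½ tightly.

Condition-parallel solving (`parallel_solve`) is embarrassingly parallel
over conditions via joblib worker processes; outputs are returned in input
order and are bitwise identical for any worker count.  The parallelism
benchmark model (drift 2C over 64 coherences in [0, 0.63], unit noise and
bounds) is solved with backward Euler.

The test suite and the acceptance script keep problem sizes modest by
design: sweeps use Δx = Δt ∈ {0.04…0.005}, recovery studies use ≈ 5000
trials, trajectory checks use 10⁴–10⁵ trials at Δt = 10⁻³.

## What the synthetic data does and does not show

Fixtures are sampled from the package's own solved distributions, so
recovery tests demonstrate self-consistency of the solve–sample–fit loop
(including the censored-likelihood bias noted above), not robustness to the
ways real data deviate from the model: sequential dependencies between
trials, non-uniform contaminant distributions, parameter drift over a
session, or asymmetric bounds (unsupported — bounds are symmetric around
zero by construction).  Continuous across-trial drift variability is
supported only through the quadrature approximation; evidence streams that
vary within a timestep are aliased onto the step grid.

## Known limitations

* Bin-midpoint mass convention makes extremely coarse time bins inaccurate
  (use Δt well below the RT distribution's width).
* Centered spatial differencing is oscillation-prone for cell Péclet
  numbers above 2; no upwinding is implemented.
* The moving-bound path is first-order in time (backward Euler) by design.
* Likelihoods ignore unobserved censored trials (see Fitting), a
  deliberate modelling choice that biases bound estimates downward when
  undecided mass is appreciable.
* No hierarchical (group-level) fitting or posterior sampling.
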