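# Methods

This note records the models, algorithms, numerical choices and known
limitations of `wesample`, at the level of detail a user would need to
judge what the package's results do and do not demonstrate.

## The weighted-ensemble resampling step

State space is partitioned along one or more progress coordinates into
half-open rectilinear bins `[low, high)` (the final edge of a dimension
may be `+inf`).  At every interval τ each walker is assigned to exactly
one bin; out-of-domain coordinates are a hard error naming the walker —
never a silent clamp, because a clamped coordinate would silently merge
distinct states.

For each occupied bin with target count `m`:

* **Up-sampling** (fewer than `m` walkers): daughter slots are allocated
  one at a time to the walker with the largest weight per slot (ties
  broken by lowest walker id), then each walker with `k` slots is split
  into `k` copies of weight `w/k` — one division, so the weights sum back
  to `w` up to a final-ulp rounding.  This allocation flattens the
  post-split weight variance; with a single walker in the bin it reduces
  to an even `m`-way split.
* **Down-sampling** (more than `m` walkers): the two lowest-weight
  walkers are merged repeatedly until the bin is at target.  One of the
  pair survives, drawn with probability proportional to its weight, and
  inherits the summed weight, so the expectation of any state indicator
  is exactly preserved.  Merging lightest-first minimizes the weight
  distortion per merge.  Among three equal-weight walkers the merged pair
  is the lowest-(weight, id) pair — a deterministic convention; which
  *member* survives remains random.

Empty bins stay empty: resampling never invents probability in regions
no trajectory has reached.  Total weight is conserved exactly (the suite
asserts `|Σw − 1| < 1e-12` across 10⁴ randomized resamples and across
every iteration boundary of full runs).

**Randomness.**  One root seed spawns an independent PCG64 stream per
(iteration, purpose) pair — propagation, recycling, resampling — via
`numpy` `SeedSequence` spawn keys.  Runs are therefore bit-reproducible
regardless of how many draws any phase consumes, and the seed is stored
in the run record.

**Weight floor.**  None is imposed; ultralight walkers are retained.

## Steady state, recycling and MFPT

Recycling removes every walker whose end-of-interval progress coordinate
lies in the target state B and restarts a fresh walker from the t = 0
distribution with the identical weight.  After a burn-in transient
(default: the first 50% of iterations, consistent with the
most-recent-half running-average convention used for flux convergence
plots) the mean recycled weight per unit time estimates the steady-state
first-arrival flux, and MFPT = 1/flux.  If the retained window contains
no arrivals the estimator degenerates to an explicit lower bound (the
retained simulated time), never a division by zero.

**Arrival detection and the running-max coordinate.**  Walkers are
inspected only at interval ends; nothing catches a trajectory "in the
act" of crossing mid-interval.  For first-passage problems whose target
is a sharp, quickly-exited count threshold this matters: a chain that
touches the threshold and falls back within τ would go uncounted, and
the measured flux would underestimate the true first-arrival flux (on
the birth–death benchmark below, by nearly a factor of two at τ = 0.2).
The package therefore uses a *monotone* progress coordinate for such
runs: the well-mixed engine can exactly track the running maximum copy
number (it visits every reaction event), and with pcoord = running max,
"in B at the interval end" is identical to "first touched B during the
interval".  This is the history-labelled-trajectory device in its
simplest form and is the package's default recommendation for MFPT and
threshold-crossing measurements.

**Transition-matrix route.**  The stored walker tables link every walker
to its ancestor in the previous iteration's table (the run loop rewrites
parent ids after resampling so the link always resolves exactly one
step back, even when a freshly recycled walker is split in the same
resampling event).  Aggregating child weight over (ancestor bin → own
bin) pairs and normalizing rows gives the conditional transition
probabilities k_ij per τ.  Because a recycled replacement's ancestor is
the arrival walker, the recycling boundary condition is embedded in the
estimated chain as B→A transitions; the stationary solution of that
chain reproduces the recycling steady state, and the flux
Σ_{i∉B} Σ_{j∈B} p_i k_ij is a second, largely independent route to the
same MFPT.  Under recycling every walker descends from an A-injection,
so the "trajectories originating in A" restriction is satisfied by
construction.  The stationary solve uses a dense linear system with the
normalization row substituted; reducibility of the observed submatrix is
detected by strongly-connected-component analysis and reported with the
disconnected blocks.  The bin-level chain is only "Markov-like": if the
binned coordinate hides slow degrees of freedom the matrix route can be
biased even when the direct flux is not, which is why both estimators
are reported and compared.

**First-passage-time distributions.**  Per-iteration arrival weights,
averaged over independent runs, estimate P(first passage in iteration t)
with 1σ errors across runs; their sum is the total crossing probability
in the window.  Under recycling, reinjected weight can in principle
arrive a second time; this contributes at second order in the total
probability and is negligible in the ~10⁻⁴ regimes this estimator is
used for (fixed-horizon runs on time-dependent models use absorbing
boundaries, where the issue does not arise at all).

## The well-mixed engine

Exact Gillespie direct-method SSA.  Rate conventions: zero-order rates in
molecules/s, first-order in 1/s, bimolecular in 1/M/s converted to a
per-pair propensity constant k/(N_A·V) (distinct pairs, i.e. n(n−1)/2
for identical reactants); models without a declared volume interpret
second-order constants directly as stochastic per-pair rates.

Time-dependent rates are piecewise-constant schedules; propagation is
segmented at schedule breakpoints and the SSA is exact within each
segment, so no thinning error is incurred for piecewise-constant drives.
Smooth rate laws are tabulated by `RateSchedule.from_function`, which
refines the grid until the rate changes by < 1% (configurable) between
adjacent sub-steps.  Models with time-dependent rates have no steady
state; the run loop refuses recycling for them and only fixed-horizon
(absorbing) runs are allowed.

## The spatial engine

Point particles take Gaussian steps of per-axis variance 2DΔt inside a
rectangular box with specular reflective walls (reflection by folding,
correct for arbitrarily large steps).  Receptors are a patch-level
free/bound count on a named wall, not individually positioned sites.
Per step: (1) bound ligands unbind with probability 1 − exp(−k_off Δt)
and re-enter the volume at the wall, taking their first diffusive step
the *next* Δt; (2) each particle free at the start of the step proposes
a displacement; (3) a proposal crossing a receptor wall binds with
probability min(1, c·n_free); (4) survivors reflect.

The encounter coefficient c is fixed in closed form by a well-mixed-limit
matching argument: a uniformly distributed particle attempts a crossing
of a given wall with probability σ/(L⊥√(2π)) per step (the integral of
the Gaussian tail over the distance to the wall), so

    c = k_on · Δt · √(2π) · L⊥ / (N_A · V · σ),    σ = √(2DΔt)

makes the realized per-ligand binding rate equal the macroscopic
mass-action rate k_on·n_free/(N_A V) when the particle distribution is
uniform.  The test suite verifies the contract directly: at 100× the toy
diffusion constant the realized association rate matches mass action
within 5%, and reversible binding reaches the same equilibrium as the
well-mixed SSA engine within sampling error.  Validity limits: the
closed form assumes σ ≪ L⊥ and a per-encounter acceptance ≲ a few
percent.  At higher acceptance a depletion layer forms at the wall and
the realized rate falls below mass action (measured: −1.5% at 2%
acceptance, −12% at 7%); in that regime the engine's binding is
diffusion-influenced and the macroscopic k_on is no longer the right
reference.  All of the package's built-in models operate at ≤ 2.5%
acceptance.

**Toy diffusive-binding model.**  Cube of side 2 μm; 1000 ligands all
bound to 1000 top-face receptors at t = 0; 1000 free bottom-face
receptors; k_off = 10³/s, k_on = 10⁸/M/s at both faces (one chemistry,
two patches); D = 10⁻⁶ cm²/s; Δt = 10 μs; horizon 10 ms; progress
coordinate = bottom-bound count, with one bin per integer on [0, 1000]
and τ equal to exactly one internal step.  Initial bound positions are a
deterministic golden-ratio lattice on the top face — they act only as
unbinding release points.  Brute-force replicas are propagated in a
single vectorized batch (replicas × particles), which is what makes the
e.g. 200-trajectory reference ensemble a sub-minute computation.

## Fixtures and their oracles

Every fixture ships at least one oracle, and every oracle is itself
cross-checked by a second route before the suite relies on it:

* **Birth–death chain** (births at λ, per-capita deaths at γ): truncated
  stationary law = renormalized Poisson(λ/γ) (detailed balance);
  MFPT(0→n) from the first-step linear system, cross-checked against the
  classical closed-form double sum.
* **Finite-state jump process** from a rate matrix Q: occupancies
  p(t) = p(0)·exp(Qt), cross-checked by uniformization.
* **Pulsed rare-crossing model**: an immigration–death chain whose birth
  rate is η₀ only during [t₁, t₂).  Crossing probabilities come from
  exact path sampling in the M/G/∞ representation (Poisson births,
  independent exponential lifetimes, maximum concurrency scanned at
  birth epochs — exact because the count increases only at births),
  cross-checked by an absorbing-boundary matrix exponential.  Default
  parameters (η₀ = 1.8, window [0.5, 2.0), γ = 1, threshold 8) put the
  crossing probability at ~3×10⁻⁴, exercising the many-small-runs
  averaging protocol.

## Problem sizes used by the test and acceptance runs

Chosen so the full suite completes in a few minutes on one CPU while
every assertion retains statistical power: 10⁴ randomized resamples for
conservation; 32 independent WE runs for the occupancy/bootstrap checks;
8 independent recycling runs × 400 iterations (τ = 0.2) for the MFPT
comparison; a 600-iteration (τ = 0.1) single run plus its equal-cost
~200-trajectory brute-force ensemble for the tail-resolution check; 100
small WE runs vs a 10⁶-path oracle for the pulse protocol; ≥ 50 (200 in
the acceptance script) brute-force toy trajectories for the modal
bound-count.  The tail check uses τ = 0.1 rather than 0.3 because the
splitting ladder only populates deep bins efficiently when τ is short
compared to the bin relaxation time; with τ = 0.3 the same cost resolves
roughly one fewer decade of probability.

## What the synthetic models do and do not show

The fixtures are low-dimensional count processes with fast, well-mixed
internal dynamics and progress coordinates that capture the slow
direction essentially perfectly.  Passing tests therefore demonstrate
the *exactness* of the resampling, recycling and estimation machinery —
not that WE will be efficient on a given realistic system, where
progress-coordinate quality, orthogonal slow degrees of freedom and
inter-walker correlation dominate practical performance.  The spatial
engine reproduces the physics the toy study depends on (Brownian
transport, reflective geometry, calibrated surface binding at patch
resolution) but is deliberately simplified: box geometry only, no
mesh surfaces, no individually positioned receptor sites, no
volume-volume bimolecular reactions between diffusing species.
Uncertainty is always quoted across independent runs; within-run
correlation of walkers sharing ancestry is real and no
autocorrelation-corrected single-run error bar is attempted.

Bootstrap intervals are percentile bootstrap of the mean (default
10,000 resamples, 95%); with few runs the percentile interval slightly
undercovers (a generic small-sample property, ~94% at 40 runs), which
the coverage test accounts for.
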