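# wesample

Weighted-ensemble (WE) rare-event sampling for stochastic models of
cellular biology: a reusable resampling framework with steady-state
recycling and Hill-relation mean-first-passage-time estimation, plus two
built-in dynamics engines (exact well-mixed stochastic kinetics and a
simplified particle-based spatial kinetic Monte Carlo engine).

## The problem and the method

Many quantities of biological interest — the probability that an unusual
number of receptors is occupied, the time to the first vesicle fusion at
low calcium, the mean time to produce a handful of signaling proteins —
live in the *tails* of a stochastic model's distribution.  Plain
("brute-force") simulation concentrates its samples at the peak: with *N*
independent trajectories, nothing rarer than probability 1/*N* is ever
seen.

Weighted ensemble spreads the sampling out instead.  An ensemble of
trajectory replicas ("walkers"), each carrying a statistical weight, is
propagated under the **unmodified** dynamics for a fixed interval τ and
then resampled by bin along a progress coordinate: a bin below its target
count of walkers has its heaviest walker **split** (the weight divided
exactly among the daughters), a bin above target has its two lightest
walkers **merged** (one survives with probability ∝ weight, carrying the
summed weight).  Total weight is conserved to machine precision, no bias
is introduced, and hard-to-reach bins stay populated by low-weight
walkers.  The weighted histogram over any coordinate is then an unbiased
estimate of the true distribution — including tail bins far below the
brute-force floor.

With **recycling** boundary conditions (walkers entering a target state B
are removed and their weight reinjected at the initial state A) the
ensemble relaxes to a steady A→B flow, and the Hill relation converts the
mean recycled flux into a mean first passage time:

    MFPT(A → B) = 1 / Flux(A → B)

A second, independent route estimates bin-to-bin transition probabilities
k_ij per interval τ from the stored walker lineage, solves the
stationarity condition ∀i: Σ_j k_ji p_j = Σ_j k_ij p_i, and evaluates
Flux(A→B) = Σ_{i∉B} Σ_{j∈B} p_i k_ij.  The package implements both and
cross-checks them.

## Worked example

Estimate the mean first passage time from an empty immigration–death
chain (births at λ = 10/s, per-capita deaths at γ = 1/s) to a count of
20 — a mildly rare excursion — and compare both WE routes with the exact
first-step-analysis answer:

```python
import numpy as np
import wesample as ws
from wesample.fixtures import make_birth_death
from wesample.steady_state import StateDefinition, hill_mfpt_multi, \
    mfpt_from_transition_matrix

fx = make_birth_death(lam=10.0, gamma=1.0, n_states=20)
print(f"analytic MFPT(0->20): {fx.mfpt():.2f}")

engine = fx.engine(track_max=True)         # monotone running-max coordinate
scheme = ws.BinScheme.integer_bins(0, 20, target_count=8, top_to=np.inf)
B = StateDefinition.at_least("B", 20.0)

series, matrix_route = [], []
for seed in range(8):                      # independent runs -> error bars
    cfg = ws.WEConfig(tau=0.2, n_iterations=400, mode="recycle",
                      initial_states=[fx.initial_state()],
                      target_state=B, seed=100 + seed)
    store = ws.run_we(engine, scheme, cfg)
    series.append(store.flux_series())
    matrix_route.append(mfpt_from_transition_matrix(store, scheme, B).mfpt)

hill = hill_mfpt_multi(series, burn_in=0.5)
m = np.asarray(matrix_route)
print(f"Hill-relation MFPT:   {hill.mfpt:.2f} +- {hill.se:.2f}")
print(f"matrix-route MFPT:    {m.mean():.2f} +- {m.std(ddof=1)/np.sqrt(8):.2f}")
```

Output:

```
analytic MFPT(0->20): 62.42
Hill-relation MFPT:   61.79 +- 4.85
matrix-route MFPT:    62.38 +- 4.36
```

Both WE estimates bracket the exact value of 62.42 time units within one
standard error, using only 80 time units of simulation per run.

## Command line

```
wesample run config.yaml          # -> <output>.h5 + <output>_summary.tsv
wesample bruteforce config.yaml -n 611
wesample analyze hist|mfpt|fpt|compare <store.h5> --out table.tsv
wesample fixtures birth_death --lam 10 --gamma 1 --n-states 20
```

See `wesample.cli` for the YAML schema.  Stores are HDF5 (one group per
iteration: walker ids, parents, weights, progress coordinates, bin
indices, recycled flux; config and seed embedded) with flat TSV mirrors.

## The toy diffusive-binding model

`wesample.engines.build_toy_model()` constructs the built-in spatial
benchmark: a 2 μm cube whose top face carries 1000 receptors, all
ligand-bound at t = 0, and whose bottom face carries 1000 free
receptors.  Ligands unbind (k_off = 10³/s), diffuse (D = 10⁻⁶ cm²/s,
10 μs timestep) and rebind at either face (k_on = 10⁸/M/s).  After 10 ms
the number of bottom-bound receptors is typically 10–20, and the far
tail of that distribution is exactly what WE resolves at equal cost
while brute force cannot.

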