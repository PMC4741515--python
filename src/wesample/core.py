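"""Walkers, ensembles and the weighted-ensemble resampling algorithm.

The resampling step is the heart of weighted ensemble: at the end of each
propagation interval tau the walkers are grouped by progress-coordinate
bin, and every occupied bin is brought to its target walker count.

* Under-populated bins are **up-sampled**: the highest-weight walker is
  split into identical daughters, the parent's weight divided exactly
  among them (one division per daughter, never repeated subtraction).
  Extra copies are allocated greedily to whichever walker currently has
  the largest weight per copy, which flattens the weight variance.
* Over-populated bins are **down-sampled** by iterated pairwise merging of
  the two lowest-weight walkers: one of the pair survives, chosen randomly
  with probability proportional to its weight, and inherits the summed
  weight.  The expectation of any state indicator is thereby preserved.

Ties in either direction are broken by walker id (stable, reproducible).
Total weight is conserved to within floating-point rounding (< 1e-12 in
practice), and empty bins stay empty: resampling never invents probability
in unvisited regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from wesample.binning import BinningError, BinScheme

__all__ = [
    "Walker",
    "Ensemble",
    "ResampleReport",
    "WERunError",
    "split_walker",
    "merge_walkers",
    "resample",
    "run_we",
    "rng_stream",
]

# Sub-stream purpose codes for the per-iteration RNG streams.
_PROPAGATE, _RECYCLE, _RESAMPLE, _INIT = 0, 1, 2, 3


def rng_stream(seed: int, iteration: int, purpose: int) -> np.random.Generator:
    """Independent RNG stream keyed by (root seed, iteration, purpose).

    One root seed spawns a distinct, reproducible PCG64 stream for every
    (iteration, purpose) pair, so runs are bit-reproducible regardless of
    how many random draws any single phase consumes.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=(int(iteration), int(purpose)))
    return np.random.Generator(np.random.PCG64(ss))


@dataclass(frozen=True)
class Walker:
    """One trajectory replica carrying a statistical weight.

    ``state`` is opaque to the WE machinery; only the engine interprets
    it.  ``pcoord`` is the walker's current progress-coordinate vector.
    ``parent_id`` names the walker this one was copied from at the last
    resampling (itself, if it has not been split or recycled).
    """

    id: int
    weight: float
    state: Any
    pcoord: np.ndarray
    parent_id: int
    iteration_created: int = 0

    def __post_init__(self):
        pc = np.asarray(self.pcoord, dtype=float).reshape(-1)
        object.__setattr__(self, "pcoord", pc)
        if not (self.weight > 0.0):
            raise ValueError(
                f"walker {self.id} has non-positive weight {self.weight}"
            )
        if not math.isfinite(self.weight):
            raise ValueError(f"walker {self.id} has non-finite weight")
        if not np.all(np.isfinite(pc)):
            raise ValueError(f"walker {self.id} has non-finite pcoord {pc}")


@dataclass
class Ensemble:
    """A collection of weighted walkers at one WE iteration boundary."""

    walkers: list[Walker]
    iteration: int = 0
    next_id: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.next_id is None:
            self.next_id = 1 + max((w.id for w in self.walkers), default=-1)

    @property
    def total_weight(self) -> float:
        return math.fsum(w.weight for w in self.walkers)

    def __len__(self) -> int:
        return len(self.walkers)

    def allocate_ids(self, n: int) -> list[int]:
        ids = list(range(self.next_id, self.next_id + n))
        self.next_id += n
        return ids

    def pcoord_array(self) -> np.ndarray:
        if not self.walkers:
            return np.empty((0, 0))
        return np.stack([w.pcoord for w in self.walkers])


@dataclass(frozen=True)
class ResampleReport:
    """Audit record of one resampling event."""

    iteration: int
    n_splits: int
    n_merges: int
    bin_populations_before: dict[int, int]
    bin_populations_after: dict[int, int]
    weight_before: float
    weight_after: float


class WERunError(RuntimeError):
    """A WE run aborted mid-iteration; carries the partial RunStore."""

    def __init__(self, message: str, iteration: int, store=None):
        super().__init__(message)
        self.iteration = iteration
        self.store = store


def split_walker(
    w: Walker, n: int, ids: Sequence[int] | None = None, iteration: int | None = None
) -> list[Walker]:
    """Split one walker into ``n`` identical daughters.

    Each daughter shares the parent's state and pcoord and carries exactly
    ``w.weight / n``; the weights sum back to the parent weight up to one
    rounding ulp because a single division is used.  ``parent_id`` of each
    daughter is ``w.id``.
    """
    if n < 2:
        raise ValueError(f"cannot split a walker into n={n} < 2 daughters")
    if not math.isfinite(w.weight) or w.weight <= 0.0:
        raise ValueError(f"walker {w.id} has invalid weight {w.weight}")
    if ids is None:
        ids = [w.id] + [-(k + 1) for k in range(n - 1)]  # placeholder ids
    if len(ids) != n:
        raise ValueError(f"{len(ids)} ids supplied for n={n} daughters")
    wt = w.weight / n
    it = w.iteration_created if iteration is None else iteration
    return [
        Walker(
            id=i,
            weight=wt,
            state=w.state,
            pcoord=w.pcoord,
            parent_id=w.id,
            iteration_created=it,
        )
        for i in ids
    ]


def merge_walkers(pair: Sequence[Walker], rng: np.random.Generator) -> Walker:
    """Merge two walkers into one survivor.

    The survivor is drawn with probability ``w_i / (w_i + w_j)`` and keeps
    its own state, pcoord and identity, but carries the summed weight, so
    the statistical expectation of any state indicator is preserved.
    """
    a, b = pair
    for w in (a, b):
        if not math.isfinite(w.weight) or w.weight <= 0.0:
            raise ValueError(f"walker {w.id} has invalid weight {w.weight}")
    total = a.weight + b.weight
    survivor = a if rng.random() < a.weight / total else b
    return replace(survivor, weight=total)


def _assign_with_ids(ensemble: Ensemble, scheme: BinScheme) -> np.ndarray:
    """Bin indices for every walker; errors name the offending walker."""
    if not ensemble.walkers:
        return np.empty(0, dtype=int)
    pcs = ensemble.pcoord_array()
    try:
        return scheme.assign(pcs)
    except BinningError as exc:
        # Re-raise naming the walker rather than the anonymous row.
        for w in ensemble.walkers:
            try:
                scheme.assign_one(w.pcoord)
            except BinningError:
                raise BinningError(
                    f"walker {w.id}: pcoord {w.pcoord} outside bin domain"
                ) from exc
        raise


def _merge_bin(
    walkers: list[Walker], target: int, rng: np.random.Generator
) -> tuple[list[Walker], int]:
    """Iterated pairwise merging of the two lowest-weight walkers."""
    pool = sorted(walkers, key=lambda w: (w.weight, w.id))
    n_merges = 0
    while len(pool) > target:
        a = pool.pop(0)
        b = pool.pop(0)
        surv = merge_walkers((a, b), rng)
        n_merges += 1
        # re-insert keeping (weight, id) order
        lo, hi = 0, len(pool)
        key = (surv.weight, surv.id)
        while lo < hi:
            mid = (lo + hi) // 2
            if (pool[mid].weight, pool[mid].id) < key:
                lo = mid + 1
            else:
                hi = mid
        pool.insert(lo, surv)
    return pool, n_merges


def _split_bin(
    walkers: list[Walker], target: int, ensemble: Ensemble, iteration: int
) -> tuple[list[Walker], int]:
    """Allocate daughter slots to flatten weight variance, then split."""
    slots = {w.id: 1 for w in walkers}
    by_id = {w.id: w for w in walkers}
    n_extra = target - len(walkers)
    for _ in range(n_extra):
        # walker with the largest weight per daughter slot; ties -> low id
        best = min(
            slots, key=lambda i: (-by_id[i].weight / slots[i], i)
        )
        slots[best] += 1
    out: list[Walker] = []
    n_splits = 0
    for w in walkers:
        m = slots[w.id]
        if m == 1:
            out.append(w)
        else:
            ids = [w.id] + ensemble.allocate_ids(m - 1)
            out.extend(split_walker(w, m, ids=ids, iteration=iteration))
            n_splits += 1
    return out, n_splits


def resample(
    ensemble: Ensemble, scheme: BinScheme, rng: np.random.Generator
) -> tuple[Ensemble, ResampleReport]:
    """Bring every occupied bin to its target walker count.

    Returns a new :class:`Ensemble` (the input is not modified beyond id
    allocation) together with a :class:`ResampleReport`.  Empty bins stay
    empty, total weight is conserved, and a walker whose pcoord falls
    outside the scheme's domain raises a hard error naming it.
    """
    weight_before = ensemble.total_weight
    bin_idx = _assign_with_ids(ensemble, scheme)
    targets = scheme.targets()

    groups: dict[int, list[Walker]] = {}
    for w, b in zip(ensemble.walkers, bin_idx):
        groups.setdefault(int(b), []).append(w)
    pops_before = {b: len(ws) for b, ws in groups.items()}

    out: list[Walker] = []
    n_splits = n_merges = 0
    for b in sorted(groups):
        ws = groups[b]
        tgt = int(targets[b])
        if len(ws) > tgt:
            ws, nm = _merge_bin(ws, tgt, rng)
            n_merges += nm
        elif len(ws) < tgt:
            ws, ns = _split_bin(ws, tgt, ensemble, ensemble.iteration)
            n_splits += ns
        out.extend(ws)
    out.sort(key=lambda w: w.id)

    new_ens = Ensemble(out, iteration=ensemble.iteration, next_id=ensemble.next_id)
    pops_after: dict[int, int] = {}
    for b in np.asarray(_assign_with_ids(new_ens, scheme)):
        pops_after[int(b)] = pops_after.get(int(b), 0) + 1
    report = ResampleReport(
        iteration=ensemble.iteration,
        n_splits=n_splits,
        n_merges=n_merges,
        bin_populations_before=pops_before,
        bin_populations_after=pops_after,
        weight_before=weight_before,
        weight_after=new_ens.total_weight,
    )
    return new_ens, report


def run_we(engine, scheme: BinScheme, config, store=None, progress=None):
    """Run the full weighted-ensemble loop and return a RunStore.

    Each iteration: propagate every walker by tau under the engine's
    unmodified dynamics, detect arrivals in the target state (recording
    the recycled/absorbed flux when steady-state boundary conditions are
    enabled), record the walker table, then resample.  The run is fully
    deterministic given ``config.seed``.

    Parameters
    ----------
    engine
        Object satisfying the engine contract: ``propagate(state, tau,
        rng) -> state`` (returning a *new* state object) and
        ``pcoord(state) -> array``.
    scheme
        The :class:`~wesample.binning.BinScheme` for resampling.
    config
        A :class:`~wesample.config.WEConfig`.
    store
        Optional pre-built :class:`~wesample.store.RunStore` to append to
        (used by the CLI); a fresh in-memory store is created by default.
    progress
        Optional callback invoked once per iteration with
        ``(iteration, n_walkers, total_weight, flux, wall_seconds)``.
    """
    import time as _time
    from wesample.config import WEConfig  # local import: avoid cycle
    from wesample.store import RunStore

    if not isinstance(config, WEConfig):
        raise TypeError("config must be a WEConfig")
    config.validate()
    if config.mode in ("recycle", "absorb"):
        if getattr(engine, "time_dependent", False) and config.mode == "recycle":
            raise ValueError(
                "recycling (steady-state) analysis is not valid for a "
                "time-dependent model; use mode='absorb' with a fixed horizon"
            )
        if config.target_state is None:
            raise ValueError(f"mode={config.mode!r} requires a target_state")

    seed = int(config.seed)
    rng_init = rng_stream(seed, 0, _INIT)
    walkers = []
    for i, (state, wt) in enumerate(zip(config.initial_states, config.initial_weights)):
        pc = np.asarray(engine.pcoord(state), dtype=float).reshape(-1)
        walkers.append(
            Walker(id=i, weight=wt, state=state, pcoord=pc, parent_id=i)
        )
    ens = Ensemble(walkers, iteration=0)

    if store is None:
        store = RunStore.new(config=config, scheme=scheme)
    bins0 = _assign_with_ids(ens, scheme)
    store.record_iteration(0, ens, bins0, flux=0.0, n_splits=0, n_merges=0)

    target = config.target_state
    sampler = config.reinjection_sampler()

    for it in range(1, config.n_iterations + 1):
        _t0 = _time.perf_counter()
        rng_p = rng_stream(seed, it, _PROPAGATE)
        new_walkers = []
        for w in ens.walkers:
            try:
                s2 = engine.propagate(w.state, config.tau, rng_p)
            except Exception as exc:  # noqa: BLE001 - persist partial store
                raise WERunError(
                    f"engine failed at iteration {it} on walker {w.id}: {exc}",
                    iteration=it,
                    store=store,
                ) from exc
            pc = np.asarray(engine.pcoord(s2), dtype=float).reshape(-1)
            new_walkers.append(replace(w, state=s2, pcoord=pc))
        ens = Ensemble(new_walkers, iteration=it, next_id=ens.next_id)

        # Arrival detection at tau resolution: a walker is "in B" iff its
        # end-of-interval pcoord satisfies the target predicate.
        flux = 0.0
        arrived = []
        if config.mode in ("recycle", "absorb") and target is not None:
            arrived = [w for w in ens.walkers if target.contains(w.pcoord)]
            flux = math.fsum(w.weight for w in arrived)

        bins = _assign_with_ids(ens, scheme)
        store.record_iteration(it, ens, bins, flux=flux)

        recorded_ids = {w.id for w in ens.walkers}
        repl_parent: dict[int, int] = {}
        if arrived:
            rng_r = rng_stream(seed, it, _RECYCLE)
            kept = [w for w in ens.walkers if not target.contains(w.pcoord)]
            if config.mode == "recycle":
                for w in arrived:
                    s0 = sampler(rng_r)
                    pc0 = np.asarray(engine.pcoord(s0), dtype=float).reshape(-1)
                    if target.contains(pc0):
                        raise ValueError(
                            "initial sampler produced a state already inside "
                            "the target state: ill-posed steady state"
                        )
                    (nid,) = ens.allocate_ids(1)
                    repl_parent[nid] = w.id
                    kept.append(
                        Walker(
                            id=nid,
                            weight=w.weight,
                            state=s0,
                            pcoord=pc0,
                            parent_id=w.id,
                            iteration_created=it,
                        )
                    )
            ens = Ensemble(kept, iteration=it, next_id=ens.next_id)
            if not ens.walkers:  # every walker absorbed
                store.finalize_early(it)
                break

        rng_s = rng_stream(seed, it, _RESAMPLE)
        ens, report = resample(ens, scheme, rng_s)
        store.record_resample(it, report, ens)

        # Rewrite parent links so that each walker entering the next
        # propagation names its ancestor in the table just recorded (or
        # itself, if it appeared there unchanged).  This keeps the stored
        # lineage resolvable one iteration back even when a recycled
        # replacement is split in the same resampling event.
        fixed = []
        for w in ens.walkers:
            if w.id in recorded_ids:
                anc = w.id
            elif w.parent_id in recorded_ids:
                anc = w.parent_id
            elif w.parent_id in repl_parent:
                anc = repl_parent[w.parent_id]
            elif w.id in repl_parent:
                anc = repl_parent[w.id]
            else:  # pragma: no cover - defensive; lineage depth is <= 2
                raise WERunError(
                    f"unresolvable lineage for walker {w.id}",
                    iteration=it,
                    store=store,
                )
            fixed.append(w if w.parent_id == anc else replace(w, parent_id=anc))
        ens = Ensemble(fixed, iteration=it, next_id=ens.next_id)

        if progress is not None:
            progress(
                it, len(ens), ens.total_weight, flux, _time.perf_counter() - _t0
            )

    store.close()
    return store
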