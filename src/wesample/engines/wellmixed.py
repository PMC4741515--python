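"""Exact well-mixed stochastic chemical kinetics (Gillespie SSA).

Models are collections of reactions over named species.  Rate constants
carry conventional units: per second for zero- and first-order reactions
(zero-order rates are given directly in molecules per second), per molar
per second for bimolecular reactions, which are converted to stochastic
propensity constants via ``k / (N_A * V)`` per reactant pair.  Models
without a declared volume interpret second-order constants directly as
stochastic per-pair rates.

Time-dependent rates are supported through piecewise-constant schedules:
propagation is segmented at schedule breakpoints and the SSA is exact
within each constant segment.  Smooth rate laws can be tabulated onto a
grid fine enough that the rate changes by less than a chosen relative
tolerance per sub-step (see :meth:`RateSchedule.from_function`).
"""

from __future__ import annotations


from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from wesample.engines.base import EngineError

AVOGADRO = 6.02214076e23

__all__ = [
    "AVOGADRO",
    "Reaction",
    "RateSchedule",
    "ReactionModel",
    "WellMixedState",
    "WellMixedEngine",
    "time_dependent_rate",
]


@dataclass(frozen=True)
class RateSchedule:
    """Piecewise-constant rate as a function of absolute time.

    ``rate(t) = values[k]`` for ``t`` in ``[times[k], times[k+1])``; the
    first value extends to ``-inf`` and the last to ``+inf``.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        ts = np.asarray(self.times, dtype=float)
        vs = np.asarray(self.values, dtype=float)
        if ts.ndim != 1 or ts.size != vs.size or ts.size == 0:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if not np.all(np.diff(ts) > 0):
            raise ValueError("schedule times must be strictly increasing")
        if np.any(vs < 0):
            raise ValueError("schedule rates must be non-negative")
        object.__setattr__(self, "times", ts)
        object.__setattr__(self, "values", vs)

    def rate(self, t: float) -> float:
        k = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.values[max(k, 0)])

    def breakpoints_in(self, t0: float, t1: float) -> np.ndarray:
        ts = self.times
        return ts[(ts > t0) & (ts < t1)]

    @classmethod
    def constant(cls, value: float) -> "RateSchedule":
        return cls(times=np.array([0.0]), values=np.array([float(value)]))

    @classmethod
    def from_function(
        cls, fn: Callable[[float], float], t_max: float, rel_tol: float = 0.01
    ) -> "RateSchedule":
        """Tabulate a smooth rate law onto a sufficiently fine grid.

        The grid is refined until the rate changes by less than
        ``rel_tol`` (relative to the schedule maximum) between adjacent
        sub-steps, so the stepwise-constant approximation perturbs
        propensities by under that tolerance.
        """
        n = 16
        while True:
            ts = np.linspace(0.0, t_max, n + 1)[:-1]
            vs = np.array([fn(t) for t in ts])
            vmax = vs.max() if vs.size else 0.0
            if vmax == 0.0 or np.all(np.abs(np.diff(vs)) <= rel_tol * vmax):
                return cls(times=ts, values=vs)
            if n >= 1 << 20:
                raise ValueError("rate law refuses to resolve; check rel_tol")
            n *= 2


@dataclass(frozen=True)
class Reaction:
    """One reaction channel with integer stoichiometries."""

    reactants: dict[str, int]
    products: dict[str, int]
    rate: float
    name: str = ""
    schedule: RateSchedule | None = None

    @property
    def order(self) -> int:
        return sum(self.reactants.values())


@dataclass(frozen=True)
class ReactionModel:
    """Well-mixed reaction network (species, reactions, optional volume)."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    volume: float | None = None  # liters

    def __init__(self, species: Sequence[str], reactions: Sequence[Reaction],
                 volume: float | None = None):
        object.__setattr__(self, "species", tuple(species))
        object.__setattr__(self, "reactions", tuple(reactions))
        object.__setattr__(self, "volume", volume)
        idx = {s: i for i, s in enumerate(self.species)}
        for r in self.reactions:
            for s, n in list(r.reactants.items()) + list(r.products.items()):
                if s not in idx:
                    raise ValueError(f"unknown species {s!r} in reaction {r.name!r}")
                if n < 0 or n != int(n):
                    raise ValueError("stoichiometries must be non-negative integers")
            if r.order > 2:
                raise ValueError("reactions above second order are not supported")
            if r.order == 2 and volume is None and r.rate > 0:
                # allowed: rate is then a stochastic per-pair constant
                pass

    @property
    def time_dependent(self) -> bool:
        return any(r.schedule is not None for r in self.reactions)

    def species_index(self, name: str) -> int:
        return self.species.index(name)


def time_dependent_rate(model: ReactionModel, schedules: dict) -> ReactionModel:
    """Attach piecewise-constant rate schedules to named reactions.

    Keys of ``schedules`` are reaction names (or integer indices); values
    are :class:`RateSchedule` objects giving the absolute rate constant as
    a function of time.  The returned model is flagged time-dependent and
    the WE layer will refuse recycling/steady-state analysis for it —
    a system with time-varying kinetics has no steady state and is only
    meaningfully simulated over a fixed horizon.
    """
    new_reactions = list(model.reactions)
    for key, sched in schedules.items():
        if isinstance(key, int):
            i = key
        else:
            names = [r.name for r in model.reactions]
            if key not in names:
                raise ValueError(f"no reaction named {key!r}")
            i = names.index(key)
        if not isinstance(sched, RateSchedule):
            raise TypeError("schedule must be a RateSchedule")
        new_reactions[i] = replace(new_reactions[i], schedule=sched)
    return ReactionModel(model.species, new_reactions, volume=model.volume)


@dataclass(frozen=True)
class WellMixedState:
    """Integer copy numbers plus the current model time.

    ``max_counts`` carries the running per-species maximum since the
    state was created, maintained exactly (the SSA visits every event),
    for use as a monotone progress coordinate in threshold-crossing
    problems.
    """

    counts: np.ndarray
    time: float = 0.0
    max_counts: np.ndarray | None = None

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if np.any(c < 0):
            raise ValueError("copy numbers must be non-negative")
        object.__setattr__(self, "counts", c)
        if self.max_counts is not None:
            object.__setattr__(
                self, "max_counts", np.asarray(self.max_counts, dtype=np.int64)
            )


class WellMixedEngine:
    """Exact SSA propagator for a :class:`ReactionModel`.

    Parameters
    ----------
    model
        The reaction network.
    pcoord_species
        Species whose copy numbers form the progress coordinate
        (default: all species, in declaration order).
    track_max
        If True the progress coordinate reports the *running maximum*
        copy number instead of the instantaneous one — a monotone
        coordinate for first-crossing problems.
    """

    def __init__(
        self,
        model: ReactionModel,
        pcoord_species: str | Sequence[str] | None = None,
        track_max: bool = False,
    ):
        self.model = model
        if pcoord_species is None:
            pcoord_species = model.species
        elif isinstance(pcoord_species, str):
            pcoord_species = [pcoord_species]
        self._pc_idx = np.array(
            [model.species_index(s) for s in pcoord_species], dtype=int
        )
        self.track_max = track_max
        self._compile()

    @property
    def time_dependent(self) -> bool:
        return self.model.time_dependent

    def _compile(self):
        m = self.model
        ns = len(m.species)
        idx = {s: i for i, s in enumerate(m.species)}
        self._delta = np.zeros((len(m.reactions), ns), dtype=np.int64)
        self._react = []  # list of (species_idx array, stoich array)
        self._c = np.zeros(len(m.reactions))
        self._sched = [r.schedule for r in m.reactions]
        na_v = AVOGADRO * m.volume if m.volume else None
        for j, r in enumerate(m.reactions):
            for s, n in r.reactants.items():
                self._delta[j, idx[s]] -= n
            for s, n in r.products.items():
                self._delta[j, idx[s]] += n
            ridx = np.array([idx[s] for s in r.reactants], dtype=int)
            rsto = np.array([r.reactants[s] for s in r.reactants], dtype=int)
            self._react.append((ridx, rsto))
            if r.order == 2 and na_v is not None:
                self._c[j] = r.rate / na_v
            else:
                self._c[j] = r.rate

    def _propensities(self, counts: np.ndarray, t: float) -> np.ndarray:
        a = np.empty(len(self._c))
        for j, (ridx, rsto) in enumerate(self._react):
            c = self._c[j]
            if self._sched[j] is not None:
                c = self._sched[j].rate(t)
            h = 1.0
            for i, n in zip(ridx, rsto):
                x = counts[i]
                if n == 1:
                    h *= x
                else:  # n == 2 : x(x-1)/2 distinct pairs
                    h *= x * (x - 1) / 2.0
            a[j] = c * h
        return a

    def initial_state(self, counts) -> WellMixedState:
        c = np.asarray(counts, dtype=np.int64)
        return WellMixedState(
            counts=c, time=0.0, max_counts=c.copy() if self.track_max else None
        )

    def pcoord(self, state: WellMixedState) -> np.ndarray:
        if self.track_max and state.max_counts is not None:
            src = state.max_counts
        else:
            src = state.counts
        return np.asarray(src, dtype=float)[self._pc_idx]

    def propagate(
        self, state: WellMixedState, tau: float, rng: np.random.Generator
    ) -> WellMixedState:
        if not tau > 0:
            raise EngineError(f"tau must be > 0, got {tau}")
        t0, t_end = state.time, state.time + tau
        counts = state.counts.copy()
        if state.max_counts is not None:
            maxc = state.max_counts.copy()
        elif self.track_max:
            maxc = counts.copy()
        else:
            maxc = None
        # split the interval at schedule breakpoints: SSA is exact within
        # each piecewise-constant segment
        cuts = {t_end}
        for s in self._sched:
            if s is not None:
                cuts.update(s.breakpoints_in(t0, t_end).tolist())
        t = t0
        for seg_end in sorted(cuts):
            t = self._ssa_segment(counts, maxc, t, seg_end, rng)
        return WellMixedState(counts=counts, time=t_end, max_counts=maxc)

    def _ssa_segment(self, counts, maxc, t, t_end, rng) -> float:
        delta = self._delta
        while True:
            a = self._propensities(counts, t)
            a0 = a.sum()
            if a0 <= 0.0:
                return t_end
            dt = rng.exponential(1.0 / a0)
            if t + dt > t_end:
                return t_end
            t += dt
            j = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
            j = min(j, len(a) - 1)
            counts += delta[j]
            if maxc is not None:
                np.maximum(maxc, counts, out=maxc)
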