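"""Synthetic fixture models with independently computable ground truth.

Each fixture couples a model (runnable through the standard engines) with
at least one oracle evaluated by an independent route — closed forms,
dense linear algebra on the master equation, or exact path sampling — so
that every WE mechanism can be validated without external data.

* :func:`make_birth_death` — immigration-death chain (birth at constant
  rate lambda, per-capita death rate gamma).  Oracles: the Poisson
  stationary law (mean lambda/gamma) and the exact MFPT to a target
  count from first-step analysis (a dense linear solve on the
  generator).
* :func:`make_jump_process` — an arbitrary finite-state continuous-time
  jump process from its rate matrix Q.  Oracles: matrix-exponential
  occupancies ``p(t) = p(0) exp(Q t)`` cross-checked by uniformization.
* :func:`make_nmj_like_pulse` — an immigration-death chain whose birth
  rate switches on only during a pulse window, emulating protocols where
  a brief time-dependent drive makes a threshold crossing rare
  (probability tunable to ~1e-4).  Oracle: exact path sampling through
  the M/G/inf representation (births are a Poisson process; each born
  molecule carries an independent exponential lifetime), cross-checked
  by an absorbing-boundary master-equation solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.stats import poisson

from wesample.engines.wellmixed import (
    RateSchedule,
    Reaction,
    ReactionModel,
    WellMixedEngine,
    WellMixedState,
    time_dependent_rate,
)

__all__ = [
    "BirthDeathFixture",
    "JumpProcessFixture",
    "PulseFixture",
    "JumpProcessEngine",
    "JumpState",
    "make_birth_death",
    "make_jump_process",
    "make_nmj_like_pulse",
]


# ---------------------------------------------------------------------
# birth-death chain


@dataclass(frozen=True)
class BirthDeathFixture:
    """Immigration-death chain with analytic stationary law and MFPT."""

    lam: float  # birth rate, molecules per unit time
    gamma: float  # per-capita death rate
    n_states: int  # target count; the chain is studied on {0..n_states}
    model: ReactionModel

    def engine(self, track_max: bool = False) -> WellMixedEngine:
        return WellMixedEngine(self.model, pcoord_species="A", track_max=track_max)

    def initial_state(self, count: int = 0) -> WellMixedState:
        return WellMixedState(counts=np.array([count]))

    # -- oracles ------------------------------------------------------

    def stationary_mean(self) -> float:
        """Untruncated stationary mean (Poisson law)."""
        return self.lam / self.gamma

    def stationary_pmf(self, nmax: int | None = None) -> np.ndarray:
        """Stationary law truncated at ``nmax`` (renormalized Poisson).

        Truncating the chain by blocking births from ``nmax`` preserves
        detailed balance, so the truncated stationary law is exactly the
        Poisson(lambda/gamma) pmf renormalized on {0..nmax}.
        """
        if nmax is None:
            nmax = self.n_states
        pmf = poisson.pmf(np.arange(nmax + 1), self.lam / self.gamma)
        return pmf / pmf.sum()

    def generator(self, nmax: int) -> np.ndarray:
        """CTMC generator on {0..nmax} with births blocked at nmax."""
        q = np.zeros((nmax + 1, nmax + 1))
        for i in range(nmax + 1):
            if i < nmax:
                q[i, i + 1] = self.lam
            if i > 0:
                q[i, i - 1] = self.gamma * i
            q[i, i] = -q[i].sum()
        return q

    def mfpt(self, start: int = 0, target: int | None = None) -> float:
        """Exact MFPT(start -> target) by first-step analysis.

        On the transient states {0..target-1} the hitting times satisfy
        ``Q_t u = -1``; a dense solve gives ``u[start]``.
        """
        if target is None:
            target = self.n_states
        if not 0 <= start < target:
            raise ValueError("require 0 <= start < target")
        qt = np.zeros((target, target))
        for i in range(target):
            if i > 0:
                qt[i, i - 1] = self.gamma * i
            if i + 1 < target:
                qt[i, i + 1] = self.lam
            qt[i, i] = -(self.lam + self.gamma * i)  # birth from target-1 exits
        u = np.linalg.solve(qt, -np.ones(target))
        return float(u[start])


def make_birth_death(lam: float, gamma: float, n_states: int) -> BirthDeathFixture:
    """Immigration-death chain: 0 -> A at rate lam, A -> 0 at gamma per A."""
    if lam <= 0 or gamma <= 0:
        raise ValueError("lam and gamma must be positive")
    model = ReactionModel(
        species=["A"],
        reactions=[
            Reaction(reactants={}, products={"A": 1}, rate=lam, name="birth"),
            Reaction(reactants={"A": 1}, products={}, rate=gamma, name="death"),
        ],
    )
    return BirthDeathFixture(lam=lam, gamma=gamma, n_states=n_states, model=model)


# ---------------------------------------------------------------------
# finite-state jump process


@dataclass(frozen=True)
class JumpState:
    index: int
    time: float = 0.0


class JumpProcessEngine:
    """Exact CTMC simulation of a finite-state jump process."""

    time_dependent = False

    def __init__(self, q: np.ndarray):
        self.q = np.asarray(q, dtype=float)
        self._exit = -np.diag(self.q)
        self._jump_p = []
        n = self.q.shape[0]
        for i in range(n):
            row = self.q[i].copy()
            row[i] = 0.0
            tot = row.sum()
            self._jump_p.append(row / tot if tot > 0 else row)

    def initial_state(self, index: int = 0) -> JumpState:
        return JumpState(index=index, time=0.0)

    def pcoord(self, state: JumpState) -> np.ndarray:
        return np.array([float(state.index)])

    def propagate(self, state: JumpState, tau: float, rng: np.random.Generator):
        t, t_end = state.time, state.time + tau
        i = state.index
        while True:
            rate = self._exit[i]
            if rate <= 0.0:
                break  # absorbing
            dt = rng.exponential(1.0 / rate)
            if t + dt > t_end:
                break
            t += dt
            i = int(rng.choice(len(self._jump_p[i]), p=self._jump_p[i]))
        return JumpState(index=i, time=t_end)


@dataclass(frozen=True)
class JumpProcessFixture:
    q: np.ndarray

    def engine(self) -> JumpProcessEngine:
        return JumpProcessEngine(self.q)

    def initial_state(self, index: int = 0) -> JumpState:
        return JumpState(index=index)

    @property
    def n_states(self) -> int:
        return self.q.shape[0]

    # -- oracles ------------------------------------------------------

    def occupancy(self, p0, t: float) -> np.ndarray:
        """Master-equation solution p(t) = p(0) exp(Q t)."""
        p0 = np.asarray(p0, dtype=float)
        return p0 @ expm(self.q * t)

    def occupancy_uniformization(self, p0, t: float, tol: float = 1e-12):
        """Independent route to p(t): uniformization (randomization).

        With ``lam >= max_i |q_ii|`` and ``P = I + Q/lam``, the occupancy
        is a Poisson(lam t)-weighted average of powers of P.
        """
        p0 = np.asarray(p0, dtype=float)
        lam = float(np.max(-np.diag(self.q)))
        if lam == 0.0:
            return p0.copy()
        pmat = np.eye(self.n_states) + self.q / lam
        out = np.zeros_like(p0)
        term = p0.copy()
        k = 0
        w = math.exp(-lam * t)
        acc = 0.0
        while acc < 1.0 - tol:
            out += w * term
            acc += w
            k += 1
            w *= lam * t / k
            term = term @ pmat
            if k > 10_000:
                raise RuntimeError("uniformization failed to converge")
        return out


def make_jump_process(q) -> JumpProcessFixture:
    """Finite-state CTMC from a rate matrix with zero row sums."""
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("Q must be square")
    off = q - np.diag(np.diag(q))
    if np.any(off < 0):
        raise ValueError("off-diagonal rates must be non-negative")
    if np.max(np.abs(q.sum(axis=1))) > 1e-10 * max(1.0, np.max(np.abs(q))):
        raise ValueError("rows of Q must sum to zero")
    return JumpProcessFixture(q=q)


# ---------------------------------------------------------------------
# pulsed rare-event model


@dataclass(frozen=True)
class PulseFixture:
    """Immigration-death chain driven by a birth-rate pulse.

    Births occur at rate ``eta0`` only during ``[t1, t2)`` and molecules
    die at per-capita rate ``gamma``.  The observable is the probability
    that the molecule count ever reaches ``threshold`` within
    ``[0, horizon]``; with the default parameters this is a rare event
    of order 1e-4, mirroring protocols where many small independent WE
    runs are averaged.  Because the rates depend on absolute time the
    model has no steady state: only fixed-horizon WE (mode="absorb")
    applies.
    """

    eta0: float
    t1: float
    t2: float
    gamma: float
    threshold: int
    horizon: float
    model: ReactionModel

    def engine(self) -> WellMixedEngine:
        # the running-max count is the (monotone) progress coordinate
        return WellMixedEngine(self.model, pcoord_species="A", track_max=True)

    def initial_state(self) -> WellMixedState:
        return WellMixedState(counts=np.array([0]), max_counts=np.array([0]))

    # -- oracles ------------------------------------------------------

    def crossing_probability_bruteforce(
        self, n: int, rng: np.random.Generator
    ) -> tuple[float, float]:
        """Exact path-sampled crossing probability over ``n`` replicas.

        Uses the M/G/inf representation: births form a Poisson process
        of rate eta0 on [t1, t2); each molecule lives Exp(gamma).  The
        maximum concurrent count is scanned at birth epochs, which is
        exact because the count only increases at births.  Returns
        (estimate, standard error).
        """
        crossed = self.bruteforce_crossing_samples(n, rng)
        p = float(crossed.mean())
        se = math.sqrt(max(p * (1.0 - p), 0.0) / n)
        return p, se

    def bruteforce_crossing_samples(
        self, n: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Boolean crossing indicator for ``n`` exact sample paths."""
        if self.eta0 <= 0:
            return np.zeros(n, dtype=bool)
        width = self.t2 - self.t1
        n_births = rng.poisson(self.eta0 * width, size=n)
        total = int(n_births.sum())
        if total == 0:
            return np.zeros(n, dtype=bool)
        rep = np.repeat(np.arange(n), n_births)
        births = self.t1 + rng.random(total) * width
        deaths = births + rng.exponential(1.0 / self.gamma, total)
        times = np.concatenate([births, deaths])
        delta = np.concatenate(
            [np.ones(total, dtype=np.int64), -np.ones(total, dtype=np.int64)]
        )
        reps = np.concatenate([rep, rep])
        order = np.lexsort((delta, times, reps))
        reps_o = reps[order]
        cs = np.cumsum(delta[order])
        starts = np.flatnonzero(np.diff(reps_o, prepend=reps_o[0] - 1))
        base = np.where(starts > 0, cs[starts - 1], 0)
        # running count within each replica = global cumsum minus the
        # cumsum value at the end of the previous replica
        offset = np.repeat(base, np.diff(np.append(starts, reps_o.size)))
        counts = cs - offset
        max_per_rep = np.maximum.reduceat(counts, starts)
        crossed = np.zeros(n, dtype=bool)
        crossed[reps_o[starts]] = max_per_rep >= self.threshold
        return crossed

    def crossing_probability_exact(self) -> float:
        """Absorbing-boundary master-equation solve (independent route).

        States {0..threshold} with ``threshold`` absorbing; the count
        cannot increase after the pulse ends, so the crossing
        probability by the horizon equals the absorbed mass at t2.
        """
        k = self.threshold
        q = np.zeros((k + 1, k + 1))
        for i in range(k):
            q[i, i + 1] = self.eta0
            if i > 0:
                q[i, i - 1] = self.gamma * i
            q[i, i] = -q[i].sum()
        p0 = np.zeros(k + 1)
        p0[0] = 1.0
        p = p0 @ expm(q * (self.t2 - self.t1))
        return float(p[k])


def make_nmj_like_pulse(
    eta0: float,
    t1: float,
    t2: float,
    gamma: float = 1.0,
    threshold: int = 8,
    horizon: float | None = None,
) -> PulseFixture:
    """Pulse-driven rare-crossing fixture (see :class:`PulseFixture`)."""
    if not t1 < t2:
        raise ValueError("require t1 < t2")
    if eta0 < 0 or gamma <= 0:
        raise ValueError("eta0 must be >= 0 and gamma > 0")
    if horizon is None:
        horizon = t2 + 1.0
    if not t2 <= horizon:
        raise ValueError("require t2 <= horizon")
    base = ReactionModel(
        species=["A"],
        reactions=[
            Reaction(reactants={}, products={"A": 1}, rate=eta0, name="birth"),
            Reaction(reactants={"A": 1}, products={}, rate=gamma, name="death"),
        ],
    )
    sched = RateSchedule(
        times=np.array([0.0, t1, t2]), values=np.array([0.0, eta0, 0.0])
    )
    model = time_dependent_rate(base, {"birth": sched})
    return PulseFixture(
        eta0=eta0,
        t1=t1,
        t2=t2,
        gamma=gamma,
        threshold=threshold,
        horizon=horizon,
        model=model,
    )
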