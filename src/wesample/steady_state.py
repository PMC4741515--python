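"""Steady-state weighted ensemble: recycling, flux and MFPT estimation.

At steady state the Hill relation links the mean first passage time
between two states A and B to the probability flux of first arrivals:

    MFPT(A -> B) = 1 / Flux(A -> B)

where the flux is the probability per unit time that a trajectory which
originated in A arrives at B for the first time.  A steady flow from A to
B is induced by *recycling* boundary conditions: whenever a walker enters
B it is removed and a fresh walker is started from the initial state with
the identical weight.  After a burn-in transient, the mean recycled flux
per unit time is the steady-state flux.

A second, independent route to the same flux goes through the bin-to-bin
transition probabilities k_ij (per fixed interval tau) estimated from the
stored walker lineage.  Solving the stationarity condition

    for all i:  sum_j k_ji p_j = sum_j k_ij p_i

for the bin probabilities p_i and summing the stationary flow into B,

    Flux(A -> B) = sum_{i not in B} sum_{j in B} p_i k_ij,

gives the matrix-route estimate.  Under recycling every walker descends
from an A-injection, so both routes use only trajectories originating in
A by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from wesample.binning import BinScheme
from wesample.core import Ensemble, Walker

__all__ = [
    "StateDefinition",
    "FluxSeries",
    "MFPTEstimate",
    "TransitionEstimate",
    "FPTDistribution",
    "recycle",
    "hill_mfpt",
    "hill_mfpt_multi",
    "running_average",
    "flux_table",
    "estimate_transition_matrix",
    "solve_steady_state",
    "flux_from_matrix",
    "mfpt_from_transition_matrix",
    "fpt_distribution",
]


@dataclass(frozen=True)
class StateDefinition:
    """Membership predicate over progress coordinates.

    States may be defined independently of the WE bin boundaries; all
    that is required is that membership is decidable for every walker.
    """

    name: str
    predicate: Callable[[np.ndarray], bool]

    def contains(self, pcoord) -> bool:
        return bool(self.predicate(np.asarray(pcoord, dtype=float).reshape(-1)))

    @classmethod
    def interval(cls, name: str, dim: int = 0, low=-np.inf, high=np.inf):
        """State = {pcoord : low <= pcoord[dim] < high}."""
        lo, hi = float(low), float(high)
        return cls(name, lambda pc: lo <= pc[dim] < hi)

    @classmethod
    def at_least(cls, name: str, threshold: float, dim: int = 0):
        """State = {pcoord : pcoord[dim] >= threshold}."""
        return cls.interval(name, dim=dim, low=threshold)

    @classmethod
    def at_most(cls, name: str, threshold: float, dim: int = 0):
        """State = {pcoord : pcoord[dim] <= threshold}."""
        thr = float(threshold)
        return cls(name, lambda pc, d=dim: pc[d] <= thr)


@dataclass(frozen=True)
class FluxSeries:
    """Per-iteration recycled (or absorbed) weight into the target state."""

    weights: np.ndarray  # probability per iteration of length tau
    tau: float
    iterations: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -1e-15) or np.any(w > 1 + 1e-12):
            raise ValueError("flux entries must lie in [0, 1]")
        object.__setattr__(self, "weights", w)
        if self.iterations is None:
            object.__setattr__(self, "iterations", np.arange(1, w.size + 1))

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.iterations) * self.tau

    def per_unit_time(self) -> np.ndarray:
        return self.weights / self.tau


@dataclass(frozen=True)
class MFPTEstimate:
    """Hill-relation (or matrix-route) MFPT with provenance."""

    mfpt: float
    mean_flux: float  # probability per unit time
    burn_in_discarded: int
    se: float = float("nan")
    no_arrivals: bool = False
    mfpt_lower_bound: float | None = None
    running_avg: np.ndarray | None = None  # per unit time, full series


@dataclass
class TransitionEstimate:
    """Bin-to-bin conditional transition probabilities per interval tau."""

    k: np.ndarray  # (n_bins, n_bins), unobserved rows all zero
    weight_flow: np.ndarray  # raw weight transferred i -> j
    observed: np.ndarray  # bool mask of bins with outgoing weight
    tau: float
    n_transitions: int = 0


@dataclass(frozen=True)
class FPTDistribution:
    """First-passage-time histogram averaged over independent runs."""

    iterations: np.ndarray
    times: np.ndarray
    mean_weight: np.ndarray  # P(first passage in iteration t) per run
    se_weight: np.ndarray
    total_probability: float
    total_se: float
    n_runs: int
    no_arrivals: bool = False


# ---------------------------------------------------------------------
# recycling


def recycle(
    ensemble: Ensemble,
    target: StateDefinition,
    initial_sampler: Callable,
    rng: np.random.Generator,
) -> tuple[Ensemble, float]:
    """Replace every walker inside the target state by a fresh one.

    ``initial_sampler(rng)`` must return ``(state, pcoord)`` drawn from
    the configured t = 0 distribution.  Each replacement carries the
    identical weight of the walker it replaces, so total ensemble weight
    is unchanged; the summed replaced weight is returned as this
    iteration's recycled flux.
    """
    kept: list[Walker] = []
    recycled_weight = 0.0
    arrivals = []
    for w in ensemble.walkers:
        if target.contains(w.pcoord):
            arrivals.append(w)
        else:
            kept.append(w)
    if not arrivals:
        return ensemble, 0.0
    recycled_weight = math.fsum(w.weight for w in arrivals)
    for w in arrivals:
        state, pcoord = initial_sampler(rng)
        pcoord = np.asarray(pcoord, dtype=float).reshape(-1)
        if target.contains(pcoord):
            raise ValueError(
                "initial sampler produced a state already inside the target "
                "state: ill-posed steady state"
            )
        (nid,) = ensemble.allocate_ids(1)
        kept.append(
            Walker(
                id=nid,
                weight=w.weight,
                state=state,
                pcoord=pcoord,
                parent_id=w.id,
                iteration_created=ensemble.iteration,
            )
        )
    out = Ensemble(kept, iteration=ensemble.iteration, next_id=ensemble.next_id)
    return out, recycled_weight


# ---------------------------------------------------------------------
# Hill relation


def running_average(values: np.ndarray) -> np.ndarray:
    """Running average over the most recent half of the data.

    Entry ``t`` is the mean of the most recent ``ceil((t+1)/2)`` values
    up to and including ``t`` — the convention used for flux-convergence
    plots.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    out = np.empty(n)
    c = np.concatenate([[0.0], np.cumsum(v)])
    for t in range(n):
        win = (t + 2) // 2  # ceil((t+1)/2)
        out[t] = (c[t + 1] - c[t + 1 - win]) / win
    return out


def hill_mfpt(flux: FluxSeries, burn_in: float = 0.5) -> MFPTEstimate:
    """MFPT = 1 / (mean steady-state flux per unit time).

    The first ``burn_in`` fraction of iterations is discarded as the
    relaxation transient.  If no arrivals occurred in the retained
    window the estimate degenerates to a lower bound (the retained
    simulated time) rather than a division by zero.
    """
    if not (0.0 <= burn_in < 1.0):
        raise ValueError("burn_in must be in [0, 1)")
    w = flux.weights
    if w.size == 0:
        raise ValueError("empty flux series")
    start = int(math.floor(w.size * burn_in))
    retained = w[start:]
    ra = running_average(w / flux.tau)
    mean_per_tau = float(np.mean(retained))
    if mean_per_tau <= 0.0:
        return MFPTEstimate(
            mfpt=float("inf"),
            mean_flux=0.0,
            burn_in_discarded=start,
            no_arrivals=True,
            mfpt_lower_bound=retained.size * flux.tau,
            running_avg=ra,
        )
    mean_flux = mean_per_tau / flux.tau
    return MFPTEstimate(
        mfpt=1.0 / mean_flux,
        mean_flux=mean_flux,
        burn_in_discarded=start,
        running_avg=ra,
    )


def hill_mfpt_multi(
    series: Sequence[FluxSeries], burn_in: float = 0.5
) -> MFPTEstimate:
    """Hill MFPT pooled over independent runs, with a standard error.

    The per-run post-burn-in mean fluxes are averaged; the standard error
    of that mean propagates to the MFPT through the reciprocal (delta
    method).  Independent runs give uncorrelated errors, unlike segments
    within a single run.
    """
    if len(series) < 2:
        raise ValueError("need >= 2 independent runs for a standard error")
    per_run = []
    for f in series:
        est = hill_mfpt(f, burn_in=burn_in)
        per_run.append(est.mean_flux)
    per_run = np.asarray(per_run)
    mean_flux = float(np.mean(per_run))
    se_flux = float(np.std(per_run, ddof=1) / math.sqrt(len(per_run)))
    start = int(math.floor(series[0].weights.size * burn_in))
    if mean_flux <= 0:
        return MFPTEstimate(
            mfpt=float("inf"),
            mean_flux=0.0,
            burn_in_discarded=start,
            no_arrivals=True,
            mfpt_lower_bound=(series[0].weights.size - start)
            * series[0].tau
            * len(series),
        )
    return MFPTEstimate(
        mfpt=1.0 / mean_flux,
        mean_flux=mean_flux,
        burn_in_discarded=start,
        se=se_flux / mean_flux**2,
    )


def flux_table(flux: FluxSeries):
    """Per-iteration flux table for convergence inspection.

    Columns: iteration, time, instantaneous flux (per unit time), the
    running average over the most recent half of the data, and the
    cumulative MFPT estimate (reciprocal of that running average; inf
    while no weight has arrived).
    """
    import pandas as pd

    inst = flux.per_unit_time()
    ra = running_average(inst)
    with np.errstate(divide="ignore"):
        mfpt_est = np.where(ra > 0, 1.0 / np.where(ra > 0, ra, 1.0), np.inf)
    return pd.DataFrame(
        {
            "iteration": flux.iterations,
            "time": flux.times,
            "flux": inst,
            "running_avg_flux": ra,
            "mfpt_estimate": mfpt_est,
        }
    )


# ---------------------------------------------------------------------
# transition-matrix route


def estimate_transition_matrix(
    store, scheme: BinScheme, burn_in: float = 0.0
) -> TransitionEstimate:
    """Estimate k_ij from the stored walker lineage.

    For every recorded iteration the weight of each walker is attributed
    to the transition (parent's bin at the previous iteration) -> (own
    bin), and rows of the aggregated weight-flow matrix are normalized.
    Under recycling the stored lineage routes arrival weight through the
    target bins and back to the initial state, so the recycling boundary
    condition is embedded in the estimated chain.
    """
    if len(store.iterations) < 2:
        raise ValueError("store needs >= 2 recorded iterations with lineage")
    n = scheme.n_bins
    flow = np.zeros((n, n))
    first = max(1, int(math.floor(store.n_iterations * burn_in)))
    n_transitions = 0
    for k in range(first, len(store.iterations)):
        prev = store.iterations[k - 1]
        cur = store.iterations[k]
        prev_bin = dict(zip(prev.ids.tolist(), prev.bins.tolist()))
        for pid, b, w in zip(
            cur.parent_ids.tolist(), cur.bins.tolist(), cur.weights.tolist()
        ):
            try:
                i = prev_bin[pid]
            except KeyError:
                raise ValueError(
                    f"iteration {cur.index}: parent id {pid} not found in "
                    f"iteration {prev.index} (broken lineage)"
                ) from None
            flow[i, b] += w
            n_transitions += 1
    rowsum = flow.sum(axis=1)
    observed = rowsum > 0
    k_mat = np.zeros_like(flow)
    k_mat[observed] = flow[observed] / rowsum[observed, None]
    return TransitionEstimate(
        k=k_mat,
        weight_flow=flow,
        observed=observed,
        tau=store.tau,
        n_transitions=n_transitions,
    )


def solve_steady_state(t: TransitionEstimate) -> np.ndarray:
    """Stationary bin probabilities of the estimated chain.

    Solves ``p K = p`` with ``sum p = 1`` on the observed-bin submatrix.
    Raises if the observed chain is reducible (naming the disconnected
    blocks) or if the solution has meaningfully negative components.
    """
    obs = np.flatnonzero(t.observed)
    if obs.size == 0:
        raise ValueError("no observed bins")
    K = t.k[np.ix_(obs, obs)]
    # Rows may leak weight to unobserved bins; renormalize the submatrix.
    rs = K.sum(axis=1)
    if np.any(rs <= 0):
        raise ValueError("observed bin with no transitions among observed bins")
    K = K / rs[:, None]
    n_comp, labels = connected_components(
        csr_matrix(K > 0), directed=True, connection="strong"
    )
    if n_comp > 1:
        blocks = [obs[labels == c].tolist() for c in range(n_comp)]
        raise ValueError(
            f"transition matrix is reducible; strongly connected blocks "
            f"(bin indices): {blocks}"
        )
    m = obs.size
    a = K.T - np.eye(m)
    a[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    p_sub = np.linalg.solve(a, b)
    if np.any(p_sub < -1e-9):
        raise ValueError(f"negative stationary probabilities: {p_sub.min()}")
    p_sub = np.clip(p_sub, 0.0, None)
    p_sub /= p_sub.sum()
    p = np.zeros(t.k.shape[0])
    p[obs] = p_sub
    return p


def _bins_in_state(scheme: BinScheme, state: StateDefinition) -> np.ndarray:
    """Flat indices of bins whose lower corner lies in ``state``.

    For the integer-valued count coordinates used throughout, the lower
    corner of a half-open bin is exactly the count it holds, so this
    classification is unambiguous.
    """
    members = []
    for b in range(scheme.n_bins):
        corner = np.array([lo for lo, _ in scheme.bin_bounds(b)])
        if state.contains(corner):
            members.append(b)
    return np.asarray(members, dtype=int)


def flux_from_matrix(
    t: TransitionEstimate,
    target,
    scheme: BinScheme | None = None,
    p: np.ndarray | None = None,
) -> float:
    """Steady-state probability flow into B, per interval tau.

    ``target`` is either an explicit sequence of flat bin indices or a
    :class:`StateDefinition` (then ``scheme`` is required to classify the
    bins).  ``p`` defaults to :func:`solve_steady_state`.
    """
    if isinstance(target, StateDefinition):
        if scheme is None:
            raise ValueError("scheme required to classify bins by state")
        target_bins = _bins_in_state(scheme, target)
    else:
        target_bins = np.asarray(target, dtype=int)
    if target_bins.size == 0:
        warnings.warn("no bin lies in the target state; flux is 0", stacklevel=2)
        return 0.0
    if p is None:
        p = solve_steady_state(t)
    in_b = np.zeros(t.k.shape[0], dtype=bool)
    in_b[target_bins] = True
    return float(p[~in_b] @ t.k[~in_b][:, in_b].sum(axis=1))


def mfpt_from_transition_matrix(
    store, scheme: BinScheme, target, burn_in: float = 0.5
) -> MFPTEstimate:
    """Matrix-route MFPT: estimate k_ij, solve for p_i, invert the flux."""
    te = estimate_transition_matrix(store, scheme, burn_in=burn_in)
    flux_per_tau = flux_from_matrix(te, target, scheme=scheme)
    start = int(math.floor(store.n_iterations * burn_in))
    if flux_per_tau <= 0:
        return MFPTEstimate(
            mfpt=float("inf"),
            mean_flux=0.0,
            burn_in_discarded=start,
            no_arrivals=True,
            mfpt_lower_bound=(store.n_iterations - start) * store.tau,
        )
    mean_flux = flux_per_tau / te.tau
    return MFPTEstimate(
        mfpt=1.0 / mean_flux, mean_flux=mean_flux, burn_in_discarded=start
    )


# ---------------------------------------------------------------------
# first-passage-time distributions


def fpt_distribution(stores: Sequence) -> FPTDistribution:
    """Average per-iteration arrival weight across independent runs.

    With every run started in A at t = 0, the recycled/absorbed weight in
    iteration t estimates P(first passage in iteration t); averaging over
    independent runs gives the distribution with 1-sigma standard errors,
    and its sum is the total threshold-crossing probability within the
    simulated window.  (Under recycling, re-injected probability can in
    principle arrive a second time; for the rare events this estimator is
    used on, that contribution is second order in the total probability.)
    """
    if not stores:
        raise ValueError("need at least one run store")
    lengths = {s.n_iterations for s in stores}
    if len(lengths) != 1:
        raise ValueError(f"runs have differing iteration counts: {lengths}")
    tau = stores[0].tau
    per_run = np.stack([s.flux_values() for s in stores])  # (runs, iters)
    mean_w = per_run.mean(axis=0)
    n_runs = per_run.shape[0]
    if n_runs > 1:
        se_w = per_run.std(axis=0, ddof=1) / math.sqrt(n_runs)
    else:
        se_w = np.full_like(mean_w, np.nan)
    totals = per_run.sum(axis=1)
    total = float(totals.mean())
    total_se = (
        float(totals.std(ddof=1) / math.sqrt(n_runs)) if n_runs > 1 else float("nan")
    )
    iters = np.arange(1, mean_w.size + 1)
    return FPTDistribution(
        iterations=iters,
        times=iters * tau,
        mean_weight=mean_w,
        se_weight=se_w,
        total_probability=total,
        total_se=total_se,
        n_runs=n_runs,
        no_arrivals=bool(total == 0.0),
    )
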