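"""Weighted histograms, equal-cost accounting and multi-run statistics.

The central diagnostic of a WE study is the weighted histogram of a
progress coordinate: bin mass is the summed statistical weight of the
walkers in the bin, an unbiased estimate of the occupation probability.
Comparisons against brute force are made at *equal simulated-dynamics
cost*: a WE run that propagated S trajectory segments over I iterations
is charged the same as ceil(S / I) independent brute-force trajectories
(rounding up to give brute force the benefit).  A brute-force ensemble of
N trajectories cannot resolve probabilities below 1/N — the tail floor —
whereas WE populates tail bins with low-weight walkers.

Uncertainty across independent runs is summarized either by the standard
error of the per-bin mean or by a percentile bootstrap confidence
interval for the mean (default 10,000 resamples, 95% level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeightedHistogram",
    "CostLedger",
    "weighted_histogram",
    "multi_run_mean",
    "bootstrap_ci",
    "equivalent_bf_count",
    "sampling_power_ratio",
    "tail_floor",
    "tail_comparison",
]


@dataclass(frozen=True)
class WeightedHistogram:
    """Probability mass per half-open coordinate bin.

    ``se`` (per-bin standard error) and ``observed`` (was the bin
    populated in any contributing run?) are set by multi-run averaging;
    bins observed in no run are *absent* — zero mass but flagged, never
    zero-with-an-error-bar.
    """

    edges: np.ndarray
    mass: np.ndarray
    se: np.ndarray | None = None
    observed: np.ndarray | None = None
    n_runs: int = 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> float:
        return float(math.fsum(self.mass.tolist()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "low": self.edges[:-1],
                "high": self.edges[1:],
                "mass": self.mass,
            }
        )
        if self.se is not None:
            df["se"] = self.se
        if self.observed is not None:
            df["observed"] = self.observed
        return df


def _values_weights(source, dim: int):
    """Accept an Ensemble, an IterationRecord, or (values, weights)."""
    if isinstance(source, tuple) and len(source) == 2:
        v, w = source
        return np.asarray(v, dtype=float), np.asarray(w, dtype=float)
    if hasattr(source, "walkers"):  # Ensemble
        v = np.array([w.pcoord[dim] for w in source.walkers])
        w = np.array([w.weight for w in source.walkers])
        return v, w
    if hasattr(source, "pcoords"):  # IterationRecord
        return np.asarray(source.pcoords[:, dim], dtype=float), np.asarray(
            source.weights, dtype=float
        )
    raise TypeError(f"cannot extract values/weights from {type(source)!r}")


def weighted_histogram(source, edges, dim: int = 0) -> WeightedHistogram:
    """Sum walker weights into half-open coordinate bins ``[lo, hi)``.

    ``source`` may be an :class:`~wesample.core.Ensemble`, a stored
    iteration record, or an explicit ``(values, weights)`` pair.  Values
    outside the edge range contribute nothing (the histogram then sums
    to less than the ensemble weight).
    """
    values, weights = _values_weights(source, dim)
    if not np.all(np.isfinite(values)):
        raise ValueError("histogram coordinates must be finite")
    e = np.asarray(edges, dtype=float)
    idx = np.searchsorted(e, values, side="right") - 1
    valid = (idx >= 0) & (idx < e.size - 1) & (values < e[-1])
    mass = np.zeros(e.size - 1)
    np.add.at(mass, idx[valid], weights[valid])
    return WeightedHistogram(edges=e, mass=mass)


def multi_run_mean(histograms: Sequence[WeightedHistogram]) -> WeightedHistogram:
    """Per-bin mean and 1-sigma standard error across independent runs.

    All histograms must share identical edges.  With a single run the
    means are returned and the errors flagged unavailable (NaN).  Bins
    populated in no run are marked unobserved.
    """
    if not histograms:
        raise ValueError("no histograms given")
    e0 = histograms[0].edges
    for h in histograms[1:]:
        if h.edges.shape != e0.shape or not np.allclose(h.edges, e0):
            raise ValueError("histograms have mismatched bin edges")
    stack = np.stack([h.mass for h in histograms])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    observed = np.any(stack > 0, axis=0)
    if n >= 2:
        se = stack.std(axis=0, ddof=1) / math.sqrt(n)
        se = np.where(observed, se, np.nan)
    else:
        se = np.full_like(mean, np.nan)
    return WeightedHistogram(
        edges=e0, mass=mean, se=se, observed=observed, n_runs=n
    )


def bootstrap_ci(
    values,
    n_boot: int = 10_000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean.

    Resamples the per-run values with replacement ``n_boot`` times and
    returns the central ``level`` percentile interval of the resampled
    means.  Requires at least two values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("bootstrap needs >= 2 per-run values")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class CostLedger:
    """Simulated-dynamics cost of a WE run, in brute-force currency."""

    n_segments: int
    n_iterations: int

    @property
    def equivalent_bf(self) -> int:
        return equivalent_bf_count(self.n_segments, self.n_iterations)

    @classmethod
    def from_store(cls, store) -> "CostLedger":
        return cls(n_segments=store.n_segments, n_iterations=store.n_iterations)


def equivalent_bf_count(n_segments: int, n_iterations: int) -> int:
    """Equal-cost brute-force trajectory count: ceil(segments/iterations).

    Rounding is always up, giving brute force the benefit of the doubt.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if n_segments < 0:
        raise ValueError("n_segments must be >= 0")
    return -(-int(n_segments) // int(n_iterations))


def sampling_power_ratio(
    config_a: tuple[int, int], config_b: tuple[int, int]
) -> float:
    """(runs x per-bin target)_a / (runs x per-bin target)_b."""
    (na, ta), (nb, tb) = config_a, config_b
    denom = nb * tb
    if denom == 0:
        raise ValueError("zero sampling power in the reference configuration")
    return (na * ta) / denom


def tail_floor(n_trajectories: int) -> float:
    """Smallest probability resolvable by N brute-force trajectories."""
    if n_trajectories < 1:
        raise ValueError("need >= 1 trajectory")
    return 1.0 / n_trajectories


def tail_comparison(
    we_hist: WeightedHistogram,
    bf_values,
    n_bf: int | None = None,
) -> pd.DataFrame:
    """Side-by-side WE vs equal-cost brute-force occupation table.

    ``bf_values`` are the raw brute-force samples (e.g. final coordinate
    values); they are binned on the WE histogram's edges.  The returned
    table reports, per bin, the WE mass, the brute-force frequency, and
    whether the bin lies below the brute-force resolution floor 1/N.
    """
    bf_values = np.asarray(bf_values, dtype=float)
    if n_bf is None:
        n_bf = bf_values.size
    bf_hist = weighted_histogram(
        (bf_values, np.full(bf_values.size, 1.0 / n_bf)), we_hist.edges
    )
    floor = tail_floor(n_bf)
    return pd.DataFrame(
        {
            "low": we_hist.edges[:-1],
            "high": we_hist.edges[1:],
            "we_mass": we_hist.mass,
            "bf_mass": bf_hist.mass,
            "below_bf_floor": we_hist.mass < floor,
            "bf_floor": floor,
        }
    )
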