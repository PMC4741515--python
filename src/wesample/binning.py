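"""Progress-coordinate bin schemes and ranked-entity coordinate reduction.

A :class:`BinScheme` partitions progress-coordinate space into
non-overlapping half-open rectangles ``[low, high)`` that completely cover
the declared domain; the last edge of a dimension may be ``+inf`` to give
an unbounded top bin.  Bins are indexed by a flat, row-major integer so a
scheme of shape ``(4, 22)`` has bins ``0..87``.

:class:`RankedReducer` implements the "best entity" reduction used when a
model contains many interchangeable entities (e.g. synaptic vesicles), each
with its own coordinate vector: entities are ranked lexicographically in
descending order on a chosen sequence of coordinate indices, and the
coordinates of the top-ranked entity become the walker's progress
coordinate.  The ranking is re-evaluated fresh at every resampling, so the
chosen entity may change over time, always in favor of progress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BinningError",
    "BinScheme",
    "RankedReducer",
    "assign_bin",
    "reduce_ranked",
]


class BinningError(ValueError):
    """A progress coordinate fell outside the declared bin domain."""


@dataclass(frozen=True)
class BinScheme:
    """Rectilinear partition of progress-coordinate space.

    Parameters
    ----------
    edges
        One strictly increasing edge array per dimension.  ``d`` edge
        arrays of lengths ``m_k + 1`` produce ``prod(m_k)`` bins.  The
        final edge of a dimension may be ``np.inf``.
    target_count
        Desired number of walkers per occupied bin.  Either a scalar
        (applied to every bin) or an array of per-bin counts in flat
        row-major order.  Every target must be >= 1.
    """

    edges: tuple[np.ndarray, ...]
    target_count: int | np.ndarray = 1

    def __init__(self, edges: Sequence[Sequence[float]], target_count=1):
        arrs = tuple(np.asarray(e, dtype=float) for e in edges)
        if not arrs:
            raise ValueError("at least one dimension of edges is required")
        for e in arrs:
            if e.ndim != 1 or e.size < 2:
                raise ValueError("each edge array needs >= 2 entries")
            if not np.all(np.diff(e) > 0):
                raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", arrs)
        n_bins = int(np.prod([e.size - 1 for e in arrs]))
        tc = np.asarray(target_count, dtype=int)
        if tc.ndim == 0:
            tc = np.full(n_bins, int(tc))
        if tc.size != n_bins:
            raise ValueError(
                f"target_count has {tc.size} entries for {n_bins} bins"
            )
        if np.any(tc < 1):
            raise ValueError("every per-bin target count must be >= 1")
        tc.setflags(write=False)
        object.__setattr__(self, "target_count", tc)

    # -- geometry -----------------------------------------------------

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(e.size - 1 for e in self.edges)

    @property
    def n_bins(self) -> int:
        return int(np.prod(self.shape))

    def targets(self) -> np.ndarray:
        """Per-bin target walker counts, flat row-major order."""
        return self.target_count

    # -- assignment ---------------------------------------------------

    def assign(self, pcoords: np.ndarray) -> np.ndarray:
        """Map an ``(n, ndim)`` coordinate array to flat bin indices.

        Raises :class:`BinningError` (naming the offending row and value)
        for any coordinate outside the covered domain; coordinates are
        never silently clamped.
        """
        pc = np.atleast_2d(np.asarray(pcoords, dtype=float))
        if pc.shape[1] != self.ndim:
            raise BinningError(
                f"pcoord has {pc.shape[1]} dimensions, scheme has {self.ndim}"
            )
        if not np.all(np.isfinite(pc)):
            bad = np.argwhere(~np.isfinite(pc))
            r, c = bad[0]
            raise BinningError(
                f"non-finite progress coordinate {pc[r, c]!r} "
                f"(walker row {r}, dimension {c})"
            )
        multi = []
        for k, e in enumerate(self.edges):
            idx = np.searchsorted(e, pc[:, k], side="right") - 1
            out = (idx < 0) | (idx >= e.size - 1) | (pc[:, k] >= e[-1])
            if np.any(out):
                r = int(np.argmax(out))
                raise BinningError(
                    f"progress coordinate {pc[r, k]} (walker row {r}, "
                    f"dimension {k}) is outside the bin domain "
                    f"[{e[0]}, {e[-1]})"
                )
            multi.append(idx)
        return np.ravel_multi_index(tuple(multi), self.shape)

    def assign_one(self, pcoord) -> int:
        """Flat bin index of a single coordinate vector."""
        return int(self.assign(np.asarray(pcoord, dtype=float)[None, :])[0])

    def bin_bounds(self, flat_index: int) -> tuple[tuple[float, float], ...]:
        """Half-open ``(low, high)`` interval per dimension for one bin."""
        multi = np.unravel_index(flat_index, self.shape)
        return tuple(
            (float(e[i]), float(e[i + 1])) for e, i in zip(self.edges, multi)
        )

    # -- constructors -------------------------------------------------

    @classmethod
    def integer_bins(
        cls, low: int, high: int, target_count=1, top_to=None
    ) -> "BinScheme":
        """One bin per integer value on ``[low, high]`` (1-D).

        Bin ``i`` is ``[i, i+1)`` so a count-valued coordinate equal to
        ``i`` lands in its own bin.  If ``top_to`` is given, one extra bin
        ``[high+1, top_to)`` is appended (``top_to`` may be ``np.inf``).
        """
        edges = list(range(low, high + 2))
        if top_to is not None:
            if not top_to > high + 1:
                raise ValueError("top_to must exceed high + 1")
            edges.append(float(top_to))
        return cls([edges], target_count=target_count)


def assign_bin(pcoord, scheme: BinScheme) -> int:
    """Flat bin index of ``pcoord`` under ``scheme`` (half-open bins)."""
    return scheme.assign_one(pcoord)


@dataclass(frozen=True)
class RankedReducer:
    """Reduce many per-entity coordinate vectors to the single best one.

    ``sort_keys`` lists coordinate indices in priority order; entities are
    sorted descending on the first key, ties broken descending on the
    second, and so on.  Remaining ties are broken in favor of the lowest
    entity index, which makes the reduction deterministic and
    permutation-invariant up to entities with identical key values.
    """

    sort_keys: tuple[int, ...] = field(default=(0,))

    def __init__(self, sort_keys: Sequence[int] = (0,)):
        keys = tuple(int(k) for k in sort_keys)
        if not keys:
            raise ValueError("at least one sort key is required")
        object.__setattr__(self, "sort_keys", keys)

    def reduce(self, entities: np.ndarray) -> np.ndarray:
        ents = np.atleast_2d(np.asarray(entities, dtype=float))
        if ents.shape[0] == 0:
            raise ValueError("cannot reduce an empty entity collection")
        # np.lexsort sorts ascending on the *last* key first; negate for
        # descending order and use the row index as the final tie-break.
        keys = [np.arange(ents.shape[0])]
        for k in reversed(self.sort_keys):
            keys.append(-ents[:, k])
        best = np.lexsort(tuple(keys))[0]
        return ents[best].copy()


def reduce_ranked(entities, reducer: RankedReducer) -> np.ndarray:
    """Coordinate vector of the top-ranked entity under ``reducer``."""
    return reducer.reduce(np.asarray(entities, dtype=float))
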