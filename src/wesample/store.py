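"""Hierarchical run records: walker tables, flux and bin populations.

A :class:`RunStore` accumulates, for every WE iteration, the full walker
table (id, parent id, weight, progress coordinates, bin index), the
recycled/absorbed probability flux into the target state, and resampling
audit counts.  Iteration 0 is the initial ensemble; iteration ``k >= 1``
is recorded *after* propagation and arrival detection but *before*
resampling, so the stored pcoords include arrivals in the target state
and the stored lineage links each walker to its ancestor in the previous
table.

Stores persist to HDF5 (one group per iteration, config and seed as root
attributes, schema version tagged) and export flat TSV summaries for
quick inspection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

__all__ = ["RunStore", "IterationRecord", "SCHEMA_VERSION"]


@dataclass
class IterationRecord:
    index: int
    ids: np.ndarray
    parent_ids: np.ndarray
    weights: np.ndarray
    pcoords: np.ndarray
    bins: np.ndarray
    flux: float = 0.0
    n_splits: int = 0
    n_merges: int = 0
    n_walkers_after_resample: int = -1

    @property
    def n_walkers(self) -> int:
        return len(self.ids)

    @property
    def total_weight(self) -> float:
        return math.fsum(self.weights.tolist())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "parent_id": self.parent_ids,
                "weight": self.weights,
                "bin": self.bins,
            }
        )
        for d in range(self.pcoords.shape[1]):
            df[f"pcoord_{d}"] = self.pcoords[:, d]
        return df


@dataclass
class RunStore:
    """In-memory (and HDF5-persistable) record of a WE run."""

    meta: dict = field(default_factory=dict)
    scheme_edges: list = field(default_factory=list)
    scheme_targets: np.ndarray | None = None
    iterations: list[IterationRecord] = field(default_factory=list)
    ended_early_at: int | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def new(cls, config, scheme) -> "RunStore":
        store = cls()
        store.meta = dict(config.summary())
        store.meta["schema_version"] = SCHEMA_VERSION
        store.scheme_edges = [np.asarray(e, dtype=float) for e in scheme.edges]
        store.scheme_targets = np.asarray(scheme.targets(), dtype=int)
        return store

    # -- recording ----------------------------------------------------

    def record_iteration(self, index, ensemble, bins, flux=0.0, **counts):
        pcoords = ensemble.pcoord_array()
        if pcoords.size == 0:
            pcoords = pcoords.reshape(0, len(self.scheme_edges) or 1)
        rec = IterationRecord(
            index=int(index),
            ids=np.asarray([w.id for w in ensemble.walkers], dtype=np.int64),
            parent_ids=np.asarray(
                [w.parent_id for w in ensemble.walkers], dtype=np.int64
            ),
            weights=np.asarray([w.weight for w in ensemble.walkers], dtype=float),
            pcoords=np.asarray(pcoords, dtype=float),
            bins=np.asarray(bins, dtype=np.int64),
            flux=float(flux),
            n_splits=int(counts.get("n_splits", 0)),
            n_merges=int(counts.get("n_merges", 0)),
        )
        self.iterations.append(rec)

    def record_resample(self, index, report, ensemble):
        rec = self.iterations[-1]
        assert rec.index == index
        rec.n_splits = report.n_splits
        rec.n_merges = report.n_merges
        rec.n_walkers_after_resample = len(ensemble)

    def finalize_early(self, iteration: int) -> None:
        self.ended_early_at = int(iteration)

    def close(self) -> None:  # symmetry with file-backed stores
        pass

    # -- access -------------------------------------------------------

    @property
    def tau(self) -> float:
        return float(self.meta["tau"])

    @property
    def n_iterations(self) -> int:
        """Number of recorded post-propagation iterations (excl. t=0)."""
        return len(self.iterations) - 1 if self.iterations else 0

    @property
    def n_segments(self) -> int:
        """Total trajectory segments propagated (cost accounting)."""
        return int(sum(rec.n_walkers for rec in self.iterations[1:]))

    def iteration(self, index: int) -> IterationRecord:
        rec = self.iterations[index]
        if rec.index != index:  # records are appended densely
            raise KeyError(f"iteration {index} not recorded")
        return rec

    def final(self) -> IterationRecord:
        return self.iterations[-1]

    def flux_values(self) -> np.ndarray:
        """Recycled/absorbed weight per iteration (1..N), prob per tau."""
        return np.asarray([rec.flux for rec in self.iterations[1:]], dtype=float)

    def flux_series(self):
        from wesample.steady_state import FluxSeries

        return FluxSeries(
            weights=self.flux_values(),
            tau=self.tau,
            iterations=np.arange(1, len(self.iterations)),
        )

    def bin_populations(self, index: int, n_bins: int) -> np.ndarray:
        rec = self.iteration(index)
        return np.bincount(rec.bins, minlength=n_bins)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.iterations:
            rows.append(
                {
                    "iteration": rec.index,
                    "time": rec.index * self.tau,
                    "n_walkers": rec.n_walkers,
                    "total_weight": rec.total_weight,
                    "flux": rec.flux,
                    "n_splits": rec.n_splits,
                    "n_merges": rec.n_merges,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        """Flat per-iteration summary, one row per iteration."""
        self.summary_frame().to_csv(path, sep="\t", index=False)

    # -- HDF5 persistence ---------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["meta_json"] = json.dumps(self.meta)
            if self.ended_early_at is not None:
                f.attrs["ended_early_at"] = self.ended_early_at
            g = f.create_group("scheme")
            for d, e in enumerate(self.scheme_edges):
                g.create_dataset(f"edges_{d}", data=e)
            if self.scheme_targets is not None:
                g.create_dataset("targets", data=self.scheme_targets)
            g_it = f.create_group("iterations")
            for rec in self.iterations:
                gi = g_it.create_group(f"{rec.index:06d}")
                gi.create_dataset("ids", data=rec.ids)
                gi.create_dataset("parent_ids", data=rec.parent_ids)
                gi.create_dataset("weights", data=rec.weights)
                gi.create_dataset("pcoords", data=rec.pcoords)
                gi.create_dataset("bins", data=rec.bins)
                gi.attrs["flux"] = rec.flux
                gi.attrs["n_splits"] = rec.n_splits
                gi.attrs["n_merges"] = rec.n_merges
                gi.attrs["n_walkers_after_resample"] = rec.n_walkers_after_resample

    @classmethod
    def from_hdf5(cls, path) -> "RunStore":
        store = cls()
        with h5py.File(path, "r") as f:
            store.meta = json.loads(f.attrs["meta_json"])
            if "ended_early_at" in f.attrs:
                store.ended_early_at = int(f.attrs["ended_early_at"])
            g = f["scheme"]
            d = 0
            while f"edges_{d}" in g:
                store.scheme_edges.append(np.asarray(g[f"edges_{d}"]))
                d += 1
            if "targets" in g:
                store.scheme_targets = np.asarray(g["targets"])
            for name in sorted(f["iterations"]):
                gi = f["iterations"][name]
                store.iterations.append(
                    IterationRecord(
                        index=int(name),
                        ids=np.asarray(gi["ids"]),
                        parent_ids=np.asarray(gi["parent_ids"]),
                        weights=np.asarray(gi["weights"]),
                        pcoords=np.asarray(gi["pcoords"]),
                        bins=np.asarray(gi["bins"]),
                        flux=float(gi.attrs["flux"]),
                        n_splits=int(gi.attrs["n_splits"]),
                        n_merges=int(gi.attrs["n_merges"]),
                        n_walkers_after_resample=int(
                            gi.attrs["n_walkers_after_resample"]
                        ),
                    )
                )
        return store

    def scheme(self):
        from wesample.binning import BinScheme

        return BinScheme(self.scheme_edges, target_count=self.scheme_targets)
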