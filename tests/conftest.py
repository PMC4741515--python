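"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from wesample.core import Ensemble, Walker


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_walker(wid, weight, pcoord, parent=None, state=None):
    return Walker(
        id=wid,
        weight=weight,
        state=state,
        pcoord=np.atleast_1d(np.asarray(pcoord, dtype=float)),
        parent_id=wid if parent is None else parent,
    )


def random_ensemble(rng, n_walkers, domain_high, ndim=1):
    """Random walkers with weights normalized to exactly 1 (fsum-safe)."""
    w = rng.random(n_walkers) + 0.05
    w /= w.sum()
    # renormalize the largest entry so the fsum is 1 to the last ulp
    import math

    w[-1] += 1.0 - math.fsum(w.tolist())
    pcs = rng.random((n_walkers, ndim)) * domain_high
    walkers = [
        make_walker(i, float(w[i]), pcs[i]) for i in range(n_walkers)
    ]
    return Ensemble(walkers)
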