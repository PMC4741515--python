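"""The engine contract.

Engines are deliberately decoupled from the WE machinery: trajectories run
independently between resampling events, and the WE layer needs only
intermittent reports of a progress coordinate.  Any object satisfying
:class:`Engine` can be driven by :func:`wesample.core.run_we`.
"""

from __future__ import annotations

from typing import Any, Protocol, runtime_checkable

import numpy as np


class EngineError(RuntimeError):
    """An engine rejected its input (bad tau, invalid model state...)."""


@runtime_checkable
class Engine(Protocol):
    """Contract every dynamics engine must satisfy.

    ``propagate`` must advance exactly ``tau`` units of model time under
    the unmodified model dynamics and return a *new* state object — the
    input state must not be mutated, because split walkers share state
    references until they are next propagated.  Given a fixed RNG stream
    the result must be deterministic.
    """

    #: True for models whose rate constants depend on absolute time;
    #: steady-state (recycling) analysis is refused for such models.
    time_dependent: bool

    def propagate(
        self, state: Any, tau: float, rng: np.random.Generator
    ) -> Any: ...

    def pcoord(self, state: Any) -> np.ndarray: ...
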