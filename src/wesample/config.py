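"""Run configuration for weighted-ensemble simulations.

A :class:`WEConfig` bundles everything the WE loop needs besides the
engine and the bin scheme: the resampling interval tau (in the engine's
time units, seconds for the built-in engines), the iteration count, the
initial distribution over dynamical states, the steady-state boundary
condition (none / recycle / absorb) with its target-state definition, and
the root random seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

__all__ = ["WEConfig"]


@dataclass
class WEConfig:
    """Settings for one weighted-ensemble run.

    Parameters
    ----------
    tau
        Resampling interval in model time units (> 0).  For engines with a
        fixed internal step, tau must be a positive multiple of that step;
        tau equal to exactly one internal step is fully supported.
    n_iterations
        Number of propagate/resample cycles (>= 0).
    initial_states
        Engine states present at t = 0.
    initial_weights
        Matching statistical weights; must sum to 1.  Defaults to uniform.
    mode
        ``"none"`` (plain fixed-horizon WE), ``"recycle"`` (steady-state
        boundary conditions: walkers entering the target state are removed
        and their weight reinjected at the initial state) or ``"absorb"``
        (arrivals are removed and their weight recorded but not
        reinjected; used for first-passage measurements on time-dependent
        models where a steady state does not exist).
    target_state
        A :class:`~wesample.steady_state.StateDefinition` for state B;
        required when mode is not ``"none"``.
    initial_sampler
        Optional ``f(rng) -> state`` used to draw reinjection states when
        recycling.  By default a state is re-drawn from the configured
        t = 0 distribution (``initial_states`` with ``initial_weights``).
    seed
        Root seed; every stream of randomness in the run derives from it.
    burn_in
        Fraction of iterations discarded before steady-state averages
        (default 0.5, matching the most-recent-half convention used for
        flux running averages).
    """

    tau: float
    n_iterations: int
    initial_states: Sequence[Any]
    initial_weights: Sequence[float] | None = None
    mode: str = "none"
    target_state: Any = None
    initial_sampler: Callable | None = None
    seed: int = 0
    burn_in: float = 0.5
    label: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.initial_weights is None:
            n = len(self.initial_states)
            self.initial_weights = [1.0 / n] * n if n else []
        self.initial_weights = [float(w) for w in self.initial_weights]

    def validate(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.mode not in ("none", "recycle", "absorb"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.initial_states) == 0:
            raise ValueError("at least one initial state is required")
        if len(self.initial_weights) != len(self.initial_states):
            raise ValueError("initial_weights/initial_states length mismatch")
        total = math.fsum(self.initial_weights)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial weights sum to {total}, expected 1")
        if any(w <= 0 for w in self.initial_weights):
            raise ValueError("initial weights must be positive")
        if not (0.0 <= self.burn_in < 1.0):
            raise ValueError("burn_in must be in [0, 1)")

    def reinjection_sampler(self) -> Callable:
        """Sampler used to restart recycled walkers at the initial state."""
        if self.initial_sampler is not None:
            return self.initial_sampler
        states = list(self.initial_states)
        probs = np.asarray(self.initial_weights, dtype=float)
        probs = probs / probs.sum()

        def _draw(rng: np.random.Generator):
            return states[rng.choice(len(states), p=probs)]

        return _draw

    def summary(self) -> dict:
        """Plain-scalar summary embedded in run stores for provenance."""
        return {
            "tau": float(self.tau),
            "n_iterations": int(self.n_iterations),
            "n_initial_states": len(self.initial_states),
            "mode": self.mode,
            "seed": int(self.seed),
            "burn_in": float(self.burn_in),
            "label": self.label,
        }
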