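"""Obstacle scenarios and virtual-motor ablations.

Obstacles are mechanical constraints on the cargo, not simulated objects.
A *static* obstacle pins the cargo at a fixed position once the cargo
reaches it; a *moving* obstacle (e.g. a retrograde cargo) pushes the cargo
toward the minus end at a fixed speed.  Either constraint is released —
permanently — as soon as the summed linker force of the bound motors
exceeds ``F_obs``.  The team *overcomes* the obstacle if the cargo then
advances at least one lattice site (8 nm) past the release point before
every motor has detached; the fraction of replicates that do is ``P_oc``,
and surviving ``n`` consecutive obstacles has probability ``P_oc**n``.

Virtual motors isolate which kinesin property produces highly loaded
behavior (HLB): variant 1 spreads the per-cycle unbinding probability
equally over the three vulnerable states, variant 2 makes the stepping
frequency force-independent, variant 3 does both.  The per-cycle
unbinding probability at fixed force is identical for all variants; only
its placement in the cycle (and the cycle's tempo) differs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "ObstacleSpec",
    "make_virtual_motor",
    "apply_obstacle",
    "overcoming_probability",
]


@dataclass(frozen=True)
class ObstacleSpec:
    """A static or moving obstacle on the cargo's path.

    Attributes
    ----------
    kind : str
        ``"static"`` or ``"moving"``.
    F_obs : float
        Summed motor force (pN) needed to overcome the obstacle.
    v_obs : float
        Retrograde speed (nm/s) imposed on the cargo (moving only).
    position : float
        Obstacle position (nm) on the MT axis (static only).
    """

    kind: str = "static"
    F_obs: float = 15.0
    v_obs: float = 0.0
    position: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("static", "moving"):
            raise ValueError("kind must be 'static' or 'moving'")
        if self.F_obs < 0:
            raise ValueError("F_obs must be >= 0")
        if self.v_obs < 0:
            raise ValueError("v_obs must be >= 0")


def make_virtual_motor(config, variant: Optional[int]):
    """Return a copy of ``config`` running the requested motor model.

    ``variant=None`` restores the real kinesin.  See the module docstring
    for what each variant changes.
    """
    if variant not in (None, 1, 2, 3):
        raise ValueError("variant must be None, 1, 2 or 3")
    return replace(config, variant=variant)


def apply_obstacle(state, spec: ObstacleSpec, dt: float):
    """Apply one interval of the obstacle constraint to a team state.

    This is the same rule the engine applies internally each step; it is
    exposed for direct inspection: the cargo is clamped (static) or pushed
    back at ``v_obs`` (moving) until the summed motor force exceeds
    ``F_obs``, after which the constraint is gone for good.
    """
    if state.obstacle_released:
        return state
    if spec.kind == "static":
        state.x_c = min(state.x_c, spec.position)
    else:
        state.x_c = state.x_c - spec.v_obs * dt
    if state._team_force_on_cargo(state.x_c) > spec.F_obs:
        state.obstacle_released = True
        state.release_ref = spec.position if spec.kind == "static" else state.x_c
    return state


def overcoming_probability(config, spec: ObstacleSpec, n_reps: int = 200):
    """Estimate ``P_oc`` for one obstacle.

    Runs ``n_reps`` independent replicates of ``config`` with the obstacle
    installed and returns ``(P_oc, SE)`` with the binomial standard error.
    """
    from .engine import run_transport  # deferred to avoid an import cycle
    import numpy as np

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = replace(config, obstacle=spec)
    children = np.random.SeedSequence(cfg.seed).spawn(n_reps)
    n_pass = sum(bool(run_transport(cfg, seed_seq=c).overcame) for c in children)
    p = n_pass / n_reps
    se = math.sqrt(p * (1.0 - p) / n_reps)
    return p, se
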