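"""Force- and state-dependent detachment of a bound kinesin from the MT.

Both heads are strongly bound during ``[K.ATP+MT]_2`` and
``[K.ADP.Pi+MT]``, so detachment from those states is negligible.  The two
unbinding pathways are:

* during ``[K+MT]`` (one head waiting for ATP): a first-order hazard with
  rate ``k_D0``; the survival probability obeys
  ``P_[K+MT](t) + P_D0(t) = 1`` with ``P_D0(t) = 1 - exp(-k_D0 t)``;
* at the stepping checkpoint ``[K.ATP+MT]_1`` (one head diffusing between
  sites): a single per-step probability ``P_D1``, because the state is
  negligibly short compared with the dwell time.

Both quantities amplify exponentially with the magnitude of the linker
force (Bell model)::

    k_D0 = k_D0_0 * exp(|F_k| d_0 / kBT)
    P_D1 = P_D1_0 * exp(|F_k| d_1 / kBT)   (clipped at 1)

The default constants were fitted to measured single-kinesin run lengths;
the fit leaves ``d_0 = 0``, i.e. detachment while waiting for ATP is
force-independent, and puts all force sensitivity in the stepping
checkpoint.  They are intended for teams of one to five motors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "UnbindingParams",
    "rate_kD0",
    "prob_PD0",
    "prob_PD1",
    "kmt_race",
    "checkpoint_unbinds",
    "sample_unbinding",
    "per_cycle_unbinding_probability",
]


@dataclass(frozen=True)
class UnbindingParams:
    """Bell-model unbinding constants (run-length-fitted defaults)."""

    k_D0_0: float = 0.01633  # base [K+MT] detachment rate, 1/s
    P_D1_0: float = 0.01     # base per-step checkpoint probability
    d_0: float = 0.0         # force distance of the [K+MT] pathway, nm
    d_1: float = 1.272       # force distance of the checkpoint pathway, nm
    kBT: float = 4.1         # thermal energy, pN*nm

    def __post_init__(self) -> None:
        if self.k_D0_0 < 0 or self.d_0 < 0 or self.d_1 < 0:
            raise ValueError("rates and force distances must be >= 0")
        if not 0.0 <= self.P_D1_0 <= 1.0:
            raise ValueError("P_D1_0 must be a probability")


def rate_kD0(F_k: float, p: UnbindingParams) -> float:
    """Detachment rate (1/s) from ``[K+MT]`` at linker force ``F_k`` (pN)."""
    return p.k_D0_0 * math.exp(abs(F_k) * p.d_0 / p.kBT)


def prob_PD0(t: float, F_k: float, p: UnbindingParams) -> float:
    """Probability of having detached from ``[K+MT]`` within dwell time t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return -math.expm1(-rate_kD0(F_k, p) * t)


def prob_PD1(F_k: float, p: UnbindingParams) -> float:
    """Per-step detachment probability at the stepping checkpoint."""
    return min(1.0, p.P_D1_0 * math.exp(abs(F_k) * p.d_1 / p.kBT))


def kmt_race(
    F_k: float, k_chem: float, p: UnbindingParams, r_w: float, r_d0: float
) -> tuple[float, bool]:
    """Race between ATP binding and detachment during ``[K+MT]``.

    Both waiting times are exponential, so the winner and the instant are
    closed-form given the cycle's uniform draws: the chemical transition
    fires when its CDF reaches ``r_w``, detachment when ``P_D0`` reaches
    ``r_d0``.  Returns ``(dwell, unbinds)``; ``dwell`` may be ``inf`` when
    both rates vanish.
    """
    for r in (r_w, r_d0):
        if not 0.0 < r < 1.0:
            raise ValueError(f"uniform draw must lie in (0,1), got {r}")
    kd = rate_kD0(F_k, p)
    t_unbind = -math.log1p(-r_d0) / kd if kd > 0 else math.inf
    t_chem = -math.log1p(-r_w) / k_chem if k_chem > 0 else math.inf
    if t_unbind < t_chem:
        return t_unbind, True
    return t_chem, False


def checkpoint_unbinds(F_k: float, p: UnbindingParams, r_d1: float) -> bool:
    """Detachment decision while the free head diffuses between sites."""
    if not 0.0 < r_d1 < 1.0:
        raise ValueError(f"uniform draw must lie in (0,1), got {r_d1}")
    return prob_PD1(F_k, p) > r_d1


def sample_unbinding(
    F_k: float,
    k_chem: float,
    p: UnbindingParams,
    r_w: float,
    r_d0: float,
    r_d1: float,
) -> tuple[bool, float, str | None]:
    """Unbinding decision over one full cycle, given the cycle's draws.

    Chains the ``[K+MT]`` race with the stepping checkpoint: returns
    ``(unbinds, dwell_in_K_MT, pathway)`` with pathway ``"D0"``, ``"D1"``
    or ``None``.  The later bound states carry no unbinding.
    """
    dwell, gone = kmt_race(F_k, k_chem, p, r_w, r_d0)
    if gone:
        return True, dwell, "D0"
    if checkpoint_unbinds(F_k, p, r_d1):
        return True, dwell, "D1"
    return False, dwell, None


def per_cycle_unbinding_probability(
    F_k: float, k_chem: float, p: UnbindingParams
) -> float:
    """Total probability that a cycle started in ``[K+MT]`` ends detached.

    Combines the ``[K+MT]`` race (exponential-race win probability
    ``k_D0 / (k_D0 + k_chem)``) with the stepping checkpoint.  Used for
    the virtual-motor ablations and as the analytic cross-check of the
    sampled unbinding frequency.
    """
    kd = rate_kD0(F_k, p)
    q0 = kd / (kd + k_chem) if (kd + k_chem) > 0 else 0.0
    return q0 + (1.0 - q0) * prob_PD1(F_k, p)
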