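"""Mechanochemical cycle of a bound kinesin.

A bound motor cycles through four chemical states::

    [K+MT] --ATP binding--> [K.ATP+MT]_1 --step--> [K.ATP+MT]_2
           <-- Pi release -- [K.ADP.Pi+MT] <-- hydrolysis --

The exit from ``[K+MT]`` is ATP binding with rate ``k_on_ATP * [ATP]``.
``[K.ATP+MT]_1`` — neck-linker docking plus the diffusive relocation of
the free head — is much shorter than the dwell time and is treated as
instantaneous; it exists as the stepping checkpoint where the step
direction is drawn and where the dominant unbinding pathway acts (see
:mod:`kinteam.unbinding`).  The two remaining states share the rest of
the cycle time with equal zero-load rates.

Load dependence.  A hindering load slows the transition that produces
the step: the exit from ``[K+MT]`` carries a Boltzmann factor
``exp(-F * delta / kBT)`` where ``F`` is the hindering component of the
linker force (assisting loads do not speed the motor up).  Under a large
resisting load a motor therefore sits almost motionless in ``[K+MT]``
waiting to complete ATP binding and neck-linker docking — the anchoring
behavior that drives HLB — while the post-stepping states keep their
zero-load rates.  ``delta`` and the composite post-stepping rate are
calibrated from single-molecule anchors: unloaded velocity 800 nm/s at
saturating (2 mM) ATP, a 10 ms unloaded cycle, and a 70 ms dwell under a
5 pN hindering load.  Backward steps
follow a logistic law in the hindering load centered at the ~7 pN stall
force, where forward and backward stepping balance.

Functions in this module take the hindering load ``F_k`` with the
single-molecule force-clamp sign convention: positive = resisting
(toward the minus end), negative = assisting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

__all__ = [
    "ChemicalState",
    "RateParams",
    "calibrated_rates",
    "exit_rate",
    "state_waiting_time_cdf",
    "sample_transition",
    "backward_step_probability",
    "advance_cycle",
    "MotorCycleState",
]


# calibration anchors: 10 ms unloaded cycle at 2 mM ATP, 70 ms dwell at 5 pN
_T_ATP_SAT = 1.0 / (2.0e6 * 2.0e-3)       # ATP-binding time at 2 mM, s
_T_MECH = 8.0 / 800.0 - _T_ATP_SAT        # composite post-stepping time, s
_DELTA = 4.1 / 5.0 * math.log((70.0e-3 - _T_MECH) / _T_ATP_SAT)  # nm


class ChemicalState(Enum):
    """Chemical state labels of the stepping cycle."""

    K_MT = "K_MT"
    K_ATP_MT_1 = "K_ATP_MT_1"
    K_ATP_MT_2 = "K_ATP_MT_2"
    K_ADP_PI_MT = "K_ADP_Pi_MT"
    UNBOUND = "UNBOUND"


#: bound states visited in cycle order (state 1 is instantaneous)
CYCLE_ORDER = (
    ChemicalState.K_MT,
    ChemicalState.K_ATP_MT_1,
    ChemicalState.K_ATP_MT_2,
    ChemicalState.K_ADP_PI_MT,
)


@dataclass(frozen=True)
class RateParams:
    """Kinetic constants of the cycle.

    Attributes
    ----------
    k_on_ATP : float
        Second-order ATP binding rate, 1/(M*s).
    ATP_conc : float
        ATP concentration, M.
    k_mech : float
        Exit rate of each of the two post-stepping states, 1/s
        (force-independent; the composite post-stepping time is
        ``2 / k_mech``).
    step_force_scale : float
        Characteristic distance ``delta`` (nm) of the Boltzmann slowdown
        of the ``[K+MT]`` exit (the stepping transition) under hindering
        load.
    stall_force : float
        Hindering load (pN) at which backward steps reach probability 0.5.
    backward_width : float
        Width (pN) of the logistic backward-step law.
    kBT : float
        Thermal energy, pN*nm.
    force_dependent : bool
        If False the stepping transition ignores load ("virtual motor 2").
    """

    k_on_ATP: float = 2.0e6
    ATP_conc: float = 2.0e-3
    k_mech: float = 2.0 / _T_MECH
    step_force_scale: float = _DELTA
    stall_force: float = 7.0
    backward_width: float = 1.0
    kBT: float = 4.1
    force_dependent: bool = True

    def __post_init__(self) -> None:
        if min(self.k_on_ATP, self.ATP_conc, self.k_mech) < 0:
            raise ValueError("rates and concentrations must be >= 0")

    def with_atp(self, ATP_conc: float) -> "RateParams":
        return replace(self, ATP_conc=ATP_conc)


def calibrated_rates(
    *,
    ATP_conc: float = 2.0e-3,
    k_on_ATP: float = 2.0e6,
    unloaded_cycle_time: float = 8.0 / 800.0,
    loaded_dwell: float = 70.0e-3,
    load: float = 5.0,
    kBT: float = 4.1,
    **kwargs,
) -> RateParams:
    """Build :class:`RateParams` from single-molecule calibration anchors.

    ``k_mech`` is fixed so that the unloaded cycle at saturating ATP takes
    ``unloaded_cycle_time`` (10 ms -> 800 nm/s), and ``delta`` so that the
    dwell under ``load`` equals ``loaded_dwell`` (70 ms at 5 pN).
    """
    t_atp = 1.0 / (k_on_ATP * 2.0e-3)  # anchored at saturating ATP
    t_mech = unloaded_cycle_time - t_atp
    if t_mech <= 0:
        raise ValueError("unloaded cycle time shorter than the ATP-binding time")
    if loaded_dwell <= unloaded_cycle_time:
        raise ValueError("loaded dwell must exceed the unloaded cycle time")
    delta = kBT / load * math.log((loaded_dwell - t_mech) / t_atp)
    return RateParams(
        k_on_ATP=k_on_ATP,
        ATP_conc=ATP_conc,
        k_mech=2.0 / t_mech,
        step_force_scale=delta,
        kBT=kBT,
        **kwargs,
    )


def exit_rate(state: ChemicalState, rates: RateParams, F_k: float = 0.0) -> float:
    """Exit rate (1/s) of a bound state under hindering load ``F_k`` (pN).

    ``[K.ATP+MT]_1`` is instantaneous and returns ``inf``.
    """
    if state is ChemicalState.UNBOUND:
        raise ValueError("unbound motors have no cycle exit rate")
    if state is ChemicalState.K_MT:
        hindering = max(0.0, F_k) if rates.force_dependent else 0.0
        slow = math.exp(-hindering * rates.step_force_scale / rates.kBT)
        return rates.k_on_ATP * rates.ATP_conc * slow
    if state is ChemicalState.K_ATP_MT_1:
        return math.inf
    return rates.k_mech


def state_waiting_time_cdf(
    state: ChemicalState, rates: RateParams, F_k: float, t: float
) -> float:
    """P(the transition out of ``state`` has occurred by time t)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    r = exit_rate(state, rates, F_k)
    if math.isinf(r):
        return 1.0 if t > 0 else 0.0
    return -math.expm1(-r * t)


def sample_transition(
    state: ChemicalState, rates: RateParams, F_k: float, r_w: float
) -> float:
    """Inverse-CDF waiting time of the transition out of ``state``.

    Deterministic given the uniform draw ``r_w`` in (0, 1); returns ``inf``
    when the exit rate is zero (e.g. no ATP).
    """
    if not 0.0 < r_w < 1.0:
        raise ValueError(f"uniform draw must lie in (0,1), got {r_w}")
    r = exit_rate(state, rates, F_k)
    if r == 0.0:
        return math.inf
    return -math.log1p(-r_w) / r


def backward_step_probability(
    F_k: float, stall_force: float = 7.0, width: float = 1.0
) -> float:
    """Probability that the relocating head lands on the rear site.

    Logistic in the hindering load, 0.5 at stall (~7 pN) where forward and
    backward steps balance, ~1e-3 when unloaded, monotone in ``F_k``.
    """
    return 1.0 / (1.0 + math.exp((stall_force - F_k) / width))


@dataclass
class MotorCycleState:
    """Minimal per-motor cycle bookkeeping used by :func:`advance_cycle`."""

    x_r: float = 0.0
    state: ChemicalState = ChemicalState.K_MT


def advance_cycle(
    motor: MotorCycleState,
    rates: RateParams,
    F_k: float,
    draws: tuple[float, float, float, float],
) -> tuple[MotorCycleState, float]:
    """Advance one full cycle ``K_MT -> ... -> K_MT`` ignoring unbinding.

    ``draws = (r_w, r_s2, r_s3, r_b)`` are the cycle's uniforms: ATP-binding
    waiting time, the two post-stepping waiting times, and the step
    direction.  Returns the updated motor (anchor moved +-8 nm) and the
    cycle duration; the duration is ``inf`` at zero ATP and the motor then
    dwells in ``[K+MT]`` indefinitely.
    """
    if motor.state is ChemicalState.UNBOUND:
        raise ValueError("advance_cycle requires a bound motor")
    r_w, r_s2, r_s3, r_b = draws
    t = sample_transition(ChemicalState.K_MT, rates, F_k, r_w)
    if math.isinf(t):
        return motor, math.inf
    backward = backward_step_probability(F_k, rates.stall_force, rates.backward_width) > r_b
    dx = -8.0 if backward else 8.0
    t += sample_transition(ChemicalState.K_ATP_MT_2, rates, F_k, r_s2)
    t += sample_transition(ChemicalState.K_ADP_PI_MT, rates, F_k, r_s3)
    return MotorCycleState(x_r=motor.x_r + dx, state=ChemicalState.K_MT), t
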