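"""Monte Carlo engine for team transport.

One realization starts with a single motor bound at site 0 and every other
motor unbound, and runs until all motors have detached (or a time cap).
Each engine step of length ``dt`` freezes the per-motor linker forces,
advances every bound motor through its cycle, and relaxes the cargo; the
rebinding probabilities of unbound motors are refreshed on the coarser
interval ``dt_rebind``.

Event timing is free of ``dt`` bias: within a step, transition and
unbinding instants are obtained from the analytic crossing of the
accumulated hazard with the cycle's uniform draws, so a step may contain
zero, one or several chemical events at their exact times.  ``dt`` only
limits how often forces are refreshed.

Randomness: each replicate owns a ``numpy.random.SeedSequence`` spawned
from the top-level seed, and each motor a child stream of its replicate,
so event logs are bit-identical for identical configurations and seeds
regardless of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .chemistry import ChemicalState, RateParams, backward_step_probability
from .mechanics import MechanicalParams, cargo_equilibrium
from .obstacles import ObstacleSpec
from .rebinding import (
    AttachmentProfile,
    cargo_pdf,
    mean_site_rates,
    relative_pdf,
    unbound_pdf,
)
from .unbinding import UnbindingParams, per_cycle_unbinding_probability, prob_PD1, rate_kD0

__all__ = [
    "SimulationConfig",
    "MotorState",
    "TeamState",
    "RunResult",
    "init_state",
    "step",
    "run_transport",
    "run_ensemble",
]

_STEP_NM = 8.0


@dataclass
class SimulationConfig:
    """Full configuration of one transport simulation.

    ``variant`` selects the virtual-motor ablations used to probe HLB:
    ``None`` is the real kinesin, 1 redistributes the per-cycle unbinding
    equally over the three vulnerable states, 2 makes the stepping
    frequency force-independent, 3 applies both.
    """

    n_kinesins: int = 2
    ATP_conc: float = 2.0e-3       # M
    F_L: float = 0.0               # pN, positive toward the minus end
    dt: float = 1.0e-4             # engine step, s
    dt_rebind: float = 1.0e-3      # rebinding-refresh interval, s
    t_max: float = 60.0            # s
    seed: int = 0
    obstacle: Optional[ObstacleSpec] = None
    variant: Optional[int] = None
    mech: MechanicalParams = field(default_factory=MechanicalParams)
    rates: Optional[RateParams] = None
    unbind: UnbindingParams = field(default_factory=UnbindingParams)
    profile: AttachmentProfile = field(default_factory=AttachmentProfile)
    record_trajectory: bool = False
    allow_large_teams: bool = False

    def __post_init__(self) -> None:
        if not self.allow_large_teams and not 1 <= self.n_kinesins <= 5:
            # the unbinding constants were fitted for 1-5 motor teams
            raise ValueError("n_kinesins must be between 1 and 5")
        if self.n_kinesins < 1:
            raise ValueError("need at least one motor")
        if self.dt <= 0 or self.dt > self.dt_rebind:
            raise ValueError("require 0 < dt <= dt_rebind")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.variant not in (None, 1, 2, 3):
            raise ValueError("variant must be None, 1, 2 or 3")
        if self.rates is None:
            self.rates = RateParams(ATP_conc=self.ATP_conc)
        else:
            self.rates = replace(self.rates, ATP_conc=self.ATP_conc)
        if self.variant in (2, 3):
            self.rates = replace(self.rates, force_dependent=False)


@dataclass
class MotorState:
    """One motor's chemical state, lattice position and pending draws."""

    idx: int
    rng: np.random.Generator
    bound: bool = False
    x_r: float = 0.0
    state: ChemicalState = ChemicalState.UNBOUND
    # uniforms of the current cycle (regenerated at each cycle start)
    r_d1: float = 0.5
    r_b: float = 0.5
    # exponential hazard targets and accumulators
    E_w: float = 0.0
    used_w: float = 0.0
    E_d0: float = 0.0
    used_d0: float = 0.0
    E_s2: float = 0.0
    E_s3: float = 0.0
    used_s: float = 0.0

    @property
    def site(self) -> int:
        return int(round(self.x_r / _STEP_NM))

    def new_cycle(self) -> None:
        """Draw the cycle's uniforms and reset hazard accumulators."""
        u = self.rng.random(6)
        self.E_w = -math.log1p(-u[0])
        self.E_d0 = -math.log1p(-u[1])
        self.r_d1 = u[2]
        self.r_b = u[3]
        self.E_s2 = -math.log1p(-u[4])
        self.E_s3 = -math.log1p(-u[5])
        self.used_w = self.used_d0 = self.used_s = 0.0
        self.state = ChemicalState.K_MT


@dataclass
class RunResult:
    """Outcome of one transport realization."""

    run_length: float            # nm, x_c(end) - x_c(start)
    duration: float              # s
    mean_velocity: float         # nm/s, run_length / duration
    terminated_by: str           # 'all-unbound' | 't_max' | 'overcame'
    events: list = field(default_factory=list)
    overcame: Optional[bool] = None
    trajectory: Optional[dict] = None


def _force_on_motor(x_c: float, x_r: float, K_e: float, L_c: float) -> float:
    """Scalar linker force on a motor, axis convention (fast path)."""
    d = x_c - x_r
    if d > L_c:
        return K_e * (d - L_c)
    if d < -L_c:
        return K_e * (d + L_c)
    return 0.0


class TeamState:
    """Mutable state of one realization; drives the per-``dt`` update."""

    def __init__(self, config: SimulationConfig, seed_seq: Optional[np.random.SeedSequence] = None):
        self.config = config
        mech = config.mech
        if seed_seq is None:
            seed_seq = np.random.SeedSequence(config.seed)
        streams = seed_seq.spawn(config.n_kinesins)
        self.motors = [
            MotorState(idx=i, rng=np.random.default_rng(streams[i]))
            for i in range(config.n_kinesins)
        ]
        # transport starts with exactly one motor bound, at site 0
        m0 = self.motors[0]
        m0.bound = True
        m0.x_r = 0.0
        m0.new_cycle()
        self.t = 0.0
        self.x_c = cargo_equilibrium([0.0], config.F_L, mech)
        self.x_c0 = self.x_c
        self.events: list = []
        self.steps_per_refresh = max(1, round(config.dt_rebind / config.dt))
        self.step_count = 0
        self.last_unbind_time = 0.0
        self.redistribute = config.variant in (1, 3)
        # obstacle bookkeeping
        self.obstacle_released = config.obstacle is None
        self.release_ref: Optional[float] = None
        self.overcame = False if config.obstacle is not None else None
        # caches
        self._k_on = config.rates.k_on_ATP * config.rates.ATP_conc
        self._rel_pdf = relative_pdf(mech)
        self._rebind_cache: dict = {}
        self._x_eq: float = self.x_c
        self._mech_dirty = True
        self._refresh_mechanics()
        # trajectory recording
        if config.record_trajectory:
            self.trajectory: Optional[dict] = {
                "time_s": [],
                "x_c_nm": [],
                "states": [],
                "sites": [],
                "forces": [],
            }
            self._record()
        else:
            self.trajectory = None

    # ------------------------------------------------------------------ #
    # mechanics helpers

    def bound_motors(self) -> list[MotorState]:
        return [m for m in self.motors if m.bound]

    def _refresh_mechanics(self) -> None:
        """Recompute the cargo equilibrium after any motor event."""
        bound = self.bound_motors()
        if bound:
            self._x_eq = cargo_equilibrium(
                [m.x_r for m in bound], self.config.F_L, self.config.mech
            )
        self._mech_dirty = False

    def _team_force_on_cargo(self, x_c: float) -> float:
        """Sum of linker forces exerted on the cargo (+ = plus end)."""
        mech = self.config.mech
        return -sum(
            _force_on_motor(x_c, m.x_r, mech.K_e, mech.L_c) for m in self.bound_motors()
        )

    def _update_cargo(self, dt: float) -> None:
        mech = self.config.mech
        if self._mech_dirty:
            self._refresh_mechanics()
        n_bound = sum(1 for m in self.motors if m.bound)
        decay = math.exp(-mech.K_e * n_bound * dt / mech.gamma_c)
        x_free = self._x_eq + (self.x_c - self._x_eq) * decay
        obs = self.config.obstacle
        if obs is None or self.obstacle_released:
            self.x_c = x_free
            return
        if obs.kind == "static":
            if x_free < obs.position:
                self.x_c = x_free
                return
            self.x_c = obs.position
        else:  # moving: obstacle pushes the cargo backward kinematically
            self.x_c = self.x_c - obs.v_obs * dt
        if self._team_force_on_cargo(self.x_c) > obs.F_obs:
            self.obstacle_released = True
            self.release_ref = obs.position if obs.kind == "static" else self.x_c
            self.events.append((self.t, -1, "obstacle_release", self.release_ref))

    # ------------------------------------------------------------------ #
    # bound-motor update

    def _k_chem(self, F_hind: float) -> float:
        """Exit rate of [K+MT] at the current hindering load."""
        rates = self.config.rates
        if not rates.force_dependent or F_hind <= 0.0:
            return self._k_on
        return self._k_on * math.exp(-F_hind * rates.step_force_scale / rates.kBT)

    def _virtual_state_hazard(self, F_abs: float, k_chem: float) -> float:
        """Per-state unbinding hazard of virtual motors 1 and 3.

        The real motor's total per-cycle unbinding probability at the
        current force is converted to a survival hazard and split equally
        over the three vulnerable states, so the per-cycle probability is
        preserved exactly.
        """
        p_cycle = per_cycle_unbinding_probability(F_abs, k_chem, self.config.unbind)
        return -math.log1p(-min(p_cycle, 1.0 - 1e-15)) / 3.0

    def _checkpoint_virtual(self, m: MotorState, F_abs: float, k_chem: float, t_abs: float) -> bool:
        """Equal-hazard unbinding checkpoint; True if the motor detached."""
        p3 = -math.expm1(-self._virtual_state_hazard(F_abs, k_chem))
        if p3 > m.rng.random():
            self._unbind(m, t_abs, "unbind_eq")
            return True
        return False

    def _unbind(self, m: MotorState, t_abs: float, kind: str) -> None:
        m.bound = False
        m.state = ChemicalState.UNBOUND
        self.events.append((t_abs, m.idx, kind, m.site))
        self.last_unbind_time = t_abs
        self._mech_dirty = True

    def _advance_motor(self, m: MotorState, t0: float, dt: float) -> None:
        """Advance one bound motor through the interval [t0, t0+dt].

        Linker force is frozen over the interval; events inside it occur
        at their analytic hazard-crossing times, so several transitions
        can fire within one interval.
        """
        cfg = self.config
        rates, ub, mech = cfg.rates, cfg.unbind, cfg.mech
        F_axis = _force_on_motor(self.x_c, m.x_r, mech.K_e, mech.L_c)
        F_hind = -F_axis            # positive = resisting load on the motor
        F_abs = abs(F_axis)
        local = 0.0
        while m.bound and local < dt:
            remaining = dt - local
            if m.state is ChemicalState.K_MT:
                k_chem = self._k_chem(F_hind)
                t_chem = (m.E_w - m.used_w) / k_chem if k_chem > 0 else math.inf
                if self.redistribute:
                    t_d0 = math.inf
                else:
                    kd0 = rate_kD0(F_abs, ub)
                    t_d0 = (m.E_d0 - m.used_d0) / kd0 if kd0 > 0 else math.inf
                t_evt = min(t_chem, t_d0)
                if t_evt > remaining:
                    m.used_w += k_chem * remaining
                    if not self.redistribute and not math.isinf(t_d0):
                        m.used_d0 += kd0 * remaining
                    return
                local += t_evt
                t_abs = t0 + local
                if t_d0 < t_chem:
                    self._unbind(m, t_abs, "unbind_D0")
                    return
                # ATP bound: pass through the instantaneous stepping state
                if self.redistribute:
                    if self._checkpoint_virtual(m, F_abs, k_chem, t_abs):
                        return
                    if self._checkpoint_virtual(m, F_abs, k_chem, t_abs):
                        return
                elif prob_PD1(F_abs, ub) > m.r_d1:
                    self._unbind(m, t_abs, "unbind_D1")
                    return
                backward = (
                    backward_step_probability(F_hind, rates.stall_force, rates.backward_width)
                    > m.r_b
                )
                m.x_r += -_STEP_NM if backward else _STEP_NM
                m.state = ChemicalState.K_ATP_MT_2
                m.used_s = 0.0
                self.events.append((t_abs, m.idx, "step", -1 if backward else 1))
                self._mech_dirty = True
                # the step moved the anchor: refresh the frozen force
                F_axis = _force_on_motor(self.x_c, m.x_r, mech.K_e, mech.L_c)
                F_hind, F_abs = -F_axis, abs(F_axis)
            else:
                # timed post-stepping states (force-independent exits)
                k = rates.k_mech
                target = m.E_s2 if m.state is ChemicalState.K_ATP_MT_2 else m.E_s3
                t_evt = (target - m.used_s) / k if k > 0 else math.inf
                if t_evt > remaining:
                    m.used_s += k * remaining
                    return
                local += t_evt
                t_abs = t0 + local
                if m.state is ChemicalState.K_ATP_MT_2:
                    if self.redistribute and self._checkpoint_virtual(
                        m, F_abs, self._k_chem(F_hind), t_abs
                    ):
                        return
                    m.state = ChemicalState.K_ADP_PI_MT
                    m.used_s = 0.0
                else:
                    m.new_cycle()  # back to [K+MT]

    # ------------------------------------------------------------------ #
    # rebinding

    def _rebind_entry(self):
        """Cached per-configuration site rates for the unbound motors.

        The unbound-position pdf depends on the bound anchors only through
        their relative offsets (and the fixed load), so entries are keyed
        by the offset tuple and shifted to the current absolute position.
        """
        cfg = self.config
        bound_sites = sorted(m.site for m in self.motors if m.bound)
        ref = bound_sites[0]
        key = tuple(s - ref for s in bound_sites)
        entry = self._rebind_cache.get(key)
        if entry is None:
            a = cfg.profile.lattice_a
            anchors = [o * a for o in key]
            pdf_u = unbound_pdf(cargo_pdf(anchors, cfg.F_L, cfg.mech), self._rel_pdf)
            sites, rr = mean_site_rates(pdf_u, cfg.profile)
            keep = ~np.isin(sites, np.asarray(key))
            sites, rr = sites[keep], rr[keep]
            total = float(rr.sum())
            if total * cfg.dt_rebind > 0.1:
                raise ValueError(
                    "dt_rebind too large: total rebinding probability per "
                    f"interval is {total * cfg.dt_rebind:.3f}"
                )
            cum = np.cumsum(rr) / total if total > 0 else rr
            entry = (sites, cum, total)
            self._rebind_cache[key] = entry
        return entry, ref

    def _rebind_unbound(self) -> None:
        unbound = [m for m in self.motors if not m.bound]
        if not unbound or not any(m.bound for m in self.motors):
            return
        (sites, cum, total), ref = self._rebind_entry()
        p_bind = total * self.config.dt_rebind
        for m in unbound:
            r_a1, r_a2 = m.rng.random(2)
            if p_bind > r_a1:
                site = int(sites[int(np.searchsorted(cum, r_a2, side="left"))]) + ref
                m.bound = True
                m.x_r = site * self.config.profile.lattice_a
                m.new_cycle()
                self.events.append((self.t, m.idx, "rebind", site))
                self._mech_dirty = True

    # ------------------------------------------------------------------ #
    # loop

    def _record(self) -> None:
        mech = self.config.mech
        tr = self.trajectory
        tr["time_s"].append(self.t)
        tr["x_c_nm"].append(self.x_c)
        tr["states"].append([m.state.value for m in self.motors])
        tr["sites"].append([m.site if m.bound else None for m in self.motors])
        tr["forces"].append(
            [
                _force_on_motor(self.x_c, m.x_r, mech.K_e, mech.L_c) if m.bound else 0.0
                for m in self.motors
            ]
        )

    def advance(self) -> None:
        """One engine step of length dt."""
        dt = self.config.dt
        self._update_cargo(dt)
        t0 = self.t
        for m in self.motors:
            if m.bound:
                self._advance_motor(m, t0, dt)
        self.t = t0 + dt
        self.step_count += 1
        if self.step_count % self.steps_per_refresh == 0:
            self._rebind_unbound()
            if self.trajectory is not None:
                self._record()
        if self.overcame is False and self.obstacle_released and self.release_ref is not None:
            if self.x_c >= self.release_ref + _STEP_NM:
                self.overcame = True
                self.events.append((self.t, -1, "overcome", self.x_c))

    def finished(self) -> bool:
        if not any(m.bound for m in self.motors):
            return True
        if self.overcame:
            return True
        return self.t >= self.config.t_max

    def result(self) -> RunResult:
        if self.overcame:
            terminated_by = "overcame"
            duration = self.t
        elif any(m.bound for m in self.motors):
            terminated_by = "t_max"
            duration = self.config.t_max
        else:
            terminated_by = "all-unbound"
            duration = self.last_unbind_time
        duration = max(duration, self.config.dt)
        run_length = self.x_c - self.x_c0
        # motors are advanced sequentially within a step (frozen forces), so
        # cross-motor events inside one dt window need a chronological sort
        events = sorted(self.events, key=lambda e: e[0])
        return RunResult(
            run_length=run_length,
            duration=duration,
            mean_velocity=run_length / duration,
            terminated_by=terminated_by,
            events=events,
            overcame=self.overcame,
            trajectory=self.trajectory,
        )


def init_state(
    config: SimulationConfig, seed_seq: Optional[np.random.SeedSequence] = None
) -> TeamState:
    """Initial team state: motor 0 bound at site 0, all others unbound."""
    return TeamState(config, seed_seq)


def step(state: TeamState) -> TeamState:
    """Advance the realization by one engine step ``dt`` (in place)."""
    state.advance()
    return state


def run_transport(
    config: SimulationConfig, seed_seq: Optional[np.random.SeedSequence] = None
) -> RunResult:
    """Simulate one transport until all motors detach (or ``t_max``)."""
    state = TeamState(config, seed_seq)
    while not state.finished():
        state.advance()
    return state.result()


def run_ensemble(config: SimulationConfig, n_reps: int = 200):
    """Independent replicates with per-replicate derived seed streams.

    Returns ``(results, summary)``; see
    :func:`kinteam.io_analysis.summarize`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    from .io_analysis import summarize

    children = np.random.SeedSequence(config.seed).spawn(n_reps)
    results = [run_transport(config, seed_seq=c) for c in children]
    return results, summarize(results)
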