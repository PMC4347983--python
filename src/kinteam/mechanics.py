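"""Elastic coupling between motors and cargo.

Geometry is one-dimensional along the MT axis; the plus end points in the
positive direction and binding sites sit at integer multiples of the
lattice constant (8 nm).  Each motor is connected to the cargo through two
neck linkers and a cargo linker, lumped into a single equivalent spring of
stiffness ``K_e = 2*K_n*K_c / (2*K_n + K_c)`` with a slack length ``L_c``:
while the cargo sits within ``L_c`` of the motor anchor the connection
transmits no force.

Sign conventions
----------------
* ``F_L`` is the external load on the cargo, positive when directed toward
  the MT minus end (a hindering load for plus-end-directed motors).
* :func:`kinesin_force` returns the force transmitted to a motor along the
  axis: positive values pull the motor toward the plus end (assisting),
  negative values pull it toward the minus end (hindering).  With this
  convention mechanical equilibrium reads ``F_L + sum(F_k) == 0``.
* The chemistry and unbinding modules work with the *hindering load* on a
  motor, ``max(0, -F_k)`` resp. ``|F_k|``; the engine does the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MechanicalParams",
    "MotorGeometry",
    "CargoState",
    "equivalent_stiffness",
    "elastic_energy",
    "cargo_potential_energy",
    "kinesin_force",
    "cargo_equilibrium",
    "cargo_step",
]


def equivalent_stiffness(K_n: float, K_c: float) -> float:
    """Series stiffness of one cargo linker and two parallel neck linkers.

    Parameters
    ----------
    K_n, K_c
        Neck-linker and cargo-linker stiffness in pN/nm; both must be > 0.
    """
    if K_n <= 0 or K_c <= 0:
        raise ValueError(f"stiffnesses must be positive, got K_n={K_n}, K_c={K_c}")
    return 2.0 * K_n * K_c / (2.0 * K_n + K_c)


@dataclass
class MechanicalParams:
    """Mechanical constants of the motor-cargo assembly (nm, pN, s units).

    Defaults are representative of kinesin-coated bead assays: a soft cargo
    linker (0.3 pN/nm), stiffer neck linkers (2 pN/nm), 20 nm of slack, and
    the Stokes drag of a 0.5 um bead in water.  All values can be
    overridden from a config file.
    """

    K_n: float = 2.0          # neck-linker stiffness, pN/nm
    K_c: float = 0.3          # cargo-linker stiffness, pN/nm
    L_c: float = 20.0         # slack length of the motor-cargo connection, nm
    gamma_c: float = 9.4e-4   # cargo drag coefficient, pN*s/nm
    kBT: float = 4.1          # thermal energy, pN*nm (T ~ 297 K)
    lattice_a: float = 8.0    # binding-site spacing, nm

    def __post_init__(self) -> None:
        if self.K_n <= 0 or self.K_c <= 0:
            raise ValueError("stiffnesses must be positive")
        if self.L_c < 0:
            raise ValueError("slack length L_c must be >= 0")
        if self.kBT <= 0 or self.gamma_c <= 0:
            raise ValueError("kBT and gamma_c must be positive")

    @property
    def K_e(self) -> float:
        """Equivalent stiffness of the full linkage, pN/nm."""
        return equivalent_stiffness(self.K_n, self.K_c)


@dataclass
class MotorGeometry:
    """Positions of one bound motor (nm).

    ``x_fh``/``x_bh`` are the forward and backward head positions.  The
    anchor ``x_r`` is the midpoint of the two heads; it is the point the
    cargo linkage pulls on and advances by 8 nm per completed cycle.
    """

    x_fh: float
    x_bh: float

    @property
    def x_r(self) -> float:
        return 0.5 * (self.x_fh + self.x_bh)


@dataclass
class CargoState:
    """Cargo position and load bookkeeping."""

    x_c: float
    F_L: float = 0.0
    x_c_eq: float = 0.0
    F_k_list: list[float] = field(default_factory=list)


def _branch_extension(x_c, x_r, L_c):
    """Signed spring extension beyond the slack window (0 inside it)."""
    x = np.asarray(x_c, dtype=float)
    ahead = x - x_r - L_c
    behind = x - x_r + L_c
    return np.where(ahead > 0, ahead, np.where(behind < 0, behind, 0.0))


def elastic_energy(x_c, x_r: float, params: MechanicalParams):
    """Strain energy stored in one motor linkage, pN*nm (vectorized in x_c)."""
    ext = _branch_extension(x_c, x_r, params.L_c)
    return 0.5 * params.K_e * ext**2


def cargo_potential_energy(
    x_c, x_r: float, params: MechanicalParams, F_L: float = 0.0, x_c_eq: float = 0.0
):
    """Potential energy of the cargo bound through a single motor.

    Three-branch piecewise form: quadratic in the stretched regimes on
    either side of the slack window, zero elastic energy inside it, plus
    the load term ``F_L * (x_c - x_c_eq)`` everywhere.  Continuous and
    continuously differentiable at the branch boundaries ``x_r +- L_c``.
    """
    out = elastic_energy(x_c, x_r, params) + F_L * (np.asarray(x_c, dtype=float) - x_c_eq)
    return out if out.ndim else float(out)


def kinesin_force(x_c, x_r: float, params: MechanicalParams):
    """Force transmitted from the cargo to a bound motor (axis convention).

    Zero inside the open slack window ``(x_r - L_c, x_r + L_c)``, and
    ``K_e * (x_c - x_r -+ L_c)`` outside it.  Positive values pull the
    motor toward the plus end; the magnitude enters the Bell model.
    """
    out = params.K_e * _branch_extension(x_c, x_r, params.L_c)
    return out if out.ndim else float(out)


def team_force(x_c: float, x_r_list, params: MechanicalParams) -> float:
    """Sum of the forces transmitted to all bound motors at cargo position x_c."""
    return float(sum(kinesin_force(x_c, xr, params) for xr in x_r_list))


def cargo_equilibrium(x_r_list, F_L: float, params: MechanicalParams) -> float:
    """Cargo position ``<x_c>`` where the load and the linker forces balance.

    Solves ``F_L + sum_k F_k(x_c) = 0``.  When every motor is slack and
    ``F_L = 0`` the balance holds on a whole interval; the midpoint of that
    interval is returned.
    """
    x_r = [float(g.x_r) if isinstance(g, MotorGeometry) else float(g) for g in x_r_list]
    if not x_r:
        raise ValueError("cargo equilibrium requires at least one bound motor")
    L_c, K_e = params.L_c, params.K_e
    if F_L == 0.0:
        lo_w, hi_w = max(x_r) - L_c, min(x_r) + L_c
        if lo_w <= hi_w:  # common slack window: continuum of solutions
            return 0.5 * (lo_w + hi_w)

    def h(x: float) -> float:
        return F_L + team_force(x, x_r, params)

    pad = abs(F_L) / K_e + 1.0
    lo = min(x_r) - L_c - pad
    hi = max(x_r) + L_c + pad
    # h is nondecreasing, -inf/+inf at the extremes: widen until bracketed
    while h(lo) > 0:
        lo -= 10.0 * pad
    while h(hi) < 0:
        hi += 10.0 * pad
    return float(brentq(h, lo, hi, xtol=1e-12))


def cargo_step(
    state: CargoState, x_r_list, params: MechanicalParams, dt: float
) -> CargoState:
    """Overdamped relaxation of the cargo toward mechanical equilibrium.

    The cargo inertia is negligible, so between motor events the position
    relaxes exponentially toward ``<x_c>`` with time constant
    ``gamma_c / K_total``.  The update is the exact exponential solution,
    so ``dt`` does not need to resolve the mechanical time scale; thermal
    motion of the cargo is represented statistically by the Boltzmann pdf
    in the rebinding module rather than simulated as noise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x_r = [float(g.x_r) if isinstance(g, MotorGeometry) else float(g) for g in x_r_list]
    x_eq = cargo_equilibrium(x_r, state.F_L, params)
    K_total = params.K_e * len(x_r)
    x_new = x_eq + (state.x_c - x_eq) * np.exp(-K_total * dt / params.gamma_c)
    forces = [kinesin_force(x_new, xr, params) for xr in x_r]
    return CargoState(x_c=float(x_new), F_L=state.F_L, x_c_eq=x_eq, F_k_list=forces)
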