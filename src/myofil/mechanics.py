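"""Spring mechanics of the myofilament and buckling mechanics of actin.

Each attached myosin head is a Hookean spring of stiffness kappa anchored at
its rest position on the actin filament; the myofilament is a rigid body
that slides along actin to the position where the net spring force vanishes.
The imbalance between the processively stepping leading end and the
passively dragged trailing end loads the central bare zone, and that load is
transmitted to the spanned actin segment as a compressive force.  When the
compression exceeds the Euler buckling force F_c = pi^2 EI / l^2 the actin
segment buckles: the distance between the two head zones shrinks by delta,
which relieves stress and pins the force at F_c.  The buckle is treated as a
first-mode sine shape, whose maximum curvature grows as sqrt(delta);
curvature beyond ~5.6 um^-1 (bend radius < 0.18 um) breaks the filament.

Coordinates: positions in nm along the actin axis, plus (barbed) end
positive, the leading end ahead of the trailing end.  Forces in pN,
curvature in um^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .kinetics import BOUND_STATES, HeadState, InvalidParameterError

__all__ = [
    "LEADING",
    "TRAILING",
    "MyofilamentParams",
    "Head",
    "ActinMechanics",
    "MechState",
    "FreeFilamentError",
    "equilibrium_position",
    "apply_powerstroke",
    "attach_head",
    "bare_zone_tension",
    "bending_rigidity",
    "euler_buckling_force",
    "critical_curvature",
    "shortening_to_curvature",
    "curvature_to_shortening",
    "equilibrate_buckling",
]

LEADING = "leading"
TRAILING = "trailing"

#: Thermal energy at room temperature, pN nm.
DEFAULT_KT_THERMAL = 4.0


class FreeFilamentError(RuntimeError):
    """No head is attached: the filament position is unconstrained."""


@dataclass(frozen=True)
class MyofilamentParams:
    """Geometry and mechanics constants of the bipolar myosin filament.

    Attributes
    ----------
    n_m : total number of actin-interacting heads (split between the ends)
    n_leading, n_trailing : heads per end
    p_st : probability that a trailing-end powerstroke moves its anchor
    d : powerstroke step size, nm
    kappa : head stiffness, pN/nm
    l_bz : bare-zone length, nm
    """

    n_m: int = 30
    n_leading: int = 15
    n_trailing: int = 15
    p_st: float = 0.0
    d: float = 5.0
    kappa: float = 1.0
    l_bz: float = 160.0

    def __post_init__(self) -> None:
        if self.n_leading + self.n_trailing != self.n_m:
            raise InvalidParameterError(
                f"n_leading + n_trailing must equal n_m "
                f"({self.n_leading}+{self.n_trailing} != {self.n_m})"
            )
        if not 0.0 <= self.p_st <= 1.0:
            raise InvalidParameterError(f"p_st must be in [0,1], got {self.p_st}")
        for name in ("d", "kappa", "l_bz"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.n_m < 1:
            raise InvalidParameterError("n_m must be >= 1")


@dataclass
class Head:
    """One myosin head: end assignment, cycle state and spring anchor.

    ``rest_pos`` is the actin-frame coordinate at which the head's spring is
    relaxed; it is meaningful only while the head is attached (states 3-6).
    For trailing-end heads it is a *base* anchor: the effective rest
    position is ``rest_pos + delta`` when the actin between the two head
    zones has buckled by an end-shortening delta.
    """

    end: str
    state: HeadState = HeadState.DETACHED_ATP
    rest_pos: float | None = None

    def __post_init__(self) -> None:
        if self.end not in (LEADING, TRAILING):
            raise InvalidParameterError(f"end must be 'leading' or 'trailing', got {self.end!r}")
        self.state = HeadState(self.state)

    @property
    def attached(self) -> bool:
        return self.state in BOUND_STATES

    def effective_rest(self, delta: float = 0.0) -> float:
        if self.rest_pos is None:
            raise InvalidParameterError("rest_pos undefined for a detached head")
        return self.rest_pos + (delta if self.end == TRAILING else 0.0)


@dataclass(frozen=True)
class ActinMechanics:
    """Bending mechanics of the actin segment spanned by the bare zone.

    ``EI = lp * kT`` links the bending rigidity to the 15 um persistence
    length; the buckling threshold is the Euler force of a segment of the
    bare-zone length, and breakage occurs at the curvature 1/r_min.
    """

    lp_um: float = 15.0
    kT: float = DEFAULT_KT_THERMAL
    r_min_um: float = 0.18
    l_bz: float = 160.0

    def __post_init__(self) -> None:
        for name in ("lp_um", "kT", "r_min_um", "l_bz"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @property
    def EI(self) -> float:
        """Bending rigidity, pN nm^2."""
        return bending_rigidity(self.lp_um, self.kT)

    @property
    def F_c(self) -> float:
        """Euler buckling force of the bare-zone actin segment, pN."""
        return euler_buckling_force(self.EI, self.l_bz)

    @property
    def kappa_crit(self) -> float:
        """Breakage curvature, um^-1."""
        return critical_curvature(self.r_min_um)


@dataclass(frozen=True)
class MechState:
    """Mechanical state of the filament pair after equilibration."""

    X: float  # myofilament position, nm
    delta: float = 0.0  # actin end-shortening from buckling, nm (>= 0)
    tension: float = 0.0  # bare-zone force, pN
    curvature: float = 0.0  # um^-1

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise InvalidParameterError("delta must be >= 0")


def _attached(heads: Iterable[Head]) -> list[Head]:
    return [h for h in heads if h.attached]


def equilibrium_position(heads: Sequence[Head], delta: float = 0.0) -> float:
    """Position X at which the net spring force on the myofilament is zero.

    With equal stiffness this is the mean of the (effective) rest positions.
    Raises :class:`FreeFilamentError` when no head is attached.
    """
    att = _attached(heads)
    if not att:
        raise FreeFilamentError("no attached heads: equilibrium undefined")
    return float(np.mean([h.effective_rest(delta) for h in att]))


def apply_powerstroke(head: Head, params: MyofilamentParams, rng) -> bool:
    """Advance the head's anchor by the step size d on a powerstroke.

    Leading-end heads always step; trailing-end heads step with probability
    ``p_st`` (0 by default: the trailing end acts purely as a brake).
    Returns True if the anchor moved.
    """
    if not head.attached or head.rest_pos is None:
        raise InvalidParameterError("powerstroke on a detached head")
    if head.end == LEADING or rng.random() < params.p_st:
        head.rest_pos += params.d
        return True
    return False


def attach_head(head: Head, X: float, delta: float = 0.0) -> Head:
    """Attach the head with zero spring strain at the current position X.

    Trailing anchors are stored in the unbuckled frame, so the base rest
    position absorbs the current buckling offset.
    """
    head.rest_pos = X - (delta if head.end == TRAILING else 0.0)
    return head


def bare_zone_tension(
    heads: Sequence[Head], X: float, kappa: float = 1.0, delta: float = 0.0
) -> float:
    """Magnitude of the force transmitted through the bare zone, pN.

    Equal to |sum of trailing-end spring forces| which, at equilibrium,
    balances the leading-end sum (action-reaction).  Zero when either end
    has no attached head.
    """
    trailing = [h for h in _attached(heads) if h.end == TRAILING]
    leading = [h for h in _attached(heads) if h.end == LEADING]
    if not trailing or not leading:
        return 0.0
    return abs(sum(kappa * (h.effective_rest(delta) - X) for h in trailing))


def bending_rigidity(lp_um: float, kT: float = DEFAULT_KT_THERMAL) -> float:
    """EI = lp * kT, with lp in um and kT in pN nm; returns pN nm^2."""
    if lp_um <= 0 or kT <= 0:
        raise InvalidParameterError("lp and kT must be > 0")
    return lp_um * 1e3 * kT


def euler_buckling_force(EI: float, l: float) -> float:
    """First-mode Euler buckling force F = pi^2 EI / l^2 (pN for pN nm^2, nm)."""
    if EI <= 0 or l <= 0:
        raise InvalidParameterError("EI and l must be > 0")
    return math.pi**2 * EI / l**2


def critical_curvature(r_min_um: float) -> float:
    """Breakage curvature 1/r_min, um^-1."""
    if r_min_um <= 0:
        raise InvalidParameterError("r_min must be > 0")
    return 1.0 / r_min_um


def shortening_to_curvature(delta: float, l: float) -> float:
    """Maximum curvature of a first-mode buckle with end-shortening delta.

    For y = A sin(pi x / l) the arc-length excess is delta = (pi A)^2/(4 l)
    to leading order, so A = (2/pi) sqrt(l delta) and the midpoint curvature
    is kappa_max = A pi^2 / l^2 = (2 pi / l) sqrt(delta / l).

    Parameters in nm; returns um^-1.
    """
    if delta < 0 or delta >= l:
        raise InvalidParameterError(f"delta must be in [0, l), got {delta}")
    return (2.0 * math.pi / l) * math.sqrt(delta / l) * 1e3


def curvature_to_shortening(curvature: float, l: float) -> float:
    """Inverse of :func:`shortening_to_curvature` (curvature um^-1, l nm -> delta nm)."""
    if curvature < 0:
        raise InvalidParameterError("curvature must be >= 0")
    return l * (curvature * 1e-3 * l / (2.0 * math.pi)) ** 2


def equilibrate_buckling(
    heads: Sequence[Head],
    F_c: float,
    kappa: float = 1.0,
    l_bz: float = 160.0,
    tol: float = 1e-6,
) -> MechState:
    """Quasi-static buckling equilibration.

    Finds the end-shortening delta >= 0 of the bare-zone actin segment such
    that the bare-zone tension does not exceed the buckling force F_c.  If
    the straight-filament (delta = 0) tension is below F_c the filament
    stays straight; otherwise the buckled segment pushes back at exactly
    F_c, so delta is the root of tension(delta) = F_c.  Shifting trailing
    anchors forward by delta both advances the equilibrium position and
    relaxes the trailing springs, so tension decreases monotonically in
    delta and the root is unique.

    ``tol`` is the residual tolerance on the tension, pN.
    """
    att = _attached(heads)
    if not att:
        return MechState(X=0.0, delta=0.0, tension=0.0, curvature=0.0)
    n_l = sum(1 for h in att if h.end == LEADING)
    n_t = len(att) - n_l
    if n_l == 0 or n_t == 0:
        # nothing to push against: the buckle relaxes to a straight filament
        X = equilibrium_position(heads, delta=0.0)
        return MechState(X=X, delta=0.0, tension=0.0, curvature=0.0)

    def load_at(delta: float) -> float:
        # signed bare-zone load: positive when the trailing springs drag
        # behind (compression of the spanned actin segment)
        X = equilibrium_position(heads, delta)
        return sum(
            kappa * (X - h.effective_rest(delta)) for h in att if h.end == TRAILING
        )

    if load_at(0.0) <= F_c:
        X = equilibrium_position(heads, 0.0)
        return MechState(
            X=X, delta=0.0, tension=bare_zone_tension(heads, X, kappa), curvature=0.0
        )
    # the signed load decreases linearly in delta (slope -kappa*n_l*n_t/N),
    # so bracket the unique root and cap delta below the bare-zone length
    hi = 1.0
    while load_at(hi) > F_c and hi < 4 * l_bz:
        hi *= 2.0
    if load_at(hi) > F_c:
        delta = l_bz * (1.0 - 1e-9)
    else:
        delta = min(
            brentq(lambda x: load_at(x) - F_c, 0.0, hi, xtol=1e-12, rtol=1e-15),
            l_bz * (1.0 - 1e-9),
        )
    X = equilibrium_position(heads, delta)
    tension = bare_zone_tension(heads, X, kappa, delta)
    assert tension <= F_c + max(tol, 1e-6)
    return MechState(
        X=X, delta=delta, tension=tension, curvature=shortening_to_curvature(delta, l_bz)
    )
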