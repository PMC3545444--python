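"""Six-state chemical cycle of a myosin II head.

A head cycles unidirectionally through six states: detached with bound ATP
(1), detached with ADP and phosphate after hydrolysis (2), actin-bound
pre-powerstroke (3), actin-bound post-powerstroke with ADP (4), rigor (5),
and actin-bound with freshly bound ATP (6), after which it detaches back to
state 1.  Transition rates are first order and strain-independent; only the
ATP-binding rate k5 = kt * [ATP] depends on the nucleotide concentration, so
lowering ATP lengthens the rigor dwell and raises the duty ratio.

The module provides the printed default rates, the analytic steady-state
occupancy of the cycle, and exact (Gillespie) event sampling for an ensemble
of independent heads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HeadState",
    "BOUND_STATES",
    "RateSet",
    "Occupancy",
    "make_rates",
    "steady_state_occupancy",
    "occupancy_table",
    "sample_next_event",
]


class HeadState(IntEnum):
    """The six states of the crossbridge cycle, in cyclic order."""

    DETACHED_ATP = 1
    DETACHED_ADP_PI = 2
    BOUND_ADP_PI = 3  # pre-powerstroke
    BOUND_ADP = 4  # post-powerstroke
    RIGOR = 5
    BOUND_ATP = 6

    @property
    def bound(self) -> bool:
        return self.value >= 3

    def successor(self) -> "HeadState":
        return HeadState(1 if self.value == 6 else self.value + 1)


#: States in which the head is attached to actin.
BOUND_STATES = frozenset(
    {HeadState.BOUND_ADP_PI, HeadState.BOUND_ADP, HeadState.RIGOR, HeadState.BOUND_ATP}
)

# Default first-order rates (s^-1) and the second-order ATP-binding
# constant kt (uM^-1 s^-1) for skeletal-muscle myosin II.
DEFAULT_K1 = 100.0  # ATP hydrolysis
DEFAULT_K2 = 30.0  # actin binding
DEFAULT_K3 = 1.0e4  # powerstroke + Pi release
DEFAULT_K4 = 1.0e3  # ADP release
DEFAULT_K6 = 2.0e3  # detachment
DEFAULT_KT = 4.0  # ATP binding, per uM


class InvalidParameterError(ValueError):
    """A rate or concentration is outside its physical domain."""


@dataclass(frozen=True)
class RateSet:
    """The six exit rates of the head cycle at a given ATP concentration.

    ``k5`` is the ATP-binding rate ``kt * atp``; all rates are in s^-1,
    ``kt`` in uM^-1 s^-1 and ``atp`` in uM.
    """

    k1: float = DEFAULT_K1
    k2: float = DEFAULT_K2
    k3: float = DEFAULT_K3
    k4: float = DEFAULT_K4
    k5: float = DEFAULT_KT * 1.0
    k6: float = DEFAULT_K6
    kt: float = DEFAULT_KT
    atp: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "k6", "kt", "atp"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")

    def exit_rate(self, state: HeadState | int) -> float:
        """Rate of leaving ``state`` (the single outgoing transition)."""
        return self.as_array()[int(state) - 1]

    def as_array(self) -> np.ndarray:
        """Exit rates indexed 0..5 for states 1..6."""
        return np.array([self.k1, self.k2, self.k3, self.k4, self.k5, self.k6])

    def with_atp(self, atp: float) -> "RateSet":
        if atp <= 0:
            raise InvalidParameterError(f"atp must be > 0, got {atp!r}")
        return replace(self, atp=atp, k5=self.kt * atp)


@dataclass(frozen=True)
class Occupancy:
    """Steady-state fractions of the six cycle states."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (6,):
            raise InvalidParameterError("fractions must have length 6")
        if np.any(f < 0) or np.any(f > 1) or abs(f.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("fractions must lie in [0,1] and sum to 1")
        object.__setattr__(self, "fractions", f)

    @property
    def bound_fraction(self) -> float:
        """Duty ratio: total occupancy of the actin-bound states 3-6."""
        return float(self.fractions[2:6].sum())

    def __getitem__(self, state: HeadState | int) -> float:
        return float(self.fractions[int(state) - 1])


def make_rates(atp: float, **overrides: float) -> RateSet:
    """Build the rate set at ATP concentration ``atp`` (uM).

    ``k5`` is computed as ``kt * atp`` unless overridden explicitly.
    Any of ``k1..k6, kt`` may be overridden by keyword.
    """
    if not np.isfinite(atp) or atp <= 0:
        raise InvalidParameterError(f"atp must be finite and > 0, got {atp!r}")
    allowed = {"k1", "k2", "k3", "k4", "k5", "k6", "kt"}
    unknown = set(overrides) - allowed
    if unknown:
        raise InvalidParameterError(f"unknown rate override(s): {sorted(unknown)}")
    kt = overrides.get("kt", DEFAULT_KT)
    kw = dict(
        k1=overrides.get("k1", DEFAULT_K1),
        k2=overrides.get("k2", DEFAULT_K2),
        k3=overrides.get("k3", DEFAULT_K3),
        k4=overrides.get("k4", DEFAULT_K4),
        k5=overrides.get("k5", kt * atp),
        k6=overrides.get("k6", DEFAULT_K6),
        kt=kt,
        atp=atp,
    )
    return RateSet(**kw)


def steady_state_occupancy(rates: RateSet) -> Occupancy:
    """Analytic steady state of the unidirectional six-state cycle.

    In a single loop with no reverse transitions the stationary flux J is
    common to all edges, so the occupancy of state i is proportional to its
    dwell time 1/k_i: p_i = (1/k_i) / sum_j (1/k_j).
    """
    tau = 1.0 / rates.as_array()
    return Occupancy(tau / tau.sum())


def occupancy_table(occ: Occupancy) -> pd.DataFrame:
    """Occupancy as a two-column table (state, fraction) for TSV export."""
    return pd.DataFrame({"state": np.arange(1, 7), "fraction": occ.fractions})


def sample_next_event(
    heads: Sequence, rates: RateSet, rng: np.random.Generator
) -> tuple[int, HeadState, float]:
    """Draw the next transition for an ensemble of independent heads.

    Exact continuous-time Markov (Gillespie) sampling: the waiting time is
    exponential with the summed exit rate of all heads, the transitioning
    head is chosen with probability proportional to its own exit rate, and
    the new state is the unique cyclic successor.

    Parameters
    ----------
    heads
        Objects exposing a ``state`` attribute (``HeadState`` or int 1-6).
    rates
        The rate set in force.
    rng
        Seeded ``numpy.random.Generator``.

    Returns
    -------
    (index, new_state, waiting_time)
    """
    if len(heads) == 0:
        raise InvalidParameterError("need at least one head")
    k = rates.as_array()
    exit_rates = np.array([k[int(h.state) - 1] for h in heads])
    total = exit_rates.sum()
    wait = rng.exponential(1.0 / total)
    idx = int(rng.choice(len(heads), p=exit_rates / total))
    new_state = HeadState(int(heads[idx].state)).successor()
    return idx, new_state, wait
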