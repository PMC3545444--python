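"""Head-count estimate of a bipolar myosin filament from its geometry.

A myofilament of median length 560 nm with a 160 nm central bare zone has
two 200 nm head-bearing ends.  Myosin molecules assemble in crowns of four
head pairs per 14.5 nm of filament length, giving ~110 head pairs per
filament.  Of these, only the quarter oriented towards the actin filament
can reach it, and only one head of each pair is favourably oriented, so the
number of actin-interacting heads is ~pairs/4, rounded to one significant
figure: 30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .kinetics import InvalidParameterError

__all__ = ["MyofilamentGeometry", "head_pair_count", "interacting_head_count"]


@dataclass(frozen=True)
class MyofilamentGeometry:
    """Lengths in nm; ``pairs_per_crown`` heads pairs per 14.5 nm crown."""

    total_length: float = 560.0
    bare_zone: float = 160.0
    crown_spacing: float = 14.5
    pairs_per_crown: int = 4

    def __post_init__(self) -> None:
        for name in ("total_length", "bare_zone", "crown_spacing", "pairs_per_crown"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.bare_zone >= self.total_length:
            raise InvalidParameterError("bare_zone must be shorter than total_length")

    @property
    def head_pairs_exact(self) -> float:
        """Un-rounded head-pair count: both ends, crowns of pairs_per_crown."""
        end_length = (self.total_length - self.bare_zone) / 2.0
        return 2.0 * (end_length / self.crown_spacing) * self.pairs_per_crown


def head_pair_count(geom: MyofilamentGeometry) -> int:
    """Average number of myosin head pairs per filament (nearest integer)."""
    return round(geom.head_pairs_exact)


def _round_1sf(x: float) -> int:
    if x == 0:
        return 0
    mag = 10 ** math.floor(math.log10(abs(x)))
    return int(round(x / mag) * mag)


def interacting_head_count(pairs: float, exact: bool = False) -> float:
    """Number of heads that can interact with the actin filament.

    One quarter of the pairs faces the actin filament and one head per pair
    is favourably oriented, so the estimate is ``pairs / 4`` — reported to
    one significant figure (110 pairs -> 27.5 -> 30) unless ``exact``.
    """
    if pairs < 0:
        raise InvalidParameterError("pairs must be >= 0")
    raw = pairs / 4.0
    return raw if exact else _round_1sf(raw)
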