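"""Core domain records for measured and ROV-observed sea pen colonies.

A *Pennatula rubra* colony has a basal peduncle buried in the sediment and a
polyp-bearing rachis above it; only the rachis (and its polyp leaves) is
visible to imaging. A physically measured colony therefore carries both
lengths and weights, while a colony seen on ROV video carries only a count of
polyp leaves on the side facing the camera.

Units are fixed: lengths in millimetres, weights in grams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError


@dataclass(frozen=True)
class ColonyRecord:
    """One physically measured colony.

    Attributes
    ----------
    colony_id : str
        Opaque label; never interpreted, duplicates are legal.
    leaves_left, leaves_right : int
        Polyp-leaf counts of the two sides; sides may differ after
        mechanical damage or predation.
    total_length : float
        Peduncle plus rachis, mm.
    peduncle_length : float
        Basal stalk, mm; strictly less than ``total_length`` so the rachis
        length (their difference) is positive.
    fresh_weight : float
        Wet biomass, g.
    dry_weight : float or None
        Oven-dried biomass, g; measured only for a subset of colonies and
        always below the fresh weight.
    """

    colony_id: str
    leaves_left: int
    leaves_right: int
    total_length: float
    peduncle_length: float
    fresh_weight: float
    dry_weight: Optional[float] = None

    def __post_init__(self) -> None:
        if not (isinstance(self.leaves_left, int) and self.leaves_left >= 0):
            raise ValidationError(
                f"colony {self.colony_id!r}: leaves_left must be a non-negative "
                f"integer, got {self.leaves_left!r}"
            )
        if not (isinstance(self.leaves_right, int) and self.leaves_right >= 0):
            raise ValidationError(
                f"colony {self.colony_id!r}: leaves_right must be a non-negative "
                f"integer, got {self.leaves_right!r}"
            )
        if not self.total_length > 0:
            raise ValidationError(
                f"colony {self.colony_id!r}: total_length must be > 0 mm"
            )
        if not self.peduncle_length >= 0:
            raise ValidationError(
                f"colony {self.colony_id!r}: peduncle_length must be >= 0 mm"
            )
        if not self.peduncle_length < self.total_length:
            raise ValidationError(
                f"colony {self.colony_id!r}: peduncle_length must be smaller than "
                "total_length (the rachis length, total minus peduncle, must be "
                "positive)"
            )
        if not self.fresh_weight > 0:
            raise ValidationError(
                f"colony {self.colony_id!r}: fresh_weight must be > 0 g"
            )
        if self.dry_weight is not None:
            if not self.dry_weight > 0:
                raise ValidationError(
                    f"colony {self.colony_id!r}: dry_weight must be > 0 g"
                )
            if not self.dry_weight < self.fresh_weight:
                raise ValidationError(
                    f"colony {self.colony_id!r}: dry_weight must be below "
                    "fresh_weight"
                )


@dataclass(frozen=True)
class RovObservation:
    """One colony seen on ROV video: a single visible-side polyp-leaf count."""

    colony_id: str
    leaf_count: int

    def __post_init__(self) -> None:
        if not (isinstance(self.leaf_count, int) and self.leaf_count >= 0):
            raise ValidationError(
                f"observation {self.colony_id!r}: leaf_count must be a "
                f"non-negative integer, got {self.leaf_count!r}"
            )
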