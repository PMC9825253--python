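"""Genetic marker maps anchoring a target locus on a chromosome.

A :class:`MarkerMap` holds an ordered list of markers with genetic (cM)
and optionally physical (bp) positions, plus the genetic position of
the target SI locus. It is shared between the population simulator and
the fine-mapping pipeline. The Haldane map function converts genetic
distance to a recombination fraction under no crossover interference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

__all__ = ["Marker", "MarkerMap", "haldane"]


def haldane(d_cm: float) -> float:
    """Recombination fraction for a distance of `d_cm` centimorgan.

    c = (1 - exp(-2 d / 100)) / 2, the no-interference (Haldane) map
    function; saturates at 0.5 for unlinked positions.
    """
    if d_cm < 0:
        raise ValueError("genetic distance must be non-negative")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


@dataclass(frozen=True)
class Marker:
    """A mapped marker.

    `bp` is the delimiting physical coordinate used when projecting
    recombinants onto a contig; when the amplicon extent is known,
    `bp_start`/`bp_end` allow start/mid/end endpoint conventions.
    """

    name: str
    cm: float
    contig: Optional[str] = None
    bp: Optional[int] = None
    bp_start: Optional[int] = None
    bp_end: Optional[int] = None

    def position(self, convention: str = "mid") -> int:
        """Physical coordinate under the given endpoint convention."""
        if convention not in ("start", "mid", "end"):
            raise ValueError(f"unknown endpoint convention {convention!r}")
        if self.bp_start is not None and self.bp_end is not None:
            if convention == "start":
                return self.bp_start
            if convention == "end":
                return self.bp_end
            return (self.bp_start + self.bp_end) // 2
        if self.bp is None:
            raise ValueError(f"marker {self.name!r} has no physical position")
        return self.bp


@dataclass(frozen=True)
class MarkerMap:
    """Ordered markers on one chromosome plus the target locus position."""

    markers: Tuple[Marker, ...]
    locus_cm: float
    locus_name: str = "Z"
    contig: Optional[str] = None
    contig_length: Optional[int] = None
    locus_bp: Optional[int] = None  # ground-truth physical position, if known

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        if len(self.markers) == 0:
            raise ValueError("marker map must contain at least one marker")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        cms = [m.cm for m in self.markers]
        if any(b <= a for a, b in zip(cms, cms[1:])):
            raise ValueError("marker cM positions must be strictly increasing")
        bps = [m.bp for m in self.markers if m.bp is not None]
        if len(bps) > 1 and any(b <= a for a, b in zip(bps, bps[1:])):
            raise ValueError("marker bp positions must be strictly increasing "
                             "and consistent with cM order")

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    @property
    def cm_positions(self) -> Tuple[float, ...]:
        return tuple(m.cm for m in self.markers)

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"no marker named {name!r}")

    def has_physical_positions(self) -> bool:
        return all(m.bp is not None or
                   (m.bp_start is not None and m.bp_end is not None)
                   for m in self.markers)

    def positions_with_locus(self) -> Tuple[Tuple[str, float], ...]:
        """Markers plus the locus, merged and sorted by cM position.

        The locus entry is named `locus_name`; a marker exactly at the
        locus position is not allowed (cM ties are ambiguous).
        """
        if any(m.cm == self.locus_cm for m in self.markers):
            raise ValueError("a marker coincides exactly with the locus cM "
                             "position; offset it by a small epsilon")
        entries = [(m.name, m.cm) for m in self.markers]
        entries.append((self.locus_name, self.locus_cm))
        return tuple(sorted(entries, key=lambda e: e[1]))
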