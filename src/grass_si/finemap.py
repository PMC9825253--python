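"""Recombinant screening and co-segregating interval delimitation.

In the fine-mapping designs, every cross-derived offspring is expected
to be heterozygous (HET) at markers fully linked to the target locus.
A homozygous (HOM) call therefore signals either a crossover between
that marker and the locus, or — when the whole marker panel is HOM — a
rare self-pollination event. This module classifies offspring call
patterns, tallies recombinants per marker, and projects the zero-
recombinant marker block onto physical coordinates to delimit the
co-segregating interval.

Classification is deliberately conservative: only a single contiguous
HOM block touching one end of the marker panel is accepted as a
recombinant (one crossover). Internal HOM islands and multi-transition
patterns are AMBIGUOUS — at the marker densities used here a genotyping
error is far more likely than a double crossover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from .markers import MarkerMap
from .synthetic_data import CALL_HET, CALL_HOM, CALL_MISSING

__all__ = [
    "OffspringRecord",
    "OffspringClassification",
    "RecombinationSummary",
    "CosegregatingInterval",
    "LocusNotLocalizedError",
    "classify_offspring",
    "classify_population",
    "count_recombinants",
    "delimit_interval",
]

NON_RECOMBINANT = "NON_RECOMBINANT"
RECOMBINANT = "RECOMBINANT"
SELFED_CANDIDATE = "SELFED_CANDIDATE"
AMBIGUOUS = "AMBIGUOUS"

_VALID_CALLS = (CALL_HET, CALL_HOM, CALL_MISSING)


@dataclass(frozen=True)
class OffspringRecord:
    """Per-marker zygosity calls for one offspring."""

    id: str
    calls: Mapping[str, str]  # marker name -> HET | HOM | NA


@dataclass(frozen=True)
class OffspringClassification:
    """Verdict for one offspring.

    For a RECOMBINANT, `breakpoint_interval` names the innermost HOM
    marker and its nearest informative HET neighbour (missing calls in
    between widen the interval rather than being guessed), and `side`
    records whether the HOM block sits at the low- or high-cM end.
    """

    category: str
    breakpoint_interval: Optional[Tuple[str, str]] = None
    side: Optional[str] = None  # 'left' | 'right'


class LocusNotLocalizedError(ValueError):
    """No zero-recombinant marker exists: the locus cannot be delimited."""


def classify_offspring(record: OffspringRecord, mmap: MarkerMap) -> OffspringClassification:
    """Classify one offspring's HET/HOM pattern along the marker map.

    All informative (non-missing) calls HET -> NON_RECOMBINANT; all HOM
    -> SELFED_CANDIDATE; exactly one contiguous HOM block touching one
    end of the panel and lying entirely on one side of the locus ->
    RECOMBINANT with the breakpoint between the innermost HOM marker
    and its HET neighbour; anything else (or fewer than two informative
    calls) -> AMBIGUOUS. A terminal HOM block spanning the locus cannot
    arise from a single crossover (the offspring would be homozygous at
    the locus itself), so it is AMBIGUOUS — typically a selfed plant
    with one miscalled marker.
    """
    missing_markers = [m for m in mmap.names if m not in record.calls]
    if missing_markers:
        raise ValueError(f"offspring {record.id!r} lacks calls for markers "
                         f"{missing_markers}")
    informative: List[Tuple[str, str]] = []
    for name in mmap.names:
        call = record.calls[name]
        if call not in _VALID_CALLS:
            raise ValueError(f"invalid call {call!r} for offspring "
                             f"{record.id!r} at marker {name!r}")
        if call != CALL_MISSING:
            informative.append((name, call))
    if len(informative) < 2:
        return OffspringClassification(AMBIGUOUS)

    hom = [call == CALL_HOM for _, call in informative]
    if not any(hom):
        return OffspringClassification(NON_RECOMBINANT)
    if all(hom):
        return OffspringClassification(SELFED_CANDIDATE)

    transitions = sum(a != b for a, b in zip(hom, hom[1:]))
    if transitions != 1:
        return OffspringClassification(AMBIGUOUS)
    # the HOM block must sit entirely on one side of the locus
    cm = {m.name: m.cm for m in mmap.markers}
    block_cms = [cm[name] for (name, _), h in zip(informative, hom) if h]
    if min(block_cms) < mmap.locus_cm < max(block_cms):
        return OffspringClassification(AMBIGUOUS)
    # exactly one transition: the HOM block is terminal on one side
    if hom[0]:
        innermost = max(i for i, h in enumerate(hom) if h)
        pair = (informative[innermost][0], informative[innermost + 1][0])
        side = "left"
    else:
        innermost = min(i for i, h in enumerate(hom) if h)
        pair = (informative[innermost - 1][0], informative[innermost][0])
        side = "right"
    return OffspringClassification(RECOMBINANT, breakpoint_interval=pair, side=side)


def _iter_records(records, mmap: MarkerMap) -> Iterable[OffspringRecord]:
    if isinstance(records, pd.DataFrame):
        for off_id, row in records.iterrows():
            yield OffspringRecord(id=str(off_id), calls=row.to_dict())
    else:
        yield from records


def classify_population(records, mmap: MarkerMap) -> pd.DataFrame:
    """Classify every offspring; accepts a calls DataFrame
    (offspring x markers) or an iterable of :class:`OffspringRecord`."""
    rows = []
    for rec in _iter_records(records, mmap):
        c = classify_offspring(rec, mmap)
        rows.append({"offspring_id": rec.id, "category": c.category,
                     "breakpoint_left": c.breakpoint_interval[0] if c.breakpoint_interval else "",
                     "breakpoint_right": c.breakpoint_interval[1] if c.breakpoint_interval else "",
                     "side": c.side or ""})
    return pd.DataFrame(rows).set_index("offspring_id")


@dataclass
class RecombinationSummary:
    """Per-marker recombinant counts plus selfing/ambiguity tallies."""

    counts: Dict[str, int]
    n_non_recombinant: int = 0
    n_selfed_candidates: int = 0
    n_ambiguous: int = 0
    n_recombinant: int = 0
    cosegregating_interval: Optional["CosegregatingInterval"] = None


def count_recombinants(records, mmap: MarkerMap) -> RecombinationSummary:
    """Tally, per marker, the recombinants separating it from the locus.

    A marker's count is the number of RECOMBINANT offspring whose
    breakpoint lies between that marker and the locus — i.e. every
    marker on the HOM-block side of the breakpoint, outward from it.
    SELFED_CANDIDATE and AMBIGUOUS offspring are tallied separately and
    never contribute to marker counts.
    """
    counts = {name: 0 for name in mmap.names}
    summary = RecombinationSummary(counts=counts)
    any_records = False
    cm = {m.name: m.cm for m in mmap.markers}
    for rec in _iter_records(records, mmap):
        any_records = True
        c = classify_offspring(rec, mmap)
        if c.category == NON_RECOMBINANT:
            summary.n_non_recombinant += 1
        elif c.category == SELFED_CANDIDATE:
            summary.n_selfed_candidates += 1
        elif c.category == AMBIGUOUS:
            summary.n_ambiguous += 1
        else:
            summary.n_recombinant += 1
            inner_hom = c.breakpoint_interval[0] if c.side == "left" else c.breakpoint_interval[1]
            boundary = cm[inner_hom]
            for name in mmap.names:
                if c.side == "left" and cm[name] <= boundary:
                    counts[name] += 1
                elif c.side == "right" and cm[name] >= boundary:
                    counts[name] += 1
    if not any_records:
        raise ValueError("no offspring records supplied")
    return summary


@dataclass(frozen=True)
class CosegregatingInterval:
    """A physical interval co-segregating with the locus.

    Half-open, left-exclusive: (start, end]; `length = end - start`.
    An `unresolved_*` flag means no recombinant-bearing marker bounds
    that side and the interval runs to the contig boundary.
    """

    contig: Optional[str]
    start: int
    end: int
    left_marker: Optional[str]
    right_marker: Optional[str]
    unresolved_left: bool = False
    unresolved_right: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, bp: int) -> bool:
        return self.start < bp <= self.end


def delimit_interval(summary: RecombinationSummary, mmap: MarkerMap,
                     convention: str = "mid") -> CosegregatingInterval:
    """Project recombinant counts onto physical coordinates.

    The zero-count marker block nearest the locus defines the
    co-segregating region; the interval runs from the innermost
    recombinant-bearing marker on its left to the innermost one on its
    right (half-open, left-exclusive). `convention` selects which
    amplicon coordinate delimits (start/mid/end) when marker extents
    are known. A side without any recombinant-bearing marker is
    open-ended to the contig boundary and flagged unresolved.
    """
    if len(mmap.markers) < 2:
        raise ValueError("interval delimitation needs at least two mapped markers")
    if not mmap.has_physical_positions():
        raise ValueError("all markers need physical (bp) positions to "
                         "delimit an interval")
    zero = [summary.counts.get(m.name, 0) == 0 for m in mmap.markers]
    if not any(zero):
        raise LocusNotLocalizedError(
            "locus not localized: every marker carries recombinants")

    # contiguous zero-count runs; pick the one containing (or nearest to)
    # the locus genetic position
    runs: List[Tuple[int, int]] = []
    i = 0
    while i < len(zero):
        if zero[i]:
            j = i
            while j + 1 < len(zero) and zero[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    def run_distance(run: Tuple[int, int]) -> float:
        lo, hi = mmap.markers[run[0]].cm, mmap.markers[run[1]].cm
        if lo <= mmap.locus_cm <= hi:
            return 0.0
        return min(abs(mmap.locus_cm - lo), abs(mmap.locus_cm - hi))

    first, last = min(runs, key=run_distance)

    unresolved_left = first == 0
    unresolved_right = last == len(mmap.markers) - 1
    left_marker = None if unresolved_left else mmap.markers[first - 1]
    right_marker = None if unresolved_right else mmap.markers[last + 1]

    contig = mmap.contig or (mmap.markers[0].contig if mmap.markers[0].contig else None)
    if unresolved_left:
        start = 0
    else:
        start = left_marker.position(convention)
    if unresolved_right:
        if mmap.contig_length is not None:
            end = mmap.contig_length
        else:
            end = mmap.markers[-1].position(convention)
    else:
        end = right_marker.position(convention)

    return CosegregatingInterval(
        contig=contig, start=start, end=end,
        left_marker=left_marker.name if left_marker else None,
        right_marker=right_marker.name if right_marker else None,
        unresolved_left=unresolved_left, unresolved_right=unresolved_right,
    )
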