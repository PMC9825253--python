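"""Microsynteny comparison of two locus annotations.

Compares the ordered, stranded gene lists of two S- or Z-locus
annotations: which genes pair up (by curated name, with ``-1``/``-2``
duplication suffixes, or by best-reciprocal sequence identity), which
matched pairs changed orientation after normalising for a global flip,
which fall off the conserved order backbone (longest common
subsequence), which are duplicated, and which are absent from one
side. Annotations can be exported to a simple tab-separated CMAP text
(one row per gene boundary) consumed by SimpleSynteny-class plotters
and re-read losslessly by this module's own reader.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import diversity

__all__ = [
    "AnnotatedGene",
    "LocusAnnotation",
    "MatchSet",
    "SyntenyReport",
    "match_genes",
    "compare_loci",
    "export_cmap",
    "read_cmap",
]

_SUFFIX_RE = re.compile(r"-(\d+)$")


def base_name(name: str) -> str:
    """Gene name with a trailing duplication suffix ('-1', '-2') removed."""
    return _SUFFIX_RE.sub("", name)


@dataclass(frozen=True)
class AnnotatedGene:
    """One gene of a locus annotation (1-based inclusive coordinates)."""

    name: str
    start: int
    end: int
    strand: str
    functional: Optional[str] = None
    seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.name!r}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class LocusAnnotation:
    """An ordered, stranded gene list for one locus of one genotype."""

    locus_id: str            # 'S' or 'Z' (free-form accepted)
    label: str               # genotype / species label
    genes: Tuple[AnnotatedGene, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        starts = [g.start for g in genes]
        if starts != sorted(starts):
            raise ValueError("genes must be sorted by start coordinate")
        names = [g.name for g in genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names within an annotation must be unique")

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(g.name for g in self.genes)


@dataclass
class MatchSet:
    """Gene pairing between two annotations.

    `pairs` holds the 1:1 assignment used for order comparison;
    `duplications` the extra one-to-many partners (side, gene name,
    partner base name); `unmatched_a`/`unmatched_b` the leftovers.
    """

    pairs: List[Tuple[str, str]]
    duplications: List[Tuple[str, str, str]] = field(default_factory=list)
    unmatched_a: List[str] = field(default_factory=list)
    unmatched_b: List[str] = field(default_factory=list)


def match_genes(a: LocusAnnotation, b: LocusAnnotation,
                mode: str = "by_name",
                identity_threshold: float = 70.0) -> MatchSet:
    """Pair genes of two annotations.

    ``by_name`` pairs genes sharing a base name (duplication suffixes
    stripped); within a shared base name, copies are paired in position
    order and surplus copies are flagged as duplications. ``by_identity``
    pairs by best-reciprocal pairwise percent identity at or above
    `identity_threshold` (sequences required). The default thresholds
    (70% genes, 35% suggested for the fast-evolving female determinants)
    mirror the homology stringencies used for curated locus comparisons
    but are not equivalent to BLAST E-value cut-offs.
    """
    if not a.genes or not b.genes:
        raise ValueError("both annotations must contain at least one gene")
    if mode == "by_name":
        return _match_by_name(a, b)
    if mode == "by_identity":
        return _match_by_identity(a, b, identity_threshold)
    raise ValueError(f"unknown matching mode {mode!r}")


def _match_by_name(a: LocusAnnotation, b: LocusAnnotation) -> MatchSet:
    groups_a: Dict[str, List[str]] = {}
    groups_b: Dict[str, List[str]] = {}
    for g in a.genes:
        groups_a.setdefault(base_name(g.name), []).append(g.name)
    for g in b.genes:
        groups_b.setdefault(base_name(g.name), []).append(g.name)

    ms = MatchSet(pairs=[])
    for base in {**groups_a, **groups_b}:
        in_a = groups_a.get(base, [])
        in_b = groups_b.get(base, [])
        k = min(len(in_a), len(in_b))
        for i in range(k):
            ms.pairs.append((in_a[i], in_b[i]))
        # surplus copies beyond the 1:1 assignment: duplications when the
        # base name exists on both sides, absences otherwise
        for extra in in_a[k:]:
            if k:
                ms.duplications.append(("a", extra, base))
            else:
                ms.unmatched_a.append(extra)
        for extra in in_b[k:]:
            if k:
                ms.duplications.append(("b", extra, base))
            else:
                ms.unmatched_b.append(extra)
    # keep deterministic order: sort pairs by position in a
    order_a = {name: i for i, name in enumerate(a.names)}
    ms.pairs.sort(key=lambda p: order_a[p[0]])
    ms.unmatched_a.sort(key=lambda n: order_a[n])
    order_b = {name: i for i, name in enumerate(b.names)}
    ms.unmatched_b.sort(key=lambda n: order_b[n])
    return ms


def _match_by_identity(a: LocusAnnotation, b: LocusAnnotation,
                       threshold: float) -> MatchSet:
    for ann in (a, b):
        missing = [g.name for g in ann.genes if not g.seq]
        if missing:
            raise ValueError(f"by_identity matching requires sequences; "
                             f"missing for {missing} in {ann.label!r}")
    pid: Dict[Tuple[str, str], float] = {}
    for ga in a.genes:
        for gb in b.genes:
            aln = diversity.align_pair(ga.seq, gb.seq)
            pid[(ga.name, gb.name)] = diversity.percent_identity(aln)
    best_a = {ga.name: max(b.names, key=lambda n: pid[(ga.name, n)]) for ga in a.genes}
    best_b = {gb.name: max(a.names, key=lambda n: pid[(n, gb.name)]) for gb in b.genes}
    ms = MatchSet(pairs=[])
    matched_b = set()
    for ga in a.genes:
        partner = best_a[ga.name]
        if best_b[partner] == ga.name and pid[(ga.name, partner)] >= threshold:
            ms.pairs.append((ga.name, partner))
            matched_b.add(partner)
        else:
            ms.unmatched_a.append(ga.name)
    ms.unmatched_b = [n for n in b.names if n not in matched_b]
    return ms


@dataclass
class SyntenyReport:
    """Outcome of a pairwise locus comparison.

    Every gene lands in exactly one category per side (precedence:
    duplication > absence > order break > inversion > conserved).
    `orientation_flipped` records whether the second annotation was
    globally reversed to maximise strand agreement before residual
    flips were counted as inversions.
    """

    label_a: str
    label_b: str
    conserved: List[Tuple[str, str]] = field(default_factory=list)
    inversions: List[Tuple[str, str]] = field(default_factory=list)
    order_breaks: List[Tuple[str, str]] = field(default_factory=list)
    duplications: List[Tuple[str, str, str]] = field(default_factory=list)
    absent_in_b: List[str] = field(default_factory=list)
    absent_in_a: List[str] = field(default_factory=list)
    orientation_flipped: bool = False

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a, "label_b": self.label_b,
            "conserved": self.conserved, "inversions": self.inversions,
            "order_breaks": self.order_breaks, "duplications": self.duplications,
            "absent_in_b": self.absent_in_b, "absent_in_a": self.absent_in_a,
            "orientation_flipped": self.orientation_flipped,
        }


def _longest_increasing_subsequence(seq: Sequence[int]) -> List[int]:
    """Indices of one longest strictly increasing subsequence (stable)."""
    if not seq:
        return []
    tails: List[int] = []      # index into seq of smallest tail per length
    prev = [-1] * len(seq)
    for i, v in enumerate(seq):
        lo, hi = 0, len(tails)
        while lo < hi:
            mid = (lo + hi) // 2
            if seq[tails[mid]] < v:
                lo = mid + 1
            else:
                hi = mid
        if lo > 0:
            prev[i] = tails[lo - 1]
        if lo == len(tails):
            tails.append(i)
        else:
            tails[lo] = i
    out = []
    i = tails[-1]
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


def compare_loci(a: LocusAnnotation, b: LocusAnnotation,
                 matches: Optional[MatchSet] = None,
                 mode: str = "by_name",
                 identity_threshold: float = 70.0) -> SyntenyReport:
    """Build a synteny report from a gene pairing.

    Orientation is normalised first: if most matched pairs disagree in
    strand, the second annotation is treated as globally flipped
    (reversed order, reversed strands) so a wholesale inversion of the
    locus is not reported gene by gene. Residual strand disagreements
    are inversions. The longest common subsequence of the matched gene
    orders forms the conserved backbone; matched genes off the backbone
    are order breaks.
    """
    if matches is None:
        matches = match_genes(a, b, mode=mode, identity_threshold=identity_threshold)
    report = SyntenyReport(label_a=a.label, label_b=b.label,
                           duplications=list(matches.duplications),
                           absent_in_b=list(matches.unmatched_a),
                           absent_in_a=list(matches.unmatched_b))
    if not matches.pairs:
        return report

    strand_a = {g.name: g.strand for g in a.genes}
    strand_b = {g.name: g.strand for g in b.genes}
    disagreements = sum(strand_a[x] != strand_b[y] for x, y in matches.pairs)
    flipped = disagreements * 2 > len(matches.pairs)
    report.orientation_flipped = flipped

    def b_strand(name: str) -> str:
        s = strand_b[name]
        return s if not flipped else ("+" if s == "-" else "-")

    order_b = {name: i for i, name in enumerate(b.names)}
    if flipped:
        nb = len(b.names)
        order_b = {name: nb - 1 - i for name, i in order_b.items()}

    order_a = {name: i for i, name in enumerate(a.names)}
    pairs = sorted(matches.pairs, key=lambda p: order_a[p[0]])
    ranks = [order_b[y] for _, y in pairs]
    backbone = set(_longest_increasing_subsequence(ranks))

    for idx, (x, y) in enumerate(pairs):
        if idx not in backbone:
            report.order_breaks.append((x, y))
        elif strand_a[x] != b_strand(y):
            report.inversions.append((x, y))
        else:
            report.conserved.append((x, y))
    return report


# --------------------------------------------------------------------------
# CMAP text export / import
# --------------------------------------------------------------------------

_CMAP_HEADER = "#map_label\tlocus_id\tfeature\tboundary\tposition\tstrand\tfunctional"


def export_cmap(annotations: Sequence[LocusAnnotation]) -> str:
    """Serialise annotations as tab-separated CMAP-style text.

    One row per gene boundary (start and end), ordered by position
    within each map; round-trips exactly through :func:`read_cmap`.
    """
    lines = [_CMAP_HEADER]
    for ann in annotations:
        rows = []
        for g in ann.genes:
            rows.append((g.start, "start", g))
            rows.append((g.end, "end", g))
        rows.sort(key=lambda r: (r[0], r[2].name, r[1] == "end"))
        for pos, boundary, g in rows:
            lines.append("\t".join([ann.label, ann.locus_id, g.name, boundary,
                                    str(pos), g.strand, g.functional or "NA"]))
    return "\n".join(lines) + "\n"


def read_cmap(text: str) -> List[LocusAnnotation]:
    """Parse CMAP text written by :func:`export_cmap`."""
    partial: Dict[Tuple[str, str], Dict[str, dict]] = {}
    order: List[Tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise ValueError(f"CMAP line {lineno}: expected 7 tab-separated "
                             f"fields, got {len(fields)}")
        label, locus_id, feature, boundary, pos, strand, functional = fields
        if boundary not in ("start", "end"):
            raise ValueError(f"CMAP line {lineno}: boundary must be "
                             f"'start' or 'end', got {boundary!r}")
        try:
            position = int(pos)
        except ValueError:
            raise ValueError(f"CMAP line {lineno}: position {pos!r} is not "
                             "an integer") from None
        key = (label, locus_id)
        if key not in partial:
            partial[key] = {}
            order.append(key)
        entry = partial[key].setdefault(feature, {"strand": strand,
                                                  "functional": functional})
        entry[boundary] = position
    annotations = []
    for label, locus_id in order:
        genes = []
        for feature, entry in partial[(label, locus_id)].items():
            if "start" not in entry or "end" not in entry:
                raise ValueError(f"gene {feature!r} in map {label!r} lacks a "
                                 "start or end boundary row")
            functional = entry["functional"]
            genes.append(AnnotatedGene(
                name=feature, start=entry["start"], end=entry["end"],
                strand=entry["strand"],
                functional=None if functional == "NA" else functional))
        genes.sort(key=lambda g: g.start)
        annotations.append(LocusAnnotation(locus_id=locus_id, label=label,
                                           genes=tuple(genes)))
    return annotations
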