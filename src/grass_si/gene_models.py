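"""Gene-structure analysis and the SI-candidate functionality classifier.

The putative grass SI determinants fall into two structural classes:

* male candidates (``SDUF247-I/II``, ``ZDUF247-I/II``): an intronless
  open reading frame encoding a 508-559 amino-acid protein of the
  DUF247 family (pfam03140) with a predicted transmembrane segment in
  the expected layout;
* female candidates (``sS``, ``sZ``): a one-intron ORF encoding an
  82-122 amino-acid secreted protein with a signal peptide.

A candidate is called FUNCTIONAL only when every structural and
protein-feature criterion for its class is met; any violated criterion
makes it NON_FUNCTIONAL (with the failed rules listed), and a missing
feature annotation yields UNKNOWN in strict mode. The six-gene
phenotype rule then predicts self-compatibility whenever any of the six
determinants is non-functional or absent; a complete functional set
only makes self-incompatibility *possible*, never guaranteed, because
self-compatibility can also arise downstream of the recognition step.

Domain and topology calls (DUF247 membership, transmembrane segment,
signal peptide) are consumed as input flags from an external predictor;
a rough Kyte-Doolittle hydropathy heuristic is available to fill in a
missing transmembrane flag and is clearly labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Data import CodonTable

__all__ = [
    "ProteinFeatures",
    "GeneRecord",
    "FunctionalityCall",
    "Orf",
    "find_orfs",
    "translate_cds",
    "classify_si_duf247",
    "classify_s_female",
    "predict_phenotype",
    "infer_transmembrane_kd",
    "SIX_GENES",
    "GENE_CLASSES",
    "STATUS_VALUES",
]

GENE_CLASSES = ("SI_DUF247", "S_FEMALE", "OTHER")
STATUS_VALUES = ("FUNCTIONAL", "NON_FUNCTIONAL", "ABSENT")

#: The six putative SI determinants, in physical order at S then Z.
SIX_GENES = ("SDUF247-I", "sS", "SDUF247-II", "ZDUF247-I", "sZ", "ZDUF247-II")

_FLAG_VALUES = ("yes", "no", "unknown")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP: Dict[str, str] = dict(_STANDARD_TABLE.forward_table)
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str, to_stop: bool = True) -> str:
    """Translate a coding sequence with the standard genetic code.

    Codons containing characters outside A/C/G/T translate to ``X`` and
    never terminate translation. Trailing partial codons are ignored.
    """
    protein: List[str] = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if codon in _STOP_CODONS:
            if to_stop:
                break
            protein.append("*")
        else:
            protein.append(_CODON_MAP.get(codon, "X"))
    return "".join(protein)


@dataclass(frozen=True)
class ProteinFeatures:
    """Externally predicted protein features, each yes/no/unknown.

    `layout_ok` records whether the predicted topology matches the
    expected arrangement for the gene class under the configured
    terminus convention (the published wording of the topology is
    ambiguous, so only the flag is interpreted, never re-derived).
    """

    has_duf247: str = "unknown"
    has_transmembrane: str = "unknown"
    has_signal_peptide: str = "unknown"
    layout_ok: str = "unknown"

    def __post_init__(self) -> None:
        for name in ("has_duf247", "has_transmembrane",
                     "has_signal_peptide", "layout_ok"):
            if getattr(self, name) not in _FLAG_VALUES:
                raise ValueError(f"{name} must be one of {_FLAG_VALUES}")


@dataclass(frozen=True)
class GeneRecord:
    """A gene model: genomic sequence plus exon structure and features.

    Exon coordinates are 0-based half-open on `seq` internally; the
    GFF3 writers/readers convert to 1-based inclusive externally.
    """

    id: str
    gene_class: str
    seq: str
    exons: Tuple[Tuple[int, int], ...]
    strand: str = "+"
    features: ProteinFeatures = field(default_factory=ProteinFeatures)

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"gene_class must be one of {GENE_CLASSES}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        last_end = -1
        for start, end in exons:
            if not (0 <= start < end <= len(self.seq)):
                raise ValueError(f"exon ({start}, {end}) outside sequence of "
                                 f"length {len(self.seq)}")
            if start < last_end:
                raise ValueError("exons must be sorted and non-overlapping")
            last_end = end

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def spliced_cds(self) -> str:
        """Exonic sequence in transcription order (reverse-complemented
        for minus-strand genes)."""
        cds = "".join(self.seq[s:e] for s, e in self.exons)
        return _revcomp(cds) if self.strand == "-" else cds

    def protein(self) -> str:
        """Translation of the spliced CDS up to the first stop codon."""
        return translate_cds(self.spliced_cds(), to_stop=True)

    def protein_length(self) -> int:
        return len(self.protein())


@dataclass(frozen=True)
class Orf:
    """An open reading frame: ATG to the first in-frame stop codon.

    `start`/`end` are 0-based half-open coordinates on the forward
    strand of the scanned sequence (the stop codon is included in the
    span); `frame` is the offset of the reading frame on the scanned
    strand; `protein` excludes the stop.
    """

    frame: int
    strand: str
    start: int
    end: int
    protein: str


_VALID_NT = frozenset("ACGTN")


def find_orfs(seq: str, min_aa: int = 1) -> List[Orf]:
    """Six-frame ORF scan: every ATG with a downstream in-frame stop.

    Nested ATGs sharing a stop codon each yield an ORF (matching an
    exhaustive every-start scan). Codons containing N translate to X.
    Returns ORFs sorted by protein length, longest first.
    """
    seq = seq.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    n = len(seq)
    orfs: List[Orf] = []
    for strand in ("+", "-"):
        scanned = seq if strand == "+" else _revcomp(seq)
        for frame in range(3):
            # first in-frame stop at/after each codon index, per frame
            codon_starts = range(frame, n - 2, 3)
            stops = [i for i in codon_starts if scanned[i:i + 3] in _STOP_CODONS]
            stop_iter = iter(stops)
            next_stop = next(stop_iter, None)
            for i in codon_starts:
                while next_stop is not None and next_stop < i:
                    next_stop = next(stop_iter, None)
                if scanned[i:i + 3] != "ATG":
                    continue
                if next_stop is None:
                    continue
                protein = translate_cds(scanned[i:next_stop], to_stop=False)
                if len(protein) < min_aa:
                    continue
                s, e = i, next_stop + 3
                if strand == "-":
                    s, e = n - e, n - s
                orfs.append(Orf(frame=frame, strand=strand, start=s, end=e,
                                protein=protein))
    orfs.sort(key=lambda o: (-len(o.protein), o.strand, o.start, o.frame))
    return orfs


@dataclass(frozen=True)
class FunctionalityCall:
    """Classifier verdict with the identifiers of violated criteria."""

    status: str  # FUNCTIONAL | NON_FUNCTIONAL | UNKNOWN
    failed_criteria: Tuple[str, ...] = ()
    unknown_criteria: Tuple[str, ...] = ()


def _scaled_bounds(bounds: Tuple[int, int], tolerance: float) -> Tuple[float, float]:
    lo, hi = bounds
    return lo * (1.0 - tolerance), hi * (1.0 + tolerance)


def _finish_call(failed: List[str], unknown: List[str], strict: bool) -> FunctionalityCall:
    if failed:
        return FunctionalityCall("NON_FUNCTIONAL", tuple(failed), tuple(unknown))
    if unknown and strict:
        return FunctionalityCall("UNKNOWN", (), tuple(unknown))
    return FunctionalityCall("FUNCTIONAL", (), tuple(unknown))


def classify_si_duf247(record: GeneRecord,
                       bounds: Tuple[int, int] = (508, 559),
                       strict: bool = True,
                       tolerance: float = 0.0) -> FunctionalityCall:
    """Apply the male-determinant (DUF247) functionality rules.

    FUNCTIONAL requires: a single-exon (intronless) ORF; a translated
    protein length within `bounds` (508-559 aa by default, optionally
    widened by a relative `tolerance` for novel alleles); a DUF247
    domain call; and a transmembrane segment in the accepted layout.
    """
    if record.gene_class != "SI_DUF247":
        raise ValueError(f"record {record.id!r} has gene_class "
                         f"{record.gene_class!r}, expected 'SI_DUF247'")
    failed: List[str] = []
    unknown: List[str] = []
    if record.n_introns != 0:
        failed.append("intronless")
    lo, hi = _scaled_bounds(bounds, tolerance)
    if not (lo <= record.protein_length() <= hi):
        failed.append("length")
    for rule, flag in (("duf247_domain", record.features.has_duf247),
                       ("transmembrane", record.features.has_transmembrane),
                       ("layout", record.features.layout_ok)):
        if flag == "no":
            failed.append(rule)
        elif flag == "unknown":
            unknown.append(rule)
    return _finish_call(failed, unknown, strict)


def classify_s_female(record: GeneRecord,
                      bounds: Tuple[int, int] = (82, 122),
                      strict: bool = True,
                      tolerance: float = 0.0) -> FunctionalityCall:
    """Apply the female-determinant (sS/sZ) functionality rules.

    FUNCTIONAL requires: exactly two exons (a one-intron ORF); a
    translated length within `bounds` (82-122 aa by default); a signal
    peptide call; and the accepted topology layout.
    """
    if record.gene_class != "S_FEMALE":
        raise ValueError(f"record {record.id!r} has gene_class "
                         f"{record.gene_class!r}, expected 'S_FEMALE'")
    failed: List[str] = []
    unknown: List[str] = []
    if record.n_introns != 1:
        failed.append("one_intron")
    lo, hi = _scaled_bounds(bounds, tolerance)
    if not (lo <= record.protein_length() <= hi):
        failed.append("length")
    for rule, flag in (("signal_peptide", record.features.has_signal_peptide),
                       ("layout", record.features.layout_ok)):
        if flag == "no":
            failed.append(rule)
        elif flag == "unknown":
            unknown.append(rule)
    return _finish_call(failed, unknown, strict)


def classify_gene(record: GeneRecord, **kwargs) -> FunctionalityCall:
    """Dispatch to the class-appropriate rule set."""
    if record.gene_class == "SI_DUF247":
        return classify_si_duf247(record, **kwargs)
    if record.gene_class == "S_FEMALE":
        return classify_s_female(record, **kwargs)
    raise ValueError(f"no functionality rules for gene_class {record.gene_class!r}")


def predict_phenotype(table: Mapping[str, Mapping[str, str]]) -> Dict[str, str]:
    """Predict compatibility phenotypes from six-gene status tables.

    `table` maps genotype name -> {gene -> status} where every entry
    must contain all six determinants with status FUNCTIONAL,
    NON_FUNCTIONAL, or ABSENT. A genotype is SC_PREDICTED as soon as
    any determinant is NON_FUNCTIONAL or ABSENT; otherwise it is
    SI_POSSIBLE — a complete functional set never guarantees
    self-incompatibility, since compatibility can also break down
    outside the recognition genes.
    """
    out: Dict[str, str] = {}
    for genotype, statuses in table.items():
        missing = [g for g in SIX_GENES if g not in statuses]
        if missing:
            raise ValueError(f"genotype {genotype!r} is missing determinant "
                             f"entries: {missing}")
        for gene in SIX_GENES:
            if statuses[gene] not in STATUS_VALUES:
                raise ValueError(f"invalid status {statuses[gene]!r} for "
                                 f"{genotype!r}/{gene!r}")
        broken = any(statuses[g] in ("NON_FUNCTIONAL", "ABSENT") for g in SIX_GENES)
        out[genotype] = "SC_PREDICTED" if broken else "SI_POSSIBLE"
    return out


# Kyte-Doolittle hydropathy values.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


def infer_transmembrane_kd(protein: str, window: int = 19,
                           threshold: float = 1.6) -> str:
    """Heuristic transmembrane call from Kyte-Doolittle hydropathy.

    Returns "yes" if any sliding window of `window` residues has a mean
    hydropathy above `threshold`, else "no". This is a rough fallback
    for records lacking an external topology prediction — it knows
    nothing about topology or orientation, only hydrophobicity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    vals = [_KD.get(aa, 0.0) for aa in protein.upper()]
    if len(vals) < window:
        return "no"
    acc = sum(vals[:window])
    best = acc
    for i in range(window, len(vals)):
        acc += vals[i] - vals[i - window]
        best = max(best, acc)
    return "yes" if best / window > threshold else "no"
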