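"""Readers and writers for the pipeline's file formats.

FASTA via Biopython; a minimal GFF3 reader/writer for the gene-model
subset this package produces (gene + exon features, 1-based inclusive
coordinates externally, converted to the 0-based half-open internal
convention); CSV/TSV tables via pandas with column validation; CMAP
text via the synteny module. Parse errors name the file, line, and
field concerned.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .finemap import RecombinationSummary
from .gene_models import GeneRecord, ProteinFeatures
from .markers import Marker, MarkerMap
from .qpcr import REQUIRED_CT_COLUMNS
from . import synteny as _synteny

__all__ = [
    "read_fasta", "write_fasta",
    "read_gff3", "write_gff3",
    "read_marker_table", "write_marker_table",
    "read_ct_table", "write_ct_table",
    "read_cmap", "write_cmap",
    "write_population_tsv", "read_population_tsv",
    "write_summary_json",
]

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Sequences keyed by record id, preserving file order."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], path: PathLike,
                width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=label, description="")
               for label, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# --------------------------------------------------------------------------
# GFF3 gene models
# --------------------------------------------------------------------------

_GFF_COLS = 9


def _parse_gff_attributes(text: str, path: PathLike, lineno: int) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"{path}:{lineno}: malformed attribute {item!r} "
                             "(expected key=value)")
        k, v = item.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: PathLike, sequences: Mapping[str, str]) -> List[GeneRecord]:
    """Assemble :class:`GeneRecord` objects from GFF3 gene/exon features.

    `sequences` maps seqid -> genomic sequence (e.g. from
    :func:`read_fasta`). Each gene feature needs an ``ID`` attribute;
    exons attach via ``Parent``. The record's `seq` is the gene span
    and exon coordinates are re-based onto it. Optional gene attributes
    ``gene_class`` and the four protein-feature flags are honoured.
    """
    genes: Dict[str, dict] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF_COLS:
                raise ValueError(f"{path}:{lineno}: expected {_GFF_COLS} "
                                 f"tab-separated columns, got {len(fields)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate "
                                 f"in columns 4-5") from None
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            attrs = _parse_gff_attributes(attr_s, path, lineno)
            if ftype == "gene":
                if "ID" not in attrs:
                    raise ValueError(f"{path}:{lineno}: gene feature lacks "
                                     "an ID attribute")
                genes[attrs["ID"]] = {"seqid": seqid, "start": start,
                                      "end": end, "strand": strand,
                                      "attrs": attrs, "line": lineno}
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if not parent:
                    raise ValueError(f"{path}:{lineno}: exon feature lacks "
                                     "a Parent attribute")
                exons.setdefault(parent, []).append((start, end))

    records: List[GeneRecord] = []
    for gene_id, info in genes.items():
        seqid = info["seqid"]
        if seqid not in sequences:
            raise ValueError(f"{path}: gene {gene_id!r} references unknown "
                             f"sequence {seqid!r}")
        gene_exons = sorted(exons.get(gene_id, [(info["start"], info["end"])]))
        # 1-based inclusive -> 0-based half-open, re-based on the gene span
        offset = info["start"] - 1
        internal = tuple((s - 1 - offset, e - offset) for s, e in gene_exons)
        seq = sequences[seqid][offset:info["end"]]
        attrs = info["attrs"]
        features = ProteinFeatures(
            has_duf247=attrs.get("has_duf247", "unknown"),
            has_transmembrane=attrs.get("has_transmembrane", "unknown"),
            has_signal_peptide=attrs.get("has_signal_peptide", "unknown"),
            layout_ok=attrs.get("layout_ok", "unknown"),
        )
        records.append(GeneRecord(
            id=gene_id, gene_class=attrs.get("gene_class", "OTHER"),
            seq=seq, exons=internal, strand=info["strand"], features=features))
    return records


def write_gff3(records: Sequence[GeneRecord], path: PathLike,
               seqids: Optional[Mapping[str, str]] = None) -> Dict[str, str]:
    """Write gene models as GFF3 plus return their genomic sequences.

    Each record becomes its own seqid (record id unless remapped via
    `seqids`), with the gene spanning the whole sequence and one exon
    row per exon. Returns {seqid: sequence} suitable for
    :func:`write_fasta`, so that ``read_gff3(path, seqs)`` round-trips.
    """
    seqids = dict(seqids or {})
    sequences: Dict[str, str] = {}
    lines = ["##gff-version 3"]
    for rec in records:
        seqid = seqids.get(rec.id, rec.id)
        sequences[seqid] = rec.seq
        attrs = [f"ID={rec.id}", f"gene_class={rec.gene_class}"]
        f = rec.features
        for key, val in (("has_duf247", f.has_duf247),
                         ("has_transmembrane", f.has_transmembrane),
                         ("has_signal_peptide", f.has_signal_peptide),
                         ("layout_ok", f.layout_ok)):
            if val != "unknown":
                attrs.append(f"{key}={val}")
        lines.append("\t".join([seqid, "grass_si", "gene", "1",
                                str(len(rec.seq)), ".", rec.strand, ".",
                                ";".join(attrs)]))
        for i, (s, e) in enumerate(rec.exons, start=1):
            lines.append("\t".join([seqid, "grass_si", "exon",
                                    str(s + 1), str(e), ".", rec.strand, ".",
                                    f"ID={rec.id}.exon{i};Parent={rec.id}"]))
    Path(path).write_text("\n".join(lines) + "\n")
    return sequences


# --------------------------------------------------------------------------
# tabular inputs
# --------------------------------------------------------------------------

def read_marker_table(path: PathLike, locus_cm: float,
                      locus_name: str = "Z",
                      contig_length: Optional[int] = None,
                      locus_bp: Optional[int] = None) -> MarkerMap:
    """Marker map from a CSV with columns name, cm, contig, bp
    (optionally bp_start, bp_end)."""
    df = pd.read_csv(path)
    required = ["name", "cm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: marker table is missing columns {missing}")
    markers = []
    for _, row in df.iterrows():
        markers.append(Marker(
            name=str(row["name"]), cm=float(row["cm"]),
            contig=str(row["contig"]) if "contig" in df.columns and pd.notna(row.get("contig")) else None,
            bp=int(row["bp"]) if "bp" in df.columns and pd.notna(row.get("bp")) else None,
            bp_start=int(row["bp_start"]) if "bp_start" in df.columns and pd.notna(row.get("bp_start")) else None,
            bp_end=int(row["bp_end"]) if "bp_end" in df.columns and pd.notna(row.get("bp_end")) else None,
        ))
    contig = markers[0].contig if markers and markers[0].contig else None
    return MarkerMap(markers=tuple(markers), locus_cm=locus_cm,
                     locus_name=locus_name, contig=contig,
                     contig_length=contig_length, locus_bp=locus_bp)


def write_marker_table(mmap: MarkerMap, path: PathLike) -> None:
    rows = [{"name": m.name, "cm": m.cm, "contig": m.contig, "bp": m.bp,
             "bp_start": m.bp_start, "bp_end": m.bp_end}
            for m in mmap.markers]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ct_table(path: PathLike) -> pd.DataFrame:
    """Ct table CSV with the columns the qPCR pipeline requires.

    The sentinel Ct (999) is preserved verbatim; allele may be empty.
    """
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"allele": str, "sample_id": str})
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: Ct table is missing required columns: "
                         f"{missing}")
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    return df


def write_ct_table(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False)


def write_population_tsv(calls: pd.DataFrame, path: PathLike) -> None:
    """Offspring calls as TSV: offspring_id then one column per marker."""
    calls.to_csv(path, sep="\t")


def read_population_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="offspring_id",
                     keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: no offspring rows found")
    return df


def write_summary_json(summary: RecombinationSummary, path: PathLike) -> None:
    payload = {
        "counts": summary.counts,
        "n_non_recombinant": summary.n_non_recombinant,
        "n_selfed_candidates": summary.n_selfed_candidates,
        "n_ambiguous": summary.n_ambiguous,
        "n_recombinant": summary.n_recombinant,
    }
    if summary.cosegregating_interval is not None:
        iv = summary.cosegregating_interval
        payload["cosegregating_interval"] = {
            "contig": iv.contig, "start": iv.start, "end": iv.end,
            "length": iv.length, "left_marker": iv.left_marker,
            "right_marker": iv.right_marker,
            "unresolved_left": iv.unresolved_left,
            "unresolved_right": iv.unresolved_right,
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_cmap(path: PathLike):
    return _synteny.read_cmap(Path(path).read_text())


def write_cmap(annotations, path: PathLike) -> None:
    Path(path).write_text(_synteny.export_cmap(annotations))
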