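"""Pairwise protein identity matrices for SI candidate alleles.

SI determinants are expected to be highly diverse between allelic
specificities. This module quantifies that diversity as percent
identity from pairwise global alignments (Needleman-Wunsch with affine
gap penalties, BLOSUM62 by default), assembled into a symmetric
identity matrix with within- and between-group summary statistics
(mean and standard deviation over distinct pairs).

Identity from a pairwise global alignment is not numerically identical
to identity read off a multiple sequence alignment; group means carry a
few percentage points of method dependence, which is why three
denominator conventions are implemented and reported.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "PairAlignment",
    "IdentityMatrix",
    "align_pair",
    "percent_identity",
    "identity_matrix",
    "group_summary",
]

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

IDENTITY_MODES = ("aligned_columns", "alignment_length", "shorter_sequence")


@dataclass(frozen=True)
class PairAlignment:
    """A gapped global alignment of two protein sequences."""

    a: str          # gapped, '-' for gaps
    b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned strings must have equal length")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_pair(a: str, b: str, matrix: str = "BLOSUM62",
               gap_open: float = 10.0, gap_extend: float = 0.5) -> PairAlignment:
    """Optimal global alignment of two protein sequences.

    Affine gap penalties (defaults: open 10, extend 0.5) with the named
    substitution matrix. Ties between co-optimal alignments are broken
    deterministically (first alignment in the aligner's enumeration
    order), so repeated calls are reproducible.
    """
    for name, seq in (("first", a), ("second", b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"{name} sequence contains invalid residues: "
                             f"{sorted(bad)}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a.upper(), b.upper())[0]
    a_gapped, b_gapped = str(aln[0]), str(aln[1])
    return PairAlignment(a=a_gapped, b=b_gapped, score=float(aln.score))


def percent_identity(alignment: PairAlignment,
                     mode: str = "aligned_columns") -> float:
    """Percent identity of an alignment under a denominator convention.

    ``aligned_columns`` (default): identical residue pairs over columns
    where both sequences hold a residue; ``alignment_length``: over all
    columns including gaps; ``shorter_sequence``: over the length of
    the shorter ungapped sequence. A fully gapped overlap yields 0 with
    a warning.
    """
    if mode not in IDENTITY_MODES:
        raise ValueError(f"mode must be one of {IDENTITY_MODES}")
    matches = 0
    both = 0
    for x, y in zip(alignment.a, alignment.b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                matches += 1
    if mode == "aligned_columns":
        denom = both
    elif mode == "alignment_length":
        denom = len(alignment.a)
    else:
        denom = min(len(alignment.a.replace("-", "")),
                    len(alignment.b.replace("-", "")))
    if denom == 0 or both == 0:
        if both == 0:
            warnings.warn("alignment has no mutually aligned columns; "
                          "identity defined as 0", stacklevel=2)
            return 0.0
    return 100.0 * matches / denom


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix with optional group labels."""

    labels: Tuple[str, ...]
    matrix: np.ndarray
    groups: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(m), 100.0):
            raise ValueError("identity matrix diagonal must be 100")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        """Heat-map-ready long format: one row per ordered label pair."""
        df = self.to_frame().stack().rename("identity").reset_index()
        df.columns = ["label_a", "label_b", "identity"]
        if self.groups:
            df["group_a"] = df["label_a"].map(self.groups)
            df["group_b"] = df["label_b"].map(self.groups)
        return df


def identity_matrix(sequences: Mapping[str, str],
                    groups: Optional[Mapping[str, str]] = None,
                    mode: str = "aligned_columns",
                    matrix: str = "BLOSUM62",
                    gap_open: float = 10.0,
                    gap_extend: float = 0.5) -> IdentityMatrix:
    """All-against-all percent identity of a set of protein sequences."""
    labels = tuple(sequences)
    n = len(labels)
    if n == 0:
        raise ValueError("no sequences supplied")
    out = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        aln = align_pair(sequences[labels[i]], sequences[labels[j]],
                         matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
        pid = percent_identity(aln, mode=mode)
        out[i, j] = out[j, i] = pid
    return IdentityMatrix(labels=labels, matrix=out,
                          groups=dict(groups) if groups else None)


def group_summary(im: IdentityMatrix, ddof: int = 1) -> pd.DataFrame:
    """Mean and sigma of identities within and between groups.

    Within-group statistics run over the unordered distinct pairs of
    each group; between-group statistics over all cross pairs of each
    group pair. `ddof=1` gives the sample standard deviation (default);
    0 the population value. Singleton groups are skipped with a warning.
    """
    if not im.groups:
        raise ValueError("identity matrix carries no group assignment")
    by_group: Dict[str, List[int]] = {}
    for idx, label in enumerate(im.labels):
        by_group.setdefault(im.groups[label], []).append(idx)

    rows = []
    for group in sorted(by_group):
        members = by_group[group]
        if len(members) < 2:
            warnings.warn(f"group {group!r} has a single member; skipped",
                          stacklevel=2)
            continue
        vals = [im.matrix[i, j] for i, j in itertools.combinations(members, 2)]
        rows.append({"comparison": "within", "group_a": group, "group_b": group,
                     "n_pairs": len(vals), "mean": float(np.mean(vals)),
                     "sigma": float(np.std(vals, ddof=ddof)) if len(vals) > ddof else 0.0})
    for ga, gb in itertools.combinations(sorted(by_group), 2):
        vals = [im.matrix[i, j] for i in by_group[ga] for j in by_group[gb]]
        rows.append({"comparison": "between", "group_a": ga, "group_b": gb,
                     "n_pairs": len(vals), "mean": float(np.mean(vals)),
                     "sigma": float(np.std(vals, ddof=ddof)) if len(vals) > ddof else 0.0})
    return pd.DataFrame(rows)
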