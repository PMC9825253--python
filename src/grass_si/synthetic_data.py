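"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, all seeded and fully deterministic:

* :func:`simulate_population` — an SI-filtered mapping population for a
  given cross design. Gametes recombine along a marker map under the
  Haldane (no-interference) model; pollen is rejection-sampled through
  the two-locus compatibility rule; rare self-pollination bypasses SI;
  HET/HOM zygosity calls are derived from the simulated genotypes and
  then corrupted by call error and missingness. Ground truth (origin,
  gamete homolog paths, true recombination status) is returned
  alongside the calls.
* :func:`simulate_gene_locus` — SI candidate gene models from clean
  templates, optionally carrying a frameshift, premature stop, gained
  intron, or truncation, for exercising the functionality classifier.
* :func:`simulate_qpcr` — technical-replicate Ct tables (and optional
  amplification curves) from known per-sample quantities and amplicon
  efficiencies, Ct = C0 - log(Q)/log(E) + Gaussian noise.

Zygosity calls model a mapping design in which the pollen donor is
heterozygous for a marker variant carried on the chromosome whose Z
allele is absent from the mother (the SI-transmissible homolog), so
cross-derived offspring score HET at fully linked markers and HOM
signals either a crossover or a selfing event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .gene_models import GeneRecord, ProteinFeatures, _STOP_CODONS
from .markers import MarkerMap, haldane
from .si_core import (CrossDesign, IncompatibleCrossError, SIGenotype,
                      compatible_fraction, pollen_compatible, SIHaplotype)

__all__ = [
    "PopulationSimSpec",
    "PopulationTruth",
    "PopulationSim",
    "simulate_population",
    "QpcrSimSpec",
    "simulate_qpcr",
    "simulate_gene_locus",
    "make_duf247_template",
    "make_female_template",
]

CALL_HET = "HET"
CALL_HOM = "HOM"
CALL_MISSING = "NA"


# --------------------------------------------------------------------------
# mapping-population simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSimSpec:
    """Parameters of one simulated mapping population.

    `selfing_rate` is the per-offspring probability of maternal
    self-fertilisation bypassing SI (default 0.005 — self-pollination
    is rare but observed in these designs); `call_error_rate` flips a
    HET/HOM call symmetrically; `missing_rate` drops a call to NA.
    """

    cross: CrossDesign
    marker_map: MarkerMap
    n: int
    selfing_rate: float = 0.005
    call_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    # Optional explicit marker phases: arrays of shape (2, n_markers) of
    # small integers, one row per homolog, in marker-map order. Defaults:
    # the mother is marker-homozygous (all zeros) and the father carries
    # variant 1 on the SI-transmissible homolog only.
    mother_marker_alleles: Optional[Sequence[Sequence[int]]] = None
    father_marker_alleles: Optional[Sequence[Sequence[int]]] = None

    def __post_init__(self) -> None:
        for name in ("selfing_rate", "call_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n < 1:
            raise ValueError("population size n must be >= 1")


@dataclass
class PopulationTruth:
    """Ground truth for a simulated population.

    `paternal_origin`/`maternal_origin` give, per offspring and per
    position (markers plus the locus, in cM order), the index (0/1) of
    the parental homolog the gamete copied at that position. For selfed
    offspring both gametes are maternal. A cross offspring is a true
    recombinant at a marker iff its paternal gamete switched homologs
    between that marker and the locus.
    """

    origin: np.ndarray                # 'cross' | 'self' per offspring
    position_names: Tuple[str, ...]   # markers + locus, sorted by cM
    locus_index: int
    marker_indices: Dict[str, int]    # marker name -> column in origin arrays
    paternal_origin: np.ndarray       # (n, n_positions) int8
    maternal_origin: np.ndarray       # (n, n_positions) int8
    z_genotypes: List[Tuple[str, str]]
    transmissible_homolog: int        # father homolog index carrying variant 1

    def is_cross(self) -> np.ndarray:
        return self.origin == "cross"

    def true_recombinant(self, marker: str) -> np.ndarray:
        """Cross offspring whose paternal gamete recombined between
        `marker` and the locus (False for selfed offspring)."""
        j = self.marker_indices[marker]
        rec = self.paternal_origin[:, j] != self.paternal_origin[:, self.locus_index]
        return rec & self.is_cross()

    def z_heterozygous(self) -> np.ndarray:
        return np.array([a != b for a, b in self.z_genotypes])


@dataclass
class PopulationSim:
    """Result bundle: observed calls plus ground truth."""

    calls: pd.DataFrame       # offspring x markers, values HET/HOM/NA
    truth: PopulationTruth
    spec: PopulationSimSpec


def _transmissible_homolog(father: SIGenotype, mother: SIGenotype) -> int:
    """Index of the father's Z homolog whose allele the stigma cannot
    reject (an allele absent from the mother), falling back to 0 when
    no or both homologs qualify."""
    for i, z in enumerate(father.z_pair):
        if z not in mother.z_pair:
            return i
    return 0


def _sample_origin_paths(rng: np.random.Generator, k: int,
                         recomb: np.ndarray) -> np.ndarray:
    """Homolog-origin paths along positions for `k` gametes.

    The starting homolog is fair; between adjacent positions the path
    switches homolog with the Haldane recombination fraction for that
    interval (no interference: switches are independent)."""
    origins = np.empty((k, len(recomb) + 1), dtype=np.int8)
    origins[:, 0] = rng.integers(0, 2, size=k, dtype=np.int8)
    if len(recomb):
        switches = (rng.random((k, len(recomb))) < recomb[None, :]).astype(np.int8)
        # XOR scan: the homolog at position j is the start homolog flipped
        # once per crossover along the way
        origins[:, 1:] = switches
        for j in range(1, origins.shape[1]):
            origins[:, j] ^= origins[:, j - 1]
    return origins


def simulate_population(spec: PopulationSimSpec) -> PopulationSim:
    """Simulate one SI-filtered mapping population.

    Cross-derived offspring get a maternal gamete (unfiltered) and a
    paternal gamete rejection-sampled through the pollen-stigma
    compatibility rule, the transmitted Z allele being read off the
    homolog path at the locus position. With probability
    `selfing_rate` the offspring instead derives from two maternal
    gametes (SI bypassed). Calls are HET where the two marker alleles
    differ, then corrupted by `call_error_rate` (symmetric flip) and
    `missing_rate`.
    """
    mother, father = spec.cross.mother, spec.cross.father
    if compatible_fraction(father, mother) == 0.0 and spec.selfing_rate < 1.0:
        raise IncompatibleCrossError(
            f"cross {spec.cross.name or '(unnamed)'} is fully incompatible; "
            "only selfed offspring could exist")

    mmap = spec.marker_map
    positions = mmap.positions_with_locus()
    names = tuple(name for name, _ in positions)
    cms = np.array([cm for _, cm in positions])
    locus_index = names.index(mmap.locus_name)
    marker_indices = {name: i for i, name in enumerate(names) if i != locus_index}
    recomb = np.array([haldane(d) for d in np.diff(cms)])
    n_markers = len(mmap.markers)
    marker_cols = np.array([marker_indices[m.name] for m in mmap.markers])

    h_star = _transmissible_homolog(father, mother)
    if spec.father_marker_alleles is not None:
        father_phase = np.asarray(spec.father_marker_alleles, dtype=np.int64)
    else:
        father_phase = np.zeros((2, n_markers), dtype=np.int64)
        father_phase[h_star, :] = 1
    if spec.mother_marker_alleles is not None:
        mother_phase = np.asarray(spec.mother_marker_alleles, dtype=np.int64)
    else:
        mother_phase = np.zeros((2, n_markers), dtype=np.int64)
    for phase, who in ((father_phase, "father"), (mother_phase, "mother")):
        if phase.shape != (2, n_markers):
            raise ValueError(f"{who}_marker_alleles must have shape "
                             f"(2, {n_markers}), got {phase.shape}")

    rng = np.random.default_rng(spec.seed)
    n = spec.n
    selfed = rng.random(n) < spec.selfing_rate

    father_z = np.array(father.z_pair)
    mother_z = np.array(mother.z_pair)
    mother_s = np.array(mother.s_pair)
    father_s = np.array(father.s_pair)

    # paternal gametes for every offspring slot; selfed slots are
    # overwritten by a second maternal gamete below
    pat_origin = _sample_origin_paths(rng, n, recomb)
    pat_s = father_s[rng.integers(0, 2, size=n)]
    # rejection sampling through the SI filter, cross offspring only
    def _incompatible(origins: np.ndarray, s_alleles: np.ndarray) -> np.ndarray:
        z_alleles = father_z[origins[:, locus_index]]
        return (np.isin(s_alleles, mother_s) & np.isin(z_alleles, mother_z))

    active = np.flatnonzero(~selfed & _incompatible(pat_origin, pat_s))
    while active.size:
        redraw = _sample_origin_paths(rng, active.size, recomb)
        pat_origin[active] = redraw
        pat_s[active] = father_s[rng.integers(0, 2, size=active.size)]
        active = active[_incompatible(pat_origin[active], pat_s[active])]

    mat_origin = _sample_origin_paths(rng, n, recomb)
    # second maternal gamete replacing the paternal one in selfed slots
    n_self = int(selfed.sum())
    if n_self:
        pat_origin[selfed] = _sample_origin_paths(rng, n_self, recomb)

    # marker alleles carried by each gamete
    mat_alleles = mother_phase[mat_origin[:, marker_cols],
                               np.arange(n_markers)[None, :]]
    pat_alleles = np.where(selfed[:, None],
                           mother_phase[pat_origin[:, marker_cols],
                                        np.arange(n_markers)[None, :]],
                           father_phase[pat_origin[:, marker_cols],
                                        np.arange(n_markers)[None, :]])
    het = mat_alleles != pat_alleles

    # call corruption: symmetric HET<->HOM flips, then missingness
    flips = rng.random((n, n_markers)) < spec.call_error_rate
    het = het ^ flips
    missing = rng.random((n, n_markers)) < spec.missing_rate

    calls = np.where(het, CALL_HET, CALL_HOM).astype(object)
    calls[missing] = CALL_MISSING
    ids = [f"off_{i + 1:05d}" for i in range(n)]
    calls_df = pd.DataFrame(calls, index=ids, columns=list(mmap.names))
    calls_df.index.name = "offspring_id"

    mat_z = mother_z[mat_origin[:, locus_index]]
    pat_z = np.where(selfed, mother_z[pat_origin[:, locus_index]],
                     father_z[pat_origin[:, locus_index]])
    z_genotypes = [tuple(sorted((a, b))) for a, b in zip(mat_z, pat_z)]

    truth = PopulationTruth(
        origin=np.where(selfed, "self", "cross"),
        position_names=names,
        locus_index=locus_index,
        marker_indices=marker_indices,
        paternal_origin=pat_origin,
        maternal_origin=mat_origin,
        z_genotypes=z_genotypes,
        transmissible_homolog=h_star,
    )
    return PopulationSim(calls=calls_df, truth=truth, spec=spec)


# --------------------------------------------------------------------------
# gene-model simulation
# --------------------------------------------------------------------------

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    """A clean CDS of `n_aa` sense codons: ATG ... stop, no internal stop."""
    body = rng.choice(len(_SENSE_CODONS), size=n_aa - 1)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def make_duf247_template(record_id: str = "SI_DUF247_template",
                         n_aa: int = 535, seed: int = 0) -> GeneRecord:
    """An intronless male-determinant template passing every rule.

    535 codons sits mid-range of the observed 508-559 aa DUF247 allele
    sizes; domain/topology flags are set to 'yes' (the classifier
    consumes them as given).
    """
    rng = np.random.default_rng(seed)
    seq = _random_cds(rng, n_aa)
    return GeneRecord(
        id=record_id, gene_class="SI_DUF247", seq=seq,
        exons=((0, len(seq)),), strand="+",
        features=ProteinFeatures(has_duf247="yes", has_transmembrane="yes",
                                 has_signal_peptide="unknown", layout_ok="yes"),
    )


def make_female_template(record_id: str = "S_FEMALE_template",
                         n_aa: int = 100, intron_length: int = 120,
                         seed: int = 0) -> GeneRecord:
    """A one-intron female-determinant (sS/sZ-like) template.

    100 codons sits mid-range of the observed 82-122 aa allele sizes;
    the intron (GT..AG) is inserted at a codon boundary mid-CDS.
    """
    if intron_length < 4:
        raise ValueError("intron_length must be >= 4 (GT..AG)")
    rng = np.random.default_rng(seed)
    cds = _random_cds(rng, n_aa)
    cut = 3 * ((n_aa + 1) // 2)
    intron = "GT" + "".join(rng.choice(list("ACGT"), size=intron_length - 4)) + "AG"
    seq = cds[:cut] + intron + cds[cut:]
    return GeneRecord(
        id=record_id, gene_class="S_FEMALE", seq=seq,
        exons=((0, cut), (cut + intron_length, len(seq))), strand="+",
        features=ProteinFeatures(has_duf247="unknown", has_transmembrane="unknown",
                                 has_signal_peptide="yes", layout_ok="yes"),
    )


def _cds_offset_to_genomic(record: GeneRecord, offset: int) -> int:
    """Genomic coordinate of a spliced-CDS offset (plus-strand records)."""
    if record.strand != "+":
        raise ValueError("lesion placement supports plus-strand templates only")
    remaining = offset
    for start, end in record.exons:
        length = end - start
        if remaining < length:
            return start + remaining
        remaining -= length
    raise ValueError(f"CDS offset {offset} outside the coding sequence "
                     f"(CDS length {sum(e - s for s, e in record.exons)})")


def _shift_exons(exons, at: int, delta: int):
    out = []
    for start, end in exons:
        out.append((start + delta if start > at else start,
                    end + delta if end > at else end))
    return tuple(out)


def simulate_gene_locus(template: GeneRecord,
                        lesion: Optional[Tuple] = None,
                        seed: int = 0) -> Tuple[GeneRecord, str]:
    """Derive a (possibly lesioned) gene model from a template.

    `lesion` is None for a faithful copy, or one of::

        ("frameshift", codon_index)      delete one nucleotide
        ("premature_stop", codon_index)  replace the codon with TAA
        ("intron_gain",)                 insert a GT..AG intron mid-exon
        ("truncation", genomic_length)   keep only the 5' portion

    Returns the lesioned :class:`GeneRecord` and its genomic sequence.
    Lesion positions outside the CDS raise ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    cds_len = sum(e - s for s, e in template.exons)
    n_codons = cds_len // 3

    if lesion is None:
        rec = GeneRecord(id=template.id, gene_class=template.gene_class,
                         seq=template.seq, exons=template.exons,
                         strand=template.strand, features=template.features)
        return rec, rec.seq

    kind = lesion[0]
    seq, exons = template.seq, template.exons

    if kind in ("frameshift", "premature_stop"):
        codon = int(lesion[1])
        if not (0 <= codon < n_codons):
            raise ValueError(f"codon index {codon} outside CDS of "
                             f"{n_codons} codons")
        g = _cds_offset_to_genomic(template, 3 * codon)
        if kind == "frameshift":
            seq = seq[:g] + seq[g + 1:]
            exons = _shift_exons(exons, g, -1)
        else:
            g_end = _cds_offset_to_genomic(template, 3 * codon + 2)
            if g_end != g + 2:
                raise ValueError("premature-stop codon spans an intron; "
                                 "choose another codon")
            seq = seq[:g] + "TAA" + seq[g + 3:]
    elif kind == "intron_gain":
        intron_length = int(lesion[1]) if len(lesion) > 1 else 120
        # split the longest exon at an internal codon boundary
        widest = max(range(len(exons)), key=lambda i: exons[i][1] - exons[i][0])
        start, end = exons[widest]
        cut = start + 3 * max(1, (end - start) // 6)
        intron = "GT" + "".join(rng.choice(list("ACGT"), size=intron_length - 4)) + "AG"
        seq = seq[:cut] + intron + seq[cut:]
        new_exons = []
        for i, (s, e) in enumerate(exons):
            if i < widest:
                new_exons.append((s, e))
            elif i == widest:
                new_exons.append((s, cut))
                new_exons.append((cut + intron_length, e + intron_length))
            else:
                new_exons.append((s + intron_length, e + intron_length))
        exons = tuple(new_exons)
    elif kind == "truncation":
        keep = int(lesion[1])
        if not (0 < keep < len(seq)):
            raise ValueError(f"truncation length {keep} outside sequence of "
                             f"length {len(seq)}")
        seq = seq[:keep]
        exons = tuple((s, min(e, keep)) for s, e in exons if s < keep)
    else:
        raise ValueError(f"unknown lesion kind {kind!r}")

    rec = GeneRecord(id=f"{template.id}|{kind}", gene_class=template.gene_class,
                     seq=seq, exons=exons, strand=template.strand,
                     features=template.features)
    return rec, seq


# --------------------------------------------------------------------------
# qPCR simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrSimSpec:
    """Ground truth for a simulated RT-qPCR experiment.

    `quantities[gene][sample]` are true relative template quantities;
    `efficiencies[gene]` the per-amplicon amplification efficiency
    E in (1, 2] (doubling per cycle at E = 2). Observed
    Ct = ct_at_unit_quantity - log(Q)/log(E) + Normal(0, ct_noise_sd)
    per technical replicate. Amplification curves, when requested,
    follow F(c) = f0 * Q * E^c + baseline + Normal(0, curve_noise_sd).
    """

    quantities: Mapping[str, Mapping[str, float]]
    efficiencies: Mapping[str, float]
    ct_noise_sd: float = 0.0
    technical_replicates: int = 2
    ct_at_unit_quantity: float = 20.0
    seed: int = 0
    sample_meta: Optional[Mapping[str, Mapping[str, object]]] = None
    nort_ct_offset: Optional[float] = None  # add noRT rows at RT + offset
    simulate_curves: bool = False
    f0: float = 1.0
    baseline: float = 0.0
    curve_noise_sd: float = 0.0
    n_cycles: int = 40

    def __post_init__(self) -> None:
        for gene, e in self.efficiencies.items():
            if not (1.0 < e <= 2.0):
                raise ValueError(f"efficiency for {gene!r} must lie in (1, 2], "
                                 f"got {e}")
        if self.ct_noise_sd < 0 or self.curve_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.technical_replicates < 1:
            raise ValueError("technical_replicates must be >= 1")


def simulate_qpcr(spec: QpcrSimSpec) -> Tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Generate a Ct table (and optional curves) from known truth.

    The Ct table matches the analysis module's reader: columns
    sample_id, bio_rep, tissue, timepoint, gene, allele, tech_rep, ct,
    rt_flag. Identical spec (including seed) gives identical output.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    curve_rows = []
    meta = spec.sample_meta or {}
    for gene in spec.quantities:
        if gene not in spec.efficiencies:
            raise ValueError(f"no efficiency given for gene {gene!r}")
    for gene, per_sample in spec.quantities.items():
        e = spec.efficiencies[gene]
        for sample, q in per_sample.items():
            if q <= 0:
                raise ValueError(f"true quantity must be positive "
                                 f"({gene!r}/{sample!r}: {q})")
            m = meta.get(sample, {})
            base_ct = spec.ct_at_unit_quantity - math.log(q) / math.log(e)
            for rep in range(1, spec.technical_replicates + 1):
                noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0
                rows.append({
                    "sample_id": sample,
                    "bio_rep": m.get("bio_rep", "A"),
                    "tissue": m.get("tissue", "leaf"),
                    "timepoint": m.get("timepoint", "TNA"),
                    "gene": gene,
                    "allele": m.get("allele", ""),
                    "tech_rep": rep,
                    "ct": base_ct + noise,
                    "rt_flag": "RT",
                })
                if spec.nort_ct_offset is not None:
                    rows.append({**rows[-1], "tech_rep": rep,
                                 "ct": base_ct + spec.nort_ct_offset,
                                 "rt_flag": "noRT"})
            if spec.simulate_curves:
                cycles = np.arange(1, spec.n_cycles + 1)
                f = spec.f0 * q * np.power(e, cycles) + spec.baseline
                if spec.curve_noise_sd:
                    f = f + rng.normal(0.0, spec.curve_noise_sd, size=f.shape)
                for c, fl in zip(cycles, f):
                    curve_rows.append({"well_id": f"{sample}:{gene}",
                                       "sample_id": sample, "gene": gene,
                                       "cycle": int(c), "fluorescence": float(fl)})
    table = pd.DataFrame(rows)
    curves = pd.DataFrame(curve_rows) if spec.simulate_curves else None
    return table, curves
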