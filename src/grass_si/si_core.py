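"""Two-locus gametophytic self-incompatibility (SI) compatibility model.

Grass SI is governed by two independent, multi-allelic loci, S and Z
(on different chromosomes). Pollen specificity is gametophytic: a pollen
grain carries one S and one Z allele, and fertilisation is blocked
exactly when *both* the pollen's S allele and its Z allele are present
in the diploid stigma genotype. This module provides the pollen-stigma
compatibility predicate, cross compatibility fractions, and expected
offspring genotype distributions at either locus under SI filtering.

Allele labels are opaque strings; the compact field notation ``S12Z22``
denotes S alleles {1, 2} and Z alleles {2, 2} (homozygous).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Dict, List, Tuple

__all__ = [
    "SIHaplotype",
    "SIGenotype",
    "CrossDesign",
    "IncompatibleCrossError",
    "pollen_compatible",
    "compatible_fraction",
    "offspring_locus_distribution",
    "VRNA_XL",
    "DTZ",
]


@dataclass(frozen=True)
class SIHaplotype:
    """A haploid S/Z allele combination, as carried by a pollen grain."""

    s_allele: str
    z_allele: str

    def __post_init__(self) -> None:
        if not self.s_allele or not self.z_allele:
            raise ValueError("allele labels must be non-empty strings")


def _norm_pair(pair) -> Tuple[str, str]:
    alleles = tuple(sorted(str(a) for a in pair))
    if len(alleles) != 2:
        raise ValueError(f"a locus genotype needs exactly two alleles, got {pair!r}")
    if any(not a for a in alleles):
        raise ValueError("allele labels must be non-empty strings")
    return alleles


_COMPACT_RE = re.compile(r"^S(\w)(\w)Z(\w)(\w)$")


@dataclass(frozen=True)
class SIGenotype:
    """A diploid SI genotype: an unordered allele pair at S and at Z.

    Equal entries within a pair denote homozygosity. Gametes are the
    (up to four) distinct S x Z combinations, with probability mass
    preserved when duplicate classes collapse.
    """

    s_pair: Tuple[str, str]
    z_pair: Tuple[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "s_pair", _norm_pair(self.s_pair))
        object.__setattr__(self, "z_pair", _norm_pair(self.z_pair))

    @classmethod
    def from_string(cls, text: str) -> "SIGenotype":
        """Parse the compact field notation, e.g. ``"S12Z22"``.

        Single-character allele labels only; use the constructor or
        :meth:`from_json` for multi-character labels.
        """
        m = _COMPACT_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse SI genotype notation {text!r}")
        return cls(s_pair=(m.group(1), m.group(2)), z_pair=(m.group(3), m.group(4)))

    def to_string(self) -> str:
        parts = list(self.s_pair) + list(self.z_pair)
        if any(len(a) != 1 for a in parts):
            raise ValueError("compact notation requires single-character labels")
        return f"S{self.s_pair[0]}{self.s_pair[1]}Z{self.z_pair[0]}{self.z_pair[1]}"

    @classmethod
    def from_json(cls, text: str) -> "SIGenotype":
        d = json.loads(text)
        return cls(s_pair=tuple(d["s_pair"]), z_pair=tuple(d["z_pair"]))

    def to_json(self) -> str:
        return json.dumps({"s_pair": list(self.s_pair), "z_pair": list(self.z_pair)})

    def gametes(self) -> List[Tuple[SIHaplotype, float]]:
        """Distinct gamete classes with probabilities summing to 1.

        S and Z segregate independently (they reside on different
        chromosomes), so each of the four ordered S x Z combinations has
        prior probability 1/4; duplicate classes collapse but keep mass.
        """
        mass: Dict[SIHaplotype, float] = {}
        for s in self.s_pair:
            for z in self.z_pair:
                hap = SIHaplotype(s, z)
                mass[hap] = mass.get(hap, 0.0) + 0.25
        return list(mass.items())

    def locus_gametes(self, locus: str) -> List[Tuple[str, float]]:
        """Allele classes transmitted at one locus ('S' or 'Z')."""
        pair = _locus_pair(self, locus)
        mass: Dict[str, float] = {}
        for a in pair:
            mass[a] = mass.get(a, 0.0) + 0.5
        return list(mass.items())

    def is_homozygous(self, locus: str) -> bool:
        pair = _locus_pair(self, locus)
        return pair[0] == pair[1]


def _locus_pair(genotype: SIGenotype, locus: str) -> Tuple[str, str]:
    if locus == "S":
        return genotype.s_pair
    if locus == "Z":
        return genotype.z_pair
    raise ValueError(f"locus must be 'S' or 'Z', got {locus!r}")


@dataclass(frozen=True)
class CrossDesign:
    """A named mother x pollen-donor cross."""

    mother: SIGenotype
    father: SIGenotype
    name: str = ""


class IncompatibleCrossError(ValueError):
    """Raised when a cross admits no compatible pollen class at all."""


def pollen_compatible(pollen: SIHaplotype, stigma: SIGenotype) -> bool:
    """Whether a pollen grain can fertilise the given stigma.

    Fertilisation is halted exactly when the pollen's S allele and its
    Z allele are *both* matched in the stigma; a mismatch at either
    locus lets the pollen through.
    """
    return not (pollen.s_allele in stigma.s_pair and pollen.z_allele in stigma.z_pair)


def compatible_fraction(father: SIGenotype, mother: SIGenotype) -> float:
    """Fraction of the father's pollen accepted by the mother's stigma.

    The mean of :func:`pollen_compatible` over the father's equiprobable
    pollen classes; always one of {0, 0.25, 0.5, 0.75, 1.0}.
    """
    return sum(p for hap, p in father.gametes() if pollen_compatible(hap, mother))


def offspring_locus_distribution(cross: CrossDesign, locus: str) -> Dict[Tuple[str, str], float]:
    """Expected offspring genotype frequencies at one locus under SI.

    Enumerates the father's pollen classes, discards those rejected by
    the mother's stigma, renormalises, and combines the transmitted
    paternal allele at `locus` with the maternal gamete alleles.
    Returns a map from unordered allele pairs to frequencies (sum 1).

    Raises :class:`IncompatibleCrossError` for a fully incompatible
    cross (e.g. selfing), which produces no offspring.
    """
    pollen = [(hap, p) for hap, p in cross.father.gametes()
              if pollen_compatible(hap, cross.mother)]
    total = sum(p for _, p in pollen)
    if total == 0.0:
        raise IncompatibleCrossError(
            f"cross {cross.name or '(unnamed)'} is fully incompatible; "
            "no offspring distribution exists"
        )
    dist: Dict[Tuple[str, str], float] = {}
    for hap, p_pollen in pollen:
        paternal = hap.s_allele if locus == "S" else hap.z_allele
        if locus not in ("S", "Z"):
            raise ValueError(f"locus must be 'S' or 'Z', got {locus!r}")
        for maternal, p_mat in cross.mother.locus_gametes(locus):
            genotype = tuple(sorted((maternal, paternal)))
            dist[genotype] = dist.get(genotype, 0.0) + (p_pollen / total) * p_mat
    return dist


#: The VrnA-XL fine-mapping design: mother S12 Z22 clonally propagated and
#: pollinated by a donor S12 Z12. SI admits only Z1-carrying pollen, so all
#: cross-derived offspring are heterozygous at Z.
VRNA_XL = CrossDesign(
    mother=SIGenotype.from_string("S12Z22"),
    father=SIGenotype.from_string("S12Z12"),
    name="VrnA-XL",
)

#: The DTZ design: female S12 Z12 crossed with a male S12 Z13. Only
#: Z3-carrying pollen is compatible, giving Z13 and Z23 offspring 1:1.
DTZ = CrossDesign(
    mother=SIGenotype.from_string("S12Z12"),
    father=SIGenotype.from_string("S12Z13"),
    name="DTZ",
)
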