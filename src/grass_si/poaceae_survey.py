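"""Synthetic six-gene status survey across Poaceae genotypes.

A 17-genotype encoding of the published presence/functionality survey
of the six SI determinants (SDUF247-I, sS, SDUF247-II at S; ZDUF247-I,
sZ, ZDUF247-II at Z) across 13 grass species, for exercising the
phenotype-prediction rule. The load-bearing facts are taken from
explicit published statements: all Poeae-tribe genotypes carry six
functional determinants; the rye inbred Lo7 lacks a functional
ZDUF247-I while the outcrossing Weining genotype carries a full
functional set; the self-compatible L. perenne genotype P226/135/16 is
the one genotype with six functional determinants and no
self-incompatible phenotype; S. italica and Z. mays essentially lack
the SI candidates. For the remaining self-compatible species the
statement is only that at least one determinant is non-functional or
absent (with the female determinants mostly intact); the gene-by-gene
marks for those rows are therefore a plausible synthetic encoding
consistent with the published summary, not a reproduction of the
original figure.

Status codes: FUNCTIONAL, NON_FUNCTIONAL (sequence present but
violating a functionality criterion), ABSENT (no orthologous sequence
found). Phenotypes: SI (self-incompatible) or SC (self-compatible).
"""

from __future__ import annotations

from typing import Dict, Tuple

import pandas as pd

from .gene_models import SIX_GENES

__all__ = ["survey_table", "survey_phenotypes", "survey_dataframe"]

_F = "FUNCTIONAL"
_N = "NON_FUNCTIONAL"
_A = "ABSENT"


def _row(sduf1=_F, ss=_F, sduf2=_F, zduf1=_F, sz=_F, zduf2=_F) -> Dict[str, str]:
    return {"SDUF247-I": sduf1, "sS": ss, "SDUF247-II": sduf2,
            "ZDUF247-I": zduf1, "sZ": sz, "ZDUF247-II": zduf2}


# genotype -> (species, phenotype, statuses)
_SURVEY: Dict[str, Tuple[str, str, Dict[str, str]]] = {
    "F1-30 (P205)":      ("Lolium perenne",        "SI", _row()),
    "Kyuss":             ("Lolium perenne",        "SI", _row()),
    "P226/135/16":       ("Lolium perenne",        "SC", _row()),
    "S23 Z":             ("Lolium perenne",        "SI", _row()),
    "Rabiosa":           ("Lolium multiflorum",    "SI", _row()),
    "D. glomerata":      ("Dactylis glomerata",    "SI", _row()),
    "B. distachyon":     ("Brachypodium distachyon", "SC", _row(sduf1=_N, zduf1=_N)),
    "T. aestivum":       ("Triticum aestivum",     "SC", _row(sduf1=_N, zduf2=_N)),
    "H. vulgare":        ("Hordeum vulgare",       "SC", _row(sduf2=_N)),
    "S. cereale Lo7":    ("Secale cereale",        "SC", _row(zduf1=_N)),
    "S. cereale Weining": ("Secale cereale",       "SI", _row()),
    "L. perrieri":       ("Leersia perrieri",      "SC", _row(sduf1=_N)),
    "O. sativa":         ("Oryza sativa",          "SC", _row(zduf1=_N, zduf2=_N)),
    "O. longistaminata": ("Oryza longistaminata",  "SI", _row()),
    "S. italica":        ("Setaria italica",       "SC", _row(sduf1=_A, sduf2=_A,
                                                             zduf1=_A, sz=_A, zduf2=_A)),
    "Z. mays":           ("Zea mays",              "SC", _row(sduf1=_A, ss=_A, sduf2=_A,
                                                             zduf1=_A, sz=_A, zduf2=_A)),
    "S. bicolor":        ("Sorghum bicolor",       "SC", _row(sduf2=_N)),
}


def survey_table() -> Dict[str, Dict[str, str]]:
    """Genotype -> {determinant -> status}, ready for phenotype prediction."""
    return {genotype: dict(statuses) for genotype, (_, _, statuses) in _SURVEY.items()}


def survey_phenotypes() -> Dict[str, str]:
    """Genotype -> observed compatibility phenotype (SI or SC)."""
    return {genotype: phenotype for genotype, (_, phenotype, _) in _SURVEY.items()}


def survey_dataframe() -> pd.DataFrame:
    """The survey as a DataFrame (one row per genotype)."""
    rows = []
    for genotype, (species, phenotype, statuses) in _SURVEY.items():
        rows.append({"genotype": genotype, "species": species,
                     "phenotype": phenotype,
                     **{gene: statuses[gene] for gene in SIX_GENES}})
    return pd.DataFrame(rows).set_index("genotype")
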