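"""ORF finder against a brute-force oracle; classifier rule coverage."""

import numpy as np
import pytest

from grass_si.gene_models import (GeneRecord, ProteinFeatures, classify_s_female,
                                  classify_si_duf247, find_orfs,
                                  infer_transmembrane_kd, predict_phenotype,
                                  translate_cds, SIX_GENES)
from grass_si.poaceae_survey import (survey_dataframe, survey_phenotypes,
                                     survey_table)

# Independent codon table for the oracle (hand-entered, standard code).
_ORACLE_CODONS = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        for _k, _c in enumerate(_BASES):
            _ORACLE_CODONS[_a + _b + _c] = _AAS[16 * _i + 4 * _j + _k]

_RC = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def _oracle_orfs(seq):
    """Every-ATG six-frame scan, written independently of the package."""
    seq = seq.upper()
    found = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else "".join(_RC[b] for b in reversed(seq))
        for i in range(len(s) - 2):
            if s[i:i + 3] != "ATG":
                continue
            j = i
            protein = []
            while j + 3 <= len(s):
                codon = s[j:j + 3]
                aa = _ORACLE_CODONS.get(codon, "X")
                if aa == "*":
                    start, end = i, j + 3
                    if strand == "-":
                        start, end = len(s) - end, len(s) - start
                    found.add((strand, start, end, "".join(protein)))
                    break
                protein.append(aa)
                j += 3
    return found


class TestFindOrfs:
    def test_minimal_orf(self):
        orfs = find_orfs("ATGAAATAA")
        assert len(orfs) == 1
        assert orfs[0].protein == "MK"
        assert (orfs[0].start, orfs[0].end) == (0, 9)

    def test_no_atg_gives_empty_list(self):
        assert find_orfs("CCCTTTGGGCCC") == []

    def test_n_codons_translate_to_x(self):
        orfs = find_orfs("ATGNNNAAATAA")
        assert orfs[0].protein == "MXK"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            find_orfs("ATGXXXTAA")

    def test_sorted_by_length_descending(self):
        seq = "ATGAAATAA" + "ATG" + "AAA" * 10 + "TAA"
        orfs = find_orfs(seq)
        lengths = [len(o.protein) for o in orfs]
        assert lengths == sorted(lengths, reverse=True)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(30, 2000))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        ours = {(o.strand, o.start, o.end, o.protein) for o in find_orfs(seq)}
        assert ours == _oracle_orfs(seq)

    def test_translate_cds_matches_oracle(self):
        rng = np.random.default_rng(99)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        expected = []
        for i in range(0, 300, 3):
            aa = _ORACLE_CODONS[seq[i:i + 3]]
            if aa == "*":
                break
            expected.append(aa)
        assert translate_cds(seq) == "".join(expected)


def _duf_record(n_exons=1, n_aa=535, **flags):
    cds = "ATG" + "GCT" * (n_aa - 1) + "TAA"
    if n_exons == 1:
        exons = ((0, len(cds)),)
        seq = cds
    else:
        cut = 300
        intron = "GT" + "A" * 50 + "AG"
        seq = cds[:cut] + intron + cds[cut:]
        exons = ((0, cut), (cut + len(intron), len(seq)))
    defaults = dict(has_duf247="yes", has_transmembrane="yes", layout_ok="yes")
    defaults.update(flags)
    return GeneRecord(id="g", gene_class="SI_DUF247", seq=seq, exons=exons,
                      features=ProteinFeatures(**defaults))


class TestClassifySiDuf247:
    def test_clean_record_functional(self):
        assert classify_si_duf247(_duf_record()).status == "FUNCTIONAL"

    def test_two_exons_fail_intronless_rule(self):
        call = classify_si_duf247(_duf_record(n_exons=2))
        assert call.status == "NON_FUNCTIONAL"
        assert call.failed_criteria == ("intronless",)

    def test_length_bounds(self):
        assert "length" in classify_si_duf247(_duf_record(n_aa=507)).failed_criteria
        assert "length" in classify_si_duf247(_duf_record(n_aa=560)).failed_criteria
        assert classify_si_duf247(_duf_record(n_aa=508)).status == "FUNCTIONAL"
        assert classify_si_duf247(_duf_record(n_aa=559)).status == "FUNCTIONAL"

    def test_length_tolerance_mode(self):
        rec = _duf_record(n_aa=505)
        assert classify_si_duf247(rec).status == "NON_FUNCTIONAL"
        assert classify_si_duf247(rec, tolerance=0.05).status == "FUNCTIONAL"

    def test_unknown_domain_flag_gives_unknown_in_strict_mode(self):
        rec = _duf_record(has_duf247="unknown")
        assert classify_si_duf247(rec).status == "UNKNOWN"
        lenient = classify_si_duf247(rec, strict=False)
        assert lenient.status == "FUNCTIONAL"
        assert lenient.unknown_criteria == ("duf247_domain",)

    def test_definite_failure_beats_unknown(self):
        rec = _duf_record(n_exons=2, has_duf247="unknown")
        assert classify_si_duf247(rec).status == "NON_FUNCTIONAL"

    def test_wrong_gene_class_rejected(self):
        rec = GeneRecord(id="g", gene_class="S_FEMALE", seq="ATGTAA",
                         exons=((0, 6),))
        with pytest.raises(ValueError):
            classify_si_duf247(rec)


def _female_record(n_exons=2, n_aa=100, **flags):
    cds = "ATG" + "GCT" * (n_aa - 1) + "TAA"
    if n_exons == 1:
        seq, exons = cds, ((0, len(cds)),)
    else:
        cut = 150
        intron = "GT" + "A" * 30 + "AG"
        seq = cds[:cut] + intron + cds[cut:]
        exons = ((0, cut), (cut + len(intron), len(seq)))
    defaults = dict(has_signal_peptide="yes", layout_ok="yes")
    defaults.update(flags)
    return GeneRecord(id="g", gene_class="S_FEMALE", seq=seq, exons=exons,
                      features=ProteinFeatures(**defaults))


class TestClassifySFemale:
    def test_clean_record_functional(self):
        assert classify_s_female(_female_record()).status == "FUNCTIONAL"

    def test_intronless_fails_one_intron_rule(self):
        call = classify_s_female(_female_record(n_exons=1))
        assert call.failed_criteria == ("one_intron",)

    def test_oversized_protein_fails_length(self):
        call = classify_s_female(_female_record(n_aa=130))
        assert call.failed_criteria == ("length",)

    def test_missing_signal_peptide(self):
        call = classify_s_female(_female_record(has_signal_peptide="no"))
        assert "signal_peptide" in call.failed_criteria


class TestPredictPhenotype:
    def test_one_broken_determinant_predicts_sc(self):
        row = {g: "FUNCTIONAL" for g in SIX_GENES}
        row["ZDUF247-I"] = "NON_FUNCTIONAL"  # the rye Lo7 situation
        assert predict_phenotype({"Lo7": row}) == {"Lo7": "SC_PREDICTED"}

    def test_full_functional_set_only_si_possible(self):
        row = {g: "FUNCTIONAL" for g in SIX_GENES}
        assert predict_phenotype({"x": row}) == {"x": "SI_POSSIBLE"}

    def test_absent_gene_predicts_sc(self):
        row = {g: "FUNCTIONAL" for g in SIX_GENES}
        row["sZ"] = "ABSENT"
        assert predict_phenotype({"x": row}) == {"x": "SC_PREDICTED"}

    def test_missing_gene_key_rejected(self):
        row = {g: "FUNCTIONAL" for g in SIX_GENES[:-1]}
        with pytest.raises(ValueError):
            predict_phenotype({"x": row})

    def test_survey_predictions_match_mark_rule(self):
        # SC is predicted exactly for the genotypes carrying any
        # non-functional or absent determinant
        table = survey_table()
        predictions = predict_phenotype(table)
        for genotype, statuses in table.items():
            has_mark = any(s != "FUNCTIONAL" for s in statuses.values())
            expected = "SC_PREDICTED" if has_mark else "SI_POSSIBLE"
            assert predictions[genotype] == expected

    def test_survey_has_17_genotypes_and_known_rows(self):
        df = survey_dataframe()
        assert len(df) == 17
        predictions = predict_phenotype(survey_table())
        assert predictions["S. cereale Lo7"] == "SC_PREDICTED"
        assert predictions["S. cereale Weining"] == "SI_POSSIBLE"
        # the one genotype with a full functional set but an SC phenotype
        assert predictions["P226/135/16"] == "SI_POSSIBLE"
        assert survey_phenotypes()["P226/135/16"] == "SC"

    def test_every_predicted_sc_has_sc_phenotype(self):
        # the prediction rule never calls SC on a self-incompatible
        # genotype in the survey (the converse does not hold: P226)
        predictions = predict_phenotype(survey_table())
        phenotypes = survey_phenotypes()
        for genotype, pred in predictions.items():
            if pred == "SC_PREDICTED":
                assert phenotypes[genotype] == "SC"


class TestHydropathyHeuristic:
    def test_hydrophobic_stretch_detected(self):
        protein = "M" + "K" * 30 + "LLLLLLLLLLLLLLLLLLL" + "K" * 30
        assert infer_transmembrane_kd(protein) == "yes"

    def test_polar_protein_negative(self):
        assert infer_transmembrane_kd("MKDEQRNSKDEQRNSKDEQRNS" * 3) == "no"

    def test_short_protein_negative(self):
        assert infer_transmembrane_kd("MLLV") == "no"
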