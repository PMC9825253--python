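"""qPCR pipeline: QC decisions, efficiency, geNorm, Pfaffl ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grass_si.qpcr import (CT_SENTINEL, QcThresholds, apply_ct_qc, check_gdna,
                           delta_ct_matrix, estimate_efficiency, genorm,
                           pfaffl_ratio)
from grass_si.synthetic_data import QpcrSimSpec, simulate_qpcr


def ct_rows(groups):
    """Build a Ct table from {(sample, gene): [ct, ...]} duplicates."""
    rows = []
    for (sample, gene), cts in groups.items():
        for i, ct in enumerate(cts, start=1):
            rows.append({"sample_id": sample, "bio_rep": "A", "tissue": "leaf",
                         "timepoint": "TNA", "gene": gene, "allele": "",
                         "tech_rep": i, "ct": ct, "rt_flag": "RT"})
    return pd.DataFrame(rows)


class TestCtQc:
    # hand-worked replicate pairs and their expected fate
    CASES = {
        ("s01", "g"): ([20.0, 20.4], "kept", ""),        # diff .4, dev 1.98%
        ("s02", "g"): ([20.0, 20.6], "excluded", "rep_diff"),
        ("s03", "g"): ([21.5, 20.9], "excluded", "sentinel"),  # 21.5 -> 999
        ("s04", "g"): ([10.0, 10.4], "excluded", "pct_dev"),   # dev 3.92%
        ("s05", "g"): ([15.0, 15.0], "kept", ""),
        ("s06", "g"): ([999.0, 18.0], "excluded", "sentinel"),
        ("s07", "g"): ([20.0], "excluded", "incomplete"),
        ("s08", "g"): ([20.5, 20.9], "kept", ""),        # dev 1.93%
        ("s09", "g"): ([18.0, 18.5], "kept", ""),        # diff exactly 0.5
        ("s10", "g"): ([5.0, 5.2], "excluded", "pct_dev"),     # dev 3.92%
    }

    def test_worked_fixture_decisions(self):
        table = ct_rows({k: v[0] for k, v in self.CASES.items()})
        result = apply_ct_qc(table)
        report = result.report.set_index("sample_id")
        for (sample, _), (cts, status, reason) in self.CASES.items():
            assert report.loc[sample, "status"] == status, sample
            assert report.loc[sample, "reason"] == reason, sample
        kept = result.kept.set_index("sample_id")
        assert kept.loc["s01", "mean_ct"] == pytest.approx(20.2)

    def test_every_group_accounted_exactly_once(self):
        table = ct_rows({k: v[0] for k, v in self.CASES.items()})
        result = apply_ct_qc(table)
        assert len(result.report) == len(self.CASES)
        assert len(result.kept) == sum(1 for v in self.CASES.values()
                                       if v[1] == "kept")

    def test_missing_column_named_in_error(self):
        with pytest.raises(ValueError, match="rt_flag"):
            apply_ct_qc(pd.DataFrame({"sample_id": [], "gene": []}))

    def test_custom_thresholds(self):
        table = ct_rows({("s", "g"): [30.0, 30.3]})
        strict = apply_ct_qc(table)  # 30 > 21 -> sentinel
        assert strict.report.iloc[0]["reason"] == "sentinel"
        relaxed = apply_ct_qc(table, QcThresholds(max_ct=35.0))
        assert relaxed.report.iloc[0]["status"] == "kept"


class TestGdnaCheck:
    def test_large_delta_is_negligible(self):
        assert check_gdna(18.0, 29.5) is True   # 11.5 > 10

    def test_small_delta_flagged(self):
        assert check_gdna(18.0, 25.0) is False  # 7 <= 10

    def test_no_amplification_is_negligible(self):
        assert check_gdna(18.0, CT_SENTINEL) is True
        assert check_gdna(18.0, None) is True


class TestEstimateEfficiency:
    def test_noiseless_exponential_recovered_exactly(self):
        cycles = np.arange(1, 41)
        est = estimate_efficiency(100.0 * 1.9 ** cycles)
        assert est.efficiency == pytest.approx(1.9, abs=1e-6)

    def test_baseline_recovered_within_tolerance(self):
        cycles = np.arange(1, 41)
        est = estimate_efficiency(100.0 * 1.9 ** cycles + 500.0)
        assert est.efficiency == pytest.approx(1.9, abs=0.01)

    def test_simulated_curve_round_trip(self):
        spec = QpcrSimSpec(quantities={"g": {"a": 1.0}},
                           efficiencies={"g": 1.75}, simulate_curves=True,
                           f0=100.0, baseline=0.0, seed=0)
        _, curves = simulate_qpcr(spec)
        est = estimate_efficiency(curves["fluorescence"].to_numpy())
        assert est.efficiency == pytest.approx(1.75, abs=1e-6)

    def test_flat_curve_raises(self):
        with pytest.raises(ValueError, match="no exponential phase"):
            estimate_efficiency(np.full(40, 7.0))

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            estimate_efficiency([1.0] * 5)

    def test_overfast_curve_clamped_with_warning(self):
        cycles = np.arange(1, 41)
        with pytest.warns(UserWarning, match="clamped"):
            est = estimate_efficiency(10.0 * 2.5 ** cycles)
        assert est.efficiency == 2.0
        assert est.clamped


class TestGenorm:
    def test_constant_ratio_gives_zero_m(self):
        q = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 6.0],
                          "s3": [0.5, 1.0]}, index=["A", "B"])
        res = genorm(q)
        assert res.m_values["A"] == pytest.approx(0.0)
        assert res.m_values["B"] == pytest.approx(0.0)

    def test_hand_computed_three_gene_example(self):
        # A and C constant, B alternates two-fold: sd of log2(A/B) over
        # the four samples is sqrt(1/3); hand-derived M values follow
        q = pd.DataFrame({"s1": [1.0, 1.0, 1.0], "s2": [1.0, 2.0, 1.0],
                          "s3": [1.0, 1.0, 1.0], "s4": [1.0, 2.0, 1.0]},
                         index=["A", "B", "C"])
        res = genorm(q)
        sd_ab = math.sqrt(1.0 / 3.0)
        assert res.m_values["A"] == pytest.approx(sd_ab / 2)
        assert res.m_values["B"] == pytest.approx(sd_ab)
        assert res.m_values["C"] == pytest.approx(sd_ab / 2)
        assert res.exclusion_order == ["B"]
        assert res.stability_ranking == ["A", "C", "B"]
        # V(2,3): NF2 over {A,C} is constant, NF3 picks up a third of
        # B's log swing: sd([0, -1/3, 0, -1/3]) = sqrt(1/3)/3
        assert res.pairwise_variation[2] == pytest.approx(sd_ab / 3)

    def test_noisy_gene_excluded_first(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(0.0, 0.05, size=12)
        q = pd.DataFrame({f"s{i}": [base[i], base[i] * 2.0,
                                    base[i] * rng.lognormal(0.0, 1.0)]
                          for i in range(12)}, index=["stable1", "stable2", "noisy"])
        res = genorm(q)
        assert res.exclusion_order[0] == "noisy"
        assert res.m_values["noisy"] == res.m_values.max()

    def test_all_identical_genes_all_zero(self):
        q = pd.DataFrame({"s1": [1.0, 1.0, 1.0], "s2": [2.0, 2.0, 2.0]},
                         index=["A", "B", "C"])
        res = genorm(q)
        assert (res.m_values == 0).all()
        assert all(v == pytest.approx(0.0) for v in res.pairwise_variation.values())
        assert all(res.acceptable.values())

    def test_scaling_a_sample_leaves_m_unchanged(self):
        rng = np.random.default_rng(8)
        q = pd.DataFrame(rng.lognormal(0, 0.3, size=(4, 6)),
                         index=list("ABCD"),
                         columns=[f"s{i}" for i in range(6)])
        res1 = genorm(q)
        q2 = q.copy()
        q2["s0"] *= 37.5
        res2 = genorm(q2)
        pd.testing.assert_series_equal(res1.m_values, res2.m_values)

    def test_non_positive_quantity_rejected(self):
        q = pd.DataFrame({"s1": [1.0, 0.0], "s2": [1.0, 1.0]}, index=["A", "B"])
        with pytest.raises(ValueError):
            genorm(q)


def kept_table(cts):
    """{(sample, gene): mean_ct} -> minimal QC 'kept' frame."""
    rows = [{"sample_id": s, "gene": g, "allele": "", "rt_flag": "RT",
             "mean_ct": ct} for (s, g), ct in cts.items()]
    return pd.DataFrame(rows)


class TestPfafflRatio:
    def test_two_cycle_shift_with_e2_gives_ratio_4(self):
        kept = kept_table({("ctrl", "goi"): 20.0, ("s", "goi"): 18.0,
                           ("ctrl", "ref"): 20.0, ("s", "ref"): 20.0})
        out = pfaffl_ratio(kept, {"goi": 2.0, "ref": 2.0}, "goi", ["ref"], "ctrl")
        ratios = dict(zip(out["sample_id"], out["ratio"]))
        assert ratios["s"] == pytest.approx(4.0)
        assert ratios["ctrl"] == pytest.approx(1.0)

    def test_control_against_itself_is_one(self):
        kept = kept_table({("ctrl", "goi"): 17.3, ("ctrl", "r1"): 19.0,
                           ("ctrl", "r2"): 21.0})
        out = pfaffl_ratio(kept, {"goi": 1.9, "r1": 1.8, "r2": 2.0},
                           "goi", ["r1", "r2"], "ctrl")
        assert out.set_index("sample_id").loc["ctrl", "ratio"] == pytest.approx(1.0)

    def test_simulated_fold_recovered_exactly(self):
        spec = QpcrSimSpec(
            quantities={"goi": {"ctrl": 1.0, "s": 8.0},
                        "ref": {"ctrl": 1.0, "s": 1.0}},
            efficiencies={"goi": 1.9, "ref": 1.9}, ct_noise_sd=0.0, seed=0)
        table, _ = simulate_qpcr(spec)
        qc = apply_ct_qc(table)
        out = pfaffl_ratio(qc.kept, {"goi": 1.9, "ref": 1.9},
                           "goi", ["ref"], "ctrl")
        ratios = dict(zip(out["sample_id"], out["ratio"]))
        assert ratios["s"] == pytest.approx(8.0, abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=5.0, max_value=20.99),
                    min_size=4, max_size=4))
    def test_e2_limit_equals_classic_ddct(self, cts):
        ct_goi_ctrl, ct_goi_s, ct_ref_ctrl, ct_ref_s = cts
        kept = kept_table({("ctrl", "goi"): ct_goi_ctrl, ("s", "goi"): ct_goi_s,
                           ("ctrl", "ref"): ct_ref_ctrl, ("s", "ref"): ct_ref_s})
        out = pfaffl_ratio(kept, {"goi": 2.0, "ref": 2.0}, "goi", ["ref"], "ctrl")
        ratio = out.set_index("sample_id").loc["s", "ratio"]
        ddct = (ct_goi_s - ct_goi_ctrl) - (ct_ref_s - ct_ref_ctrl)
        assert ratio == pytest.approx(2.0 ** (-ddct), rel=1e-9)

    def test_missing_control_reported_na(self):
        kept = kept_table({("s", "goi"): 18.0, ("s", "ref"): 20.0})
        out = pfaffl_ratio(kept, {"goi": 2.0, "ref": 2.0}, "goi", ["ref"], "ctrl")
        assert out["ratio"].isna().all()
        assert (out["reason"] != "").all()

    def test_direction_switch_inverts_ratio(self):
        kept = kept_table({("ctrl", "goi"): 20.0, ("s", "goi"): 18.0,
                           ("ctrl", "ref"): 20.0, ("s", "ref"): 20.0})
        fwd = pfaffl_ratio(kept, {"goi": 2.0, "ref": 2.0}, "goi", ["ref"], "ctrl")
        rev = pfaffl_ratio(kept, {"goi": 2.0, "ref": 2.0}, "goi", ["ref"], "ctrl",
                           direction="sample_minus_control")
        f = fwd.set_index("sample_id").loc["s", "ratio"]
        r = rev.set_index("sample_id").loc["s", "ratio"]
        assert f * r == pytest.approx(1.0)


class TestDeltaCtMatrix:
    def test_equal_cts_give_zero(self):
        kept = kept_table({("s", "goi"): 20.0, ("s", "ref"): 20.0})
        out = delta_ct_matrix(kept, ["ref"])
        assert out.loc["s", "goi"] == pytest.approx(0.0)

    def test_hand_computed_geometric_mean(self):
        kept = kept_table({("s", "goi"): 20.0, ("s", "r1"): 16.0,
                           ("s", "r2"): 18.0, ("s", "r3"): 20.25})
        out = delta_ct_matrix(kept, ["r1", "r2", "r3"])
        expected = 20.0 - (16.0 * 18.0 * 20.25) ** (1.0 / 3.0)
        assert out.loc["s", "goi"] == pytest.approx(expected)

    def test_sentinel_propagates_to_na(self):
        kept = kept_table({("s", "goi"): CT_SENTINEL, ("s", "ref"): 20.0})
        out = delta_ct_matrix(kept, ["ref"])
        assert math.isnan(out.loc["s", "goi"])

    def test_missing_reference_blanks_sample_row(self):
        kept = kept_table({("s1", "goi"): 20.0, ("s1", "ref"): 18.0,
                           ("s2", "goi"): 20.0})
        out = delta_ct_matrix(kept, ["ref"])
        assert not math.isnan(out.loc["s1", "goi"])
        assert math.isnan(out.loc["s2", "goi"])
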