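"""Replicate statistics, recovery, LOD/LOQ, t/F comparison, report builders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftirquant import (MethodSummary, ReplicateSet, accuracy_report, assay_report,
                       compare_methods_f, compare_methods_t, lod_loq, mg_per_tablet,
                       precision_report, recovery, replicate_stats)
from ftirquant.datasets import (load_assay_table, load_method_comparison_table,
                                load_repeatability_table)
from ftirquant.validation import round_half_up


class TestReplicateStats:
    @pytest.mark.parametrize("values,mean,sd,rsd", [
        ((4.44, 4.49, 4.54), 4.49, 0.041, 0.91),
        ((6.58, 6.56, 6.67), 6.60, 0.048, 0.72),
        ((2.63, 2.42, 2.41), 2.49, 0.10, 4.08),
        ((7.16, 6.43, 5.90), 6.50, 0.52, 7.95),
    ])
    def test_population_convention_reference_values(self, values, mean, sd, rsd):
        m, s, r = replicate_stats(ReplicateSet(values, sd_convention="population"))
        assert round_half_up(m, 2) == mean
        assert round_half_up(s, len(str(sd).split(".")[1])) == sd
        assert round_half_up(r, 2) == rsd

    def test_identical_values_zero_sd(self):
        m, s, r = replicate_stats(ReplicateSet((5.0, 5.0, 5.0)))
        assert (s, r) == (0.0, 0.0)

    def test_sample_vs_population_divisor(self):
        vals = (1.0, 2.0, 3.0)
        _, s_pop, _ = replicate_stats(ReplicateSet(vals, sd_convention="population"))
        _, s_smp, _ = replicate_stats(ReplicateSet(vals, sd_convention="sample"))
        assert s_smp == pytest.approx(s_pop * np.sqrt(3 / 2))

    def test_zero_mean_rsd_undefined(self):
        with pytest.raises(ZeroDivisionError):
            replicate_stats(ReplicateSet((-1.0, 1.0)))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            ReplicateSet((1.0,))

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=40, deadline=None)
    def test_rsd_scale_invariance(self, c):
        vals = (4.4, 4.6, 4.5)
        _, _, r1 = replicate_stats(ReplicateSet(vals))
        _, _, r2 = replicate_stats(ReplicateSet(tuple(c * v for v in vals)))
        assert r2 == pytest.approx(r1, rel=1e-9)


class TestRecovery:
    @pytest.mark.parametrize("found,ref,expected", [
        (0.493, 0.500, 98.60),
        (5.03, 5.0, 100.60),
        (1.0, 1.0, 100.0),
    ])
    def test_values(self, found, ref, expected):
        pct, _ = recovery(found, ref)
        assert round_half_up(pct, 2) == expected

    def test_acceptance_band(self):
        assert recovery(0.97, 1.0)[1] is False
        assert recovery(0.99, 1.0)[1] is True

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            recovery(1.0, 0.0)


class TestLodLoq:
    def test_direct_substitution(self):
        lod, loq = lod_loq(1.0, 1.0, 3.0)
        assert lod == pytest.approx(1.0)
        assert loq == pytest.approx(10.0 / 3.0)

    def test_zero_sd_degenerate(self):
        assert lod_loq(0.0, 1.0, 1.0) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        lod, loq = lod_loq(0.05, 0.05, 0.6)
        assert lod == pytest.approx(0.0125)
        assert loq == pytest.approx(0.0416667, rel=1e-4)

    def test_zero_mean_area_rejected(self):
        with pytest.raises(ZeroDivisionError):
            lod_loq(1.0, 1.0, 0.0)

    @given(st.floats(1e-6, 10.0), st.floats(1e-6, 10.0), st.floats(1e-6, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_loq_lod_ratio_is_ten_thirds(self, sd, c, m):
        lod, loq = lod_loq(sd, c, m)
        assert loq / lod == pytest.approx(10.0 / 3.0, rel=1e-12)


class TestCompareMethodsF:
    def test_reference_f_values(self):
        # reference: F = (larger SD / smaller SD)^2 on the published
        # method-comparison summaries (printed values rounded to 3 dp)
        expected = {("5/10", "AML"): 7.326, ("5/10", "ATV"): 1.784,
                    ("5/20", "AML"): 3.930, ("5/20", "ATV"): 2.904,
                    ("10/20", "AML"): 2.813, ("10/20", "ATV"): 1.017,
                    ("10/40", "AML"): 4.559, ("10/40", "ATV"): 1.512}
        df = load_method_comparison_table()
        for row in df.itertuples():
            a = MethodSummary(row.ftir_mean, row.ftir_sd, row.n, "FTIR")
            b = MethodSummary(row.hplc_mean, row.hplc_sd, row.n, "HPLC")
            f, sig = compare_methods_f(a, b, critical_value=19.25)
            # one printed value carries a rounding slip of 1 ulp
            assert f == pytest.approx(expected[(row.formulation, row.analyte)],
                                      abs=2e-3)
            assert not sig

    def test_symmetry_and_at_least_one(self):
        a = MethodSummary(100.0, 0.2, 5)
        b = MethodSummary(100.0, 0.5, 5)
        fa, _ = compare_methods_f(a, b)
        fb, _ = compare_methods_f(b, a)
        assert fa == fb >= 1.0

    def test_equal_sds_give_unity(self):
        a = MethodSummary(99.0, 0.3, 5)
        assert compare_methods_f(a, a)[0] == pytest.approx(1.0)

    def test_zero_denominator_flagged_infinite(self):
        a = MethodSummary(100.0, 0.0, 5)
        b = MethodSummary(100.0, 0.3, 5)
        with pytest.warns(UserWarning, match="infinite"):
            f, sig = compare_methods_f(a, b)
        assert np.isinf(f) and sig


class TestCompareMethodsT:
    def test_identical_summaries_zero(self):
        a = MethodSummary(100.0, 0.3, 5)
        t, df, sig = compare_methods_t(a, a)
        assert t == pytest.approx(0.0) and not sig
        assert df == 8.0

    def test_pooled_formula_hand_case(self):
        a = MethodSummary(100.31, 0.167, 5)
        b = MethodSummary(99.69, 0.452, 5)
        t, _, _ = compare_methods_t(a, b)
        assert t == pytest.approx(2.877, abs=1e-3)

    def test_extreme_difference_flagged(self):
        a = MethodSummary(100.0, 0.3, 5)
        b = MethodSummary(110.0, 0.3, 5)
        assert compare_methods_t(a, b)[2]

    def test_pooled_matches_raw_sample_oracle(self):
        """Summary-stat pooled t equals scipy's ttest_ind on raw samples
        constructed to have exactly those summary statistics."""
        from scipy import stats as sps
        rng = np.random.default_rng(3)
        for _ in range(20):
            xa = rng.normal(100, 0.5, 5)
            xb = rng.normal(99, 1.0, 5)
            a = MethodSummary(xa.mean(), xa.std(ddof=1), 5)
            b = MethodSummary(xb.mean(), xb.std(ddof=1), 5)
            t, df, _ = compare_methods_t(a, b, variant="pooled")
            ref = sps.ttest_ind(xa, xb)
            assert t == pytest.approx(abs(ref.statistic), abs=1e-9)
            t_w, df_w, _ = compare_methods_t(a, b, variant="welch")
            ref_w = sps.ttest_ind(xa, xb, equal_var=False)
            assert t_w == pytest.approx(abs(ref_w.statistic), abs=1e-9)
            assert df_w == pytest.approx(ref_w.df, abs=1e-9)


class TestAccuracyReport:
    def test_reference_standard_addition_levels(self):
        # AML standard-addition: found means at 0.400/0.500/0.600 % w/w
        levels = [(0.400, ReplicateSet((0.400, 0.400), sd_convention="population")),
                  (0.500, ReplicateSet((0.493, 0.493), sd_convention="population")),
                  (0.600, ReplicateSet((0.609, 0.609), sd_convention="population"))]
        df = accuracy_report(levels)
        assert [round_half_up(v, 2) for v in df["recovery_pct"]] == \
            [100.00, 98.60, 101.50]
        assert round_half_up(df.attrs["mean_recovery"], 2) == 100.03
        assert round_half_up(df.attrs["recovery_sd"], 2) == 1.18
        assert df.attrs["accepted"]

    def test_perfect_recovery_passes(self):
        levels = [(c, ReplicateSet((c, c, c))) for c in (0.4, 0.5, 0.6)]
        df = accuracy_report(levels)
        assert df.attrs["mean_recovery"] == pytest.approx(100.0)
        assert df.attrs["accepted"]

    def test_out_of_band_level_fails(self):
        levels = [(0.5, ReplicateSet((0.45, 0.45)))]
        assert not accuracy_report(levels).attrs["accepted"]


class TestPrecisionReport:
    def test_repeatability_reference_gate(self):
        groups = {f"AML {lvl}": ReplicateSet(vals, sd_convention="population")
                  for lvl, vals in load_repeatability_table("AML").items()}
        df = precision_report(groups)
        assert df.attrs["accepted"]
        assert df["rsd_pct"].max() <= 2.0

    def test_noisy_group_fails_gate(self):
        df = precision_report({"bad": ReplicateSet((1.0, 2.0, 3.0))})
        assert not df.attrs["accepted"]


class TestAssay:
    def test_reference_tablet_recoveries(self):
        df = load_assay_table()
        samples = [{"analyte": r.analyte, "labeled_mg": r.labeled_mg,
                    "found_mg": r.found_mg, "found_sd": r.sd}
                   for r in df.itertuples()]
        results = assay_report(samples)
        by_key = {(r.analyte, r.labeled_mg, round_half_up(r.found_mg, 3)): r
                  for r in results}
        s04_aml = by_key[("AML", 5, 5.03)]
        assert round_half_up(s04_aml.recovery_pct, 2) == 100.60
        assert s04_aml.compliant
        s04_atv = by_key[("ATV", 80, 79.63)]
        assert round_half_up(s04_atv.recovery_pct, 2) == 99.54
        assert s04_atv.compliant
        assert all(r.compliant for r in results)

    def test_found_equals_label(self):
        r, = assay_report([{"analyte": "AML", "labeled_mg": 5.0, "found_mg": 5.0}])
        assert r.recovery_pct == pytest.approx(100.0) and r.compliant

    def test_spiked_sample_arithmetic(self):
        # 0.5% w/w pellet of 100 mg -> 0.5 mg analyte; 0.3 mg was spiked;
        # the 0.2 mg left came from 4 mg of powder from a 200 mg tablet
        mg = mg_per_tablet(0.5, 100.0, 4.0, 200.0, spiked_mg=0.3)
        assert mg == pytest.approx((0.5 - 0.3) * 200.0 / 4.0)

    def test_spiked_sample_requires_spike_amount(self):
        with pytest.raises(ValueError, match="spiked_mg"):
            assay_report([{"analyte": "AML", "labeled_mg": 5.0, "spiked": True,
                           "predicted_pct": 0.5, "pellet_mass_mg": 100.0,
                           "sample_mass_mg": 4.0, "tablet_mass_mg": 200.0}])

    def test_noncompliant_flagged(self):
        r, = assay_report([{"analyte": "ATV", "labeled_mg": 10.0, "found_mg": 9.0}])
        assert not r.compliant  # 90% is outside the 94.5-105 ATV band


def test_round_half_up_at_five():
    assert round_half_up(2.5) == 3.0
    assert round_half_up(0.3145, 3) == 0.315  # bankers' rounding would give 0.314
    assert round_half_up(-2.5) == -3.0
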