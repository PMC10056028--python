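"""Interpretation rule, contingency metrics, association tests, tables."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dopapet as dp
from dopapet.cohort import Call, Diagnosis
from dopapet.evaluate import (ContingencyTable, cohort_indicators, percent,
                              reproduce_reference_tables)


class TestInterpretationAlgorithm:
    @pytest.mark.parametrize("va, por, expected", [
        (Call.POSITIVE, 0.5, Call.POSITIVE),   # POR never overrides a positive read
        (Call.NEGATIVE, 1.57, Call.POSITIVE),  # fallback, inclusive cutoff
        (Call.NEGATIVE, 1.0, Call.NEGATIVE),
        (Call.EQUIVOCAL, 1.0, Call.NEGATIVE),  # equivocal routed like negative
        (Call.EQUIVOCAL, 2.0, Call.POSITIVE),
    ])
    def test_routing(self, va, por, expected):
        assert dp.apply_interpretation_algorithm(va, por) is expected

    def test_positive_visual_read_needs_no_por(self):
        assert dp.apply_interpretation_algorithm(
            Call.POSITIVE, None) is Call.POSITIVE

    def test_missing_por_on_fallback_branch_rejected(self):
        with pytest.raises(ValueError, match="POR"):
            dp.apply_interpretation_algorithm(Call.NEGATIVE, None)

    def test_equals_or_rule_without_equivocal_reads(self):
        """Structural identity with OR(visual, POR>=cutoff) on random cohorts."""
        rng = np.random.default_rng(6)
        for _ in range(200):
            va = Call.POSITIVE if rng.random() < 0.5 else Call.NEGATIVE
            por = float(rng.lognormal(0.4, 0.4))
            por_call = Call.POSITIVE if por >= dp.POR_CUTOFF else Call.NEGATIVE
            assert dp.apply_interpretation_algorithm(va, por) is \
                dp.combine_or(va, por_call)


class TestCombiners:
    def test_truth_tables(self):
        P, N = Call.POSITIVE, Call.NEGATIVE
        assert dp.combine_or(N, P) is P
        assert dp.combine_or(N, N) is N
        assert dp.combine_and(N, P) is N
        assert dp.combine_and(P, P) is P

    def test_equivocal_rejected(self):
        with pytest.raises(ValueError, match="EQUIVOCAL"):
            dp.combine_or(Call.EQUIVOCAL, Call.POSITIVE)


class TestContingency:
    def test_visual_read_on_reconstructed_cohort(self, cohort0):
        calls = [r.va_bg_call for r in cohort0]
        labels = [r.true_label for r in cohort0]
        t = dp.contingency(calls, labels)
        assert (t.tp, t.fp, t.fn, t.tn) == (61, 3, 8, 40)

    def test_automated_read_on_reconstructed_cohort(self, cohort0):
        t = dp.contingency([r.am_bg_call for r in cohort0],
                           [r.true_label for r in cohort0])
        assert (t.tp, t.fp) == (37, 3)

    def test_all_positive(self):
        t = dp.contingency([Call.POSITIVE] * 4,
                           [Diagnosis.NSD, Diagnosis.NSD,
                            Diagnosis.NON_NSD, Diagnosis.NON_NSD])
        assert (t.fn, t.tn) == (0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            dp.contingency([Call.POSITIVE], [])


class TestPerformance:
    def test_visual_read_metrics(self):
        rep = dp.performance(ContingencyTable(61, 3, 8, 40))
        assert rep.sensitivity.fraction == Fraction(61, 69)
        assert rep.sensitivity.pct == 88.4
        assert rep.specificity.pct == 93.0
        assert rep.accuracy.fraction == Fraction(101, 112)
        assert rep.accuracy.pct == 90.2
        assert rep.ppv.pct == 95.3
        assert rep.npv.pct == 83.3

    def test_automated_read_metrics(self):
        rep = dp.performance(ContingencyTable(37, 3, 32, 40))
        assert rep.accuracy.fraction == Fraction(77, 112)
        assert rep.accuracy.pct == 68.8
        assert rep.npv.fraction == Fraction(40, 72)
        assert rep.npv.pct == 55.6

    def test_perfect_classifier(self):
        rep = dp.performance(ContingencyTable(1, 0, 0, 1))
        assert all(m.pct == 100.0 for m in rep.as_dict().values())

    def test_zero_denominator_flagged_not_zero(self):
        rep = dp.performance(ContingencyTable(0, 0, 3, 5))
        assert not rep.ppv.defined
        assert rep.ppv.pct is None
        assert "undefined" in str(rep.ppv)

    def test_accuracy_is_prevalence_weighted_mean(self):
        """accuracy = prev*sens + (1-prev)*spec, any table."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 50, size=4)
            rep = dp.performance(ContingencyTable(tp, fp, fn, tn))
            n = tp + fp + fn + tn
            acc = (rep.sensitivity.fraction * Fraction(int(tp + fn), int(n))
                   + rep.specificity.fraction * Fraction(int(tn + fp), int(n)))
            assert rep.accuracy.fraction == acc

    def test_percent_rounds_half_up(self):
        assert percent(1, 8) == 12.5
        assert percent(29, 30) == 96.7
        assert percent(63, 69) == 91.3
        assert percent(1, 16) == 6.3   # 6.25 rounds up, not to even


class TestAssociation:
    def test_visual_read_highly_significant(self):
        res = dp.association_test(ContingencyTable(61, 3, 8, 40))
        assert res.test_used == "CHI_SQUARE"
        assert res.p_value < 0.01

    def test_visual_pineal_read_significant(self):
        res = dp.association_test(ContingencyTable(48, 17, 21, 26))
        assert res.p_value < 0.01

    def test_null_case_large_counts(self):
        res = dp.association_test(ContingencyTable(50, 50, 50, 50))
        assert res.p_value > 0.9

    def test_small_expected_counts_use_fisher(self):
        res = dp.association_test(ContingencyTable(2, 1, 3, 4))
        assert res.test_used == "FISHER_EXACT"
        assert 0 <= res.p_value <= 1


class TestDominance:
    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_or_sensitivity_and_and_specificity_dominate(self, data):
        n = data.draw(st.integers(6, 60))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        labels = [Diagnosis.NSD if rng.random() < 0.5 else Diagnosis.NON_NSD
                  for _ in range(n)]
        labels[0], labels[1] = Diagnosis.NSD, Diagnosis.NON_NSD  # both classes
        a = [Call.POSITIVE if rng.random() < 0.5 else Call.NEGATIVE
             for _ in range(n)]
        b = [Call.POSITIVE if rng.random() < 0.5 else Call.NEGATIVE
             for _ in range(n)]
        or_calls = [dp.combine_or(x, y) for x, y in zip(a, b)]
        and_calls = [dp.combine_and(x, y) for x, y in zip(a, b)]
        perf = {k: dp.performance(dp.contingency(c, labels))
                for k, c in (("a", a), ("b", b), ("or", or_calls),
                             ("and", and_calls))}
        assert perf["or"].sensitivity.fraction >= max(
            perf["a"].sensitivity.fraction, perf["b"].sensitivity.fraction)
        assert perf["and"].specificity.fraction >= max(
            perf["a"].specificity.fraction, perf["b"].specificity.fraction)


class TestFalseNegativeRate:
    def test_visual_alone_vs_two_stage_rule(self, cohort0):
        labels = [r.true_label for r in cohort0]
        va = [r.va_bg_call for r in cohort0]
        algo = [dp.apply_interpretation_algorithm(r.va_bg_call, r.por)
                for r in cohort0]
        assert dp.false_negative_rate(va, labels).fraction == Fraction(8, 112)
        assert dp.false_negative_rate(va, labels).pct == 7.1
        assert dp.false_negative_rate(algo, labels).fraction == Fraction(1, 112)
        assert dp.false_negative_rate(algo, labels).pct == 0.9

    def test_perfect_classifier(self):
        m = dp.false_negative_rate(
            [Call.POSITIVE, Call.NEGATIVE], [Diagnosis.NSD, Diagnosis.NON_NSD])
        assert m.fraction == 0


class TestTables:
    def test_verification_passes_on_reconstructed_cohort(self, cohort0):
        report = reproduce_reference_tables(cohort0, verify=True)
        por_row = report.pineal_positivity.set_index("criterion").loc["por"]
        assert (por_row["nsd_positive"], por_row["non_nsd_positive"]) == (44, 11)
        suv_row = report.pineal_positivity.set_index("criterion").loc["suvmax"]
        assert (suv_row["nsd_positive"], suv_row["non_nsd_positive"]) == (47, 14)

    def test_combination_rows(self, cohort0):
        report = reproduce_reference_tables(cohort0)
        perf = report.pineal_performance.set_index("criterion")
        assert perf.loc["va_and_por", "ppv"] == "37/37 (100.0%)"
        # 68/69 = 98.55% -> 98.6 under half-up (published table truncates)
        assert perf.loc["va_or_por", "sensitivity"] == "68/69 (98.6%)"
        assert perf.loc["va_or_por", "npv"] == "29/30 (96.7%)"

    def test_verification_fails_on_perturbed_cohort(self, cohort0):
        from dataclasses import replace
        bad = list(cohort0)
        flip = next(i for i, r in enumerate(bad)
                    if r.va_bg_call is Call.NEGATIVE)
        bad[flip] = replace(bad[flip], va_bg_call=Call.POSITIVE)
        with pytest.raises(ValueError, match="verification failed"):
            reproduce_reference_tables(bad, verify=True)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            reproduce_reference_tables([])

    def test_missing_indicator_names_blocked_row(self, cohort0):
        from dataclasses import replace
        bad = [replace(r, am_bg_call=None) for r in cohort0]
        with pytest.raises(ValueError, match="AM-BG"):
            cohort_indicators(bad)


class TestDiagnosticStudyModel:
    def test_summary_carries_headline_numbers(self, cohort0):
        results = dp.DiagnosticStudy(cohort0).fit()
        text = results.summary()
        assert "112" in text
        assert "8/112 (7.1%)" in text
        assert "1/112 (0.9%)" in text

    def test_from_csv_matches_in_memory(self, cohort0, tmp_path):
        path = tmp_path / "cohort.csv"
        dp.write_cohort(cohort0, path)
        a = dp.DiagnosticStudy.from_csv(path).fit()
        b = dp.DiagnosticStudy(cohort0).fit()
        assert a.tables.bg_performance.equals(b.tables.bg_performance)

    def test_custom_cutoffs_change_calls(self, cohort0):
        strict = dp.DiagnosticStudy(cohort0, por_cutoff=10.0).fit()
        t = strict.contingency["por"]
        assert t.tp + t.fp == 0  # nobody reaches a POR of 10
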