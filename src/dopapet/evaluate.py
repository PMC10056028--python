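"""Diagnostic-performance evaluation and the two-stage interpretation rule.

The two-stage interpretation rule for ¹⁸F-DOPA PET reads: a scan positive on
the visual basal-ganglia read (VA-BG) is reported positive outright; a
negative or equivocal visual read falls back to the pineal-to-occipital ratio
and is reported positive iff POR >= 1.57.  When no visual read is equivocal
the rule is identically OR(VA-BG, POR >= 1.57).

``DiagnosticStudy(cohort).fit()`` evaluates every criterion and combination
on a cohort and reproduces the four published summary tables (positivity by
group with association tests; full five-metric performance) as exact count
fractions.  Percentages are rounded half-up to one decimal; the fractions
are the source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.stats.contingency import expected_freq

from .cohort import (Call, Diagnosis, PatientRecord, POR_CUTOFF, STUDY_COUNTS,
                     SUVMAX_CUTOFF)

__all__ = [
    "ContingencyTable",
    "Metric",
    "PerformanceReport",
    "AssociationResult",
    "apply_interpretation_algorithm",
    "combine_or",
    "combine_and",
    "contingency",
    "performance",
    "association_test",
    "false_negative_rate",
    "percent",
    "cohort_indicators",
    "reproduce_reference_tables",
    "TableReport",
    "DiagnosticStudy",
    "DiagnosticStudyResults",
]


def percent(numerator: int, denominator: int) -> float:
    """100·num/den rounded half-up to one decimal (the printed convention)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


# ---------------------------------------------------------------------------
# interpretation rules
# ---------------------------------------------------------------------------

def apply_interpretation_algorithm(va_call: Call, por: float | None,
                                   por_cutoff: float = POR_CUTOFF) -> Call:
    """Two-stage read: visual call first, POR fallback when not positive.

    A positive visual read is never overridden.  Negative and equivocal reads
    are routed identically to the POR criterion; ``por`` must be available on
    that branch.
    """
    if va_call is Call.POSITIVE:
        return Call.POSITIVE
    if por is None:
        raise ValueError(
            f"POR is required when the visual call is {va_call.value}")
    return Call.POSITIVE if por >= por_cutoff else Call.NEGATIVE


def _as_binary(call: Call, side: str) -> bool:
    if call is Call.EQUIVOCAL:
        raise ValueError(f"{side} call must be binary, got EQUIVOCAL")
    return call is Call.POSITIVE


def combine_or(call_a: Call, call_b: Call) -> Call:
    a, b = _as_binary(call_a, "first"), _as_binary(call_b, "second")
    return Call.POSITIVE if a or b else Call.NEGATIVE


def combine_and(call_a: Call, call_b: Call) -> Call:
    a, b = _as_binary(call_a, "first"), _as_binary(call_b, "second")
    return Call.POSITIVE if a and b else Call.NEGATIVE


# ---------------------------------------------------------------------------
# contingency and performance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """2×2 array, rows = true class (diseased, healthy), cols = (pos, neg)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def contingency(calls: Sequence[Call], labels: Sequence[Diagnosis]
                ) -> ContingencyTable:
    """Cross-tabulate binary calls against true diagnoses."""
    if len(calls) != len(labels):
        raise ValueError("calls and labels must have equal length")
    tp = fp = fn = tn = 0
    for call, label in zip(calls, labels):
        pos = _as_binary(call, "patient")
        if label is Diagnosis.NSD:
            tp, fn = tp + pos, fn + (not pos)
        else:
            fp, tn = fp + pos, tn + (not pos)
    return ContingencyTable(tp, fp, fn, tn)


@dataclass(frozen=True)
class Metric:
    """An exact count fraction with its printed-style percentage.

    ``fraction`` is ``None`` when the metric's denominator is zero (flagged
    undefined rather than silently reported as 0).
    """

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def fraction(self) -> Fraction | None:
        return Fraction(self.numerator, self.denominator) if self.defined else None

    @property
    def pct(self) -> float | None:
        return percent(self.numerator, self.denominator) if self.defined else None

    def __str__(self) -> str:
        if not self.defined:
            return "undefined (0 denominator)"
        return f"{self.numerator}/{self.denominator} ({self.pct}%)"


@dataclass(frozen=True)
class PerformanceReport:
    sensitivity: Metric
    specificity: Metric
    accuracy: Metric
    ppv: Metric
    npv: Metric

    def as_dict(self) -> dict[str, Metric]:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "accuracy": self.accuracy, "ppv": self.ppv, "npv": self.npv}


def performance(t: ContingencyTable) -> PerformanceReport:
    """The five diagnostic-performance metrics as exact count fractions."""
    return PerformanceReport(
        sensitivity=Metric(t.tp, t.tp + t.fn),
        specificity=Metric(t.tn, t.tn + t.fp),
        accuracy=Metric(t.tp + t.tn, t.total),
        ppv=Metric(t.tp, t.tp + t.fp),
        npv=Metric(t.tn, t.tn + t.fn),
    )


@dataclass(frozen=True)
class AssociationResult:
    test_used: str  # "CHI_SQUARE" or "FISHER_EXACT"
    statistic: float | None
    p_value: float


def association_test(t: ContingencyTable) -> AssociationResult:
    """Group-vs-call association: Pearson χ² (no continuity correction), or
    Fisher's exact test when any expected cell count is below 5.  Two-sided.
    """
    table = t.as_array()
    if np.any(expected_freq(table) < 5):
        res = _sps.fisher_exact(table, alternative="two-sided")
        return AssociationResult("FISHER_EXACT", None, float(res.pvalue))
    res = _sps.chi2_contingency(table, correction=False)
    return AssociationResult("CHI_SQUARE", float(res.statistic),
                             float(res.pvalue))


def false_negative_rate(calls: Sequence[Call], labels: Sequence[Diagnosis]
                        ) -> Metric:
    """False negatives as a fraction of the whole cohort."""
    t = contingency(calls, labels)
    return Metric(t.fn, t.total)


# ---------------------------------------------------------------------------
# cohort indicators and table reproduction
# ---------------------------------------------------------------------------

_CRITERIA = ("va_bg", "am_bg", "va_pb", "suvmax", "por")
_ROW_LABELS = {
    "va_bg": "VA-BG",
    "am_bg": "AM-BG",
    "va_pb": "VA-PB",
    "suvmax": f"SUVmax >= {SUVMAX_CUTOFF}",
    "por": f"POR >= {POR_CUTOFF}",
    "va_or_am": "VA-BG OR AM-BG",
    "va_and_am": "VA-BG AND AM-BG",
    "va_or_por": f"VA-BG OR POR >= {POR_CUTOFF}",
    "va_and_por": f"VA-BG AND POR >= {POR_CUTOFF}",
    "algorithm": "Two-stage algorithm (VA-BG, POR fallback)",
}


def cohort_indicators(cohort: Sequence[PatientRecord],
                      por_cutoff: float = POR_CUTOFF,
                      suvmax_cutoff: float = SUVMAX_CUTOFF) -> pd.DataFrame:
    """Per-patient binary calls for every criterion and combination.

    Raises ``ValueError`` naming the first table row a missing optional
    indicator blocks.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rows = []
    for r in cohort:
        if r.am_bg_call is None:
            raise ValueError(
                f"patient {r.patient_id}: missing AM-BG call blocks the "
                f"'{_ROW_LABELS['am_bg']}' rows")
        if r.visual_pineal_call is None:
            raise ValueError(
                f"patient {r.patient_id}: missing visual pineal call blocks "
                f"the '{_ROW_LABELS['va_pb']}' rows")
        va = Call.POSITIVE if r.va_bg_call is Call.POSITIVE else Call.NEGATIVE
        por_call = Call.POSITIVE if r.por >= por_cutoff else Call.NEGATIVE
        suv_call = (Call.POSITIVE if r.pineal_suvmax >= suvmax_cutoff
                    else Call.NEGATIVE)
        rows.append({
            "patient_id": r.patient_id,
            "label": r.true_label,
            "va_bg": va,
            "am_bg": r.am_bg_call,
            "va_pb": r.visual_pineal_call,
            "suvmax": suv_call,
            "por": por_call,
            "va_or_am": combine_or(va, r.am_bg_call),
            "va_and_am": combine_and(va, r.am_bg_call),
            "va_or_por": combine_or(va, por_call),
            "va_and_por": combine_and(va, por_call),
            "algorithm": apply_interpretation_algorithm(
                r.va_bg_call, r.por, por_cutoff),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TableReport:
    """The four summary tables, as exact fractions and rounded percentages.

    ``bg_positivity`` / ``pineal_positivity``: per-group positivity with the
    association test.  ``bg_performance`` / ``pineal_performance``: the five
    metrics per criterion / combination.
    """

    bg_positivity: pd.DataFrame
    bg_performance: pd.DataFrame
    pineal_positivity: pd.DataFrame
    pineal_performance: pd.DataFrame

    def verify(self) -> None:
        """Assert every reproducible cell against the published counts.

        Raises ``ValueError`` listing all mismatches.
        """
        expected = _expected_published_cells()
        errors = []
        for table_name in ("bg_positivity", "pineal_positivity"):
            df = getattr(self, table_name)
            for _, row in df.iterrows():
                key = row["criterion"]
                if key not in expected["positivity"]:
                    continue
                want = expected["positivity"][key]
                got = (row["nsd_positive"], row["non_nsd_positive"])
                if got != want:
                    errors.append(
                        f"{table_name} {_ROW_LABELS[key]}: positivity {got} "
                        f"!= published {want}")
                if row["p_value"] >= 0.01:
                    errors.append(
                        f"{table_name} {_ROW_LABELS[key]}: p = "
                        f"{row['p_value']:.3g} not < 0.01")
        for table_name in ("bg_performance", "pineal_performance"):
            df = getattr(self, table_name)
            for _, row in df.iterrows():
                key = row["criterion"]
                if key not in expected["contingency"]:
                    continue
                want = expected["contingency"][key]
                got = (row["tp"], row["fp"], row["fn"], row["tn"])
                if got != want:
                    errors.append(
                        f"{table_name} {_ROW_LABELS[key]}: cells "
                        f"(tp,fp,fn,tn) {got} != published {want}")
        if errors:
            raise ValueError("published-count verification failed:\n  "
                             + "\n  ".join(errors))

    def to_text(self) -> str:
        out = []
        for title, df in (
                ("Basal-ganglia criteria: positivity by group", self.bg_positivity),
                ("Basal-ganglia criteria: diagnostic performance", self.bg_performance),
                ("Pineal criteria: positivity by group", self.pineal_positivity),
                ("Pineal criteria: diagnostic performance", self.pineal_performance)):
            out.append(title)
            out.append(df.to_string(index=False))
            out.append("")
        return "\n".join(out)


def _expected_published_cells() -> dict:
    c = STUDY_COUNTS
    n1, n0 = c["n_nsd"], c["n_non_nsd"]

    def cells(a, b):
        return (a, b, n1 - a, n0 - b)

    positivity = {k: c[k] for k in _CRITERIA}
    or_am = (c["va_bg"][0] + c["am_bg"][0] - c["va_and_am"][0],
             c["va_bg"][1] + c["am_bg"][1] - c["va_and_am"][1])
    or_por = (c["va_bg"][0] + c["por"][0] - c["va_and_por"][0],
              c["va_bg"][1] + c["por"][1] - c["va_and_por"][1])
    contingency_cells = {k: cells(*c[k]) for k in _CRITERIA}
    contingency_cells.update({
        "va_or_am": cells(*or_am),
        "va_and_am": cells(*c["va_and_am"]),
        "va_or_por": cells(*or_por),
        "va_and_por": cells(*c["va_and_por"]),
        "algorithm": cells(*or_por),
    })
    return {"positivity": positivity, "contingency": contingency_cells}


def _positivity_frame(ind: pd.DataFrame, criteria: Sequence[str]) -> pd.DataFrame:
    rows = []
    labels = np.asarray([l is Diagnosis.NSD for l in ind["label"]])
    n1, n0 = int(labels.sum()), int((~labels).sum())
    for key in criteria:
        pos = np.asarray([c is Call.POSITIVE for c in ind[key]])
        a, b = int(pos[labels].sum()), int(pos[~labels].sum())
        t = ContingencyTable(a, b, n1 - a, n0 - b)
        assoc = association_test(t)
        rows.append({
            "criterion": key, "label": _ROW_LABELS[key],
            "nsd_positive": a, "nsd_total": n1, "nsd_pct": percent(a, n1),
            "non_nsd_positive": b, "non_nsd_total": n0,
            "non_nsd_pct": percent(b, n0),
            "test": assoc.test_used, "p_value": assoc.p_value,
        })
    return pd.DataFrame(rows)


def _performance_frame(ind: pd.DataFrame, criteria: Sequence[str]) -> pd.DataFrame:
    rows = []
    for key in criteria:
        t = contingency(list(ind[key]), list(ind["label"]))
        rep = performance(t)
        row = {"criterion": key, "label": _ROW_LABELS[key],
               "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn}
        for mname, m in rep.as_dict().items():
            row[mname] = str(m)
            row[f"{mname}_pct"] = m.pct
        rows.append(row)
    return pd.DataFrame(rows)


def reproduce_reference_tables(cohort: Sequence[PatientRecord],
                               verify: bool = False) -> TableReport:
    """Recompute the four published summary tables from a cohort.

    With ``verify=True`` every published cell is asserted (raises
    ``ValueError`` listing mismatches) — meaningful for cohorts generated in
    reconstructed mode.
    """
    ind = cohort_indicators(cohort)
    report = TableReport(
        bg_positivity=_positivity_frame(ind, ["va_bg", "am_bg"]),
        bg_performance=_performance_frame(
            ind, ["va_bg", "am_bg", "va_or_am", "va_and_am"]),
        pineal_positivity=_positivity_frame(ind, ["va_pb", "suvmax", "por"]),
        pineal_performance=_performance_frame(
            ind, ["va_bg", "va_pb", "suvmax", "por", "va_or_por",
                  "va_and_por", "algorithm"]),
    )
    if verify:
        report.verify()
    return report


# ---------------------------------------------------------------------------
# model-style wrapper
# ---------------------------------------------------------------------------

class DiagnosticStudy:
    """Diagnostic-accuracy evaluation of a cohort, statsmodels-style.

    ``fit()`` computes the per-patient indicator matrix, the four summary
    tables, contingency tables for every criterion and the whole-cohort
    false-negative rates of the visual read alone versus the two-stage
    interpretation rule.
    """

    def __init__(self, cohort: Sequence[PatientRecord],
                 por_cutoff: float = POR_CUTOFF,
                 suvmax_cutoff: float = SUVMAX_CUTOFF):
        if len(cohort) == 0:
            raise ValueError("cohort is empty")
        self.cohort = list(cohort)
        self.por_cutoff = por_cutoff
        self.suvmax_cutoff = suvmax_cutoff

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DiagnosticStudy":
        from .cohort import read_cohort
        return cls(read_cohort(path), **kwargs)

    def fit(self) -> "DiagnosticStudyResults":
        return DiagnosticStudyResults(self)


class DiagnosticStudyResults:
    def __init__(self, model: DiagnosticStudy):
        self.model = model
        self.indicators = cohort_indicators(
            model.cohort, model.por_cutoff, model.suvmax_cutoff)
        self.tables = TableReport(
            bg_positivity=_positivity_frame(self.indicators, ["va_bg", "am_bg"]),
            bg_performance=_performance_frame(
                self.indicators, ["va_bg", "am_bg", "va_or_am", "va_and_am"]),
            pineal_positivity=_positivity_frame(
                self.indicators, ["va_pb", "suvmax", "por"]),
            pineal_performance=_performance_frame(
                self.indicators, ["va_bg", "va_pb", "suvmax", "por",
                                  "va_or_por", "va_and_por", "algorithm"]),
        )
        labels = list(self.indicators["label"])
        self.contingency: dict[str, ContingencyTable] = {
            key: contingency(list(self.indicators[key]), labels)
            for key in self.indicators.columns
            if key not in ("patient_id", "label")}
        self.performance: dict[str, PerformanceReport] = {
            key: performance(t) for key, t in self.contingency.items()}
        self.fn_rate_visual = false_negative_rate(
            list(self.indicators["va_bg"]), labels)
        self.fn_rate_algorithm = false_negative_rate(
            list(self.indicators["algorithm"]), labels)

    def summary(self) -> str:
        n = len(self.model.cohort)
        n1 = sum(r.true_label is Diagnosis.NSD for r in self.model.cohort)
        head = [
            "Diagnostic accuracy study",
            f"  subjects: {n} ({n1} NSD, {n - n1} non-NSD)",
            f"  pineal cutoffs: SUVmax >= {self.model.suvmax_cutoff}, "
            f"POR >= {self.model.por_cutoff}",
            f"  false-negative rate, visual read alone: {self.fn_rate_visual}",
            f"  false-negative rate, two-stage rule:    {self.fn_rate_algorithm}",
            "",
        ]
        return "\n".join(head) + self.tables.to_text()
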