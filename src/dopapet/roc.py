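"""ROC curves, AUC and Youden-optimal cutoff selection.

Candidate thresholds are the distinct observed scores plus a +inf sentinel,
with the '>= threshold is positive' rule, so a selected cutoff is always an
attainable data value (the clinical cutoffs 0.72 and 1.57 were published as
such values).  The optimal cutoff maximizes sensitivity + specificity; ties
are broken toward higher specificity, then toward the lower cutoff.

``CutpointAnalysis`` wraps the procedure as a small model object:
``CutpointAnalysis(scores, labels).fit()`` returns a ``CutpointResults`` with
the curve, AUC, selected cutoff and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .cohort import Call, Diagnosis

__all__ = [
    "RocCurve",
    "OptimalCutoff",
    "roc_curve",
    "optimal_cutoff",
    "dichotomize",
    "CutpointAnalysis",
    "CutpointResults",
]


def _as_bool_labels(labels) -> np.ndarray:
    out = np.asarray([
        l.value == "NSD" if isinstance(l, Diagnosis) else bool(l)
        for l in labels])
    return out


@dataclass(frozen=True)
class RocCurve:
    """Thresholds (ascending, last = +inf) with sens/spec at each, plus AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


@dataclass(frozen=True)
class OptimalCutoff:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_sum(self) -> float:
        return self.sensitivity + self.specificity


def roc_curve(scores: Sequence[float], labels) -> RocCurve:
    """ROC over the distinct observed scores (plus +inf sentinel).

    ``labels`` may be booleans (True = diseased) or ``Diagnosis`` values.
    Raises ``ValueError`` if only one class is present or scores are missing.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if scores.shape[0] != y.shape[0]:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite (no missing values)")
    if y.all() or not y.any():
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = _skm.roc_curve(y, scores, drop_intermediate=False)
    # sklearn returns thresholds descending with a +inf sentinel first;
    # reorder ascending and recompute spec = 1 - fpr.
    return RocCurve(
        thresholds=thr[::-1].copy(),
        sensitivity=tpr[::-1].copy(),
        specificity=(1.0 - fpr[::-1]).copy(),
        auc=float(_skm.roc_auc_score(y, scores)),
    )


def optimal_cutoff(curve: RocCurve) -> OptimalCutoff:
    """Threshold maximizing sensitivity + specificity (Youden criterion).

    Deterministic tie-breaks: highest specificity, then lowest cutoff value.
    """
    youden = curve.sensitivity + curve.specificity
    best = 0
    for i in range(1, len(curve.thresholds)):
        if (youden[i], curve.specificity[i], -curve.thresholds[i]) > \
                (youden[best], curve.specificity[best], -curve.thresholds[best]):
            best = i
    return OptimalCutoff(float(curve.thresholds[best]),
                         float(curve.sensitivity[best]),
                         float(curve.specificity[best]))


def dichotomize(scores: Sequence[float], cutoff: float) -> list[Call]:
    """Positive iff score >= cutoff."""
    return [Call.POSITIVE if s >= cutoff else Call.NEGATIVE
            for s in np.asarray(scores, dtype=float)]


class CutpointAnalysis:
    """Optimal-cutpoint model for one continuous criterion.

    Parameters
    ----------
    scores : continuous criterion values (e.g. POR), one per subject.
    labels : true diagnoses (``Diagnosis`` values or booleans, True = NSD).
    name : criterion name used in the summary.
    """

    def __init__(self, scores, labels, name: str = "score"):
        self.scores = np.asarray(scores, dtype=float)
        self.labels = _as_bool_labels(labels)
        self.name = name

    def fit(self) -> "CutpointResults":
        curve = roc_curve(self.scores, self.labels)
        return CutpointResults(self, curve, optimal_cutoff(curve))


class CutpointResults:
    """Fitted ROC curve and selected cutoff, with summary/plot/export."""

    def __init__(self, model: CutpointAnalysis, curve: RocCurve,
                 cutoff: OptimalCutoff):
        self.model = model
        self.curve = curve
        self.cutoff = cutoff

    @property
    def auc(self) -> float:
        return self.curve.auc

    def calls(self) -> list[Call]:
        """Dichotomize the model's scores at the selected cutoff."""
        return dichotomize(self.model.scores, self.cutoff.cutoff)

    def summary(self) -> str:
        c = self.cutoff
        lines = [
            f"Cutpoint analysis: {self.model.name}",
            f"  subjects: {len(self.model.scores)} "
            f"({int(self.model.labels.sum())} diseased)",
            f"  AUC: {self.auc:.3f}",
            f"  optimal cutoff (max sens+spec): {c.cutoff:g}",
            f"  sensitivity at cutoff: {c.sensitivity:.3f}",
            f"  specificity at cutoff: {c.specificity:.3f}",
            f"  Youden sum: {c.youden_sum:.3f}",
        ]
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        self.curve.frame().to_csv(path, index=False)

    def plot(self, ax=None, path: str | Path | None = None):
        """Plot sensitivity vs 1−specificity; optionally save to ``path``."""
        import matplotlib
        if ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(1.0 - self.curve.specificity, self.curve.sensitivity,
                drawstyle="steps-post", label=f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        i = int(np.argmin(np.abs(self.curve.thresholds - self.cutoff.cutoff)))
        ax.plot(1.0 - self.curve.specificity[i], self.curve.sensitivity[i],
                "o", c="C3", label=f"cutoff = {self.cutoff.cutoff:g}")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(self.model.name)
        ax.legend(loc="lower right")
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight")
        return ax
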