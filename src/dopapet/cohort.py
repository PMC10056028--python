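"""Synthetic patient cohorts for ¹⁸F-DOPA PET interpretation analysis.

Two generation modes are provided:

*Reconstructed* — rebuilds, record by record, the 112-subject clinical cohort
(69 with nigrostriatal dysfunction, 43 without) from the published per-group
positivity counts.  The pairwise joint structure of the binary reads
(visual basal-ganglia read vs. automated read, visual read vs. POR criterion)
is recovered exactly by inclusion–exclusion from the published marginal and
AND counts; continuous uptake values are then sampled consistently with each
record's binary indicators relative to the published cutoffs (pineal
SUVmax 0.72, POR 1.57).

*Parametric* — samples continuous uptake measurements from configurable
log-normal families, one per diagnosis group, with a shared per-patient
global-uptake factor.  Used for property tests, calibration and power
exploration; the shipped defaults are calibrated so the pineal-to-occipital
ratio separates the groups with AUC ≈ 0.71 and pineal SUVmax with AUC ≈ 0.67.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Diagnosis",
    "Call",
    "PatientRecord",
    "JointCounts",
    "CohortSpec",
    "STUDY_COUNTS",
    "SUVMAX_CUTOFF",
    "POR_CUTOFF",
    "reconstruct_joint_counts",
    "reconstructed_cohort",
    "parametric_cohort",
    "write_cohort",
    "read_cohort",
    "cohort_frame",
]

#: Published positivity cutoffs for the two pineal uptake criteria.
SUVMAX_CUTOFF = 0.72
POR_CUTOFF = 1.57


class Diagnosis(str, Enum):
    """Final clinical diagnosis by the movement-disorder specialist."""

    NSD = "NSD"
    NON_NSD = "NON_NSD"


class Call(str, Enum):
    """A scan-level read: positive / negative (visual reads may be equivocal)."""

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    EQUIVOCAL = "EQUIVOCAL"


#: Per-group positivity counts of the source clinical cohort, as published.
#: Keys "a" = count among the 69 NSD subjects, "b" = among the 43 non-NSD.
#: ``*_and_*`` entries are joint (both-positive) counts of two reads.
STUDY_COUNTS: dict = {
    "n_nsd": 69,
    "n_non_nsd": 43,
    "va_bg": (61, 3),        # visual basal-ganglia read
    "am_bg": (37, 3),        # automated basal-ganglia read
    "va_pb": (48, 17),       # visual pineal read (uptake > background)
    "suvmax": (47, 14),      # pineal SUVmax >= 0.72
    "por": (44, 11),         # POR >= 1.57
    "va_and_am": (35, 1),
    "va_and_por": (37, 0),
}


@dataclass(frozen=True)
class PatientRecord:
    """One subject: diagnosis, scan reads and continuous uptake measurements.

    ``por`` is always derived from the stored SUV fields, never stored, so the
    record cannot carry an inconsistent ratio.
    """

    patient_id: str
    true_label: Diagnosis
    va_bg_call: Call
    pineal_suvmax: float
    rt_occ_suvmean: float
    lt_occ_suvmean: float
    am_bg_call: Call | None = None
    visual_pineal_call: Call | None = None

    def __post_init__(self):
        if self.pineal_suvmax < 0:
            raise ValueError("pineal_suvmax must be >= 0")
        if self.rt_occ_suvmean <= 0 or self.lt_occ_suvmean <= 0:
            raise ValueError("occipital SUVmean values must be > 0")
        if self.am_bg_call is Call.EQUIVOCAL:
            raise ValueError("am_bg_call is binary (POSITIVE/NEGATIVE)")

    @property
    def por(self) -> float:
        """Pineal-to-occipital ratio: SUVmax over the mean occipital SUVmean."""
        return self.pineal_suvmax / ((self.rt_occ_suvmean + self.lt_occ_suvmean) / 2.0)


@dataclass(frozen=True)
class JointCounts:
    """2×2 joint structure of two binary reads within one diagnosis group."""

    n_both_pos: int
    n_a_only: int
    n_b_only: int
    n_neither: int

    @property
    def n_or_pos(self) -> int:
        return self.n_both_pos + self.n_a_only + self.n_b_only

    @property
    def total(self) -> int:
        return self.n_or_pos + self.n_neither


def reconstruct_joint_counts(n_class: int, a_pos: int, b_pos: int,
                             and_pos: int) -> JointCounts:
    """Recover the 2×2 joint cells of two binary reads by inclusion–exclusion.

    Parameters are per diagnosis group: group size, the two marginal positive
    counts and the both-positive count.  Raises ``ValueError`` naming the
    violated inequality when the counts are mutually inconsistent.
    """
    for name, v in (("n_class", n_class), ("a_pos", a_pos),
                    ("b_pos", b_pos), ("and_pos", and_pos)):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if a_pos > n_class:
        raise ValueError(f"inconsistent counts: a_pos ({a_pos}) > n_class ({n_class})")
    if b_pos > n_class:
        raise ValueError(f"inconsistent counts: b_pos ({b_pos}) > n_class ({n_class})")
    if and_pos > min(a_pos, b_pos):
        raise ValueError(
            f"inconsistent counts: and_pos ({and_pos}) > min(a_pos, b_pos) "
            f"({min(a_pos, b_pos)})")
    or_pos = a_pos + b_pos - and_pos
    if or_pos > n_class:
        raise ValueError(
            f"inconsistent counts: a_pos + b_pos - and_pos ({or_pos}) > "
            f"n_class ({n_class})")
    return JointCounts(
        n_both_pos=int(and_pos),
        n_a_only=int(a_pos - and_pos),
        n_b_only=int(b_pos - and_pos),
        n_neither=int(n_class - or_pos),
    )


@dataclass
class CohortSpec:
    """Parameters of the parametric cohort generator.

    Continuous measurements follow per-group log-normal families.  A shared
    per-patient log-normal factor (``shared_log_sd``) scales both the pineal
    and the occipital values, modelling global-uptake variability that the
    POR ratio cancels — this is what makes the ratio a better group separator
    than raw SUVmax, as observed clinically.

    Log-means are log-medians of the marginal distributions; the marginal
    log-SD of pineal SUVmax is ``sqrt(pineal_log_sd² + shared_log_sd²)``.
    """

    n_nsd: int = 69
    n_non_nsd: int = 43
    pineal_log_mean_nsd: float = -0.104
    pineal_log_mean_non_nsd: float = -0.3665
    pineal_log_sd: float = 0.30
    occipital_log_mean: float = -0.673
    occipital_log_sd: float = 0.15
    shared_log_sd: float = 0.30
    occ_asymmetry: float = 0.05
    va_bg_sensitivity: float = 61 / 69
    va_bg_specificity: float = 40 / 43
    equivocal_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_nsd <= 0 or self.n_non_nsd <= 0:
            raise ValueError("group sizes must be positive")
        for name in ("pineal_log_sd", "occipital_log_sd", "shared_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("va_bg_sensitivity", "va_bg_specificity", "equivocal_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.occ_asymmetry < 1.0:
            raise ValueError("occ_asymmetry must be in [0, 1)")

    # -- marginal distributions ------------------------------------------
    def pineal_dist(self, label: Diagnosis) -> stats.rv_continuous:
        mu = (self.pineal_log_mean_nsd if label is Diagnosis.NSD
              else self.pineal_log_mean_non_nsd)
        sd = float(np.hypot(self.pineal_log_sd, self.shared_log_sd))
        return stats.lognorm(s=sd, scale=np.exp(mu))

    def por_dist(self, label: Diagnosis) -> stats.rv_continuous:
        mu = (self.pineal_log_mean_nsd if label is Diagnosis.NSD
              else self.pineal_log_mean_non_nsd) - self.occipital_log_mean
        sd = float(np.hypot(self.pineal_log_sd, self.occipital_log_sd))
        return stats.lognorm(s=sd, scale=np.exp(mu))

    # -- JSON config -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown cohort-spec fields: {sorted(unknown)}")
        spec = cls(**data)
        spec.validate()
        return spec

    @classmethod
    def default(cls) -> "CohortSpec":
        with resources.files("dopapet.data").joinpath(
                "cohort_spec_default.json").open() as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# reconstructed mode
# ---------------------------------------------------------------------------

def _truncated_sample(rng: np.random.Generator, dist, n: int,
                      low: float | None = None,
                      high: float | None = None) -> np.ndarray:
    """Inverse-CDF sampling of ``dist`` restricted to [low, high)."""
    lo = dist.cdf(low) if low is not None else 0.0
    hi = dist.cdf(high) if high is not None else 1.0
    u = rng.uniform(lo, hi, size=n)
    return np.asarray(dist.ppf(u), dtype=float)


def _choose(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    return rng.choice(pool, size=k, replace=False)


def _spread_ranks(n_minor: int, total: int) -> np.ndarray:
    """Evenly spaced interior ranks for the minority class within one side."""
    return (np.arange(1, n_minor + 1) * total // (n_minor + 1)).astype(int)


def _pos_side_ok(is_non: np.ndarray, n_nsd: int, n_non: int) -> bool:
    """Raising the threshold must never raise the Youden sum.

    For every prefix below a candidate threshold inside the positive side the
    lost sensitivity must outweigh the gained specificity:
    k_non/n_non <= k_nsd/n_nsd (strict whenever the prefix is non-empty).
    """
    k_non = np.cumsum(is_non)
    k_nsd = np.arange(1, len(is_non) + 1) - k_non
    return bool(np.all(k_non * n_nsd <= k_nsd * n_non))


def _neg_side_ok(is_non: np.ndarray, n_nsd: int, n_non: int) -> bool:
    """Lowering the threshold must never raise the Youden sum (suffixes)."""
    rev = is_non[::-1]
    i_non = np.cumsum(rev)
    i_nsd = np.arange(1, len(rev) + 1) - i_non
    return bool(np.all(i_nsd * n_non <= i_non * n_nsd))


def _assign_por_values(rng, spec, n_pos_nsd, n_pos_non, n_neg_nsd, n_neg_non):
    """Sample POR values per class/side and rank-assign them between classes.

    Within each side of the 1.57 boundary the pooled sampled values are
    sorted and the classes are interleaved by rank so that the empirical
    Youden-optimal threshold of the finished cohort is provably unique at
    the boundary: raising the threshold always loses more sensitivity than
    it gains specificity, and lowering it the converse (checked by the
    prefix/suffix dominance conditions; a guaranteed-valid ordering is used
    as fallback should the interleaved pattern ever violate them).  The
    published positivity split (44/69 vs 11/43) is therefore recovered
    exactly on every seed.
    """
    d_nsd, d_non = spec.por_dist(Diagnosis.NSD), spec.por_dist(Diagnosis.NON_NSD)
    n_nsd_total = n_pos_nsd + n_neg_nsd
    n_non_total = n_pos_non + n_neg_non
    eps = POR_CUTOFF * 1e-9

    pos = np.sort(np.concatenate([
        _truncated_sample(rng, d_nsd, n_pos_nsd, low=POR_CUTOFF),
        _truncated_sample(rng, d_non, n_pos_non, low=POR_CUTOFF)]))
    pos = np.maximum(pos, POR_CUTOFF)
    is_non = np.zeros(pos.size, dtype=bool)
    is_non[_spread_ranks(n_pos_non, pos.size)] = True
    if is_non.sum() != n_pos_non or \
            not _pos_side_ok(is_non, n_nsd_total, n_non_total):
        is_non[:] = False
        is_non[pos.size - n_pos_non:] = True  # non-NSD on top: always valid
    pos_nsd, pos_non = pos[~is_non], pos[is_non]

    neg = np.sort(np.concatenate([
        _truncated_sample(rng, d_nsd, n_neg_nsd, high=POR_CUTOFF),
        _truncated_sample(rng, d_non, n_neg_non, high=POR_CUTOFF)]))
    neg = np.minimum(neg, POR_CUTOFF - eps)
    is_nsd = np.zeros(neg.size, dtype=bool)
    is_nsd[_spread_ranks(n_neg_nsd, neg.size)] = True
    if is_nsd.sum() != n_neg_nsd or \
            not _neg_side_ok(~is_nsd, n_nsd_total, n_non_total):
        is_nsd[:] = False
        is_nsd[:n_neg_nsd] = True  # NSD at the bottom: always valid
    neg_nsd, neg_non = neg[is_nsd], neg[~is_nsd]
    return pos_nsd, pos_non, neg_nsd, neg_non


def reconstructed_cohort(seed: int = 0,
                         spec: CohortSpec | None = None) -> list[PatientRecord]:
    """Rebuild the 112-patient study cohort from published summary counts.

    The binary-indicator joint structure — visual basal-ganglia read (VA-BG),
    automated read (AM-BG), visual pineal read, SUVmax ≥ 0.72 and POR ≥ 1.57,
    with the published pairwise joints of (VA-BG, AM-BG) and (VA-BG, POR) —
    is exact and seed-independent.  Cross-assignments the published tables do
    not constrain (which particular records carry which indicator), the
    continuous values, and the record order are sampled from ``seed``.

    ``spec`` supplies the continuous-value distributions (defaults to the
    shipped calibrated spec with the published group sizes).
    """
    spec = spec or CohortSpec.default()
    rng = np.random.default_rng(seed)
    c = STUDY_COUNTS
    groups = {
        Diagnosis.NSD: dict(n=c["n_nsd"], idx=0),
        Diagnosis.NON_NSD: dict(n=c["n_non_nsd"], idx=1),
    }

    records: list[PatientRecord] = []
    for label, g in groups.items():
        n, i = g["n"], g["idx"]
        va_n, am_n, pb_n = c["va_bg"][i], c["am_bg"][i], c["va_pb"][i]
        suv_n, por_n = c["suvmax"][i], c["por"][i]
        j_am = reconstruct_joint_counts(n, va_n, am_n, c["va_and_am"][i])
        j_por = reconstruct_joint_counts(n, va_n, por_n, c["va_and_por"][i])

        va = np.zeros(n, dtype=bool)
        va[_choose(rng, np.arange(n), va_n)] = True
        va_pos_idx, va_neg_idx = np.flatnonzero(va), np.flatnonzero(~va)

        am = np.zeros(n, dtype=bool)
        am[_choose(rng, va_pos_idx, j_am.n_both_pos)] = True
        am[_choose(rng, va_neg_idx, j_am.n_b_only)] = True

        por_ind = np.zeros(n, dtype=bool)
        por_ind[_choose(rng, va_pos_idx, j_por.n_both_pos)] = True
        por_ind[_choose(rng, va_neg_idx, j_por.n_b_only)] = True

        suv_ind = np.zeros(n, dtype=bool)
        suv_ind[_choose(rng, np.arange(n), suv_n)] = True
        pb = np.zeros(n, dtype=bool)
        pb[_choose(rng, np.arange(n), pb_n)] = True

        g.update(va=va, am=am, por_ind=por_ind, suv_ind=suv_ind, pb=pb)

    # POR values: sampled per class/side, rank-assigned across classes so the
    # Youden-optimal cutoff of the finished cohort sits exactly at the
    # published 1.57 split (see _assign_por_values).
    g1, g0 = groups[Diagnosis.NSD], groups[Diagnosis.NON_NSD]
    n_pos_nsd = int(g1["por_ind"].sum())
    n_pos_non = int(g0["por_ind"].sum())
    pos_nsd, pos_non, neg_nsd, neg_non = _assign_por_values(
        rng, spec, n_pos_nsd, n_pos_non,
        g1["n"] - n_pos_nsd, g0["n"] - n_pos_non)
    por_values = {
        Diagnosis.NSD: (rng.permutation(pos_nsd), rng.permutation(neg_nsd)),
        Diagnosis.NON_NSD: (rng.permutation(pos_non), rng.permutation(neg_non)),
    }

    for label, g in groups.items():
        n = g["n"]
        dist = spec.pineal_dist(label)
        suv = np.where(
            g["suv_ind"],
            _truncated_sample(rng, dist, n, low=SUVMAX_CUTOFF),
            _truncated_sample(rng, dist, n, high=SUVMAX_CUTOFF))
        suv = np.where(g["suv_ind"], np.maximum(suv, SUVMAX_CUTOFF),
                       np.minimum(suv, SUVMAX_CUTOFF * (1 - 1e-9)))
        por = np.empty(n)
        por[g["por_ind"]], por[~g["por_ind"]] = por_values[label]
        occ = suv / por
        asym = rng.uniform(-spec.occ_asymmetry, spec.occ_asymmetry, size=n)
        for k in range(n):
            records.append(PatientRecord(
                patient_id="",  # assigned after the shuffle
                true_label=label,
                va_bg_call=Call.POSITIVE if g["va"][k] else Call.NEGATIVE,
                pineal_suvmax=float(suv[k]),
                rt_occ_suvmean=float(occ[k] * (1 + asym[k])),
                lt_occ_suvmean=float(occ[k] * (1 - asym[k])),
                am_bg_call=Call.POSITIVE if g["am"][k] else Call.NEGATIVE,
                visual_pineal_call=Call.POSITIVE if g["pb"][k] else Call.NEGATIVE,
            ))

    order = rng.permutation(len(records))
    return [replace(records[j], patient_id=f"P{i + 1:03d}")
            for i, j in enumerate(order)]


# ---------------------------------------------------------------------------
# parametric mode
# ---------------------------------------------------------------------------

def parametric_cohort(spec: CohortSpec | None = None) -> list[PatientRecord]:
    """Sample a cohort from the log-normal families in ``spec``.

    Visual basal-ganglia calls are drawn per group from the configured
    sensitivity/specificity (optionally replaced by EQUIVOCAL at
    ``equivocal_rate``); automated and visual-pineal reads are left unset.
    """
    spec = spec or CohortSpec.default()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    records: list[PatientRecord] = []
    for label, n, p_pos in (
            (Diagnosis.NSD, spec.n_nsd, spec.va_bg_sensitivity),
            (Diagnosis.NON_NSD, spec.n_non_nsd, 1.0 - spec.va_bg_specificity)):
        mu_p = (spec.pineal_log_mean_nsd if label is Diagnosis.NSD
                else spec.pineal_log_mean_non_nsd)
        shared = rng.normal(0.0, spec.shared_log_sd, size=n)
        suv = np.exp(mu_p + shared + rng.normal(0, spec.pineal_log_sd, size=n))
        occ = np.exp(spec.occipital_log_mean + shared
                     + rng.normal(0, spec.occipital_log_sd, size=n))
        asym = rng.uniform(-spec.occ_asymmetry, spec.occ_asymmetry, size=n)
        pos = rng.random(n) < p_pos
        equiv = rng.random(n) < spec.equivocal_rate
        for k in range(n):
            call = (Call.EQUIVOCAL if equiv[k]
                    else Call.POSITIVE if pos[k] else Call.NEGATIVE)
            records.append(PatientRecord(
                patient_id="",
                true_label=label,
                va_bg_call=call,
                pineal_suvmax=float(suv[k]),
                rt_occ_suvmean=float(occ[k] * (1 + asym[k])),
                lt_occ_suvmean=float(occ[k] * (1 - asym[k])),
            ))
    order = rng.permutation(len(records))
    return [replace(records[j], patient_id=f"S{i + 1:05d}")
            for i, j in enumerate(order)]


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["patient_id", "true_label", "va_bg_call", "pineal_suvmax",
                "rt_occ_suvmean", "lt_occ_suvmean", "am_bg_call",
                "visual_pineal_call"]


def cohort_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame (enums as strings, missing optionals as NA)."""
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "true_label": r.true_label.value,
            "va_bg_call": r.va_bg_call.value,
            "pineal_suvmax": r.pineal_suvmax,
            "rt_occ_suvmean": r.rt_occ_suvmean,
            "lt_occ_suvmean": r.lt_occ_suvmean,
            "am_bg_call": r.am_bg_call.value if r.am_bg_call else "",
            "visual_pineal_call":
                r.visual_pineal_call.value if r.visual_pineal_call else "",
        })
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    cohort_frame(records).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV; raises ``ValueError`` naming the offending field."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV {path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(PatientRecord(
                patient_id=row["patient_id"],
                true_label=Diagnosis(row["true_label"]),
                va_bg_call=Call(row["va_bg_call"]),
                pineal_suvmax=float(row["pineal_suvmax"]),
                rt_occ_suvmean=float(row["rt_occ_suvmean"]),
                lt_occ_suvmean=float(row["lt_occ_suvmean"]),
                am_bg_call=Call(row["am_bg_call"]) if row["am_bg_call"] else None,
                visual_pineal_call=(Call(row["visual_pineal_call"])
                                    if row["visual_pineal_call"] else None),
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"cohort CSV {path}, line {i + 2}: {exc}") from exc
    return records
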