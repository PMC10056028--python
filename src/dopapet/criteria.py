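"""Uptake statistics and binary criterion calls.

Implements the three semiquantitative statistics used to interpret ¹⁸F-DOPA
brain PET for nigrostriatal dysfunction:

* POR — pineal-to-occipital ratio: pineal SUVmax over the mean of the right
  and left occipital SUVmean (positive at >= 1.57);
* SBR — striatal binding ratio: (region counts − background counts) /
  background counts, compared to a normal reference in SD units (Z-scores);
* pineal SUVmax thresholding (positive at >= 0.72).

The automated basal-ganglia call flags a scan when any striatal region's SBR
falls more than 2 SD *below* the normal reference — the disease signature is
uptake reduction, so the rule is one-sided low with a strict boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import Call, POR_CUTOFF, SUVMAX_CUTOFF
from .phantom import STRIATAL_REGIONS, VoxelGrid, render_phantom, default_region_map
from .voi import PatientMeasurementBundle, default_voi_set, measure_patient

__all__ = [
    "PinealMeasurement",
    "StriatalQuant",
    "ReferenceModel",
    "CriterionThreshold",
    "compute_por",
    "compute_sbr",
    "sbr_z_score",
    "am_bg_classify",
    "classify_pineal",
    "fit_reference_model",
]


@dataclass(frozen=True)
class PinealMeasurement:
    pineal_suvmax: float
    rt_occ_suvmean: float
    lt_occ_suvmean: float


@dataclass(frozen=True)
class CriterionThreshold:
    """A '>= cutoff is positive' rule for a continuous pineal criterion."""

    criterion: str  # "PINEAL_SUVMAX" or "POR"
    cutoff: float

    def __post_init__(self):
        if self.criterion not in ("PINEAL_SUVMAX", "POR"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be > 0")


SUVMAX_THRESHOLD = CriterionThreshold("PINEAL_SUVMAX", SUVMAX_CUTOFF)
POR_THRESHOLD = CriterionThreshold("POR", POR_CUTOFF)


def compute_por(m: PinealMeasurement) -> float:
    """Pineal SUVmax over the average of right/left occipital SUVmean."""
    if m.rt_occ_suvmean <= 0 or m.lt_occ_suvmean <= 0:
        raise ValueError("occipital SUVmean values must be > 0")
    return m.pineal_suvmax / ((m.rt_occ_suvmean + m.lt_occ_suvmean) / 2.0)


def compute_sbr(region_counts: float, background_counts: float) -> float:
    """Striatal binding ratio: (region − background) / background."""
    if background_counts <= 0:
        raise ValueError("background counts must be > 0")
    return (region_counts - background_counts) / background_counts


@dataclass(frozen=True)
class StriatalQuant:
    """Per-region mean counts plus background, with derived SBR values."""

    region_counts: Mapping[str, float]
    background_counts: float

    def __post_init__(self):
        if self.background_counts <= 0:
            raise ValueError("background counts must be > 0")

    @property
    def sbr(self) -> dict[str, float]:
        return {name: compute_sbr(c, self.background_counts)
                for name, c in self.region_counts.items()}

    @classmethod
    def from_bundle(cls, bundle: PatientMeasurementBundle) -> "StriatalQuant":
        return cls(bundle.striatal_counts, bundle.background_counts)


@dataclass(frozen=True)
class ReferenceModel:
    """Normal-population SBR mean/SD per region, for Z-scoring.

    The shipped default is *synthetic*: fitted from simulated healthy
    phantoms (see :func:`fit_reference_model`), since no ¹⁸F-DOPA normative
    database is published for this pipeline.
    """

    regions: Mapping[str, tuple[float, float]]  # name -> (mean, sd)
    n_reference: int

    def __post_init__(self):
        if self.n_reference < 2:
            raise ValueError("a reference model needs n_reference >= 2")
        for name, (_, sd) in self.regions.items():
            if sd <= 0:
                raise ValueError(f"region {name}: reference SD must be > 0")

    @classmethod
    def from_samples(cls, samples: Mapping[str, Sequence[float]]) -> "ReferenceModel":
        """Fit mean and sample SD (n−1 denominator) per region."""
        n = {len(v) for v in samples.values()}
        if len(n) != 1 or n.pop() < 2:
            raise ValueError("need >= 2 samples per region, equal across regions")
        regions = {name: (float(np.mean(v)), float(np.std(v, ddof=1)))
                   for name, v in samples.items()}
        return cls(regions, len(next(iter(samples.values()))))

    def to_json(self, path: str | Path) -> None:
        data = {"n_reference": self.n_reference,
                "regions": {k: {"mean": m, "sd": s}
                            for k, (m, s) in self.regions.items()}}
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceModel":
        data = json.loads(Path(path).read_text())
        return cls({k: (v["mean"], v["sd"]) for k, v in data["regions"].items()},
                   data["n_reference"])


def sbr_z_score(sbr: float, region: str, ref: ReferenceModel) -> float:
    """(SBR − reference mean) / reference SD for one region."""
    if region not in ref.regions:
        raise ValueError(f"region {region!r} not in the reference model")
    mean, sd = ref.regions[region]
    return (sbr - mean) / sd


def am_bg_classify(quant: StriatalQuant, ref: ReferenceModel,
                   regions: Iterable[str] | None = None) -> Call:
    """Automated basal-ganglia call: positive if any region's z < −2.

    ``regions`` restricts which regions may trigger positivity (e.g. the
    posterior putamina, the typical-pattern site); default is every region in
    the quantification.  The boundary is strict: z exactly −2 is negative.
    """
    names = list(regions) if regions is not None else list(quant.region_counts)
    missing = [r for r in names if r not in quant.region_counts]
    if missing:
        raise ValueError(f"regions missing from quantification: {missing}")
    sbr = quant.sbr
    for name in names:
        if sbr_z_score(sbr[name], name, ref) < -2.0:
            return Call.POSITIVE
    return Call.NEGATIVE


def classify_pineal(value: float, threshold: CriterionThreshold) -> Call:
    """Positive iff value >= cutoff (the clinical '≥' convention)."""
    return Call.POSITIVE if value >= threshold.cutoff else Call.NEGATIVE


def fit_reference_model(n_subjects: int = 8, grid: VoxelGrid | None = None,
                        noise_sd: float = 0.08, seed: int = 2000,
                        ) -> ReferenceModel:
    """Fit a synthetic normal reference from simulated healthy phantoms.

    Renders ``n_subjects`` noisy healthy phantoms (seeds ``seed..seed+n−1``),
    measures each with the default VOI set and collects per-region SBR
    samples.  Stands in for a scanner normative database, which is not
    publicly available for this tracer.
    """
    vois = default_voi_set()
    region_map = default_region_map("normal")
    samples: dict[str, list[float]] = {r: [] for r in STRIATAL_REGIONS}
    for k in range(n_subjects):
        vol = render_phantom(region_map, grid, noise_sd=noise_sd, seed=seed + k)
        quant = StriatalQuant.from_bundle(measure_patient(vol, vois))
        for name, value in quant.sbr.items():
            samples[name].append(value)
    return ReferenceModel.from_samples(samples)
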