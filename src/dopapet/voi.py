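"""Spherical volume-of-interest placement and SUV statistics.

VOIs are spheres in world millimetres (default volume 1.5 cm³, the clinical
convention for pineal/occipital sampling).  A voxel contributes to a VOI if
its center lies within Euclidean distance r of the VOI center (boundary
included), with r = (3V/4π)^(1/3).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .phantom import STRIATAL_REGIONS, SuvVolume, default_region_map

__all__ = [
    "SphericalVoi",
    "VoiStats",
    "PatientMeasurementBundle",
    "radius_from_volume",
    "extract_suv_stats",
    "measure_patient",
    "default_voi_set",
    "load_voi_set",
    "save_voi_set",
]

#: VOI names the measurement layer requires.
_MANDATORY_VOIS = ("pineal", "occipital_L", "occipital_R", "background")


def radius_from_volume(volume_cm3: float) -> float:
    """Radius in mm of a sphere of the given volume in cm³."""
    if volume_cm3 <= 0:
        raise ValueError(f"VOI volume must be positive, got {volume_cm3}")
    return (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SphericalVoi:
    name: str
    center_mm: tuple[float, float, float]
    volume_cm3: float = 1.5

    def __post_init__(self):
        radius_from_volume(self.volume_cm3)  # validates positivity

    @property
    def radius_mm(self) -> float:
        return radius_from_volume(self.volume_cm3)


@dataclass(frozen=True)
class VoiStats:
    voi_name: str
    suvmax: float
    suvmean: float
    n_voxels: int


def extract_suv_stats(volume: SuvVolume, voi: SphericalVoi) -> VoiStats:
    """SUVmax/SUVmean over voxels whose centers fall inside the sphere.

    Raises ``ValueError`` if no voxel center lies within the VOI (an empty VOI
    is a placement error, never a silent zero).
    """
    grid = volume.grid
    r = voi.radius_mm
    axes = grid.axes_mm()
    sl = []
    for d in range(3):
        i0 = int(np.searchsorted(axes[d], voi.center_mm[d] - r, side="left"))
        i1 = int(np.searchsorted(axes[d], voi.center_mm[d] + r, side="right"))
        sl.append(slice(i0, i1))
    coords = np.meshgrid(*(axes[d][sl[d]] for d in range(3)), indexing="ij")
    dist2 = sum((coords[d] - voi.center_mm[d]) ** 2 for d in range(3))
    mask = dist2 <= r * r
    if not mask.any():
        raise ValueError(
            f"VOI {voi.name!r} at {voi.center_mm} (r={r:.2f} mm) contains no "
            "voxel centers")
    vals = np.asarray(volume.values)[tuple(sl)][mask]
    return VoiStats(voi.name, float(vals.max()), float(vals.mean()),
                    int(vals.size))


@dataclass(frozen=True)
class PatientMeasurementBundle:
    """Per-region VOI statistics for one scan.

    ``striatal_counts``/``background_counts`` are the VOI SUVmeans used for
    the striatal binding ratio (the absolute scale cancels in the ratio).
    """

    stats: dict[str, VoiStats]

    @property
    def pineal_suvmax(self) -> float:
        return self.stats["pineal"].suvmax

    @property
    def rt_occ_suvmean(self) -> float:
        return self.stats["occipital_R"].suvmean

    @property
    def lt_occ_suvmean(self) -> float:
        return self.stats["occipital_L"].suvmean

    @property
    def background_counts(self) -> float:
        return self.stats["background"].suvmean

    @property
    def striatal_counts(self) -> dict[str, float]:
        return {name: s.suvmean for name, s in self.stats.items()
                if name in STRIATAL_REGIONS}


def measure_patient(volume: SuvVolume,
                    voi_set: Sequence[SphericalVoi]) -> PatientMeasurementBundle:
    """Extract the full measurement bundle for one scan.

    The VOI set must contain ``pineal``, ``occipital_L``, ``occipital_R``,
    ``background`` and at least one striatal VOI; a missing mandatory VOI
    raises ``ValueError`` naming it.
    """
    names = [v.name for v in voi_set]
    if len(set(names)) != len(names):
        raise ValueError("VOI names must be unique")
    for required in _MANDATORY_VOIS:
        if required not in names:
            raise ValueError(f"missing mandatory VOI {required!r}")
    if not any(n in STRIATAL_REGIONS for n in names):
        raise ValueError(
            f"VOI set must contain at least one striatal VOI of {STRIATAL_REGIONS}")
    return PatientMeasurementBundle(
        {v.name: extract_suv_stats(volume, v) for v in voi_set})


def default_voi_set() -> list[SphericalVoi]:
    """1.5 cm³ VOIs centred on the shipped atlas regions + a background VOI."""
    with resources.files("dopapet.data").joinpath(
            "voi_set_default.json").open() as fh:
        return _parse_voi_set(json.load(fh), "voi_set_default.json")


def _parse_voi_set(data, source) -> list[SphericalVoi]:
    try:
        return [SphericalVoi(v["name"], tuple(float(x) for x in v["center_mm"]),
                             float(v.get("volume_cm3", 1.5))) for v in data]
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed VOI set {source}: {exc}") from exc


def load_voi_set(path: str | Path) -> list[SphericalVoi]:
    return _parse_voi_set(json.loads(Path(path).read_text()), path)


def save_voi_set(vois: Sequence[SphericalVoi], path: str | Path) -> None:
    data = [{"name": v.name, "center_mm": list(v.center_mm),
             "volume_cm3": v.volume_cm3} for v in vois]
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
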