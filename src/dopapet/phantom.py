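"""Synthetic, pre-aligned 3D brain SUV phantoms.

Volumes are piecewise-constant: a background SUV level plus ellipsoidal /
spherical regions (striatal nuclei, occipital cortices, pineal body) at
configurable levels, with optional zero-truncated Gaussian noise.  Geometry is
expressed in world millimetres with a diagonal (no-rotation) world↔index
affine, so the volumes are born aligned to the VOI atlas — no registration
step is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "Region",
    "RegionMap",
    "SuvVolume",
    "STRIATAL_REGIONS",
    "MANDATORY_REGIONS",
    "default_grid",
    "default_region_map",
    "render_phantom",
    "nsd_phantom_pair",
    "save_volume",
    "load_volume",
]

STRIATAL_REGIONS = (
    "caudate_L", "caudate_R",
    "anterior_putamen_L", "anterior_putamen_R",
    "posterior_putamen_L", "posterior_putamen_R",
)
MANDATORY_REGIONS = STRIATAL_REGIONS + (
    "occipital_L", "occipital_R", "pineal", "background")


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice: world position of index i is origin + i*spacing."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ValueError("grid shape must be 3D with every axis >= 16")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin_mm[d] + np.arange(self.shape[d]) * self.spacing_mm[d]
                     for d in range(3))

    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin_mm, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing_mm)
        return lo, hi

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing_mm)
        a[:3, 3] = self.origin_mm
        return a


def default_grid() -> VoxelGrid:
    """2 mm isotropic 96x112x96 grid centred on the world origin."""
    shape = (96, 112, 96)
    spacing = (2.0, 2.0, 2.0)
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    return VoxelGrid(shape, spacing, origin)


@dataclass(frozen=True)
class Region:
    """Ellipsoidal region (equal semi-axes → sphere) at a target SUV level."""

    name: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    suv: float

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError(f"region {self.name}: semi-axes must be positive")
        if self.suv < 0:
            raise ValueError(f"region {self.name}: SUV level must be >= 0")


@dataclass(frozen=True)
class RegionMap:
    """Named regions plus the background SUV level.

    Later regions overwrite earlier ones where they overlap; the order is the
    listed order, so rendering is deterministic.
    """

    regions: tuple[Region, ...]
    background_suv: float = 0.35

    def __post_init__(self):
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        if self.background_suv < 0:
            raise ValueError("background SUV level must be >= 0")

    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions) + ("background",)

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def with_levels(self, levels: dict[str, float]) -> "RegionMap":
        regions = tuple(
            replace(r, suv=levels.get(r.name, r.suv)) for r in self.regions)
        return RegionMap(regions, levels.get("background", self.background_suv))

    def to_json(self, path: str | Path) -> None:
        data = {
            "background_suv": self.background_suv,
            "regions": [
                {"name": r.name, "center_mm": list(r.center_mm),
                 "semi_axes_mm": list(r.semi_axes_mm), "suv": r.suv}
                for r in self.regions],
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionMap":
        data = json.loads(Path(path).read_text())
        regions = tuple(
            Region(r["name"], tuple(r["center_mm"]), tuple(r["semi_axes_mm"]),
                   r["suv"]) for r in data["regions"])
        return cls(regions, data["background_suv"])


@dataclass(frozen=True)
class SuvVolume:
    """A 3D grid of SUV values."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid shape")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("SUV values must be finite and non-negative")


# geometry of the default atlas, world mm (grid centred at the origin):
# striatal nuclei around mid-brain, occipital cortices posterior, pineal midline.
_DEFAULT_GEOMETRY = (
    ("caudate_L", (-14.0, 12.0, 8.0), (8.0, 11.0, 8.0)),
    ("caudate_R", (14.0, 12.0, 8.0), (8.0, 11.0, 8.0)),
    ("anterior_putamen_L", (-26.0, 10.0, -6.0), (8.0, 10.0, 8.0)),
    ("anterior_putamen_R", (26.0, 10.0, -6.0), (8.0, 10.0, 8.0)),
    ("posterior_putamen_L", (-28.0, -12.0, -4.0), (8.0, 10.0, 8.0)),
    ("posterior_putamen_R", (28.0, -12.0, -4.0), (8.0, 10.0, 8.0)),
    ("occipital_L", (-25.0, -75.0, 0.0), (12.0, 12.0, 12.0)),
    ("occipital_R", (25.0, -75.0, 0.0), (12.0, 12.0, 12.0)),
    ("pineal", (0.0, -30.0, 6.0), (4.0, 4.0, 4.0)),
)

#: Default SUV levels.  The healthy pattern has symmetric striatal uptake and
#: near-background pineal uptake; the NSD pattern has asymmetrically reduced
#: posterior-putamen uptake with elevated pineal uptake.
NORMAL_LEVELS = {
    "caudate_L": 2.4, "caudate_R": 2.4,
    "anterior_putamen_L": 2.3, "anterior_putamen_R": 2.3,
    "posterior_putamen_L": 2.2, "posterior_putamen_R": 2.2,
    "occipital_L": 0.5, "occipital_R": 0.5,
    "pineal": 0.45,
    "background": 0.35,
}
NSD_LEVELS = dict(NORMAL_LEVELS,
                  posterior_putamen_L=0.9, posterior_putamen_R=1.3,
                  pineal=1.3)


def default_region_map(kind: str = "normal") -> RegionMap:
    """The shipped atlas with ``"normal"`` or ``"nsd"`` uptake levels."""
    levels = {"normal": NORMAL_LEVELS, "nsd": NSD_LEVELS}.get(kind)
    if levels is None:
        raise ValueError(f"unknown phantom kind {kind!r} (use 'normal' or 'nsd')")
    regions = tuple(Region(name, center, axes, levels[name])
                    for name, center, axes in _DEFAULT_GEOMETRY)
    return RegionMap(regions, background_suv=levels["background"])


def _region_mask(grid: VoxelGrid, region: Region) -> tuple[tuple, np.ndarray]:
    """Bounding-box slice and in-ellipsoid mask (voxel-center membership)."""
    axes = grid.axes_mm()
    sl = []
    for d in range(3):
        lo = region.center_mm[d] - region.semi_axes_mm[d]
        hi = region.center_mm[d] + region.semi_axes_mm[d]
        i0 = int(np.searchsorted(axes[d], lo, side="left"))
        i1 = int(np.searchsorted(axes[d], hi, side="right"))
        sl.append(slice(i0, i1))
    coords = np.meshgrid(*(axes[d][sl[d]] for d in range(3)), indexing="ij")
    q = sum(((coords[d] - region.center_mm[d]) / region.semi_axes_mm[d]) ** 2
            for d in range(3))
    return tuple(sl), q <= 1.0


def render_phantom(region_map: RegionMap, grid: VoxelGrid | None = None,
                   noise_sd: float = 0.0, seed: int = 0) -> SuvVolume:
    """Render a piecewise-constant SUV volume with optional truncated noise.

    A voxel belongs to a region if its center lies inside the primitive; the
    Gaussian noise (sd ``noise_sd``) is truncated at zero.  Deterministic for
    a given seed.  Raises ``ValueError`` if a region extends beyond the grid.
    """
    grid = grid or default_grid()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = grid.bounds_mm()
    for r in region_map.regions:
        c, a = np.asarray(r.center_mm), np.asarray(r.semi_axes_mm)
        if np.any(c - a < lo) or np.any(c + a > hi):
            raise ValueError(f"region {r.name} extends outside the grid")
    values = np.full(grid.shape, region_map.background_suv, dtype=float)
    for r in region_map.regions:
        sl, mask = _region_mask(grid, r)
        values[sl][mask] = r.suv
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.maximum(values + rng.normal(0, noise_sd, grid.shape), 0.0)
    return SuvVolume(grid, values)


def nsd_phantom_pair(grid: VoxelGrid | None = None, seed: int = 0,
                     noise_sd: float = 0.0) -> tuple[SuvVolume, SuvVolume]:
    """(NSD, normal) phantom pair differing only in the disease signature.

    Both volumes share the same noise realisation, so voxels outside the
    modified regions (posterior putamina, pineal) are identical.
    """
    grid = grid or default_grid()
    nsd = render_phantom(default_region_map("nsd"), grid, noise_sd, seed)
    normal = render_phantom(default_region_map("normal"), grid, noise_sd, seed)
    return nsd, normal


def save_volume(volume: SuvVolume, path: str | Path) -> None:
    """Write as NIfTI-1 (.nii / .nii.gz), float64, diagonal affine."""
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64),
                          volume.grid.affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> SuvVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise ValueError(f"NIfTI volume {path}: affine must be diagonal "
                         "(no rotation/shear)")
    spacing = tuple(float(x) for x in np.diag(affine[:3, :3]))
    origin = tuple(float(x) for x in affine[:3, 3])
    grid = VoxelGrid(tuple(int(s) for s in img.shape), spacing, origin)
    return SuvVolume(grid, np.asarray(img.get_fdata(), dtype=float))
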