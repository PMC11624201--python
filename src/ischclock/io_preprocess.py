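"""Volume containers, NIfTI I/O and the shared NCCT preprocessing operations.

The pipeline works on skull-stripped head CT volumes in Hounsfield units (HU).
All stages share four primitives: isotropic resampling, percentile clipping +
z-scoring (CNN input only — relative intensity is defined on raw HU),
hemispheric mirroring of a lesion mask across a sagittal midplane, and
restriction of a mask to an HU window (20-80 HU by default, excluding bone,
CSF and chronic infarct).

Coordinate convention: axis 0 is left-right (the mirroring axis), world RAS,
0-based voxel indices, world position = origin + index * spacing. Masks are
stored as uint8 NIfTI on disk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "LesionMask",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "resample_isotropic",
    "clip_and_zscore",
    "mirror_mask",
    "mirror_index",
    "hu_window_restrict",
    "EmptyWindowError",
    "HU_WINDOW",
]

#: Attenuation window used when sampling lesion voxels (excludes bone/CSF).
HU_WINDOW = (20.0, 80.0)


class EmptyWindowError(ValueError):
    """Raised when an HU-window restriction leaves no voxels.

    Signalled distinctly from other errors so callers can treat it as a
    segmentation/selection failure path rather than a bug.
    """


@dataclass
class ImageVolume:
    """A 3D scalar field in HU with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_thickness: str = "thin"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return dataclasses.replace(self, data=data)


@dataclass
class LesionMask:
    """Binary region on the grid of its parent :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = "phantom"  # expert | model | phantom

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def with_data(self, data: np.ndarray) -> "LesionMask":
        return dataclasses.replace(self, data=np.asarray(data).astype(bool))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_volume(v: ImageVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine())
    nib.save(img, str(path))


def load_volume(path, slice_thickness: str = "thin") -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite values in {path}")
    aff = img.affine
    spacing = tuple(float(s) for s in np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
    origin = tuple(float(o) for o in aff[:3, 3])
    return ImageVolume(data, spacing, origin, slice_thickness)


def save_mask(m: LesionMask, path) -> None:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(m.spacing)
    aff[:3, 3] = m.origin
    img = nib.Nifti1Image(m.data.astype(np.uint8), aff)
    nib.save(img, str(path))


def load_mask(path, provenance: str = "expert") -> LesionMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    aff = img.affine
    spacing = tuple(float(s) for s in np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
    origin = tuple(float(o) for o in aff[:3, 3])
    return LesionMask(data, spacing, origin, provenance)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def resample_isotropic(v, target: float):
    """Resample a volume (trilinear) or mask (nearest) to isotropic spacing.

    World extent is preserved to within one voxel; if spacing is already
    isotropic at ``target`` the input is returned unchanged.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if v.data.size == 0:
        raise ValueError("empty volume")
    if np.allclose(v.spacing, (target, target, target)):
        return v

    is_mask = isinstance(v, LesionMask)
    zoom = [s / target for s in v.spacing]
    new_shape = [max(1, int(round(n * z))) for n, z in zip(v.data.shape, zoom)]
    # sample at world positions of the new grid (origin preserved)
    coords = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(new_shape, v.spacing)],
        indexing="ij",
    )
    order = 0 if is_mask else 1
    src = v.data.astype(np.float32) if is_mask else v.data
    out = ndimage.map_coordinates(src, coords, order=order, mode="nearest")
    spacing = (target, target, target)
    if is_mask:
        return dataclasses.replace(v, data=out > 0.5, spacing=spacing)
    return dataclasses.replace(v, data=out, spacing=spacing)


def clip_and_zscore(v: ImageVolume, mask: np.ndarray | None = None) -> ImageVolume:
    """Clip at the 0.5/99.5 percentiles then z-score with post-clip statistics.

    Percentiles and moments are computed over ``mask`` voxels (default: the
    non-zero voxels, i.e. brain after skull-stripping / phantom padding
    excluded); the transform is applied to the whole field.
    """
    data = np.asarray(v.data, dtype=np.float64)
    if mask is None:
        mask = data != 0
    sel = data[mask] if mask.any() else data.ravel()
    if np.unique(sel).size < 2:
        raise ValueError("constant volume: z-score undefined (zero sd)")
    lo, hi = np.percentile(sel, [0.5, 99.5])
    clipped = np.clip(data, lo, hi)
    stats_src = clipped[mask] if mask.any() else clipped.ravel()
    mu = stats_src.mean()
    sd = stats_src.std()
    if sd == 0:
        raise ValueError("constant volume after clipping: zero sd")
    return v.with_data((clipped - mu) / sd)


def mirror_index(idx: np.ndarray, midplane: float) -> np.ndarray:
    """Reflect axis-0 voxel indices across the sagittal plane x = midplane."""
    return np.rint(2.0 * midplane - np.asarray(idx)).astype(int)


def mirror_mask(m: LesionMask, midplane: float | None = None) -> LesionMask:
    """Reflect a mask across the sagittal midplane (voxel coordinate on axis 0).

    Default midplane is the grid centre ``(nx - 1) / 2`` (the phantom
    convention, where reflection is an exact axis flip). Voxel count is
    preserved exactly; reflections leaving the grid raise.
    """
    nx = m.shape[0]
    if midplane is None:
        midplane = (nx - 1) / 2.0
    if abs(2.0 * midplane - round(2.0 * midplane)) > 1e-9:
        raise ValueError("midplane must lie on a voxel or half-voxel position")
    xs, ys, zs = np.nonzero(m.data)
    mx = mirror_index(xs, midplane)
    if mx.size and (mx.min() < 0 or mx.max() >= nx):
        raise ValueError("mirrored mask exits the grid")
    out = np.zeros_like(m.data)
    out[mx, ys, zs] = True
    return m.with_data(out)


def hu_window_restrict(
    v: ImageVolume,
    m: LesionMask,
    lo: float = HU_WINDOW[0],
    hi: float = HU_WINDOW[1],
) -> LesionMask:
    """Restrict a mask to voxels whose HU lies in [lo, hi].

    Raises :class:`EmptyWindowError` when nothing survives, so callers can
    route that case (e.g. report a failed relative-intensity measurement)
    without conflating it with programming errors.
    """
    if lo >= hi:
        raise ValueError(f"invalid window [{lo}, {hi}]")
    if not m.same_grid(v):
        raise ValueError("mask and volume grids differ")
    out = m.data & (v.data >= lo) & (v.data <= hi)
    if not out.any():
        raise EmptyWindowError(f"no mask voxels inside [{lo}, {hi}] HU")
    return m.with_data(out)
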