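"""Image containers, NIfTI I/O, preprocessing and peritumoral shell geometry.

The pipeline operates on portal-venous CT volumes in Hounsfield units (HU).
All downstream stages assume the preprocessing defined here: resampling to an
isotropic 1 mm grid and intensity windowing to the liver window
(level 45 HU, width 200 HU) mapped onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume",
    "RegionMask",
    "read_nifti",
    "write_nifti",
    "resample_isotropic",
    "resample_mask",
    "apply_window",
    "peritumoral_shell",
]


@dataclass
class CTVolume:
    """A 3-D scalar grid with voxel spacing and physical origin (mm).

    ``voxels`` holds HU values before windowing and dimensionless values in
    [0, 1] after :func:`apply_window`.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


@dataclass
class RegionMask:
    """A binary 3-D mask on the same grid geometry as its paired CTVolume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def volume_mm3(self) -> float:
        return float(self.voxels.sum() * np.prod(self.spacing))


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_nifti(path, kind: str = "volume"):
    """Read a NIfTI-1 file as a :class:`CTVolume` or :class:`RegionMask`.

    Parameters
    ----------
    path : str or Path
    kind : {"volume", "mask"}
        Masks are binarized at > 0.5 (so 0/255-coded masks read as 0/1).

    Spacing is recovered from the affine column norms and the origin from its
    translation; axis orientation beyond scaling is not interpreted.
    """
    img = nib.load(str(path))
    aff = img.affine
    if aff is None or not np.all(np.isfinite(aff)):
        raise ValueError(f"malformed NIfTI header in {path}: non-finite affine")
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"malformed NIfTI header in {path}: non-positive pixdim {spacing}")
    origin = tuple(float(x) for x in aff[:3, 3])
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if kind == "mask":
        return RegionMask(data > 0.5, spacing, origin)
    if kind == "volume":
        return CTVolume(data, spacing, origin)
    raise ValueError(f"kind must be 'volume' or 'mask', got {kind!r}")


def write_nifti(obj, path) -> str:
    """Write a CTVolume (float32) or RegionMask (uint8) to NIfTI-1."""
    if isinstance(obj, RegionMask):
        data = obj.voxels.astype(np.uint8)
    elif isinstance(obj, CTVolume):
        data = obj.voxels.astype(np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img = nib.Nifti1Image(data, _affine(obj.spacing, obj.origin))
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"failed to write NIfTI to {path}: {exc}") from exc
    return str(path)


def _zoom_factors(spacing, target_mm):
    return tuple(s / float(target_mm) for s in spacing)


def resample_isotropic(v: CTVolume, target_mm: float = 1.0) -> CTVolume:
    """Resample to an isotropic grid by trilinear interpolation.

    Physical extent is preserved within one voxel; an already-isotropic
    volume at the target spacing is returned unchanged (same array).
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    if all(abs(s - target_mm) < 1e-9 for s in v.spacing):
        return CTVolume(v.voxels, (target_mm,) * 3, v.origin)
    out = ndimage.zoom(
        v.voxels.astype(np.float64),
        _zoom_factors(v.spacing, target_mm),
        order=1,
        mode="grid-constant",
        cval=float(v.voxels.min()),
        grid_mode=True,
    )
    return CTVolume(out, (target_mm,) * 3, v.origin)


def resample_mask(m: RegionMask, target_mm: float = 1.0) -> RegionMask:
    """Companion resampler for masks: nearest-neighbour interpolation."""
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    if all(abs(s - target_mm) < 1e-9 for s in m.spacing):
        return RegionMask(m.voxels, (target_mm,) * 3, m.origin)
    out = ndimage.zoom(
        m.voxels.astype(np.float64),
        _zoom_factors(m.spacing, target_mm),
        order=0,
        mode="grid-constant",
        cval=0.0,
        grid_mode=True,
    )
    return RegionMask(out > 0.5, (target_mm,) * 3, m.origin)


def apply_window(v: CTVolume, width: float = 200.0, level: float = 45.0) -> CTVolume:
    """Clip HU to [level - width/2, level + width/2] and map linearly to [0, 1].

    Defaults are the standardized liver window (WW 200 HU / WL 45 HU), i.e.
    [-55, 145] HU.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    lo = level - width / 2.0
    out = np.clip(v.voxels, lo, lo + width)
    out = (out - lo) / width
    return CTVolume(out, v.spacing, v.origin)


def peritumoral_shell(
    tumor: RegionMask,
    liver: RegionMask,
    distance_mm: float,
    exclusion: RegionMask | None = None,
    include_tumor: bool = False,
) -> RegionMask:
    """Peritumoral ring within ``distance_mm`` (Euclidean) of the tumor margin.

    shell = {0 < dist-to-tumor <= d} ∩ liver \\ exclusion \\ tumor, computed
    with the exact Euclidean distance transform using the physical spacing.
    ``include_tumor=True`` returns the tumor+ring composite (sensitivity
    analyses only). Raises if the clipped shell is empty, which mirrors the
    situation where a tumor abuts the liver boundary everywhere and the
    expansion needs manual correction.
    """
    if distance_mm <= 0:
        raise ValueError("shell distance must be positive (mm)")
    if tumor.count() == 0:
        raise ValueError("tumor mask is empty")
    if tumor.shape != liver.shape:
        raise ValueError("tumor and liver masks must share a grid")
    dist = ndimage.distance_transform_edt(~tumor.voxels, sampling=tumor.spacing)
    shell = (dist > 0) & (dist <= distance_mm) & liver.voxels
    if exclusion is not None:
        shell &= ~exclusion.voxels
    shell &= ~tumor.voxels
    if include_tumor:
        shell |= tumor.voxels
    if not shell.any():
        raise ValueError(
            f"peritumoral shell at {distance_mm} mm is empty after clipping to "
            "liver; tumor reaches the liver boundary everywhere"
        )
    return RegionMask(shell, tumor.spacing, tumor.origin)
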