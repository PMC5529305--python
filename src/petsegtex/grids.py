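"""Core image containers: SUV volumes and binary volumes-of-interest.

Both types live on the same regular 3D grid with anisotropic physical
spacing (PET voxels are typically wider in-plane than the slice
thickness). Arrays are indexed ``(x, y, z)`` with ``z`` the axial
direction, matching the NIfTI on-disk layout used for serialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["PETVolume", "VOIMask", "GridMismatchError"]

#: Recognized VOI provenance labels.
PROVENANCES = ("truth", "freehand", "expanded", "40P", "FLAB")


class GridMismatchError(ValueError):
    """Two grid objects do not share the same shape/spacing."""


def _as_spacing(spacing_mm) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing_mm)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing_mm!r}")
    return s


@dataclass
class PETVolume:
    """A 3D PET activity image in SUV units.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities in standardized uptake value (SUV) units;
        must be non-negative (activity cannot be negative).
    spacing_mm : (float, float, float)
        Physical voxel size along (x, y, z) in millimetres.
    origin_mm : (float, float, float)
        Physical coordinate of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (4.7, 4.7, 3.27)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("PETVolume expects a 3D array")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine())
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "PETVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(np.clip(data, 0.0, None), tuple(float(z) for z in zooms), origin)


@dataclass
class VOIMask:
    """A binary volume-of-interest on the grid of a :class:`PETVolume`.

    ``provenance`` records which delineation produced the mask: the
    simulated ground truth, a reader's freehand contour, the 5-voxel
    expansion fed to the automatic algorithms, or the 40P / FLAB output.
    """

    mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (4.7, 4.7, 3.27)
    provenance: str = "truth"
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("VOIMask expects a 3D array")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        if self.provenance not in PROVENANCES:
            raise ValueError(
                f"provenance {self.provenance!r} not in {PROVENANCES}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_ml

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm
        )

    def require_same_grid(self, other) -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing_mm} vs "
                f"{other.shape}/{other.spacing_mm}"
            )

    def with_mask(self, new_mask: np.ndarray, provenance: str) -> "VOIMask":
        """Copy grid metadata onto a new boolean array."""
        return VOIMask(new_mask, self.spacing_mm, provenance, self.origin_mm)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.mask.astype(np.uint8), self.affine())
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, provenance: str = "freehand") -> "VOIMask":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(data > 0, tuple(float(z) for z in zooms), provenance, origin)
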