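"""Synthetic FDG-PET phantom generation.

A phantom is a heterogeneous ellipsoidal lesion on a low-uptake
background. The noiseless composite (background level + lesion plateau +
a correlated Gaussian random field inside the lesion) is convolved with
a Gaussian point-spread function to emulate partial-volume blur, then
Gaussian noise is added and the result clipped at zero. The ground-truth
mask is the pre-blur ellipsoid support.

Defaults emulate an NSCLC primary on aerated lung: tumour mean 7 SUV on
a 0.5 SUV background, 6 mm effective reconstruction FWHM,
4.7x4.7x3.27 mm voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import PETVolume, VOIMask

__all__ = ["PhantomConfig", "generate_phantom"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
#: margin (voxels) that the truth lesion must keep from every grid face
LESION_MARGIN_VOX = 5


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (44, 44, 44)
    voxel_spacing_mm: tuple[float, float, float] = (4.7, 4.7, 3.27)
    lesion_center: tuple[float, float, float] | None = None  # voxel coords
    lesion_radii_mm: tuple[float, float, float] = (15.0, 15.0, 15.0)
    tumour_suv_mean: float = 7.0
    background_suv_mean: float = 0.5
    heterogeneity_amplitude: float = 1.5  # SUV sd of within-tumour field
    heterogeneity_corr_len_mm: float = 8.0
    psf_fwhm_mm: float = 6.0
    noise_sigma_suv: float = 0.3
    seed: int = 0

    def center_vox(self) -> tuple[float, float, float]:
        if self.lesion_center is not None:
            return tuple(float(c) for c in self.lesion_center)
        return tuple((n - 1) / 2.0 for n in self.grid_shape)

    def validate(self) -> None:
        if not (self.tumour_suv_mean > self.background_suv_mean > 0):
            raise ValueError("need tumour_suv_mean > background_suv_mean > 0")
        if any(r <= 0 for r in self.lesion_radii_mm):
            raise ValueError("lesion radii must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.heterogeneity_amplitude < 0 or self.noise_sigma_suv < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.psf_fwhm_mm < 0 or self.heterogeneity_corr_len_mm <= 0:
            raise ValueError("psf_fwhm_mm >= 0 and corr length > 0 required")
        center = self.center_vox()
        for ax in range(3):
            r_vox = self.lesion_radii_mm[ax] / self.voxel_spacing_mm[ax]
            lo = center[ax] - r_vox - LESION_MARGIN_VOX
            hi = center[ax] + r_vox + LESION_MARGIN_VOX
            if lo < 0 or hi > self.grid_shape[ax] - 1:
                raise ValueError(
                    "lesion does not fit inside the grid with a "
                    f"{LESION_MARGIN_VOX}-voxel margin along axis {ax} "
                    f"(extent [{lo:.1f}, {hi:.1f}] vs grid {self.grid_shape[ax]})"
                )


def _ellipsoid_mask(cfg: PhantomConfig) -> np.ndarray:
    center = cfg.center_vox()
    coords = np.ogrid[
        0 : cfg.grid_shape[0], 0 : cfg.grid_shape[1], 0 : cfg.grid_shape[2]
    ]
    q = np.zeros(cfg.grid_shape, dtype=np.float64)
    for ax in range(3):
        d_mm = (coords[ax] - center[ax]) * cfg.voxel_spacing_mm[ax]
        q = q + (d_mm / cfg.lesion_radii_mm[ax]) ** 2
    return q <= 1.0


def _correlated_field(rng, shape, spacing_mm, corr_len_mm) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = [corr_len_mm / s for s in spacing_mm]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sd = smooth.std()
    if sd < 1e-12:  # pathological (tiny grid / huge corr length)
        return np.zeros(shape)
    return smooth / sd


def generate_phantom(config: PhantomConfig) -> tuple[PETVolume, VOIMask]:
    """Generate one PET phantom and its ground-truth lesion mask.

    Returns
    -------
    (PETVolume, VOIMask)
        The simulated SUV image and the pre-blur ellipsoid support with
        provenance ``"truth"``. Deterministic in ``config`` (including
        ``seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _ellipsoid_mask(config)

    composite = np.full(config.grid_shape, config.background_suv_mean)
    composite[truth] = config.tumour_suv_mean
    if config.heterogeneity_amplitude > 0:
        field = _correlated_field(
            rng,
            config.grid_shape,
            config.voxel_spacing_mm,
            config.heterogeneity_corr_len_mm,
        )
        composite[truth] += config.heterogeneity_amplitude * field[truth]
    composite = np.clip(composite, 0.0, None)

    if config.psf_fwhm_mm > 0:
        sigma_vox = [
            config.psf_fwhm_mm * _FWHM_TO_SIGMA / s
            for s in config.voxel_spacing_mm
        ]
        composite = ndimage.gaussian_filter(composite, sigma=sigma_vox, mode="nearest")

    if config.noise_sigma_suv > 0:
        composite = composite + rng.normal(
            0.0, config.noise_sigma_suv, size=config.grid_shape
        )

    values = np.clip(composite, 0.0, None)
    vol = PETVolume(values, config.voxel_spacing_mm)
    mask = VOIMask(truth, config.voxel_spacing_mm, "truth")
    return vol, mask
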