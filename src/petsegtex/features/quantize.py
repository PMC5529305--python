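"""Grey-level quantization of a VOI.

Fixed-bin-number scheme over the in-mask intensity range:

    level(v) = 1 + floor(n_bins * (x(v) - min) / (max - min)),

with the maximum-intensity voxel clipped to ``n_bins``. The default 64
bins is the standard choice for PET texture analysis. Quantized levels
are invariant to positive affine rescaling of the intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grids import PETVolume, VOIMask

__all__ = ["QuantizedVOI", "quantize"]


@dataclass
class QuantizedVOI:
    """Integer grey levels on a VOI.

    ``levels`` is a full-grid int array with 0 outside the mask and
    values in ``1..n_bins`` inside. ``constant`` flags a degenerate VOI
    (max == min) whose levels are all 1.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    calibration: tuple[float, float]
    spacing_mm: tuple[float, float, float]
    constant: bool = False

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    def histogram(self) -> np.ndarray:
        """Occupancy of levels 1..n_bins (counts)."""
        return np.bincount(self.in_mask_levels, minlength=self.n_bins + 1)[1:]

    def probabilities(self) -> np.ndarray:
        h = self.histogram()
        return h / h.sum()


def quantize(volume: PETVolume, mask: VOIMask, n_bins: int = 64) -> QuantizedVOI:
    """Resample in-mask intensities into ``n_bins`` discrete grey levels."""
    mask.require_same_grid(VOIMask(np.zeros(volume.shape, bool), volume.spacing_mm))
    if mask.is_empty:
        raise ValueError("mask is empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = volume.values
    inside = x[mask.mask]
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi <= lo:
        levels[mask.mask] = 1
        return QuantizedVOI(
            levels, mask.mask.copy(), n_bins, (lo, hi), volume.spacing_mm, True
        )
    lv = 1 + np.floor(n_bins * (inside - lo) / (hi - lo)).astype(np.int32)
    np.clip(lv, 1, n_bins, out=lv)
    levels[mask.mask] = lv
    return QuantizedVOI(
        levels, mask.mask.copy(), n_bins, (lo, hi), volume.spacing_mm, False
    )
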