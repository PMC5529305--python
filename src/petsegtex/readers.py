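"""Simulated freehand contouring by imperfect readers.

Real readers draw slice-by-slice contours that deviate from the true
lesion boundary in two ways: a systematic tendency to over- or
under-contour (dilation bias) and unsystematic wobble along the contour
(jitter). Both are modelled here on each axial slice by thresholding the
signed Euclidean distance to the true boundary at ``bias + jitter``,
where the jitter term is a smooth zero-mean 2D Gaussian random field —
equivalent to perturbing the contour radially by spatially correlated
noise. Marginal (first/last occupied) slices may additionally be
dropped, emulating uncertainty about where a lesion starts and ends
axially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import VOIMask

__all__ = ["ReaderModel", "simulate_reader_mask", "EmptyContourError"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class EmptyContourError(RuntimeError):
    """Reader perturbation emptied the mask even after jitter reduction."""


@dataclass(frozen=True)
class ReaderModel:
    """Parameters of one simulated reader.

    boundary_jitter_mm
        Scale (sd) of the smooth per-slice contour perturbation.
    dilation_bias_mm
        Signed systematic offset: positive means over-contouring.
    slice_dropout_prob
        Probability that each marginal axial slice is omitted.
    """

    boundary_jitter_mm: float = 1.0
    dilation_bias_mm: float = 0.0
    slice_dropout_prob: float = 0.0
    seed: int = 0

    def validate(self, min_radius_mm: float | None = None) -> None:
        if self.boundary_jitter_mm < 0:
            raise ValueError("jitter must be >= 0")
        if not (0 <= self.slice_dropout_prob < 1):
            raise ValueError("slice_dropout_prob must be in [0, 1)")
        if min_radius_mm is not None and abs(self.dilation_bias_mm) >= min_radius_mm:
            raise ValueError("|dilation_bias_mm| must be below the smallest lesion radius")


def _signed_distance_2d(sl: np.ndarray, spacing_xy) -> np.ndarray:
    """Signed distance (mm) from each voxel center to the mask contour.

    Negative inside, positive outside. The half factor references the
    distance to the interface between voxels rather than to the nearest
    voxel center, so sub-voxel offsets can flip boundary voxels.
    """
    if not sl.any():
        return np.full(sl.shape, np.inf)
    outside = ndimage.distance_transform_edt(~sl, sampling=spacing_xy)
    inside = ndimage.distance_transform_edt(sl, sampling=spacing_xy)
    d = outside - inside
    half = min(spacing_xy) / 2.0
    return d - half * np.sign(d)


def _largest_cc(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _perturb_once(truth, reader, jitter_mm, rng) -> np.ndarray:
    sx, sy, _ = truth.spacing_mm
    tm = truth.mask
    out = np.zeros_like(tm)
    occupied = np.flatnonzero(tm.any(axis=(0, 1)))
    for z in occupied:
        sl = tm[:, :, z]
        d = _signed_distance_2d(sl, (sx, sy))
        offset = reader.dilation_bias_mm
        if jitter_mm > 0:
            field = ndimage.gaussian_filter(
                rng.standard_normal(sl.shape), sigma=2.0, mode="nearest"
            )
            sd = field.std()
            if sd > 1e-12:
                offset = offset + jitter_mm * field / sd
        out[:, :, z] = d <= offset
    # marginal-slice dropout on the truth's first/last occupied slices
    if reader.slice_dropout_prob > 0 and occupied.size > 1:
        for z in (occupied[0], occupied[-1]):
            if rng.random() < reader.slice_dropout_prob:
                out[:, :, z] = False
    return out


def simulate_reader_mask(truth: VOIMask, reader: ReaderModel) -> VOIMask:
    """Simulate one reader's freehand VOI from the ground-truth mask.

    With all perturbations zero this is the identity on masks. If the
    perturbation empties the mask the jitter is halved and the draw
    repeated, up to 3 attempts, after which :class:`EmptyContourError`
    is raised. The result is restricted to its largest 26-connected
    component.
    """
    if truth.is_empty:
        raise ValueError("truth mask is empty")
    reader.validate()
    rng = np.random.default_rng(reader.seed)
    jitter = reader.boundary_jitter_mm
    for _ in range(3):
        out = _perturb_once(truth, reader, jitter, rng)
        if out.any():
            return truth.with_mask(_largest_cc(out), "freehand")
        jitter = jitter / 2.0
    raise EmptyContourError(
        "reader perturbation emptied the mask after 3 attempts"
    )
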