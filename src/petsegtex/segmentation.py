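"""The three delineation algorithms compared by the pipeline.

Freehand (FH) masks are inputs — drawn by readers (or simulated). The
two automatic algorithms both start from the freehand VOI expanded by 5
voxels:

* 40P keeps voxels at or above 40% of the maximum activity in the
  expanded VOI.
* FLAB-style segmentation fits a three-class spatially regularized
  Gaussian mixture (background / partial-volume shell / tumour core) to
  the intensities inside the expanded VOI and keeps the two
  highest-mean classes.

The FLAB variant here is a documented re-design, not a reproduction of
any published implementation: class-conditional likelihoods are
Gaussian; the per-voxel class prior blends the global mixing weights
with the label frequencies in the voxel's 26-neighbourhood from the
previous iteration (weight ``spatial_weight``); parameters are updated
by EM-style alternation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.cluster.vq import kmeans2

from .grids import PETVolume, VOIMask

__all__ = [
    "FLABParams",
    "SegmentationResult",
    "expand_mask",
    "segment_40p",
    "segment_flab",
    "DegenerateSegmentationError",
]


class DegenerateSegmentationError(RuntimeError):
    """Segmentation produced (or would produce) an unusable mask."""


@dataclass(frozen=True)
class FLABParams:
    """Settings of the three-class Bayesian segmenter.

    ``variance_mode="pooled"`` (default) shares one variance across the
    three classes: with a dominant unimodal background this prevents the
    likelihood from splitting the background mode into two classes and
    forces the background / partial-volume / core structure the model
    intends. ``"per_class"`` frees the variances.
    """

    n_classes: int = 3  # background / partial volume / core
    max_iter: int = 100
    tol: float = 1e-4  # relative change in class means
    spatial_weight: float = 1.0
    init_strategy: str = "kmeans"  # or "quantile"
    variance_mode: str = "pooled"  # or "per_class"
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes != 3:
            raise ValueError("this segmenter is defined for exactly 3 classes")
        if self.max_iter < 1 or self.tol <= 0 or self.spatial_weight < 0:
            raise ValueError("invalid FLAB parameters")
        if self.init_strategy not in ("quantile", "kmeans"):
            raise ValueError("init_strategy must be 'quantile' or 'kmeans'")
        if self.variance_mode not in ("pooled", "per_class"):
            raise ValueError("variance_mode must be 'pooled' or 'per_class'")


@dataclass
class SegmentationResult:
    mask: VOIMask
    algorithm: str  # FH / 40P / FLAB
    volume_ml: float
    n_iterations: int | None = None
    class_means: tuple[float, float, float] | None = None  # sorted ascending
    class_variances: tuple[float, float, float] | None = None  # same order
    class_weights: tuple[float, float, float] | None = None  # same order
    converged: bool = True


def expand_mask(fh: VOIMask, n_voxels: int = 5) -> VOIMask:
    """Dilate a freehand VOI by Euclidean distance ``n_voxels`` in index space.

    The expansion covers the whole tumour plus surrounding background so
    the automatic algorithms see both classes; it is clipped at the grid
    bounds. ``n_voxels=0`` is the identity.
    """
    if fh.is_empty:
        raise ValueError("freehand mask is empty")
    if n_voxels < 0:
        raise ValueError("n_voxels must be >= 0")
    if n_voxels == 0:
        return fh.with_mask(fh.mask.copy(), "expanded")
    dist = ndimage.distance_transform_edt(~fh.mask)
    return fh.with_mask(dist <= n_voxels, "expanded")


def segment_40p(
    volume: PETVolume, expanded: VOIMask, fraction: float = 0.40
) -> SegmentationResult:
    """Fixed-threshold segmentation at ``fraction`` of the VOI maximum.

    Keeps voxels with activity >= fraction x (max activity inside the
    expanded VOI); the boundary value is retained. Invariant to positive
    rescaling of the volume.
    """
    expanded.require_same_grid(
        VOIMask(np.zeros(volume.shape, bool), volume.spacing_mm)
    )
    if expanded.is_empty:
        raise ValueError("expanded VOI is empty")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    inside = volume.values[expanded.mask]
    vmax = inside.max()
    if vmax <= 0:
        raise DegenerateSegmentationError("VOI contains no positive activity")
    mask = expanded.mask & (volume.values >= fraction * vmax)
    out = expanded.with_mask(mask, "40P")
    assert not (out.mask & ~expanded.mask).any()
    return SegmentationResult(out, "40P", out.volume_ml)


def _neighbor_fraction(onehot: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fraction of each voxel's 26-neighbours (within VOI) in each class.

    onehot: (K, nx, ny, nz) float; valid: (nx, ny, nz) bool.
    """
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    denom = ndimage.convolve(valid.astype(float), kernel, mode="constant")
    denom = np.maximum(denom, 1e-12)
    out = np.empty_like(onehot)
    for k in range(onehot.shape[0]):
        out[k] = ndimage.convolve(onehot[k] * valid, kernel, mode="constant") / denom
    return out


def segment_flab(
    volume: PETVolume, expanded: VOIMask, params: FLABParams | None = None
) -> SegmentationResult:
    """Three-class spatially regularized Gaussian-mixture segmentation.

    Voxels inside the expanded VOI are classified as background,
    partial-volume shell, or tumour core; the background class is
    discarded and the union of the two highest-mean classes returned.
    Deterministic for a fixed ``params`` (including seed).
    """
    params = params or FLABParams()
    params.validate()
    K = params.n_classes
    if expanded.n_voxels < 3 * K:
        raise ValueError("expanded VOI too small for a 3-class fit")

    # crop to the VOI bounding box (+1 pad) for speed
    idx = np.nonzero(expanded.mask)
    lo = [max(int(a.min()) - 1, 0) for a in idx]
    hi = [min(int(a.max()) + 2, s) for a, s in zip(idx, expanded.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    x = volume.values[sl]
    m = expanded.mask[sl]
    xv = x[m]

    if np.unique(xv).size < K:
        raise DegenerateSegmentationError(
            "fewer than 3 distinct intensity levels inside the VOI"
        )

    if params.init_strategy == "quantile":
        mu = np.quantile(xv, [1 / 6, 1 / 2, 5 / 6])
    else:
        rng = np.random.default_rng(params.seed)
        mu, _ = kmeans2(xv.astype(float), K, minit="++", seed=rng)
        mu = np.sort(mu)
    mu = np.asarray(mu, dtype=float)
    var = np.full(K, max(xv.var() / K, 1e-6))
    pi = np.full(K, 1.0 / K)

    post = None  # (K, *crop) responsibilities, zero outside VOI
    labels = None
    converged = False
    n_iter = 0
    w = params.spatial_weight
    for n_iter in range(1, params.max_iter + 1):
        # per-voxel prior: global mixing blended with neighbourhood freqs
        if labels is None or w == 0:
            prior = np.broadcast_to(pi[:, None], (K, xv.size)).copy()
        else:
            onehot = np.zeros((K,) + m.shape)
            for k in range(K):
                onehot[k][m] = (labels == k).astype(float)
            frac = _neighbor_fraction(onehot, m)
            frac_v = frac[:, m]
            prior = (pi[:, None] + w * frac_v) / (1.0 + w)
        # E step
        dens = np.empty((K, xv.size))
        for k in range(K):
            dens[k] = np.exp(-0.5 * (xv - mu[k]) ** 2 / var[k]) / np.sqrt(
                2 * np.pi * var[k]
            )
        num = prior * np.maximum(dens, 1e-300)
        num_sum = num.sum(axis=0)
        resp = num / np.maximum(num_sum, 1e-300)
        labels = resp.argmax(axis=0)
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        new_mu = (resp * xv).sum(axis=1) / nk
        new_var = (resp * (xv - new_mu[:, None]) ** 2).sum(axis=1) / nk
        if params.variance_mode == "pooled":
            new_var = np.full(K, (nk * new_var).sum() / nk.sum())
        new_var = np.maximum(new_var, 1e-8)
        pi = nk / nk.sum()
        rel = np.abs(new_mu - mu) / np.maximum(np.abs(mu), 1e-12)
        mu, var = new_mu, new_var
        if np.max(rel) < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            "FLAB segmentation did not converge within max_iter; "
            "returning best-so-far labels",
            RuntimeWarning,
            stacklevel=2,
        )

    order = np.argsort(mu)
    keep = set(order[-2:])  # two highest-mean classes: shell + core
    keep_v = np.isin(labels, list(keep))
    crop_mask = np.zeros(m.shape, dtype=bool)
    crop_mask[m] = keep_v
    full = np.zeros(expanded.shape, dtype=bool)
    full[sl] = crop_mask
    out = expanded.with_mask(full, "FLAB")
    assert not (out.mask & ~expanded.mask).any()
    if out.is_empty:
        raise DegenerateSegmentationError("FLAB kept no voxels")
    return SegmentationResult(
        out,
        "FLAB",
        out.volume_ml,
        n_iterations=n_iter,
        class_means=tuple(float(v) for v in mu[order]),
        class_variances=tuple(float(v) for v in var[order]),
        class_weights=tuple(float(v) for v in pi[order]),
        converged=converged,
    )
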