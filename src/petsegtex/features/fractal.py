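"""Model-based (fractal) features: 6 values.

Three box-counting dimensions, estimated as the least-squares slope of
log N(s) against log(1/s) over dyadic box sizes (1, 2, 4, 8, and 16
when the VOI is large enough):

* differential box counting (DBC) on the in-mask intensity surface,
  with intensities normalized to the spatial extent of the bounding box
  so the estimate is invariant to positive intensity scaling;
* solid box counting of the mask support;
* box counting of the mask boundary (voxels removed by one 26-connected
  erosion).

Plus gliding-box lacunarity of the mask at box sizes 2 and 4, and the
log-log slope between them. All six are NaN when the mask's bounding
box spans fewer than 4 voxels along every axis; lacunarity alone is NaN
when its gliding box does not fit the bounding box.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..grids import PETVolume, VOIMask
from .registry import FRACTAL

__all__ = ["fractal_features"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _bbox_crop(arr: np.ndarray, mask: np.ndarray):
    idx = np.nonzero(mask)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    return arr[sl], mask[sl]


def _pad_to_multiple(arr: np.ndarray, s: int, fill):
    shape = [int(np.ceil(n / s)) * s for n in arr.shape]
    out = np.full(shape, fill, dtype=arr.dtype)
    out[: arr.shape[0], : arr.shape[1], : arr.shape[2]] = arr
    return out


def _block_reduce(arr: np.ndarray, s: int, op):
    a = arr.reshape(
        arr.shape[0] // s, s, arr.shape[1] // s, s, arr.shape[2] // s, s
    )
    return op(op(op(a, axis=5), axis=3), axis=1)


def _box_sizes(extent: int) -> list[int]:
    sizes = [1, 2, 4, 8]
    if extent >= 16:
        sizes.append(16)
    return sizes


def _fit_dimension(sizes, counts) -> float:
    s = np.asarray(sizes, float)
    n = np.asarray(counts, float)
    ok = n > 0
    if ok.sum() < 2:
        return np.nan
    slope = np.polyfit(np.log(1.0 / s[ok]), np.log(n[ok]), 1)[0]
    return float(slope)


def _mask_box_count(mask: np.ndarray, s: int) -> int:
    if s == 1:
        return int(mask.sum())
    m = _pad_to_multiple(mask.astype(np.int64), s, 0)
    return int((_block_reduce(m, s, np.sum) > 0).sum())


def _dbc_count(values: np.ndarray, mask: np.ndarray, s: int) -> int:
    """Sum over occupied s^3 cells of the number of height-s boxes spanned."""
    if s == 1:
        return int(mask.sum())
    vmax = _pad_to_multiple(np.where(mask, values, -np.inf), s, -np.inf)
    vmin = _pad_to_multiple(np.where(mask, values, np.inf), s, np.inf)
    gmax = _block_reduce(vmax, s, np.max)
    gmin = _block_reduce(vmin, s, np.min)
    occ = np.isfinite(gmax)
    if not occ.any():
        return 0
    n = np.floor(gmax[occ] / s) - np.floor(gmin[occ] / s) + 1
    return int(n.sum())


def _gliding_box_lacunarity(mask: np.ndarray, s: int) -> float:
    """lambda(s) = <M^2> / <M>^2 over all s^3 windows inside the bbox."""
    c = np.pad(mask.astype(np.int64), ((1, 0), (1, 0), (1, 0)))
    c = c.cumsum(0).cumsum(1).cumsum(2)
    nx, ny, nz = mask.shape
    if min(nx, ny, nz) < s:
        return np.nan
    m = (
        c[s:, s:, s:]
        - c[:-s, s:, s:]
        - c[s:, :-s, s:]
        - c[s:, s:, :-s]
        + c[:-s, :-s, s:]
        + c[:-s, s:, :-s]
        + c[s:, :-s, :-s]
        - c[:-s, :-s, :-s]
    ).astype(float)
    mu = m.mean()
    if mu <= 0:
        return np.nan
    return float((m**2).mean() / mu**2)


def fractal_features(volume: PETVolume, mask: VOIMask) -> dict[str, float]:
    if mask.is_empty:
        raise ValueError("mask is empty")
    vals, m = _bbox_crop(volume.values, mask.mask)
    spans = m.shape
    # thin slabs are allowed (their boundary is the slab itself); only a
    # mask with no extent >= 4 along any axis is too small to fit a slope
    if max(spans) < 4:
        return {name: np.nan for name in FRACTAL}
    extent = max(spans)
    sizes = _box_sizes(extent)

    # intensity surface, normalized so height units match spatial units
    inside = vals[m]
    rng_i = inside.max() - inside.min()
    if rng_i > 0:
        norm = (vals - inside.min()) / rng_i * extent
    else:
        norm = np.zeros_like(vals)
    dbc = _fit_dimension(sizes, [_dbc_count(norm, m, s) for s in sizes])
    mask_dim = _fit_dimension(sizes, [_mask_box_count(m, s) for s in sizes])

    boundary = m & ~ndimage.binary_erosion(m, structure=_STRUCT26)
    if boundary.any():
        b_dim = _fit_dimension(sizes, [_mask_box_count(boundary, s) for s in sizes])
    else:
        b_dim = np.nan

    lac2 = _gliding_box_lacunarity(m, 2)
    lac4 = _gliding_box_lacunarity(m, 4)
    if np.isfinite(lac2) and np.isfinite(lac4) and lac2 > 0 and lac4 > 0:
        lac_slope = float((np.log(lac4) - np.log(lac2)) / np.log(2.0))
    else:
        lac_slope = np.nan

    out = {
        "fractal_dbc_dimension": dbc,
        "fractal_mask_dimension": mask_dim,
        "fractal_boundary_dimension": b_dim,
        "fractal_lacunarity_b2": lac2,
        "fractal_lacunarity_b4": lac4,
        "fractal_lacunarity_slope": lac_slope,
    }
    assert tuple(out.keys()) == FRACTAL
    return out
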