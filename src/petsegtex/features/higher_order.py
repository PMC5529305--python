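"""Higher-order texture features: 16 GLRLM + 14 GLSZM + 5 NGTDM = 35.

GLRLM: run-length matrices over the 13 unit directions; because several
features normalize by per-direction run counts, features are computed
per direction and averaged.

GLSZM: 26-connected constant-level zones. The "intensity variability"
member uses the size-weighted form
``sum_i (voxels at level i)^2 / n_zones``; the conventional zone-count
grey-level non-uniformity (normalized) is carried separately.

NGTDM: per-level summed absolute deviation from the 26-neighbourhood
mean level, neighbourhoods restricted to the mask. Coarseness is
``1 / (eps + sum p_i s_i)`` with eps = 1e-6, which caps the constant
VOI at 1e6.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .glcm import OFFSETS_13, _crop
from .quantize import QuantizedVOI
from .registry import GLRLM as GLRLM_NAMES
from .registry import GLSZM as GLSZM_NAMES
from .registry import NGTDM as NGTDM_NAMES

__all__ = [
    "higher_order_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "glszm_zones",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=int)
_NGTDM_EPS = 1e-6


# ---------------------------------------------------------------- GLRLM

def _runs_one_direction(L: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """Run levels and lengths along direction d. Level 0 breaks runs."""
    valid = L > 0
    # a run starts where the previous voxel along d is absent or differs
    prev = np.zeros_like(L)
    prev_valid = np.zeros_like(valid)
    s_src, s_dst = _shift_slices(L.shape, d)
    prev[s_dst] = L[s_src]
    prev_valid[s_dst] = valid[s_src]
    start = valid & (~prev_valid | (prev != L))
    coords = np.argwhere(start)
    if coords.size == 0:
        return np.empty(0, int), np.empty(0, int)
    levels = L[tuple(coords.T)]
    lengths = np.ones(len(coords), dtype=int)
    cur = coords.copy()
    active = np.arange(len(coords))
    dvec = np.asarray(d)
    while active.size:
        nxt = cur[active] + dvec
        inb = np.all((nxt >= 0) & (nxt < L.shape), axis=1)
        cont = np.zeros(active.size, dtype=bool)
        if inb.any():
            ni = nxt[inb]
            same = L[tuple(ni.T)] == levels[active[inb]]
            cont[inb] = same
        keep = active[cont]
        lengths[keep] += 1
        cur[keep] += dvec
        active = keep
    return levels, lengths


def _shift_slices(shape, d):
    """Slices so that out[dst] = in[src] shifts the array by +d."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def _glrlm_one(levels: np.ndarray, lengths: np.ndarray, n_voxels: int) -> dict:
    i = levels.astype(float)
    l = lengths.astype(float)
    nr = float(len(levels))
    p = np.ones_like(i) / nr
    # marginal sums over runs sharing a level / a length
    lvl_tot = np.bincount(levels)
    len_tot = np.bincount(lengths)
    mu_i = (p * i).sum()
    mu_l = (p * l).sum()
    lvl_counts, len_counts = lvl_tot[lvl_tot > 0], len_tot[len_tot > 0]
    # run entropy over distinct (level, length) cells
    cell = levels.astype(np.int64) * (lengths.max() + 1) + lengths
    cell_counts = np.unique(cell, return_counts=True)[1] / nr
    re = float(-(cell_counts * np.log2(cell_counts)).sum())
    return {
        "glrlm_sre": float((1.0 / l**2).mean()),
        "glrlm_lre": float((l**2).mean()),
        "glrlm_gln": float((lvl_counts.astype(float) ** 2).sum() / nr),
        "glrlm_glnn": float((lvl_counts.astype(float) ** 2).sum() / nr**2),
        "glrlm_rln": float((len_counts.astype(float) ** 2).sum() / nr),
        "glrlm_rlnn": float((len_counts.astype(float) ** 2).sum() / nr**2),
        "glrlm_rp": float(nr / n_voxels),
        "glrlm_glv": float((p * (i - mu_i) ** 2).sum()),
        "glrlm_rv": float((p * (l - mu_l) ** 2).sum()),
        "glrlm_re": re,
        "glrlm_lglre": float((1.0 / i**2).mean()),
        "glrlm_hglre": float((i**2).mean()),
        "glrlm_srlgle": float((1.0 / (i**2 * l**2)).mean()),
        "glrlm_srhgle": float((i**2 / l**2).mean()),
        "glrlm_lrlgle": float((l**2 / i**2).mean()),
        "glrlm_lrhgle": float((i**2 * l**2).mean()),
    }


def glrlm_features(q: QuantizedVOI) -> dict[str, float]:
    L = _crop(q)
    n_vox = int((L > 0).sum())
    per_dir = []
    for d in OFFSETS_13:
        levels, lengths = _runs_one_direction(L, d)
        if levels.size:
            per_dir.append(_glrlm_one(levels, lengths, n_vox))
    if not per_dir:
        return {name: np.nan for name in GLRLM_NAMES}
    out = {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES
    }
    return out


# ---------------------------------------------------------------- GLSZM

def glszm_zones(q: QuantizedVOI) -> tuple[np.ndarray, np.ndarray]:
    """All 26-connected constant-level zones: (zone levels, zone sizes)."""
    L = _crop(q)
    levels_out, sizes_out = [], []
    for lev in np.unique(L[L > 0]):
        lab, n = ndimage.label(L == lev, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        levels_out.extend([int(lev)] * n)
        sizes_out.extend(int(s) for s in sizes)
    return np.asarray(levels_out), np.asarray(sizes_out)


def glszm_features(q: QuantizedVOI) -> dict[str, float]:
    levels, sizes = glszm_zones(q)
    if levels.size == 0:
        return {name: np.nan for name in GLSZM_NAMES}
    i = levels.astype(float)
    z = sizes.astype(float)
    nz = float(levels.size)
    n_vox = float(sizes.sum())
    p = np.ones_like(i) / nz
    mu_i = (p * i).sum()
    mu_z = (p * z).sum()
    # per-level voxel totals (size-weighted) and zone counts
    vox_per_level = np.bincount(levels, weights=sizes)
    vox_per_level = vox_per_level[vox_per_level > 0]
    zones_per_level = np.bincount(levels)
    zones_per_level = zones_per_level[zones_per_level > 0].astype(float)
    zones_per_size = np.bincount(sizes)
    zones_per_size = zones_per_size[zones_per_size > 0].astype(float)
    cell = levels.astype(np.int64) * (sizes.max() + 1) + sizes
    cell_p = np.unique(cell, return_counts=True)[1] / nz
    out = {
        "glszm_sae": float((1.0 / z**2).mean()),
        "glszm_lae": float((z**2).mean()),
        "glszm_intensity_variability": float((vox_per_level**2).sum() / nz),
        "glszm_glnn": float((zones_per_level**2).sum() / nz**2),
        "glszm_szn": float((zones_per_size**2).sum() / nz),
        "glszm_sznn": float((zones_per_size**2).sum() / nz**2),
        "glszm_zp": float(nz / n_vox),
        "glszm_glv": float((p * (i - mu_i) ** 2).sum()),
        "glszm_zv": float((p * (z - mu_z) ** 2).sum()),
        "glszm_ze": float(-(cell_p * np.log2(cell_p)).sum()),
        "glszm_lglze": float((1.0 / i**2).mean()),
        "glszm_hglze": float((i**2).mean()),
        "glszm_salgle": float((1.0 / (i**2 * z**2)).mean()),
        "glszm_sahgle": float((i**2 / z**2).mean()),
    }
    assert tuple(out.keys()) == GLSZM_NAMES
    return out


# ---------------------------------------------------------------- NGTDM

def ngtdm_features(q: QuantizedVOI) -> dict[str, float]:
    L = _crop(q).astype(float)
    m = L > 0
    kernel = _STRUCT26.copy()
    kernel[1, 1, 1] = 0
    nbr_sum = ndimage.convolve(L * m, kernel.astype(float), mode="constant")
    nbr_cnt = ndimage.convolve(m.astype(float), kernel.astype(float), mode="constant")
    use = m & (nbr_cnt > 0)
    n = float(use.sum())
    if n == 0:
        return {name: np.nan for name in NGTDM_NAMES}
    abar = nbr_sum[use] / nbr_cnt[use]
    lev = L[use].astype(int)
    dev = np.abs(L[use] - abar)
    nb = q.n_bins
    s = np.bincount(lev, weights=dev, minlength=nb + 1)[1:]
    counts = np.bincount(lev, minlength=nb + 1)[1:]
    p = counts / n
    present = p > 0
    ngp = int(present.sum())
    ivals = np.arange(1, nb + 1, dtype=float)

    ps = float((p * s).sum())
    coarseness = 1.0 / (_NGTDM_EPS + ps)

    if ngp > 1:
        pi, ii, si = p[present], ivals[present], s[present]
        dif2 = (ii[:, None] - ii[None, :]) ** 2
        pp = pi[:, None] * pi[None, :]
        contrast = (pp * dif2).sum() / (ngp * (ngp - 1)) * (s.sum() / n)
        denom_busy = np.abs(
            (ii * pi)[:, None] - (ii * pi)[None, :]
        ).sum()
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        absdif = np.abs(ii[:, None] - ii[None, :])
        psum = pi[:, None] + pi[None, :]
        complexity = (
            absdif * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :]) / psum
        ).sum() / n
        strength = (psum * dif2).sum() / (_NGTDM_EPS + s.sum())
    else:
        contrast = busyness = complexity = strength = 0.0

    out = {
        "ngtdm_coarseness": float(coarseness),
        "ngtdm_contrast": float(contrast),
        "ngtdm_busyness": float(busyness),
        "ngtdm_complexity": float(complexity),
        "ngtdm_strength": float(strength),
    }
    assert tuple(out.keys()) == NGTDM_NAMES
    return out


def higher_order_features(q: QuantizedVOI) -> dict[str, float]:
    """All 35 higher-order features (GLRLM, GLSZM, NGTDM)."""
    if not q.mask.any():
        raise ValueError("mask is empty")
    out: dict[str, float] = {}
    out.update(glrlm_features(q))
    out.update(glszm_features(q))
    out.update(ngtdm_features(q))
    return out
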