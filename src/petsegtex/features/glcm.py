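"""Second-order (grey-level co-occurrence) features: 22 values.

A symmetric 3D GLCM is accumulated for each of the 13 unique unit
offsets at distance 1 voxel (index space), counting only pairs with
both voxels inside the mask. Each direction's matrix is normalized and
the 13 normalized matrices averaged; the classical Haralick-derived
features are computed once on the averaged matrix.
"""

from __future__ import annotations

import numpy as np

from .quantize import QuantizedVOI
from .registry import GLCM

__all__ = ["glcm_features", "glcm_matrix", "OFFSETS_13"]

#: the 13 unique 26-neighbourhood directions (up to sign)
OFFSETS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


def _crop(q: QuantizedVOI) -> np.ndarray:
    idx = np.nonzero(q.mask)
    sl = tuple(
        slice(int(a.min()), int(a.max()) + 1) for a in idx
    )
    return q.levels[sl]


def _pair_slices(shape, d):
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


def glcm_matrix(q: QuantizedVOI) -> np.ndarray | None:
    """Direction-averaged normalized symmetric GLCM (n_bins x n_bins).

    Returns None when no direction has a valid in-mask pair.
    """
    L = _crop(q)
    nb = q.n_bins
    mats = []
    for d in OFFSETS_13:
        s_src, s_dst = _pair_slices(L.shape, d)
        a = L[s_src].ravel()
        b = L[s_dst].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        a, b = a[ok] - 1, b[ok] - 1
        m = np.zeros((nb, nb))
        np.add.at(m, (a, b), 1.0)
        np.add.at(m, (b, a), 1.0)  # symmetric
        mats.append(m / m.sum())
    if not mats:
        return None
    return np.mean(mats, axis=0)


def glcm_features(q: QuantizedVOI) -> dict[str, float]:
    """Compute the 22-feature GLCM family on the averaged matrix."""
    if q.mask.sum() < 2:
        raise ValueError("need at least 2 in-mask voxels")
    P = glcm_matrix(q)
    if P is None:
        return {name: np.nan for name in GLCM}
    return features_from_matrix(P, q.n_bins)


def features_from_matrix(P: np.ndarray, n_bins: int) -> dict[str, float]:
    nb = P.shape[0]
    i = np.arange(1, nb + 1, dtype=float)
    I = i[:, None] * np.ones((1, nb))
    J = I.T
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    absdiff = np.abs(I - J)
    # p_{x-y}: distribution of |i-j| over 0..nb-1
    pdiff = np.zeros(nb)
    np.add.at(pdiff, absdiff.astype(int).ravel(), P.ravel())
    k_diff = np.arange(nb, dtype=float)
    # p_{x+y}: distribution of i+j over 2..2nb
    psum = np.zeros(2 * nb + 1)
    np.add.at(psum, (I + J).astype(int).ravel(), P.ravel())
    psum = psum[2:]
    k_sum = np.arange(2, 2 * nb + 1, dtype=float)

    def ent(p):
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())

    hxy = ent(P.ravel())
    hx, hy = ent(px), ent(py)
    pxpy = px[:, None] * py[None, :]
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.maximum(pxpy, 1e-300)), 0.0)
    hxy1 = float(-(P * log_pxpy).sum())
    hxy2 = float(-(pxpy * log_pxpy).sum())

    autoc = float((I * J * P).sum())
    diff_avg = float((k_diff * pdiff).sum())
    denom_imc1 = max(hx, hy)
    imc1 = (hxy - hxy1) / denom_imc1 if denom_imc1 > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    offdiag = absdiff > 0
    inv_var = float((P[offdiag] / (I - J)[offdiag] ** 2).sum())
    if sigx * sigy > 0:
        correlation = (autoc - mux * muy) / (sigx * sigy)
    else:
        correlation = 1.0  # degenerate single-level matrix

    cdev = I + J - mux - muy
    out = {
        "glcm_autocorrelation": autoc,
        "glcm_joint_average": mux,
        "glcm_cluster_prominence": float((cdev**4 * P).sum()),
        "glcm_cluster_shade": float((cdev**3 * P).sum()),
        "glcm_cluster_tendency": float((cdev**2 * P).sum()),
        "glcm_contrast": float(((I - J) ** 2 * P).sum()),
        "glcm_correlation": float(correlation),
        "glcm_difference_average": diff_avg,
        "glcm_difference_entropy": ent(pdiff),
        "glcm_difference_variance": float(((k_diff - diff_avg) ** 2 * pdiff).sum()),
        "glcm_energy": float((P**2).sum()),
        "glcm_entropy": hxy,
        "glcm_homogeneity": float((P / (1.0 + absdiff)).sum()),
        "glcm_dissimilarity": float((absdiff * P).sum()),
        "glcm_idm": float((P / (1.0 + (I - J) ** 2)).sum()),
        "glcm_idmn": float((P / (1.0 + ((I - J) / n_bins) ** 2)).sum()),
        "glcm_idn": float((P / (1.0 + absdiff / n_bins)).sum()),
        "glcm_imc1": float(imc1),
        "glcm_imc2": imc2,
        "glcm_inverse_variance": inv_var,
        "glcm_max_probability": float(P.max()),
        "glcm_sum_entropy": ent(psum),
    }
    assert tuple(out.keys()) == GLCM
    return out
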