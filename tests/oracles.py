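"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops over explicit
definitions, independent of the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def glcm_oracle(levels: np.ndarray, n_bins: int) -> dict[str, float] | None:
    """Direction-averaged GLCM features by exhaustive pair enumeration.

    ``levels``: integer array, 0 outside the mask, 1..n_bins inside.
    """
    shape = levels.shape
    mats = []
    for d in DIRECTIONS_13:
        m = np.zeros((n_bins, n_bins))
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    a = levels[x, y, z]
                    if a == 0:
                        continue
                    xx, yy, zz = x + d[0], y + d[1], z + d[2]
                    if not (0 <= xx < shape[0] and 0 <= yy < shape[1] and 0 <= zz < shape[2]):
                        continue
                    b = levels[xx, yy, zz]
                    if b == 0:
                        continue
                    m[a - 1, b - 1] += 1
                    m[b - 1, a - 1] += 1
        if m.sum() > 0:
            mats.append(m / m.sum())
    if not mats:
        return None
    P = sum(mats) / len(mats)
    return glcm_feature_formulas(P, n_bins)


def glcm_feature_formulas(P: np.ndarray, n_bins: int) -> dict[str, float]:
    """Loop-based evaluation of the 22 feature definitions."""
    nb = P.shape[0]
    px = [P[i, :].sum() for i in range(nb)]
    py = [P[:, j].sum() for j in range(nb)]
    mux = sum((i + 1) * px[i] for i in range(nb))
    muy = sum((j + 1) * py[j] for j in range(nb))
    sigx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(nb)))
    sigy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(nb)))
    pdiff = [0.0] * nb
    psum = [0.0] * (2 * nb + 1)
    for i in range(nb):
        for j in range(nb):
            pdiff[abs(i - j)] += P[i, j]
            psum[i + j + 2] += P[i, j]

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hxy = ent(P.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * py[j])
        for i in range(nb)
        for j in range(nb)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(nb)
        for j in range(nb)
        if px[i] * py[j] > 0
    )
    autoc = sum((i + 1) * (j + 1) * P[i, j] for i in range(nb) for j in range(nb))
    diff_avg = sum(k * pdiff[k] for k in range(nb))
    corr = (autoc - mux * muy) / (sigx * sigy) if sigx * sigy > 0 else 1.0
    out = {
        "glcm_autocorrelation": autoc,
        "glcm_joint_average": mux,
        "glcm_cluster_prominence": sum(
            (i + 1 + j + 1 - mux - muy) ** 4 * P[i, j] for i in range(nb) for j in range(nb)
        ),
        "glcm_cluster_shade": sum(
            (i + 1 + j + 1 - mux - muy) ** 3 * P[i, j] for i in range(nb) for j in range(nb)
        ),
        "glcm_cluster_tendency": sum(
            (i + 1 + j + 1 - mux - muy) ** 2 * P[i, j] for i in range(nb) for j in range(nb)
        ),
        "glcm_contrast": sum((i - j) ** 2 * P[i, j] for i in range(nb) for j in range(nb)),
        "glcm_correlation": corr,
        "glcm_difference_average": diff_avg,
        "glcm_difference_entropy": ent(pdiff),
        "glcm_difference_variance": sum(
            (k - diff_avg) ** 2 * pdiff[k] for k in range(nb)
        ),
        "glcm_energy": sum(P[i, j] ** 2 for i in range(nb) for j in range(nb)),
        "glcm_entropy": hxy,
        "glcm_homogeneity": sum(
            P[i, j] / (1 + abs(i - j)) for i in range(nb) for j in range(nb)
        ),
        "glcm_dissimilarity": sum(
            abs(i - j) * P[i, j] for i in range(nb) for j in range(nb)
        ),
        "glcm_idm": sum(
            P[i, j] / (1 + (i - j) ** 2) for i in range(nb) for j in range(nb)
        ),
        "glcm_idmn": sum(
            P[i, j] / (1 + ((i - j) / n_bins) ** 2)
            for i in range(nb)
            for j in range(nb)
        ),
        "glcm_idn": sum(
            P[i, j] / (1 + abs(i - j) / n_bins) for i in range(nb) for j in range(nb)
        ),
        "glcm_imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "glcm_imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "glcm_inverse_variance": sum(
            P[i, j] / (i - j) ** 2 for i in range(nb) for j in range(nb) if i != j
        ),
        "glcm_max_probability": float(P.max()),
        "glcm_sum_entropy": ent(psum),
    }
    return out


def icc2_oracle(matrix: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA table, written out longhand.

    ``matrix``: subjects x raters.
    """
    n, k = matrix.shape
    grand = matrix.mean()
    row_means = matrix.mean(axis=1)
    col_means = matrix.mean(axis=0)
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_total = sum((v - grand) ** 2 for v in matrix.ravel())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def cox_partial_loglik(beta: float, x, time, event) -> float:
    """Breslow partial log-likelihood (exact = Efron when no ties)."""
    ll = 0.0
    for i in range(len(x)):
        if not event[i]:
            continue
        risk = [j for j in range(len(x)) if time[j] >= time[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def cox_grid_mle(x, time, event, lo=-5.0, hi=5.0) -> float:
    """Grid-search maximizer of the partial likelihood, refined twice."""
    grid = np.linspace(lo, hi, 2001)
    for _ in range(3):
        lls = [cox_partial_loglik(b, x, time, event) for b in grid]
        best = grid[int(np.argmax(lls))]
        width = (grid[1] - grid[0]) * 10
        grid = np.linspace(best - width, best + width, 401)
    return float(best)
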