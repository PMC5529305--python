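"""Agreement statistics: JSI, Mann-Whitney, ICC and bootstrap comparisons.

The intraclass correlation is the two-way random-effects,
absolute-agreement, single-measurement form ICC(2,1) by default —
readers are treated as interchangeable random raters; ICC(3,1) is
available via ``form``. Confidence intervals follow the standard
F-distribution construction. Pairwise ICC differences between
segmentation algorithms are compared with a paired patient bootstrap
(the same resampled patients enter both algorithms' ICCs) and a
percentile interval, 100 resamples by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .grids import VOIMask

__all__ = [
    "JSIResult",
    "ICCResult",
    "ICCDiff",
    "jaccard",
    "compare_jsi_sets",
    "jsi_volume_regression",
    "icc",
    "icc_value",
    "icc_band",
    "icc_diff_bootstrap",
    "select_log_transform",
]

logger = logging.getLogger(__name__)

ID_COLUMNS = ("patient_id", "reader_id", "algorithm")


@dataclass(frozen=True)
class JSIResult:
    jsi_percent: float
    patient_id: str = ""
    algo_pair: tuple[str, str] = ("", "")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    band: str
    feature: str = ""
    algorithm: str = ""
    form: str = "icc2"


@dataclass(frozen=True)
class ICCDiff:
    feature: str
    algo_pair: tuple[str, str]
    delta_icc: float
    ci95_boot: tuple[float, float]
    significant: bool
    n_boot: int
    seed: int


# ------------------------------------------------------------------ JSI

def jaccard(
    a: VOIMask,
    b: VOIMask,
    patient_id: str = "",
    algo_pair: tuple[str, str] = ("", ""),
) -> JSIResult:
    """Jaccard similarity index between two masks, as a percentage.

    100 x |a AND b| / |a OR b|; 100 iff identical, 0 iff disjoint.
    """
    a.require_same_grid(b)
    union = int((a.mask | b.mask).sum())
    if union == 0:
        raise ValueError("both masks are empty: JSI undefined (0/0)")
    inter = int((a.mask & b.mask).sum())
    return JSIResult(100.0 * inter / union, patient_id, algo_pair)


def _jsi_values(s) -> np.ndarray:
    vals = [x.jsi_percent if isinstance(x, JSIResult) else float(x) for x in s]
    return np.asarray(vals, dtype=float)


def compare_jsi_sets(set1, set2) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two JSI samples.

    Exact when both samples have n <= 20 and no cross-sample ties,
    otherwise normal approximation with tie correction.
    Returns (U statistic, p value).
    """
    x, y = _jsi_values(set1), _jsi_values(set2)
    if x.size == 0 or y.size == 0:
        raise ValueError("both JSI sets must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def jsi_volume_regression(volumes_ml, jsi) -> tuple[float, float, float]:
    """OLS of JSI% on lesion volume: returns (slope, intercept, r^2)."""
    v = np.asarray(volumes_ml, dtype=float)
    j = _jsi_values(jsi)
    if v.size < 3 or v.size != j.size:
        raise ValueError("need n >= 3 matched volumes and JSI values")
    if v.std() == 0:
        raise ValueError("zero-variance volumes: regression undefined")
    if j.std() == 0:  # flat response: slope and r^2 are exactly zero
        return 0.0, float(j[0]), 0.0
    res = sstats.linregress(v, j)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ------------------------------------------------------------------ ICC

def _mean_squares(x: np.ndarray):
    """Two-way ANOVA mean squares for stacked data (..., n subjects, k raters)."""
    n, k = x.shape[-2], x.shape[-1]
    grand = x.mean(axis=(-2, -1), keepdims=True)
    rows = x.mean(axis=-1, keepdims=True)
    cols = x.mean(axis=-2, keepdims=True)
    ssr = k * ((rows - grand) ** 2).sum(axis=(-2, -1))
    ssc = n * ((cols - grand) ** 2).sum(axis=(-2, -1))
    sst = ((x - grand) ** 2).sum(axis=(-2, -1))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = np.maximum(sse, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse, sst


def icc_value(x: np.ndarray, form: str = "icc2") -> np.ndarray:
    """Point estimate(s) of ICC for stacked matrices (..., n, k).

    Vectorized over leading axes (used by the bootstrap). ``form`` is
    ``"icc2"`` (absolute agreement) or ``"icc3"`` (consistency).
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape[-2], x.shape[-1]
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 raters")
    msr, msc, mse, sst = _mean_squares(x)
    if form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("form must be 'icc2' or 'icc3'")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (msr - mse) / denom
    return np.where(sst > 0, out, np.nan)


def icc_band(value: float) -> str:
    """high (>0.85) / moderate (0.7-0.85) / low (<0.7) reproducibility."""
    if value > 0.85:
        return "high"
    if value >= 0.7:
        return "moderate"
    return "low"


def icc(
    values: np.ndarray,
    form: str = "icc2",
    alpha: float = 0.05,
    feature: str = "",
    algorithm: str = "",
) -> ICCResult:
    """ICC of a readers x subjects matrix with an F-based 95% CI.

    ``values`` has one row per reader and one column per subject, no
    missing cells.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected a 2D readers x subjects matrix")
    if np.isnan(v).any():
        raise ValueError("missing cells are not supported")
    x = v.T  # (n subjects, k raters)
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 readers and >= 3 subjects")
    msr, msc, mse, sst = _mean_squares(x)
    if sst <= 0:
        raise ValueError("zero total variance: ICC undefined")
    est = float(icc_value(x, form))

    if form == "icc3":
        f_obs = msr / mse if mse > 0 else np.inf
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / sstats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * sstats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + (k - 1))
        hi = (fu - 1) / (fu + (k - 1))
    else:
        # Satterthwaite construction for ICC(2,1)
        fj = msc / mse if mse > 0 else np.inf
        a_ = k * est / (n * (1 - est)) if est < 1 else np.inf
        vn = (k - 1) * (n - 1) * (
            k * est * fj + n * (1 + (k - 1) * est) - k * est
        ) ** 2
        vd = (n - 1) * (k * est * fj) ** 2 + (
            n * (1 + (k - 1) * est) - k * est
        ) ** 2
        dof = vn / vd if vd > 0 else 1.0
        f_u = sstats.f.ppf(1 - alpha / 2, n - 1, dof)
        f_l = sstats.f.ppf(1 - alpha / 2, dof, n - 1)
        lo = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr
        )
    lo, hi = float(min(lo, est)), float(max(hi, est))
    return ICCResult(est, (max(lo, -1.0), min(hi, 1.0)), icc_band(est), feature, algorithm, form)


# -------------------------------------------------------- ICC bootstrap

def _algo_matrix(table: pd.DataFrame, feature: str, algo: str) -> np.ndarray:
    """Subjects x readers matrix for one feature under one algorithm."""
    sub = table.loc[table["algorithm"] == algo]
    if sub.empty:
        raise ValueError(f"algorithm {algo!r} absent from table")
    wide = sub.pivot(index="patient_id", columns="reader_id", values=feature)
    if wide.isna().any().any():
        raise ValueError(f"incomplete reader data for {feature!r}/{algo!r}")
    return wide.sort_index().to_numpy(dtype=float)


def icc_diff_bootstrap(
    table: pd.DataFrame,
    feature: str,
    algo_a: str,
    algo_b: str,
    n_boot: int = 100,
    seed: int = 0,
    form: str = "icc2",
) -> ICCDiff:
    """Percentile bootstrap 95% CI for ICC(algo_a) - ICC(algo_b).

    Patients are resampled with replacement; the same resample is
    applied to both algorithms, preserving the pairing. Replicates with
    zero between-subject variance in either algorithm are redrawn (up
    to 10 x n_boot extra draws). Deterministic under ``seed``.
    """
    xa = _algo_matrix(table, feature, algo_a)
    xb = _algo_matrix(table, feature, algo_b)
    if xa.shape != xb.shape:
        raise ValueError("algorithms cover different (patient, reader) sets")
    n = xa.shape[0]
    point = float(icc_value(xa, form) - icc_value(xb, form))
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    filled = 0
    attempts = 0
    max_attempts = 10 * n_boot
    batch = max(n_boot, 32)
    while filled < n_boot and attempts < max_attempts:
        idx = rng.integers(0, n, size=(batch, n))
        da = icc_value(xa[idx], form)
        db = icc_value(xb[idx], form)
        d = da - db
        ok = np.isfinite(d)
        take = min(int(ok.sum()), n_boot - filled)
        deltas[filled : filled + take] = d[ok][:take]
        filled += take
        attempts += batch
    if filled < n_boot:
        raise RuntimeError("too many degenerate bootstrap resamples")
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    significant = not (lo <= 0.0 <= hi)
    return ICCDiff(
        feature, (algo_a, algo_b), point, (float(lo), float(hi)),
        significant, n_boot, seed,
    )


# ---------------------------------------------------- log10 transform

def select_log_transform(
    table: pd.DataFrame,
    skew_cutoff: float = 1.0,
    feature_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """log10-transform positively skewed, strictly positive features.

    A reproducible stand-in for visual Q-Q inspection: any feature whose
    sample skewness exceeds ``skew_cutoff`` is log10-transformed.
    Features containing non-positive values are skipped with a warning
    regardless of skewness. Returns (transformed copy, transformed names).
    """
    out = table.copy()
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in ID_COLUMNS]
    transformed: list[str] = []
    for col in feature_cols:
        x = out[col].to_numpy(dtype=float)
        finite = x[np.isfinite(x)]
        if finite.size < 3:
            continue
        skew = sstats.skew(finite)
        if skew <= skew_cutoff:
            continue
        if finite.min() <= 0:
            warnings.warn(
                f"feature {col!r} is skewed (skew={skew:.2f}) but contains "
                "non-positive values; log10 transform skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        out[col] = np.log10(out[col])
        transformed.append(col)
        logger.debug("log10-transformed %s (skew %.2f)", col, skew)
    return out, transformed
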