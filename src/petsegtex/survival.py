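"""Univariate Cox proportional-hazards screen of selected texture features.

Each of the 12 screen features is fitted alone against overall
survival, per segmentation algorithm, using the Cox partial likelihood
with Efron tie handling (via lifelines). Reported per fit: hazard ratio
per unit of the (possibly log10-transformed) feature with its Wald 95%
CI and p value, the hazard ratio per standard deviation (feature scale
is arbitrary across the panel), and the partial-likelihood AIC
``-2 logPL + 2`` with an optional patient-bootstrap percentile CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cohort import SurvivalRecord
from .features.registry import SCREEN_FEATURES

__all__ = [
    "CoxScreenRow",
    "cox_univariate",
    "aic_bootstrap_ci",
    "run_survival_screen",
    "CoxFitError",
]

logger = logging.getLogger(__name__)


class CoxFitError(RuntimeError):
    """Cox fit impossible (separation, degenerate covariate, ...)."""


@dataclass
class CoxScreenRow:
    feature: str
    algorithm: str
    hr: float
    hr_ci95: tuple[float, float]
    hr_per_sd: float
    wald_p: float
    aic: float
    aic_ci95: tuple[float, float] | None
    n: int
    n_events: int
    coef: float = np.nan
    log_transformed: bool = False

    @property
    def significant(self) -> bool:
        return bool(self.wald_p < 0.05)


def _records_frame(feature_values, survival: list[SurvivalRecord]) -> pd.DataFrame:
    x = np.asarray(feature_values, dtype=float)
    if len(survival) != x.size:
        raise ValueError("feature values and survival records differ in length")
    return pd.DataFrame(
        {
            "x": x,
            "time": [r.time_months for r in survival],
            "event": [int(r.event) for r in survival],
        }
    )


def _validate(df: pd.DataFrame) -> None:
    if not np.all(np.isfinite(df["x"])):
        raise CoxFitError("non-finite feature values")
    if len(df) < 5:
        raise CoxFitError("need at least 5 patients")
    if df["event"].sum() < 3:
        raise CoxFitError("need at least 3 observed events")
    if df["x"].std(ddof=0) < 1e-12:
        raise CoxFitError("zero-variance covariate")


def _fit(df: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        # tight Newton precision: the partial likelihood is flat for the
        # small-n screens and the default stopping rule leaves ~1e-4 slack
        cph.fit(
            df,
            duration_col="time",
            event_col="event",
            fit_options={"precision": 1e-10},
        )
    except ConvergenceError as exc:  # monotone-likelihood separation etc.
        raise CoxFitError(f"Cox fit failed to converge: {exc}") from exc
    return cph


def cox_univariate(
    feature_values,
    survival: list[SurvivalRecord],
    feature: str = "",
    algorithm: str = "",
) -> CoxScreenRow:
    """Single-covariate Cox fit: HR, Wald p, and partial-likelihood AIC."""
    df = _records_frame(feature_values, survival)
    _validate(df)
    cph = _fit(df)
    s = cph.summary.loc["x"]
    beta = float(s["coef"])
    sd = float(df["x"].std(ddof=0))
    aic = float(-2.0 * cph.log_likelihood_ + 2.0)
    return CoxScreenRow(
        feature=feature,
        algorithm=algorithm,
        hr=float(np.exp(beta)),
        hr_ci95=(float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])),
        hr_per_sd=float(np.exp(beta * sd)),
        wald_p=float(s["p"]),
        aic=aic,
        aic_ci95=None,
        n=int(len(df)),
        n_events=int(df["event"].sum()),
        coef=beta,
    )


def aic_bootstrap_ci(
    feature_values,
    survival: list[SurvivalRecord],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% CI of the AIC under patient-level resampling.

    Non-convergent or degenerate replicates are redrawn, up to
    ``5 * n_boot`` attempts.
    """
    df = _records_frame(feature_values, survival)
    _validate(df)
    rng = np.random.default_rng(seed)
    n = len(df)
    aics = np.empty(n_boot)
    filled = 0
    attempts = 0
    while filled < n_boot:
        if attempts >= 5 * n_boot:
            raise RuntimeError("too many failed bootstrap replicates")
        attempts += 1
        idx = rng.integers(0, n, size=n)
        rep = df.iloc[idx].reset_index(drop=True)
        try:
            _validate(rep)
            cph = _fit(rep)
        except CoxFitError:
            continue
        aics[filled] = -2.0 * cph.log_likelihood_ + 2.0
        filled += 1
    lo, hi = np.percentile(aics, [2.5, 97.5])
    return float(lo), float(hi)


def run_survival_screen(
    table: pd.DataFrame,
    survival: list[SurvivalRecord],
    features: tuple[str, ...] = SCREEN_FEATURES,
    algorithms: tuple[str, ...] = ("FH", "FLAB", "40P"),
    skew_cutoff: float = 1.0,
    aic_n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every (feature, algorithm) cell of the survival screen.

    ``table`` is a wide feature table from a single reader (one row per
    patient per algorithm). Skewed strictly-positive features are
    log10-transformed, with one decision per feature shared across
    algorithms (a feature is transformed when skewed under any
    algorithm and positive under all). Failed fits become flagged rows;
    the screen never aborts. Rows: len(features) x len(algorithms).
    """
    if table["reader_id"].nunique() > 1:
        raise ValueError("screen expects a single reader's table")
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features missing from table: {missing}")

    # uniform per-feature transform decision across algorithms
    to_transform: set[str] = set()
    for f in features:
        skewed_any = False
        positive_all = True
        for algo in algorithms:
            sub = table.loc[table["algorithm"] == algo, f].to_numpy(dtype=float)
            sub = sub[np.isfinite(sub)]
            if sub.size >= 3 and sub.std() > 0:
                from scipy.stats import skew as _skew

                if _skew(sub) > skew_cutoff:
                    skewed_any = True
            if sub.size == 0 or sub.min() <= 0:
                positive_all = False
        if skewed_any and positive_all:
            to_transform.add(f)

    rows = []
    for algo in algorithms:
        sub = table.loc[table["algorithm"] == algo].sort_values("patient_id")
        if len(sub) != len(survival):
            raise ValueError(
                f"algorithm {algo!r}: {len(sub)} rows vs {len(survival)} survival records"
            )
        for f in features:
            x = sub[f].to_numpy(dtype=float)
            logt = f in to_transform
            if logt:
                x = np.log10(x)
            try:
                row = cox_univariate(x, survival, feature=f, algorithm=algo)
                row.log_transformed = logt
                if aic_n_boot > 0:
                    row.aic_ci95 = aic_bootstrap_ci(
                        x, survival, n_boot=aic_n_boot, seed=seed
                    )
            except CoxFitError as exc:
                logger.warning("Cox fit failed for %s/%s: %s", f, algo, exc)
                row = CoxScreenRow(
                    f, algo, np.nan, (np.nan, np.nan), np.nan, np.nan,
                    np.nan, None, len(sub), int(sum(r.event for r in survival)),
                    log_transformed=logt,
                )
            rows.append(row)

    out = pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "algorithm": [r.algorithm for r in rows],
            "log_transformed": [r.log_transformed for r in rows],
            "hr": [r.hr for r in rows],
            "hr_lo95": [r.hr_ci95[0] for r in rows],
            "hr_hi95": [r.hr_ci95[1] for r in rows],
            "hr_per_sd": [r.hr_per_sd for r in rows],
            "wald_p": [r.wald_p for r in rows],
            "significant": [
                bool(r.wald_p < 0.05) if np.isfinite(r.wald_p) else False
                for r in rows
            ],
            "aic": [r.aic for r in rows],
            "aic_lo95": [r.aic_ci95[0] if r.aic_ci95 else np.nan for r in rows],
            "aic_hi95": [r.aic_ci95[1] if r.aic_ci95 else np.nan for r in rows],
            "n": [r.n for r in rows],
            "n_events": [r.n_events for r in rows],
        }
    )
    assert len(out) == len(features) * len(algorithms)
    return out
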