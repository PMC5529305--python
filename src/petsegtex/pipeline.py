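"""End-to-end experiment: cohort -> segmentations -> features -> reports.

One seeded configuration drives the whole comparison: simulate a
phantom cohort read by three observers, delineate each reader's VOI
with the three algorithms, extract the 83-feature panel per (patient,
reader, algorithm), then produce the agreement reports (JSI against
the FLAB reference, per-feature ICC with bands and pairwise bootstrap
CIs) and the univariate Cox survival screen on the most experienced
reader's data. Every stage is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    READER_IDS,
    CohortConfig,
    SurvivalSimConfig,
    generate_cohort,
    simulate_survival,
    write_cohort,
)
from .features import SCREEN_FEATURES, extract_all, feature_table
from .features.registry import ALL_FEATURES, FAMILY_OF
from .phantom import PhantomConfig
from .repro import icc, icc_diff_bootstrap, jaccard
from .repro import compare_jsi_sets, jsi_volume_regression
from .segmentation import FLABParams, expand_mask, segment_40p, segment_flab
from .survival import run_survival_screen

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "segment_patient"]

logger = logging.getLogger(__name__)

ALGORITHMS = ("FH", "FLAB", "40P")


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    flab: FLABParams = field(default_factory=FLABParams)
    survival_sim: SurvivalSimConfig = field(default_factory=SurvivalSimConfig)
    expand_voxels: int = 5
    threshold_fraction: float = 0.40
    n_bins: int = 64
    jsi_reference: str = "FLAB"  # reference algorithm for overlap analysis
    screen_reader: str = "A"  # the single-reader dataset for JSI + survival
    icc_n_boot: int = 100
    aic_n_boot: int = 0  # 0 disables AIC bootstrap CIs
    master_seed: int = 0
    write_images: bool = False
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            sub = dict(kwargs["cohort"])
            if "base_phantom" in sub:
                sub["base_phantom"] = PhantomConfig(**sub["base_phantom"])
            kwargs["cohort"] = CohortConfig(**sub)
        if "flab" in kwargs:
            kwargs["flab"] = FLABParams(**kwargs["flab"])
        if "survival_sim" in kwargs:
            kwargs["survival_sim"] = SurvivalSimConfig(**kwargs["survival_sim"])
        return cls(**kwargs)


@dataclass
class ExperimentResult:
    features: pd.DataFrame
    volumes: pd.DataFrame
    jsi: pd.DataFrame
    jsi_tests: dict
    icc_report: pd.DataFrame
    icc_diffs: pd.DataFrame
    survival_screen: pd.DataFrame
    survival: pd.DataFrame
    out_dir: Path | None


def segment_patient(volume, reader_mask, expand_voxels=5, fraction=0.40, flab_params=None):
    """FH / 40P / FLAB segmentations from one reader's freehand mask."""
    expanded = expand_mask(reader_mask, expand_voxels)
    r40 = segment_40p(volume, expanded, fraction)
    rflab = segment_flab(volume, expanded, flab_params or FLABParams())
    return {"FH": reader_mask, "40P": r40.mask, "FLAB": rflab.mask}


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResult:
    """Run the full comparison; optionally write the report bundle to disk."""
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.master_seed)
    logger.info("simulating cohort of %d patients", cohort_cfg.n_patients)
    patients = generate_cohort(cohort_cfg)

    vectors = []
    vol_rows = []
    masks_by_patient: dict[str, dict[str, dict[str, object]]] = {}
    for p in patients:
        masks_by_patient[p.patient_id] = {}
        for rid in READER_IDS:
            masks = segment_patient(
                p.volume,
                p.reader_masks[rid],
                config.expand_voxels,
                config.threshold_fraction,
                config.flab,
            )
            masks_by_patient[p.patient_id][rid] = masks
            for algo in ALGORITHMS:
                m = masks[algo]
                vol_rows.append(
                    {
                        "patient_id": p.patient_id,
                        "reader_id": rid,
                        "algorithm": algo,
                        "volume_ml": m.volume_ml,
                        "n_voxels": m.n_voxels,
                    }
                )
                vectors.append(
                    extract_all(
                        p.volume, m, config.n_bins,
                        patient_id=p.patient_id, reader_id=rid, algorithm=algo,
                    )
                )
                logger.debug(
                    "%s reader %s %s: %.2f ml",
                    p.patient_id, rid, algo, m.volume_ml,
                )
    features = feature_table(vectors)
    volumes = pd.DataFrame(vol_rows)

    # --- overlap analysis on the screen reader, FLAB as reference
    ref = config.jsi_reference
    others = [a for a in ALGORITHMS if a != ref]
    jsi_rows = []
    for p in patients:
        masks = masks_by_patient[p.patient_id][config.screen_reader]
        for algo in others:
            r = jaccard(masks[algo], masks[ref], p.patient_id, (algo, ref))
            jsi_rows.append(
                {
                    "patient_id": p.patient_id,
                    "pair": f"{algo}/{ref}",
                    "jsi_percent": r.jsi_percent,
                    "ref_volume_ml": masks[ref].volume_ml,
                }
            )
    jsi = pd.DataFrame(jsi_rows)
    sets = {
        pair: grp["jsi_percent"].to_numpy() for pair, grp in jsi.groupby("pair")
    }
    pair_names = sorted(sets)
    u_stat, p_val = compare_jsi_sets(sets[pair_names[0]], sets[pair_names[1]])
    jsi_tests = {
        "pairs": pair_names,
        "mannwhitney_u": u_stat,
        "mannwhitney_p": p_val,
        "regressions": {},
    }
    for pair in pair_names:
        grp = jsi[jsi["pair"] == pair]
        slope, intercept, r2 = jsi_volume_regression(
            grp["ref_volume_ml"], grp["jsi_percent"]
        )
        jsi_tests["regressions"][pair] = {
            "slope": slope, "intercept": intercept, "r2": r2,
        }

    # --- per-feature ICC per algorithm, with bands
    icc_rows = []
    for algo in ALGORITHMS:
        sub = features[features["algorithm"] == algo]
        for feat in ALL_FEATURES:
            wide = sub.pivot(index="patient_id", columns="reader_id", values=feat)
            arr = wide.to_numpy(dtype=float).T  # readers x subjects
            if not np.all(np.isfinite(arr)) or arr.std() == 0:
                icc_rows.append(
                    {
                        "feature": feat, "family": FAMILY_OF[feat],
                        "algorithm": algo, "icc": np.nan,
                        "icc_lo95": np.nan, "icc_hi95": np.nan, "band": "n/a",
                    }
                )
                continue
            res = icc(arr, feature=feat, algorithm=algo)
            icc_rows.append(
                {
                    "feature": feat, "family": FAMILY_OF[feat],
                    "algorithm": algo, "icc": res.icc,
                    "icc_lo95": res.ci95[0], "icc_hi95": res.ci95[1],
                    "band": res.band,
                }
            )
    icc_report = pd.DataFrame(icc_rows)

    # --- pairwise bootstrap CIs of ICC differences
    diff_rows = []
    pairs = [("40P", "FLAB"), ("40P", "FH"), ("FLAB", "FH")]
    for feat in ALL_FEATURES:
        col = features[feat]
        if not np.all(np.isfinite(col)):
            continue
        for a, b in pairs:
            try:
                d = icc_diff_bootstrap(
                    features, feat, a, b,
                    n_boot=config.icc_n_boot, seed=config.master_seed,
                )
            except (ValueError, RuntimeError):
                continue
            diff_rows.append(
                {
                    "feature": feat, "pair": f"{a}-{b}",
                    "delta_icc": d.delta_icc,
                    "ci_lo": d.ci95_boot[0], "ci_hi": d.ci95_boot[1],
                    "significant": d.significant,
                }
            )
    icc_diffs = pd.DataFrame(diff_rows)

    # --- survival simulation + Cox screen on the screen reader's data
    screen_table = features[
        (features["reader_id"] == config.screen_reader)
    ].copy()
    driver_algo = ref if ref in ALGORITHMS else "FLAB"
    driver_tab = screen_table[screen_table["algorithm"] == driver_algo]
    driver_tab = driver_tab.sort_values("patient_id")
    surv_cfg = dataclasses.replace(
        config.survival_sim, seed=config.master_seed + 1
    )
    records = simulate_survival(
        driver_tab[["patient_id", surv_cfg.driver_feature]], surv_cfg
    )
    survival_df = pd.DataFrame(
        {
            "patient_id": driver_tab["patient_id"].to_numpy(),
            "time_months": [r.time_months for r in records],
            "event": [int(r.event) for r in records],
        }
    )
    screen = run_survival_screen(
        screen_table, records,
        features=SCREEN_FEATURES, algorithms=ALGORITHMS,
        aic_n_boot=config.aic_n_boot, seed=config.master_seed,
    )

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        features.to_csv(out_path / "features.csv", index=False)
        volumes.to_csv(out_path / "volumes.csv", index=False)
        jsi.to_csv(out_path / "jsi.csv", index=False)
        icc_report.to_csv(out_path / "icc_report.csv", index=False)
        icc_diffs.to_csv(out_path / "icc_diffs.csv", index=False)
        screen.to_csv(out_path / "survival_screen.csv", index=False)
        survival_df.to_csv(out_path / "survival.csv", index=False)
        with open(out_path / "jsi_tests.json", "w") as fh:
            json.dump(jsi_tests, fh, indent=2)
        _write_summary(
            out_path / "summary.txt", volumes, jsi, jsi_tests, icc_report, screen
        )
        if config.write_images:
            write_cohort(patients, out_path / "images", records)
        if config.make_figures:
            _write_figures(out_path, volumes, jsi, icc_report)

    return ExperimentResult(
        features, volumes, jsi, jsi_tests, icc_report, icc_diffs,
        screen, survival_df, out_path,
    )


def _write_summary(path, volumes, jsi, jsi_tests, icc_report, screen) -> None:
    lines = ["Segmentation comparison summary", "=" * 32, ""]
    med = volumes.groupby("algorithm")["volume_ml"].median()
    lines.append("Median delineated volume (ml): " + ", ".join(
        f"{a}={med[a]:.1f}" for a in med.index
    ))
    for pair, grp in jsi.groupby("pair"):
        v = grp["jsi_percent"]
        lines.append(
            f"JSI {pair}: mean {v.mean():.1f}% (range {v.min():.1f}-{v.max():.1f}, "
            f"sd {v.std():.1f})"
        )
    lines.append(
        f"Mann-Whitney comparison of JSI sets: p = {jsi_tests['mannwhitney_p']:.3g}"
    )
    med_icc = icc_report.groupby("algorithm")["icc"].median()
    lines.append("Median ICC across 83 features: " + ", ".join(
        f"{a}={med_icc[a]:.3f}" for a in med_icc.index
    ))
    for algo, grp in icc_report.groupby("algorithm"):
        bands = grp["band"].value_counts()
        lines.append(
            f"  {algo}: high {bands.get('high', 0)}, moderate "
            f"{bands.get('moderate', 0)}, low {bands.get('low', 0)}"
        )
    nsig = screen.groupby("algorithm")["significant"].sum()
    lines.append("Significant survival features (p<0.05) of 12: " + ", ".join(
        f"{a}={int(nsig[a])}" for a in nsig.index
    ))
    Path(path).write_text("\n".join(lines) + "\n")


def _write_figures(out_path, volumes, jsi, icc_report) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    data = [
        volumes.loc[volumes["algorithm"] == a, "volume_ml"] for a in ALGORITHMS
    ]
    ax.boxplot(data, tick_labels=list(ALGORITHMS))
    ax.set_ylabel("volume (ml)")
    fig.savefig(out_path / "fig_volumes.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, jsi["pair"].nunique(), figsize=(9, 4), sharey=True)
    for ax, (pair, grp) in zip(np.atleast_1d(axes), jsi.groupby("pair")):
        ax.scatter(grp["ref_volume_ml"], grp["jsi_percent"], s=12)
        ax.set_title(pair)
        ax.set_xlabel("reference volume (ml)")
    np.atleast_1d(axes)[0].set_ylabel("JSI (%)")
    fig.savefig(out_path / "fig_jsi_vs_volume.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    data = [
        icc_report.loc[icc_report["algorithm"] == a, "icc"].dropna()
        for a in ALGORITHMS
    ]
    ax.boxplot(data, tick_labels=list(ALGORITHMS))
    ax.set_ylabel("ICC")
    fig.savefig(out_path / "fig_icc.png", dpi=120)
    plt.close(fig)
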