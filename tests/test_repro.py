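import numpy as np
import pandas as pd
import pytest

from conftest import make_mask
from oracles import icc2_oracle
from petsegtex import (
    compare_jsi_sets,
    icc,
    icc_diff_bootstrap,
    jaccard,
    jsi_volume_regression,
    select_log_transform,
)
from petsegtex.repro import icc_band, icc_value


def _mask_from_indices(n, idx):
    m = np.zeros((n, 1, 1), bool)
    m[list(idx), 0, 0] = True
    return make_mask(m)


# ------------------------------------------------------------------ JSI

def test_jsi_identities():
    a = _mask_from_indices(10, range(5))
    assert jaccard(a, a).jsi_percent == 100.0
    b = _mask_from_indices(10, range(5, 10))
    assert jaccard(a, b).jsi_percent == 0.0
    assert jaccard(a, b).jsi_percent == jaccard(b, a).jsi_percent


def test_jsi_forced_value():
    """|a|=8, |b|=6, overlap 4 -> 100*4/10 = 40."""
    a = _mask_from_indices(20, range(8))
    b = _mask_from_indices(20, range(4, 10))
    assert jaccard(a, b).jsi_percent == pytest.approx(40.0)


def test_jsi_both_empty_is_error():
    e = _mask_from_indices(5, [])
    with pytest.raises(ValueError):
        jaccard(e, e)


# ---------------------------------------------------------- Mann-Whitney

def test_identical_samples_give_p_one(rng):
    x = list(rng.uniform(0, 100, size=12))
    y = list(np.random.default_rng(1).permutation(x))
    _, p = compare_jsi_sets(x, y)
    assert p == pytest.approx(1.0)


def test_extreme_separation_exact_p():
    """{1,2,3} vs {10,11,12}: U=0, exact two-sided p = 2/C(6,3) = 0.1."""
    u, p = compare_jsi_sets([1, 2, 3], [10, 11, 12])
    assert u == 0.0
    assert p == pytest.approx(0.1)


def test_large_shift_detected(rng):
    x = rng.normal(50, 5, size=50)
    y = rng.normal(60, 5, size=50)
    _, p = compare_jsi_sets(x, y)
    assert p < 0.001


# ------------------------------------------------------------ regression

def test_constant_jsi_regression():
    slope, _, r2 = jsi_volume_regression([1, 2, 3, 4], [70, 70, 70, 70])
    assert slope == 0.0
    assert r2 == 0.0


def test_perfect_line_r2_one():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    slope, intercept, r2 = jsi_volume_regression(v, 10 + 5 * v)
    assert slope == pytest.approx(5.0)
    assert r2 == pytest.approx(1.0)


def test_size_independent_noise_gives_flat_fit(rng):
    v = rng.uniform(5, 120, size=50)
    j = 70 + rng.normal(0, 5, size=50)
    slope, _, r2 = jsi_volume_regression(v, j)
    assert r2 < 0.1


def test_zero_variance_volumes_rejected():
    with pytest.raises(ValueError):
        jsi_volume_regression([2, 2, 2], [1, 2, 3])


# ------------------------------------------------------------------ ICC

def test_identical_readers_give_icc_one(rng):
    subj = rng.normal(0, 1, size=10)
    mat = np.tile(subj, (3, 1))  # readers x subjects
    res = icc(mat)
    assert res.icc == pytest.approx(1.0)
    assert res.band == "high"


def test_pure_noise_icc_near_zero(rng):
    mat = rng.normal(0, 1, size=(3, 200))
    res = icc(mat)
    assert abs(res.icc) <= 0.1


def test_icc_matches_anova_oracle(rng):
    """Biased readers, 6 subjects: agree with the mean-squares formula."""
    subj = rng.normal(0, 1.0, size=6)
    bias = np.array([0.0, 0.5, -0.5])
    mat = subj[None, :] + bias[:, None] + rng.normal(0, 0.1, size=(3, 6))
    res = icc(mat)
    assert res.icc == pytest.approx(icc2_oracle(mat.T), abs=1e-10)


@pytest.mark.parametrize("form", ["icc2", "icc3"])
def test_icc_cross_checked_against_pingouin(rng, form):
    pingouin = pytest.importorskip("pingouin")
    mat = rng.normal(0, 1, size=(3, 15)) + rng.normal(0, 1, size=(1, 15))
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(15), 3),
            "rater": np.tile(np.arange(3), 15),
            "score": mat.T.ravel(),
        }
    )
    tab = pingouin.intraclass_corr(df, "subject", "rater", "score").set_index("Type")
    ref = tab.loc["ICC(A,1)" if form == "icc2" else "ICC(C,1)"]
    res = icc(mat, form=form)
    assert res.icc == pytest.approx(float(ref["ICC"]), abs=1e-8)
    # pingouin reports the CI rounded to 2 decimals
    assert res.ci95[0] == pytest.approx(float(ref["CI95"][0]), abs=6e-3)
    assert res.ci95[1] == pytest.approx(float(ref["CI95"][1]), abs=6e-3)


def test_icc_zero_variance_rejected():
    with pytest.raises(ValueError):
        icc(np.full((3, 6), 2.0))


def test_band_mapping_is_exhaustive():
    assert icc_band(0.86) == "high"
    assert icc_band(0.85) == "moderate"
    assert icc_band(0.7) == "moderate"
    assert icc_band(0.699) == "low"
    assert icc_band(-0.3) == "low"


# -------------------------------------------------------- ICC bootstrap

def _paired_table(rng, n=30, noise_a=0.1, noise_b=0.1):
    rows = []
    subj = rng.normal(0, 1, size=n)
    for algo, noise in (("A40", noise_a), ("BFL", noise_b)):
        for r in range(3):
            for i in range(n):
                rows.append(
                    {
                        "patient_id": f"P{i:03d}",
                        "reader_id": f"R{r}",
                        "algorithm": algo,
                        "f": subj[i] + rng.normal(0, noise),
                    }
                )
    return pd.DataFrame(rows)


def test_identical_algorithms_give_null_difference(rng):
    tab = _paired_table(rng)
    dup = tab[tab["algorithm"] == "A40"].copy()
    dup["algorithm"] = "BFL"
    tab = pd.concat([tab[tab["algorithm"] == "A40"], dup])
    d = icc_diff_bootstrap(tab, "f", "A40", "BFL", n_boot=50, seed=3)
    assert d.delta_icc == 0.0
    assert d.ci95_boot == (0.0, 0.0)
    assert not d.significant


def test_bootstrap_deterministic_under_seed(rng):
    tab = _paired_table(rng)
    d1 = icc_diff_bootstrap(tab, "f", "A40", "BFL", n_boot=100, seed=11)
    d2 = icc_diff_bootstrap(tab, "f", "A40", "BFL", n_boot=100, seed=11)
    assert d1.ci95_boot == d2.ci95_boot


def test_bootstrap_midpoint_approaches_point_estimate(rng):
    tab = _paired_table(rng, n=60, noise_a=0.05, noise_b=0.5)
    d_small = icc_diff_bootstrap(tab, "f", "A40", "BFL", n_boot=100, seed=5)
    d_large = icc_diff_bootstrap(tab, "f", "A40", "BFL", n_boot=1000, seed=5)
    mid_small = sum(d_small.ci95_boot) / 2
    mid_large = sum(d_large.ci95_boot) / 2
    assert abs(mid_large - d_large.delta_icc) <= abs(mid_small - d_small.delta_icc) + 0.02


def test_bootstrap_detects_real_icc_gap():
    """Reader noise 0.05 vs 0.5 (subject sd 1, n=60): CI excludes 0 mostly."""
    hits = 0
    for rep in range(50):
        rng = np.random.default_rng(rep)
        tab = _paired_table(rng, n=60, noise_a=0.05, noise_b=0.5)
        d = icc_diff_bootstrap(tab, "f", "A40", "BFL", n_boot=100, seed=rep)
        hits += d.significant
    assert hits >= 40  # >= 80% of replicate datasets


# ------------------------------------------------------- log10 transform

def test_symmetric_feature_not_transformed(rng):
    tab = pd.DataFrame({"patient_id": range(500), "g": rng.normal(10, 1, 500)})
    out, names = select_log_transform(tab, feature_cols=["g"])
    assert names == []
    assert np.array_equal(out["g"], tab["g"])


def test_lognormal_feature_transformed_and_unskewed(rng):
    from scipy.stats import skew

    tab = pd.DataFrame(
        {"patient_id": range(500), "g": np.exp(rng.normal(0, 1, 500))}
    )
    out, names = select_log_transform(tab, feature_cols=["g"])
    assert names == ["g"]
    assert abs(skew(out["g"])) < 0.3


def test_zero_valued_feature_skipped_with_warning(rng):
    vals = np.exp(rng.normal(0, 1, 300))
    vals[0] = 0.0
    tab = pd.DataFrame({"patient_id": range(300), "g": vals})
    with pytest.warns(UserWarning, match="non-positive"):
        out, names = select_log_transform(tab, feature_cols=["g"])
    assert names == []
    assert np.array_equal(out["g"], tab["g"])
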