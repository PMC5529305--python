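import numpy as np
import pytest

from conftest import make_mask, make_volume
from petsegtex import (
    FLABParams,
    expand_mask,
    segment_40p,
    segment_flab,
)
from petsegtex.segmentation import DegenerateSegmentationError


# ------------------------------------------------------------ expand_mask

def test_expansion_of_single_voxel_is_euclidean_ball():
    """Dilating a point by 5 gives the digital ball dx^2+dy^2+dz^2 <= 25."""
    m = np.zeros((21, 21, 21), bool)
    m[10, 10, 10] = True
    out = expand_mask(make_mask(m), 5)
    brute = sum(
        1
        for dx in range(-5, 6)
        for dy in range(-5, 6)
        for dz in range(-5, 6)
        if dx * dx + dy * dy + dz * dz <= 25
    )
    assert brute == 515
    assert out.n_voxels == brute
    for dx, dy, dz in [(5, 0, 0), (3, 4, 0), (0, 0, 5)]:
        assert out.mask[10 + dx, 10 + dy, 10 + dz]
    assert not out.mask[10 + 4, 10 + 4, 10]  # 32 > 25


def test_zero_expansion_is_identity():
    m = np.zeros((8, 8, 8), bool)
    m[2:5, 3:6, 4:6] = True
    out = expand_mask(make_mask(m), 0)
    assert np.array_equal(out.mask, m)
    assert out.provenance == "expanded"


def test_expansion_clips_at_grid_corner():
    m = np.zeros((6, 6, 6), bool)
    m[0, 0, 0] = True
    out = expand_mask(make_mask(m), 5)
    assert out.mask[0, 0, 0] and out.n_voxels > 1


def test_expansion_contains_input(default_phantom):
    _, truth = default_phantom
    out = expand_mask(truth, 5)
    assert np.all(out.mask[truth.mask])
    assert out.n_voxels > truth.n_voxels


# ------------------------------------------------------------- segment_40p

def _line_volume(values):
    arr = np.zeros((len(values), 1, 1))
    arr[:, 0, 0] = values
    return make_volume(arr), make_mask(np.ones_like(arr, bool), provenance="expanded")


def test_threshold_keeps_boundary_value():
    """Values {1,3,4,5,10} at 40%: threshold 4.0 retained inclusively."""
    vol, voi = _line_volume([1, 3, 4, 5, 10])
    res = segment_40p(vol, voi, 0.40)
    assert res.mask.n_voxels == 3
    assert list(res.mask.mask[:, 0, 0]) == [False, False, True, True, True]


def test_constant_voi_fully_retained():
    vol, voi = _line_volume([2.5] * 7)
    res = segment_40p(vol, voi)
    assert res.mask.n_voxels == 7


def test_higher_fraction_nested_in_lower(default_phantom):
    vol, truth = default_phantom
    voi = expand_mask(truth, 5)
    m50 = segment_40p(vol, voi, 0.5).mask.mask
    m40 = segment_40p(vol, voi, 0.4).mask.mask
    assert np.all(m40[m50])


def test_threshold_invariant_to_rescaling(default_phantom):
    vol, truth = default_phantom
    voi = expand_mask(truth, 5)
    a = segment_40p(vol, voi).mask.mask
    vol2 = make_volume(vol.values * 3.7, vol.spacing_mm)
    b = segment_40p(vol2, voi).mask.mask
    assert np.array_equal(a, b)


def test_zero_activity_voi_is_degenerate():
    vol, voi = _line_volume([0, 0, 0, 0, 0])
    with pytest.raises(DegenerateSegmentationError):
        segment_40p(vol, voi)


# ------------------------------------------------------------ segment_flab

def _block_phantom(noise=0.1, seed=0):
    """Three constant 6x6x6 blocks at 1, 5 and 10 inside one VOI."""
    rng = np.random.default_rng(seed)
    arr = np.zeros((18, 6, 6))
    labels = np.zeros((18, 6, 6), int)
    for k, level in enumerate([1.0, 5.0, 10.0]):
        arr[6 * k : 6 * (k + 1)] = level
        labels[6 * k : 6 * (k + 1)] = k
    arr = np.clip(arr + rng.normal(0, noise, arr.shape), 0, None)
    voi = make_mask(np.ones_like(arr, bool), provenance="expanded")
    return make_volume(arr), voi, labels


def test_flab_recovers_separated_blocks():
    vol, voi, labels = _block_phantom()
    res = segment_flab(vol, voi, FLABParams(seed=1))
    assert res.converged
    for mean, target in zip(res.class_means, (1.0, 5.0, 10.0)):
        assert abs(mean - target) < 0.2
    expected = labels >= 1  # the 5- and 10-blocks
    agreement = float((res.mask.mask == expected).mean())
    assert agreement >= 0.99
    assert np.array_equal(res.mask.mask, expected)


def test_flab_without_spatial_prior_matches_pointwise_classifier():
    """spatial_weight=0 reduces to per-voxel max-posterior classification."""
    rng = np.random.default_rng(5)
    comp = rng.choice(3, size=1500, p=[0.5, 0.3, 0.2])
    means = np.array([2.0, 5.0, 9.0])
    x = np.clip(rng.normal(means[comp], 0.4), 0, None)
    arr = x.reshape((15, 10, 10))
    vol = make_volume(arr)
    voi = make_mask(np.ones_like(arr, bool), provenance="expanded")
    res = segment_flab(
        vol, voi, FLABParams(spatial_weight=0.0, variance_mode="per_class", seed=2)
    )
    mu = np.array(res.class_means)
    var = np.array(res.class_variances)
    pi = np.array(res.class_weights)
    dens = (
        pi[:, None]
        * np.exp(-0.5 * (arr.ravel()[None, :] - mu[:, None]) ** 2 / var[:, None])
        / np.sqrt(2 * np.pi * var[:, None])
    )
    keep_oracle = dens.argmax(axis=0) >= 1  # two highest-mean classes
    assert np.array_equal(res.mask.mask.ravel(), keep_oracle)


def test_flab_contained_in_expanded_voi(default_phantom):
    vol, truth = default_phantom
    voi = expand_mask(truth, 5)
    res = segment_flab(vol, voi)
    assert np.all(voi.mask[res.mask.mask])
    assert res.volume_ml > 0


def test_flab_deterministic_under_seed(default_phantom):
    vol, truth = default_phantom
    voi = expand_mask(truth, 5)
    p = FLABParams(seed=3)
    a = segment_flab(vol, voi, p)
    b = segment_flab(vol, voi, p)
    assert np.array_equal(a.mask.mask, b.mask.mask)
    assert a.class_means == b.class_means


def test_flab_needs_three_distinct_levels():
    arr = np.zeros((6, 6, 6))
    arr[:3] = 1.0
    vol = make_volume(arr)
    voi = make_mask(np.ones_like(arr, bool), provenance="expanded")
    with pytest.raises(DegenerateSegmentationError, match="distinct"):
        segment_flab(vol, voi)


def test_flab_quantile_init_also_supported():
    vol, voi, labels = _block_phantom()
    res = segment_flab(vol, voi, FLABParams(init_strategy="quantile"))
    assert np.array_equal(res.mask.mask, labels >= 1)
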