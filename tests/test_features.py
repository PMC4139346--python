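"""Unit and property tests of the LBP / LBP-TOP feature extraction."""

import numpy as np
import pytest

from lbpbrain import (FWHM_TO_SIGMA, NeighborhoodSpec, SmoothingSpec, Volume,
                      feature_image, histogram_equalize, lbp2d, lbp_top,
                      smooth_codes)

from conftest import MONOTONE_TRANSFORMS, oracle_lbp2d, oracle_lbp_top


# ---------------------------------------------------------------- oracle

def test_lbp2d_matches_oracle_on_random_slices():
    rng = np.random.default_rng(101)
    for _ in range(30):
        shape = rng.integers(3, 12, size=2)
        img = rng.standard_normal(tuple(shape))
        codes, valid = lbp2d(img)
        ocodes, ovalid = oracle_lbp2d(img)
        np.testing.assert_array_equal(codes, ocodes)
        np.testing.assert_array_equal(valid, ovalid)


def test_lbp_top_matches_oracle_on_random_volumes():
    rng = np.random.default_rng(202)
    for _ in range(25):
        shape = tuple(rng.integers(3, 9, size=3))
        vol = rng.standard_normal(shape)
        maps = lbp_top(vol)
        (o_yz, o_xz, o_xy), o_valid = oracle_lbp_top(vol)
        np.testing.assert_array_equal(maps.map_yz, o_yz)
        np.testing.assert_array_equal(maps.map_xz, o_xz)
        np.testing.assert_array_equal(maps.map_xy, o_xy)
        np.testing.assert_array_equal(maps.valid, o_valid)


def test_lbp2d_matches_oracle_with_ties():
    # integer images with many exact ties exercise the s(0)=1 convention
    rng = np.random.default_rng(303)
    for _ in range(20):
        img = rng.integers(0, 3, size=(7, 7)).astype(float)
        codes, _ = lbp2d(img)
        ocodes, _ = oracle_lbp2d(img)
        np.testing.assert_array_equal(codes, ocodes)


# ------------------------------------------------------------ code space

def test_constant_slice_gives_code_255():
    codes, valid = lbp2d(np.full((5, 6), 3.7))
    assert (codes[valid] == 255).all()
    assert (codes[~valid] == 0).all()


def test_all_256_codes_are_achievable():
    spec = NeighborhoodSpec()
    seen = set()
    for target in range(256):
        img = np.zeros((3, 3))
        for p, (dr, dc) in enumerate(spec.offsets):
            img[1 + dr, 1 + dc] = 1.0 if (target >> p) & 1 else -1.0
        codes, _ = lbp2d(img)
        assert codes[1, 1] == target
        seen.add(int(codes[1, 1]))
    assert seen == set(range(256))


def test_codes_fit_in_one_byte():
    rng = np.random.default_rng(7)
    codes, _ = lbp2d(rng.standard_normal((20, 20)))
    assert codes.dtype == np.uint8
    assert codes.min() >= 0 and codes.max() <= 255


# ------------------------------------------------------- gray invariance

def test_lbp_top_invariant_under_strictly_increasing_transforms():
    rng = np.random.default_rng(11)
    vol = rng.standard_normal((10, 9, 8))
    base = lbp_top(vol)
    for f in MONOTONE_TRANSFORMS:
        maps = lbp_top(f(vol))
        for a, b in zip(base.planes, maps.planes):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(base.valid, maps.valid)


def test_lbp_top_changes_under_non_monotone_transform():
    rng = np.random.default_rng(12)
    vol = rng.standard_normal((8, 8, 8))
    base = lbp_top(vol)
    flipped = lbp_top(-vol)  # strictly decreasing: orderings invert
    assert any(not np.array_equal(a, b)
               for a, b in zip(base.planes, flipped.planes))


# --------------------------------------------------------- axis handling

def test_cyclic_axis_permutation_consistency():
    rng = np.random.default_rng(13)
    vol = rng.standard_normal((6, 7, 8))
    base = lbp_top(vol)
    # transpose (1,2,0): the original (y,z) plane pair appears as the new
    # (x,y) pair with in-plane axis order preserved
    rolled = lbp_top(vol.transpose(1, 2, 0))
    np.testing.assert_array_equal(rolled.map_xy, base.map_yz.transpose(1, 2, 0))
    # transpose (2,0,1): original (x,y) pair appears as the new (y,z) pair
    rolled2 = lbp_top(vol.transpose(2, 0, 1))
    np.testing.assert_array_equal(rolled2.map_yz, base.map_xy.transpose(2, 0, 1))


def test_neighborhood_spec_validation():
    with pytest.raises(ValueError):
        NeighborhoodSpec(offsets=((0, 0),) * 8)
    with pytest.raises(ValueError):
        NeighborhoodSpec(bit_order=(0, 0, 1, 2, 3, 4, 5, 6))


def test_input_validation():
    with pytest.raises(ValueError):
        lbp2d(np.zeros((3, 3, 3)))
    with pytest.raises(ValueError):
        lbp2d(np.zeros((2, 5)))
    with pytest.raises(ValueError):
        lbp_top(np.zeros((5, 5)))
    with pytest.raises(ValueError):
        lbp_top(np.zeros((2, 5, 5)))


# -------------------------------------------------------------- smoothing

def test_smoothing_sigma_from_fwhm():
    spec = SmoothingSpec(fwhm_mm=(4.0, 4.0, 4.0))
    sig = spec.sigma_voxels((2.0, 2.0, 2.0))
    expected = 4.0 * FWHM_TO_SIGMA / 2.0
    assert sig == pytest.approx((expected,) * 3)
    assert expected == pytest.approx(0.8493218, abs=1e-6)


def test_smoothing_preserves_constant_maps():
    from lbpbrain import LBPTOPMaps

    const = np.full((9, 9, 9), 137, dtype=np.uint8)
    maps = LBPTOPMaps(map_yz=const, map_xz=const, map_xy=const,
                      valid=np.ones(const.shape, bool))
    smoothed = smooth_codes(maps, SmoothingSpec(), spacing=(2.0, 2.0, 2.0))
    for plane in smoothed:
        # 'reflect' boundaries keep a constant field exactly constant
        np.testing.assert_allclose(plane, 137.0, rtol=1e-12)


def test_smoothing_fwhm_zero_is_identity():
    rng = np.random.default_rng(21)
    maps = lbp_top(rng.standard_normal((6, 6, 6)))
    out = smooth_codes(maps, SmoothingSpec(fwhm_mm=(0.0, 0.0, 0.0)))
    for o, m in zip(out, maps.planes):
        np.testing.assert_array_equal(o, m.astype(np.float64))


# ---------------------------------------------------- histogram matching

def _vol(data, mask=None, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data, dtype=float), spacing, brain_mask=mask)


def test_histogram_matching_to_self_is_near_identity():
    rng = np.random.default_rng(31)
    data = rng.uniform(0.0, 1.0, (12, 12, 12))
    mask = np.ones(data.shape, dtype=bool)
    out = histogram_equalize(_vol(data, mask), _vol(data, mask))
    # identity up to the bin width of the 256-bin estimate
    assert np.abs(out.data - data).max() < 2.0 / 256


def test_histogram_matching_recovers_gamma_distortion():
    rng = np.random.default_rng(32)
    base = rng.uniform(0.1, 1.0, (14, 14, 14))
    mask = np.ones(base.shape, dtype=bool)
    distorted = base ** 2.2
    out = histogram_equalize(_vol(distorted, mask), _vol(base, mask))
    # matched values approximate the undistorted ones (same rank structure)
    assert np.abs(out.data - base).mean() < 0.02


def test_histogram_matching_is_monotone_and_masked():
    rng = np.random.default_rng(33)
    data = rng.standard_normal((10, 10, 10))
    mask = np.zeros(data.shape, dtype=bool)
    mask[2:8, 2:8, 2:8] = True
    tmpl = _vol(rng.uniform(5.0, 9.0, data.shape), np.ones(data.shape, bool))
    out = histogram_equalize(_vol(data, mask), tmpl)
    assert (out.data[~mask] == 0).all()
    # mapping is non-decreasing in the input
    order = np.argsort(data[mask], kind="stable")
    mapped = out.data[mask][order]
    assert (np.diff(mapped) >= -1e-12).all()
    # matched values live in the template's intensity range
    assert out.data[mask].min() >= 5.0 - 0.1
    assert out.data[mask].max() <= 9.0 + 0.1


def test_histogram_matching_requires_masks():
    data = np.ones((5, 5, 5))
    with pytest.raises(ValueError):
        histogram_equalize(_vol(data), _vol(data, np.ones(data.shape, bool)))
    with pytest.raises(ValueError):
        histogram_equalize(_vol(data, np.zeros(data.shape, bool)),
                           _vol(data, np.ones(data.shape, bool)))


# ---------------------------------------------------------- feature_image

def test_feature_image_type1_is_raw():
    rng = np.random.default_rng(41)
    data = rng.standard_normal((6, 6, 6))
    mask = data > 0
    fi = feature_image(_vol(data, mask), 1)
    assert fi.feature_type == 1 and len(fi.planes) == 1
    np.testing.assert_array_equal(fi.planes[0], data)
    np.testing.assert_array_equal(fi.validity, mask)


def test_feature_image_type2_requires_template():
    with pytest.raises(ValueError):
        feature_image(_vol(np.ones((5, 5, 5)), np.ones((5, 5, 5), bool)), 2)


def test_feature_image_type3_invariant_under_gamma():
    rng = np.random.default_rng(42)
    data = rng.uniform(0.1, 1.0, (9, 9, 9))
    mask = np.ones(data.shape, dtype=bool)
    a = feature_image(_vol(data, mask), 3, smoothing=SmoothingSpec())
    b = feature_image(_vol(data ** 0.4, mask), 3, smoothing=SmoothingSpec())
    assert len(a.planes) == 3
    for pa, pb in zip(a.planes, b.planes):
        np.testing.assert_array_equal(pa, pb)


def test_feature_image_type3_validity_excludes_border_and_nonbrain():
    data = np.random.default_rng(43).standard_normal((7, 7, 7))
    mask = np.zeros(data.shape, dtype=bool)
    mask[1:6, 1:6, 1:6] = True
    fi = feature_image(_vol(data, mask), 3)
    assert not fi.validity[0].any() and not fi.validity[-1].any()
    assert not fi.validity[~mask].any()
    assert fi.validity[3, 3, 3]


def test_feature_image_unknown_type():
    with pytest.raises(ValueError):
        feature_image(_vol(np.ones((5, 5, 5))), 4)
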