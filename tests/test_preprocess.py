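"""Image conditioning: z-score, resampling, erosion and quantization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rectomics import erode_mask, quantize, resample_isotropic, znormalize
from rectomics.preprocess import ball_structure


# -- z-score --------------------------------------------------------------

def test_znormalize_two_point_region():
    vol = np.zeros((2, 2, 2))
    vol[0, 0, 0], vol[0, 0, 1] = 1.0, 3.0
    mask = vol != 0
    out = znormalize(vol, mask)
    assert out[0, 0, 0] == pytest.approx(-1.0)
    assert out[0, 0, 1] == pytest.approx(1.0)


def test_znormalize_is_idempotent(rng):
    vol = rng.normal(5, 2, size=(8, 8, 8))
    mask = np.ones(vol.shape, bool)
    once = znormalize(vol, mask)
    twice = znormalize(once, mask)
    np.testing.assert_allclose(once, twice, atol=1e-10)


def test_znormalize_large_sample_moments(rng):
    vol = rng.normal(5, 2, size=(50, 50, 40))
    mask = np.ones(vol.shape, bool)
    out = znormalize(vol, mask)
    assert abs(out[mask].mean()) < 1e-12
    assert out[mask].std() == pytest.approx(1.0, abs=1e-12)


def test_znormalize_rejects_degenerate_region():
    vol = np.full((4, 4, 4), 2.0)
    with pytest.raises(ValueError, match="variance"):
        znormalize(vol, np.ones(vol.shape, bool))


# -- resampling -----------------------------------------------------------

def test_resample_identity_at_target_spacing(rng):
    vol = rng.normal(size=(10, 10, 10))
    mask = np.zeros(vol.shape, bool)
    mask[3:7, 3:7, 3:7] = True
    out_v, out_m = resample_isotropic(vol, mask, (1.0, 1.0, 1.0))
    np.testing.assert_array_equal(out_v, vol)
    np.testing.assert_array_equal(out_m, mask)


def test_resample_doubles_thick_axis(rng):
    vol = rng.normal(size=(10, 10, 6))
    mask = np.zeros(vol.shape, bool)
    mask[4:6, 4:6, 2:4] = True
    out_v, out_m = resample_isotropic(vol, mask, (1.0, 1.0, 2.0))
    assert out_v.shape[0] == 10
    assert abs(out_v.shape[2] - 12) <= 1
    assert out_m.any()


def test_resample_constant_volume_stays_constant():
    vol = np.full((8, 8, 4), 3.5)
    mask = np.ones(vol.shape, bool)
    out_v, _ = resample_isotropic(vol, mask, (1.0, 1.0, 2.0))
    np.testing.assert_allclose(out_v, 3.5, atol=1e-12)


# -- erosion --------------------------------------------------------------

def _ball_mask(shape, center, radius):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _erode_oracle(mask, margin, spacing):
    """Voxel-wise brute force: keep v iff every offset within the ball stays
    inside the mask."""
    structure = ball_structure(margin, spacing)
    offsets = np.argwhere(structure) - np.array(structure.shape) // 2
    out = np.zeros_like(mask)
    shape = np.array(mask.shape)
    for v in np.argwhere(mask):
        pts = v + offsets
        if ((pts >= 0) & (pts < shape)).all(axis=1).all() and mask[tuple(pts.T)].all():
            out[tuple(v)] = True
    return out


def test_erosion_of_ball_shrinks_radius_by_margin():
    mask = _ball_mask((13, 13, 13), (6, 6, 6), 5.0)
    eroded = erode_mask(mask, 1.0, (1.0, 1.0, 1.0))
    np.testing.assert_array_equal(eroded, _erode_oracle(mask, 1.0, (1.0, 1.0, 1.0)))
    # digital erosion of a digital ball: contains the r-1 ball, shrinks strictly
    inner = _ball_mask((13, 13, 13), (6, 6, 6), 4.0)
    assert (eroded | inner).sum() == eroded.sum()  # inner subset of eroded
    assert eroded.sum() < mask.sum()
    assert (mask | eroded).sum() == mask.sum()  # eroded subset of input


def test_erosion_matches_brute_force_on_random_masks(rng):
    for _ in range(4):
        mask = rng.random((12, 12, 12)) > 0.35
        try:
            eroded = erode_mask(mask, 1.0, (1.0, 1.0, 1.0))
        except ValueError:
            assert not _erode_oracle(mask, 1.0, (1.0, 1.0, 1.0)).any()
            continue
        np.testing.assert_array_equal(eroded, _erode_oracle(mask, 1.0, (1.0, 1.0, 1.0)))


def test_erosion_respects_anisotropic_spacing(rng):
    mask = rng.random((10, 10, 6)) > 0.3
    spacing = (1.0, 1.0, 2.0)
    try:
        eroded = erode_mask(mask, 1.5, spacing)
    except ValueError:
        eroded = None
    oracle = _erode_oracle(mask, 1.5, spacing)
    if eroded is None:
        assert not oracle.any()
    else:
        np.testing.assert_array_equal(eroded, oracle)


def test_single_voxel_mask_errors_and_margin_zero_is_identity():
    mask = np.zeros((5, 5, 5), bool)
    mask[2, 2, 2] = True
    with pytest.raises(ValueError, match="too small"):
        erode_mask(mask, 1.0, (1.0, 1.0, 1.0))
    np.testing.assert_array_equal(erode_mask(mask, 0.0, (1.0, 1.0, 1.0)), mask)


# -- quantization ---------------------------------------------------------

def test_quantize_integer_ramp_maps_one_level_per_value():
    vals = np.arange(64, dtype=float).reshape(4, 4, 4)
    q = quantize(vals, np.ones(vals.shape, bool), g=64)
    np.testing.assert_array_equal(np.sort(np.unique(q.levels)), np.arange(1, 65))
    assert q.levels.flat[0] == 1
    assert q.levels.flat[63] == 64


def test_quantize_constant_region_is_level_one():
    vol = np.full((3, 3, 3), 7.0)
    q = quantize(vol, np.ones(vol.shape, bool), g=64)
    assert set(np.unique(q.levels)) == {1}


def test_quantize_max_maps_to_g(rng):
    vol = rng.normal(size=(6, 6, 6))
    mask = np.ones(vol.shape, bool)
    q = quantize(vol, mask, g=32)
    assert q.levels[np.unravel_index(np.argmax(vol), vol.shape)] == 32


@settings(deadline=None, max_examples=25)
@given(st.lists(st.integers(-1000, 1000), min_size=8, max_size=27),
       st.sampled_from([0.5, 2.0, 4.0]), st.integers(-100, 100))
def test_quantize_monotone_and_affine_invariant(values, a, b):
    # power-of-two scale + integer shift keep the bin arithmetic exact in
    # floating point, so invariance can be asserted bit-for-bit
    n = len(values)
    vol = np.array(values, dtype=float).reshape(1, 1, n)
    mask = np.ones(vol.shape, bool)
    q1 = quantize(vol, mask, g=16).levels.ravel()
    # monotone: ordering of values implies ordering of levels
    order = np.argsort(vol.ravel(), kind="stable")
    assert (np.diff(q1[order]) >= 0).all()
    # invariant to positive affine rescaling
    q2 = quantize(a * vol + b, mask, g=16).levels.ravel()
    np.testing.assert_array_equal(q1, q2)
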