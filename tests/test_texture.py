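"""GLCM/GLRLM engines vs brute-force pair/run enumeration oracles."""

import math

import numpy as np
import pytest

from rectomics import quantize
from rectomics.texture import (
    DIRECTIONS_13,
    GLCM_FEATURE_NAMES,
    glcm_compute,
    glcm_features,
    glcm_features_averaged,
    glcm_features_fast,
    glrlm_compute,
    glrlm_counts_fast,
    glrlm_features,
    glrlm_features_averaged,
    glrlm_features_fast,
)


# -- test-side oracles (plain loops, independent of the implementation) ----

def brute_glcm(levels, mask, g, distance, direction):
    counts = np.zeros((g, g))
    off = np.array(direction) * distance
    for v in np.argwhere(mask):
        w = v + off
        if ((w >= 0) & (w < np.array(levels.shape))).all() and mask[tuple(w)]:
            counts[levels[tuple(v)] - 1, levels[tuple(w)] - 1] += 1
            counts[levels[tuple(w)] - 1, levels[tuple(v)] - 1] += 1
    return counts


def brute_runs(levels, mask, direction):
    """Enumerate all runs (level, length) along one direction by walking
    every line voxel by voxel."""
    shape = np.array(levels.shape)
    d = np.array(direction)
    runs = []
    for start in np.argwhere(mask):
        prev = start - d
        if ((prev >= 0) & (prev < shape)).all() and mask[tuple(prev)] \
                and levels[tuple(prev)] == levels[tuple(start)]:
            continue  # not a run start
        length = 1
        cur = start + d
        while ((cur >= 0) & (cur < shape)).all() and mask[tuple(cur)] \
                and levels[tuple(cur)] == levels[tuple(start)]:
            length += 1
            cur = cur + d
        runs.append((int(levels[tuple(start)]), length))
    return runs


def brute_glcm_feature(p, name):
    """Independent loop-based evaluation of one GLCM feature."""
    g = p.shape[0]
    px = p.sum(axis=1)
    mu = sum((i + 1) * px[i] for i in range(g))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(g))
    psum = {}
    pdiff = {}
    for i in range(g):
        for j in range(g):
            if p[i, j] == 0:
                continue
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]
    if name == "contrast":
        return sum((i - j) ** 2 * p[i, j] for i in range(g) for j in range(g))
    if name == "joint_entropy":
        return -sum(p[i, j] * math.log2(p[i, j])
                    for i in range(g) for j in range(g) if p[i, j] > 0)
    if name == "difference_entropy":
        return -sum(v * math.log2(v) for v in pdiff.values())
    if name == "sum_entropy":
        return -sum(v * math.log2(v) for v in psum.values())
    if name == "energy":
        return sum(p[i, j] ** 2 for i in range(g) for j in range(g))
    if name == "maximum_probability":
        return p.max()
    if name == "homogeneity":
        return sum(p[i, j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g))
    if name == "correlation":
        if var == 0:
            return 0.0
        return sum((i + 1 - mu) * (j + 1 - mu) * p[i, j]
                   for i in range(g) for j in range(g)) / var
    if name == "variance":
        return var
    if name == "sum_average":
        return sum(k * v for k, v in psum.items())
    raise KeyError(name)


def galloway(runs, n_voxels, name):
    nr = len(runs)
    if nr == 0:
        return 0.0
    if name == "sre":
        return sum(1 / l**2 for _, l in runs) / nr
    if name == "lre":
        return sum(l**2 for _, l in runs) / nr
    if name == "rp":
        return nr / n_voxels
    if name == "lgre":
        return sum(1 / i**2 for i, _ in runs) / nr
    if name == "hgre":
        return sum(i**2 for i, _ in runs) / nr
    if name == "gln":
        by_level = {}
        for i, _ in runs:
            by_level[i] = by_level.get(i, 0) + 1
        return sum(c**2 for c in by_level.values()) / nr
    if name == "rln":
        by_len = {}
        for _, l in runs:
            by_len[l] = by_len.get(l, 0) + 1
        return sum(c**2 for c in by_len.values()) / nr
    raise KeyError(name)


def _random_rois(rng, n=3):
    rois = []
    for shape, g in (((5, 4, 3), 4), ((6, 6, 6), 6), ((8, 8, 8), 5)):
        for _ in range(n):
            vol = rng.normal(size=shape)
            mask = rng.random(shape) > 0.25
            if mask.sum() < 8:
                mask[:] = True
            rois.append(quantize(vol, mask, g=g))
    return rois


# -- GLCM -----------------------------------------------------------------

def test_glcm_counts_match_pair_enumeration(rng):
    for q in _random_rois(rng, n=2):
        for distance in (1, 2):
            for direction in DIRECTIONS_13:
                m = glcm_compute(q.levels, q.mask, q.g, distance, direction)
                np.testing.assert_allclose(
                    m.counts, brute_glcm(q.levels, q.mask, q.g, distance, direction),
                    atol=0,
                )
                assert np.allclose(m.counts, m.counts.T)
                if m.counts.sum() > 0:
                    assert m.p.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("name", [
    "contrast", "joint_entropy", "difference_entropy", "sum_entropy", "energy",
    "maximum_probability", "homogeneity", "correlation", "variance", "sum_average",
])
def test_glcm_features_match_loop_oracle(rng, name):
    for q in _random_rois(rng, n=1):
        m = glcm_compute(q.levels, q.mask, q.g, 1, (1, 0, 0))
        feats = glcm_features(m)
        assert feats[name] == pytest.approx(brute_glcm_feature(m.p, name), abs=1e-10)


def test_glcm_fast_path_equals_reference(rng):
    for q in _random_rois(rng, n=1):
        for d in (1, 2):
            ref = glcm_features_averaged(q.levels, q.mask, q.g, d)
            fast = glcm_features_fast(q.levels, q.mask, q.g, d)
            for name in GLCM_FEATURE_NAMES:
                assert fast[name] == pytest.approx(ref[name], abs=1e-10), name


def test_glcm_two_pair_slab_and_closed_forms():
    # 2x2x1 levels [[1,1],[2,2]] with offset (0,1,0): pairs (1,1) and (2,2)
    levels = np.array([[1, 1], [2, 2]]).reshape(2, 2, 1)
    mask = np.ones((2, 2, 1), bool)
    m = glcm_compute(levels, mask, 2, 1, (0, 1, 0))
    assert m.p[0, 0] == pytest.approx(0.5)
    assert m.p[1, 1] == pytest.approx(0.5)
    feats = glcm_features(m)
    assert feats["difference_entropy"] == pytest.approx(0.0, abs=1e-12)
    # uniform p over g^2 cells: joint entropy = 2 log2 g
    g = 4
    uniform = np.full((g, g), 1.0)
    from rectomics.texture import GLCMatrix
    feats_u = glcm_features(GLCMatrix(uniform, 1, (1, 0, 0)))
    assert feats_u["joint_entropy"] == pytest.approx(2 * np.log2(g), abs=1e-12)


def test_glcm_constant_roi_conventions():
    levels = np.ones((3, 3, 3), dtype=np.int64)
    mask = np.ones((3, 3, 3), bool)
    for direction in DIRECTIONS_13:
        feats = glcm_features(glcm_compute(levels, mask, 4, 1, direction))
        assert feats["maximum_probability"] == 1.0
        assert feats["contrast"] == 0.0
        assert feats["correlation"] == 0.0
        assert feats["joint_entropy"] == 0.0


# -- GLRLM ----------------------------------------------------------------

def test_glrlm_counts_match_run_enumeration(rng, phantom):
    rois = _random_rois(rng, n=2)
    rois.append(quantize(phantom.channels["phantom"], phantom.mask, g=4))
    for q in rois:
        for direction in DIRECTIONS_13:
            runs = brute_runs(q.levels, q.mask, direction)
            expected = np.zeros((q.g, max(l for _, l in runs)))
            for lvl, length in runs:
                expected[lvl - 1, length - 1] += 1
            for compute in (glrlm_compute, glrlm_counts_fast):
                m = compute(q.levels, q.mask, q.g, direction)
                np.testing.assert_allclose(m.counts[:, :expected.shape[1]], expected)
                assert m.counts[:, expected.shape[1]:].sum() == 0
                # every traversed in-mask voxel is covered by exactly one run
                j = np.arange(1, m.counts.shape[1] + 1)
                assert (m.counts @ j).sum() == q.mask.sum()


def test_glrlm_features_match_galloway_oracle(rng):
    for q in _random_rois(rng, n=1):
        for direction in ((1, 0, 0), (1, 1, -1)):
            m = glrlm_compute(q.levels, q.mask, q.g, direction)
            feats = glrlm_features(m)
            runs = brute_runs(q.levels, q.mask, direction)
            for name in ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre"):
                assert feats[name] == pytest.approx(
                    galloway(runs, int(q.mask.sum()), name), abs=1e-10), name


def test_glrlm_fast_path_equals_reference(rng):
    for q in _random_rois(rng, n=1):
        ref = glrlm_features_averaged(q.levels, q.mask, q.g)
        fast = glrlm_features_fast(q.levels, q.mask, q.g)
        for name in ref:
            assert fast[name] == pytest.approx(ref[name], abs=1e-10), name


def test_glrlm_hand_enumerated_line():
    # 1D line [1,1,1,2] along x: runs {(1,3),(2,1)}
    levels = np.array([1, 1, 1, 2]).reshape(4, 1, 1)
    mask = np.ones((4, 1, 1), bool)
    m = glrlm_compute(levels, mask, 2, (1, 0, 0))
    feats = glrlm_features(m)
    assert feats["sre"] == pytest.approx(0.5 * (1 / 9 + 1))
    assert feats["lre"] == pytest.approx(5.0)
    assert feats["rp"] == pytest.approx(0.5)


def test_glrlm_constant_and_checkerboard():
    levels = np.ones((5, 1, 1), dtype=np.int64)
    mask = np.ones((5, 1, 1), bool)
    feats = glrlm_features(glrlm_compute(levels, mask, 2, (1, 0, 0)))
    assert feats["lre"] == pytest.approx(25.0)
    assert feats["rp"] == pytest.approx(1 / 5)

    x, y, z = np.indices((4, 4, 4))
    checker = ((x + y + z) % 2 + 1).astype(np.int64)
    mask = np.ones((4, 4, 4), bool)
    for direction in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
        feats = glrlm_features(glrlm_compute(checker, mask, 2, direction))
        assert feats["sre"] == pytest.approx(1.0)


def test_level_relabeling_invariance_where_formulas_permit(rng):
    """Reversing the level order leaves entropy-type features unchanged but
    moves the gray-level-weighted ones (LGRE/HGRE)."""
    q = _random_rois(rng, n=1)[0]
    flipped = np.where(q.mask, q.g + 1 - q.levels, 0)
    f1 = glcm_features_averaged(q.levels, q.mask, q.g, 1)
    f2 = glcm_features_averaged(flipped, q.mask, q.g, 1)
    for name in ("joint_entropy", "difference_entropy", "contrast", "energy"):
        assert f1[name] == pytest.approx(f2[name], abs=1e-10)
    r1 = glrlm_features_averaged(q.levels, q.mask, q.g)
    r2 = glrlm_features_averaged(flipped, q.mask, q.g)
    for name in ("sre", "lre", "rp", "rln"):
        assert r1[name] == pytest.approx(r2[name], abs=1e-10)
    assert r1["lgre"] != pytest.approx(r2["lgre"], abs=1e-6)
    assert r1["hgre"] != pytest.approx(r2["hgre"], abs=1e-6)
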