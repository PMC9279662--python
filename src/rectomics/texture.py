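"""Gray-level co-occurrence (GLCM) and run-length (GLRLM) texture engines.

Both operate on a :class:`~rectomics.preprocess.QuantizedROI` (levels 1..G
inside the mask) along the 13 unique 3D voxel directions.  GLCM uses
distances 1 and 2 voxels; each scalar feature is computed per direction and
averaged over the 13 directions, giving one value per (feature, distance).

Degenerate conventions (constant ROI / single occupied cell): entropy-,
contrast- and correlation-type features are 0 and maximum probability is 1,
so every feature is finite and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DIRECTIONS_13",
    "GLCMatrix",
    "GLRLMatrix",
    "glcm_compute",
    "glcm_features",
    "glrlm_compute",
    "glrlm_features",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "glcm_features_averaged",
    "glrlm_features_averaged",
    "glcm_features_fast",
    "glrlm_features_fast",
    "glrlm_counts_fast",
]

#: The 13 unique 3D offsets (one per opposite-direction pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

#: Canonical 22-feature GLCM set (x2 distances = 44 texture features).
GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation", "cluster_prominence", "cluster_shade", "cluster_tendency",
    "contrast", "correlation", "difference_average", "difference_entropy",
    "difference_variance", "dissimilarity", "energy", "joint_entropy",
    "homogeneity", "imc1", "imc2", "inverse_difference",
    "maximum_probability", "sum_average", "sum_entropy", "sum_variance",
    "variance", "inverse_variance",
)

#: Galloway run-length feature set.
GLRLM_FEATURE_NAMES: tuple[str, ...] = (
    "sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
)


@dataclass
class GLCMatrix:
    counts: np.ndarray  # G x G, symmetric
    distance: int
    direction: tuple[int, int, int]

    @property
    def p(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return self.counts
        return self.counts / total


@dataclass
class GLRLMatrix:
    counts: np.ndarray  # G x Lmax run counts
    direction: tuple[int, int, int]
    n_voxels: int  # in-mask voxels (Np)


from functools import lru_cache


@lru_cache(maxsize=512)
def _shift_slices(shape: tuple[int, ...], offset: tuple[int, ...]):
    sl_a, sl_b = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return tuple(sl_a), tuple(sl_b)


def _shifted_views(arr: np.ndarray, offset: tuple[int, int, int]):
    """Views (a, b) such that b is arr shifted by +offset relative to a."""
    sl_a, sl_b = _shift_slices(arr.shape, tuple(offset))
    return arr[sl_a], arr[sl_b]


def glcm_compute(levels: np.ndarray, mask: np.ndarray, g: int,
                 distance: int, direction: tuple[int, int, int]) -> GLCMatrix:
    """Symmetric co-occurrence counts at offset ``distance * direction``."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    offset = tuple(int(distance * d) for d in direction)
    la, lb = _shifted_views(levels, offset)
    ma, mb = _shifted_views(mask, offset)
    valid = ma & mb
    i = la[valid] - 1
    j = lb[valid] - 1
    counts = np.zeros((g, g), dtype=float)
    if i.size:
        np.add.at(counts, (i, j), 1.0)
        counts = counts + counts.T  # symmetric accumulation
    return GLCMatrix(counts=counts, distance=distance, direction=direction)


def glcm_features(m: GLCMatrix) -> dict[str, float]:
    """The canonical 22 Haralick-style features of one normalized GLCM."""
    p = m.p
    g = p.shape[0]
    total = p.sum()
    occupied = np.argwhere(p > 0)
    degenerate = total == 0 or len(occupied) <= 1
    if degenerate:
        feats = {name: 0.0 for name in GLCM_FEATURE_NAMES}
        feats["maximum_probability"] = 1.0
        feats["energy"] = 1.0
        if total > 0:  # single occupied cell (i, i)
            lvl = occupied[0][0] + 1.0
            feats["autocorrelation"] = lvl * lvl
            feats["sum_average"] = 2.0 * lvl
            feats["homogeneity"] = 1.0
            feats["inverse_difference"] = 1.0
            feats["inverse_variance"] = 0.0
            feats["imc2"] = 0.0
        return feats

    idx = np.arange(1, g + 1, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    px = p.sum(axis=1)
    mu = float((idx * px).sum())  # marginal mean (symmetric => mu_x = mu_y)
    var = float(((idx - mu) ** 2 * px).sum())

    # p_{x+y}(k), k = 2..2G and p_{x-y}(k), k = 0..G-1
    ksum = (ii + jj).astype(int)
    kdiff = np.abs(ii - jj).astype(int)
    p_sum = np.zeros(2 * g + 1)
    np.add.at(p_sum, ksum.ravel(), p.ravel())
    p_diff = np.zeros(g)
    np.add.at(p_diff, kdiff.ravel(), p.ravel())

    eps = np.finfo(float).tiny
    log2p = np.log2(p + eps)
    hxy = float(-(p * log2p).sum())
    hx = float(-(px * np.log2(px + eps)).sum())
    # Symmetric matrix: HY = HX, py = px.
    pxy_outer = np.outer(px, px)
    hxy1 = float(-(p * np.log2(pxy_outer + eps)).sum())
    hxy2 = float(-(pxy_outer * np.log2(pxy_outer + eps)).sum())

    ks = np.arange(2 * g + 1, dtype=float)
    kd = np.arange(g, dtype=float)
    sum_avg = float((ks * p_sum).sum())
    sum_ent = float(-(p_sum * np.log2(p_sum + eps))[p_sum > 0].sum())
    sum_var = float(((ks - sum_avg) ** 2 * p_sum).sum())
    diff_avg = float((kd * p_diff).sum())
    diff_ent = float(-(p_diff * np.log2(p_diff + eps))[p_diff > 0].sum())
    diff_var = float(((kd - diff_avg) ** 2 * p_diff).sum())

    contrast = float((((ii - jj) ** 2) * p).sum())
    dissim = float((np.abs(ii - jj) * p).sum())
    if var > 0:
        correlation = float((((ii - mu) * (jj - mu) * p).sum()) / var)
    else:
        correlation = 0.0
    # symmetric matrix => HY = HX, so max(HX, HY) = HX
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = float(np.sqrt(max(imc2_arg, 0.0)))

    nz = kd > 0
    inv_var = float((p_diff[nz] / kd[nz] ** 2).sum())

    feats = {
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_prominence": float((((ii + jj - 2 * mu) ** 4) * p).sum()),
        "cluster_shade": float((((ii + jj - 2 * mu) ** 3) * p).sum()),
        "cluster_tendency": float((((ii + jj - 2 * mu) ** 2) * p).sum()),
        "contrast": contrast,
        "correlation": correlation,
        "difference_average": diff_avg,
        "difference_entropy": diff_ent,
        "difference_variance": diff_var,
        "dissimilarity": dissim,
        "energy": float((p**2).sum()),
        "joint_entropy": hxy,
        "homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "imc1": float(imc1),
        "imc2": imc2,
        "inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "maximum_probability": float(p.max()),
        "sum_average": sum_avg,
        "sum_entropy": sum_ent,
        "sum_variance": sum_var,
        "variance": var,
        "inverse_variance": inv_var,
    }
    return feats


def glrlm_compute(levels: np.ndarray, mask: np.ndarray, g: int,
                  direction: tuple[int, int, int]) -> GLRLMatrix:
    """Run counts by (gray level, run length) along one direction.

    A run starts at a voxel whose predecessor along the direction is outside
    the volume, outside the mask, or at a different level; its length is
    found by stepping forward while the level persists.
    """
    lev = np.where(mask, levels, 0)
    # cur is lev at v, prev is lev at v - direction (defined on interior slab)
    cur, prev = _shifted_views(lev, tuple(-d for d in direction))
    same_as_prev = np.zeros(lev.shape, dtype=bool)
    sl_cur = _interior_slice(lev.shape, direction)
    same_as_prev[sl_cur] = (cur == prev) & (prev > 0)
    starts = mask & ~same_as_prev

    # longest possible run is bounded by the shortest traversed axis
    lmax = min(n for n, d in zip(lev.shape, direction) if d)

    counts = np.zeros((g, lmax + 1), dtype=float)
    # Walk forward from every start until the run breaks.
    alive = np.argwhere(starts)
    if alive.size == 0:
        return GLRLMatrix(counts=counts[:, 1:], direction=direction, n_voxels=int(mask.sum()))
    vals = lev[tuple(alive.T)]
    length = np.ones(len(alive), dtype=int)
    pos = alive.copy()
    d = np.asarray(direction)
    shape = np.asarray(lev.shape)
    running = np.ones(len(alive), dtype=bool)
    while running.any():
        pos[running] += d
        inb = running.copy()
        inb[running] = np.all((pos[running] >= 0) & (pos[running] < shape), axis=1)
        cont = inb.copy()
        if cont.any():
            nxt = lev[tuple(pos[cont].T)]
            cont[cont] = nxt == vals[cont]
        length[cont] += 1
        running = cont
    np.add.at(counts, (vals - 1, length), 1.0)
    return GLRLMatrix(counts=counts[:, 1:], direction=direction, n_voxels=int(mask.sum()))


def _interior_slice(shape, direction):
    sl = []
    for n, o in zip(shape, direction):
        if o >= 0:
            sl.append(slice(o, n))
        else:
            sl.append(slice(0, n + o))
    return tuple(sl)


def glrlm_features(m: GLRLMatrix) -> dict[str, float]:
    """Galloway run-length features of one direction's run matrix."""
    r = m.counts
    nr = r.sum()
    if nr == 0:
        return {name: 0.0 for name in GLRLM_FEATURE_NAMES}
    g, lmax = r.shape
    i = np.arange(1, g + 1, dtype=float)[:, None]
    j = np.arange(1, lmax + 1, dtype=float)[None, :]
    return {
        "sre": float((r / j**2).sum() / nr),
        "lre": float((r * j**2).sum() / nr),
        "gln": float((r.sum(axis=1) ** 2).sum() / nr),
        "rln": float((r.sum(axis=0) ** 2).sum() / nr),
        "rp": float(nr / m.n_voxels),
        "lgre": float((r / i**2).sum() / nr),
        "hgre": float((r * i**2).sum() / nr),
    }


def glcm_features_averaged(levels: np.ndarray, mask: np.ndarray, g: int,
                           distance: int) -> dict[str, float]:
    """22 GLCM features averaged over the 13 directions at one distance.

    Reference per-direction path; :func:`glcm_features_fast` is the
    vectorized equivalent used by the extractor.
    """
    acc = {name: 0.0 for name in GLCM_FEATURE_NAMES}
    for direction in DIRECTIONS_13:
        feats = glcm_features(glcm_compute(levels, mask, g, distance, direction))
        for name in GLCM_FEATURE_NAMES:
            acc[name] += feats[name]
    return {name: v / len(DIRECTIONS_13) for name, v in acc.items()}


def glrlm_features_averaged(levels: np.ndarray, mask: np.ndarray, g: int) -> dict[str, float]:
    """7 Galloway features averaged over the 13 directions (reference path)."""
    acc = {name: 0.0 for name in GLRLM_FEATURE_NAMES}
    for direction in DIRECTIONS_13:
        feats = glrlm_features(glrlm_compute(levels, mask, g, direction))
        for name in GLRLM_FEATURE_NAMES:
            acc[name] += feats[name]
    return {name: v / len(DIRECTIONS_13) for name, v in acc.items()}


# ---------------------------------------------------------------------------
# Vectorized all-directions fast paths (numerically identical to the
# reference per-direction implementations above; asserted in the test suite).
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _glcm_meshes(g: int):
    idx = np.arange(1, g + 1, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    ksum = (ii + jj).astype(int).ravel()
    kdiff = np.abs(ii - jj).astype(int).ravel()
    return idx, ii, jj, ksum, kdiff


def glcm_features_fast(levels: np.ndarray, mask: np.ndarray, g: int,
                       distance: int) -> dict[str, float]:
    """22 GLCM features averaged over the 13 directions, one vectorized pass."""
    nd = len(DIRECTIONS_13)
    counts = np.zeros((nd, g, g))
    for d_idx, direction in enumerate(DIRECTIONS_13):
        offset = tuple(int(distance * d) for d in direction)
        la, lb = _shifted_views(levels, offset)
        ma, mb = _shifted_views(mask, offset)
        valid = ma & mb
        if valid.any():
            flat = (la[valid] - 1) * g + (lb[valid] - 1)
            counts[d_idx] = np.bincount(flat, minlength=g * g).reshape(g, g)
    counts = counts + counts.transpose(0, 2, 1)
    totals = counts.sum(axis=(1, 2))
    safe = np.where(totals > 0, totals, 1.0)
    p = counts / safe[:, None, None]

    idx, ii, jj, ksum, kdiff = _glcm_meshes(g)
    px = p.sum(axis=2)  # (nd, g)
    mu = px @ idx
    var = ((idx[None, :] - mu[:, None]) ** 2 * px).sum(axis=1)

    p_flat = p.reshape(nd, -1)
    p_sum = np.zeros((nd, 2 * g + 1))
    p_diff = np.zeros((nd, g))
    for d_idx in range(nd):
        p_sum[d_idx] = np.bincount(ksum, weights=p_flat[d_idx], minlength=2 * g + 1)
        p_diff[d_idx] = np.bincount(kdiff, weights=p_flat[d_idx], minlength=g)

    eps = np.finfo(float).tiny
    hxy = -(p * np.log2(p + eps)).sum(axis=(1, 2))
    hx = -(px * np.log2(px + eps)).sum(axis=1)
    pxy_outer = px[:, :, None] * px[:, None, :]
    log_outer = np.log2(pxy_outer + eps)
    hxy1 = -(p * log_outer).sum(axis=(1, 2))
    hxy2 = -(pxy_outer * log_outer).sum(axis=(1, 2))

    ks = np.arange(2 * g + 1, dtype=float)
    kd = np.arange(g, dtype=float)
    sum_avg = p_sum @ ks
    with np.errstate(divide="ignore", invalid="ignore"):
        sum_ent = -np.where(p_sum > 0, p_sum * np.log2(p_sum + eps), 0.0).sum(axis=1)
        diff_ent = -np.where(p_diff > 0, p_diff * np.log2(p_diff + eps), 0.0).sum(axis=1)
    sum_var = ((ks[None, :] - sum_avg[:, None]) ** 2 * p_sum).sum(axis=1)
    diff_avg = p_diff @ kd
    diff_var = ((kd[None, :] - diff_avg[:, None]) ** 2 * p_diff).sum(axis=1)

    dij = ii - jj
    adij = np.abs(dij)
    contrast = (p * dij[None] ** 2).sum(axis=(1, 2))
    dissim = (p * adij[None]).sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        correlation = np.where(
            var > 0,
            ((ii[None] - mu[:, None, None]) * (jj[None] - mu[:, None, None]) * p
             ).sum(axis=(1, 2)) / np.where(var > 0, var, 1.0),
            0.0,
        )
        imc1 = np.where(hx > 0, (hxy - hxy1) / np.where(hx > 0, hx, 1.0), 0.0)
    imc2 = np.sqrt(np.maximum(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0))
    inv_var = (p[:, :, :] * np.where(adij > 0, 1.0 / np.where(adij > 0, adij, 1.0) ** 2, 0.0)[None]
               ).sum(axis=(1, 2))
    cpm = ii[None] + jj[None] - 2 * mu[:, None, None]
    cpm2 = cpm * cpm

    feats = {
        "autocorrelation": (p * (ii * jj)[None]).sum(axis=(1, 2)),
        "cluster_prominence": (p * (cpm2 * cpm2)).sum(axis=(1, 2)),
        "cluster_shade": (p * (cpm2 * cpm)).sum(axis=(1, 2)),
        "cluster_tendency": (p * cpm2).sum(axis=(1, 2)),
        "contrast": contrast,
        "correlation": correlation,
        "difference_average": diff_avg,
        "difference_entropy": diff_ent,
        "difference_variance": diff_var,
        "dissimilarity": dissim,
        "energy": (p**2).sum(axis=(1, 2)),
        "joint_entropy": hxy,
        "homogeneity": (p / (1.0 + dij[None] ** 2)).sum(axis=(1, 2)),
        "imc1": imc1,
        "imc2": imc2,
        "inverse_difference": (p / (1.0 + adij[None])).sum(axis=(1, 2)),
        "maximum_probability": p.max(axis=(1, 2)),
        "sum_average": sum_avg,
        "sum_entropy": sum_ent,
        "sum_variance": sum_var,
        "variance": var,
        "inverse_variance": inv_var,
    }
    # Degenerate directions (no pair, or a single occupied cell) follow the
    # constant-ROI convention of the reference path.
    occupied = (p > 0).sum(axis=(1, 2))
    degen = np.flatnonzero(occupied <= 1)
    if degen.size:
        for d_idx in degen:
            m = GLCMatrix(counts=counts[d_idx], distance=distance,
                          direction=DIRECTIONS_13[d_idx])
            ref = glcm_features(m)
            for name in GLCM_FEATURE_NAMES:
                feats[name][d_idx] = ref[name]
    return {name: float(v.mean()) for name, v in feats.items()}


@lru_cache(maxsize=128)
def _line_order(shape: tuple[int, int, int], direction: tuple[int, int, int]):
    """Flat voxel order grouping lines along ``direction`` (cached geometry).

    Returns (order, new_line) where ``order`` sorts flat indices by
    (line id, position along line) and ``new_line[k]`` marks the first
    voxel of each line in that order.
    """
    coords = np.indices(shape).reshape(3, -1)
    d = np.asarray(direction)[:, None]
    c = int((d**2).sum())
    t = (coords * d).sum(axis=0)
    u = coords * c - t[None, :] * d  # constant along each line
    # mixed-radix encode of u (bounded by c * shape)
    key = np.zeros(u.shape[1], dtype=np.int64)
    for axis in range(3):
        span = 2 * c * shape[axis] + 1
        key = key * span + (u[axis] + c * shape[axis])
    order = np.lexsort((t, key))
    key_sorted = key[order]
    new_line = np.empty(len(order), dtype=bool)
    new_line[0] = True
    new_line[1:] = key_sorted[1:] != key_sorted[:-1]
    return order, new_line


def glrlm_counts_fast(levels: np.ndarray, mask: np.ndarray, g: int,
                      direction: tuple[int, int, int]) -> GLRLMatrix:
    """Run-length counts via the cached line ordering (equals glrlm_compute)."""
    lev = np.where(mask, levels, 0).ravel()
    order, new_line = _line_order(levels.shape, tuple(direction))
    s = lev[order]
    brk = new_line.copy()
    brk[1:] |= s[1:] != s[:-1]
    run_id = np.cumsum(brk) - 1
    lengths = np.bincount(run_id)
    run_levels = s[brk]
    keep = run_levels > 0
    lmax = min(n for n, d in zip(levels.shape, direction) if d)
    flat = (run_levels[keep] - 1) * lmax + (lengths[keep] - 1)
    counts = np.bincount(flat, minlength=g * lmax).reshape(g, lmax).astype(float)
    return GLRLMatrix(counts=counts, direction=tuple(direction),
                      n_voxels=int(mask.sum()))


def glrlm_features_fast(levels: np.ndarray, mask: np.ndarray, g: int) -> dict[str, float]:
    """7 Galloway features averaged over the 13 directions (fast path)."""
    acc = {name: 0.0 for name in GLRLM_FEATURE_NAMES}
    for direction in DIRECTIONS_13:
        feats = glrlm_features(glrlm_counts_fast(levels, mask, g, direction))
        for name in GLRLM_FEATURE_NAMES:
            acc[name] += feats[name]
    return {name: v / len(DIRECTIONS_13) for name, v in acc.items()}
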