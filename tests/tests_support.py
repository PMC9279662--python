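"""Brute-force oracles shared by the acceptance tests (plain loops,
deliberately independent of the package implementations)."""

import numpy as np

from rectomics.preprocess import ball_structure


def brute_glcm_pairs(levels, mask, g, distance, direction):
    counts = np.zeros((g, g))
    off = np.array(direction) * distance
    shape = np.array(levels.shape)
    for v in np.argwhere(mask):
        w = v + off
        if ((w >= 0) & (w < shape)).all() and mask[tuple(w)]:
            counts[levels[tuple(v)] - 1, levels[tuple(w)] - 1] += 1
            counts[levels[tuple(w)] - 1, levels[tuple(v)] - 1] += 1
    return counts


def brute_run_enumeration(levels, mask, g, direction, lmax):
    shape = np.array(levels.shape)
    d = np.array(direction)
    counts = np.zeros((g, lmax))
    for start in np.argwhere(mask):
        prev = start - d
        if ((prev >= 0) & (prev < shape)).all() and mask[tuple(prev)] \
                and levels[tuple(prev)] == levels[tuple(start)]:
            continue
        length = 1
        cur = start + d
        while ((cur >= 0) & (cur < shape)).all() and mask[tuple(cur)] \
                and levels[tuple(cur)] == levels[tuple(start)]:
            length += 1
            cur = cur + d
        counts[levels[tuple(start)] - 1, length - 1] += 1
    return counts


def brute_ball_erosion(mask, margin, spacing=(1.0, 1.0, 1.0)):
    structure = ball_structure(margin, spacing)
    offsets = np.argwhere(structure) - np.array(structure.shape) // 2
    out = np.zeros_like(mask)
    shape = np.array(mask.shape)
    for v in np.argwhere(mask):
        pts = v + offsets
        if ((pts >= 0) & (pts < shape)).all(axis=1).all() \
                and mask[tuple(pts.T)].all():
            out[tuple(v)] = True
    return out


def brute_auc_pairs(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def brute_icc_mean_squares(x):
    """ICC(2,1) from the explicit two-way ANOVA mean squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
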