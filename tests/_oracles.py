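"""Independent brute-force oracles shared by the metric tests.

Deliberately naive (voxel loops, flood fill, full enumeration): these are
the reference implementations the vectorised metrics are checked against.
"""

import itertools

import numpy as np
from scipy import stats


def brute_overlap(pred, gt, site):
    """(tp, fp, fn) by an explicit voxel loop."""
    tp = fp = fn = 0
    for idx in np.ndindex(pred.shape):
        p, g = pred[idx] == site, gt[idx] == site
        tp += p and g
        fp += p and not g
        fn += g and not p
    return tp, fp, fn


def brute_components(mask, conn26=True):
    """Connected-component count by flood fill over an explicit neighbour list."""
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    if not conn26:
        offsets = [o for o in offsets if sum(map(abs, o)) == 1]
    seen = np.zeros(mask.shape, dtype=bool)
    n = 0
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        n += 1
        stack = [start]
        seen[start] = True
        while stack:
            cur = stack.pop()
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= c < s for c, s in zip(nb, mask.shape)) \
                        and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
    return n


def brute_confusion(pred, gt):
    out = {}
    for a, b in [(1, 2), (2, 1)]:
        out[(a, b)] = any(gt[idx] == a and pred[idx] == b
                          for idx in np.ndindex(gt.shape))
    return out


def wilcoxon_enumerate(d):
    """Exact two-sided signed-rank p over all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([np.dot(ranks, signs)
                   for signs in itertools.product((0, 1), repeat=n)])
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))
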