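"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths they verify: erosion is the
literal min-over-translated-footprint definition, labelling is a breadth
first flood fill, and the rank-sum p-value is exhaustive enumeration of all
rank assignments.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy.stats import rankdata


def erode_2d_bruteforce(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Binary erosion by definition: a pixel survives iff every footprint
    offset lands on a foreground pixel (out-of-bounds counts as background)."""
    mask = np.asarray(mask, dtype=bool)
    fy, fx = footprint.shape
    cy, cx = fy // 2, fx // 2
    offsets = [(dy - cy, dx - cx) for dy in range(fy) for dx in range(fx) if footprint[dy, dx]]
    out = np.zeros_like(mask)
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            ok = True
            for dy, dx in offsets:
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
                    ok = False
                    break
            out[y, x] = ok
    return out


def _neighbors(connectivity: int):
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(v) for v in d)
        if (connectivity == 6 and order == 1) or (
            connectivity == 18 and order <= 2
        ) or connectivity == 26:
            offs.append(d)
    return offs


def label_floodfill(mask: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Connected-component labelling via breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    offs = _neighbors(connectivity)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            p = queue.popleft()
            for d in offs:
                q = tuple(a + b for a, b in zip(p, d))
                if all(0 <= c < s for c, s in zip(q, mask.shape)) and mask[q] and not labels[q]:
                    labels[q] = current
                    queue.append(q)
    return labels, current


def ranksum_p_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all C(n, n_a) assignments."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    ranks = rankdata(pooled)
    w_obs = ranks[:na].sum()
    ws = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(n), na)]
    )
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
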