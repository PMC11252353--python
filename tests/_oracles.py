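"""Independent brute-force oracles for binary morphology and labeling.

These follow the set definitions directly — dilation as a union of
translates, erosion as an intersection of translates with out-of-image
pixels treated as background, connected components by flood fill — and
share no code with the implementation they check.
"""

from collections import deque

import numpy as np


def _shift(mask: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Translate by (di, dj), filling with background."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    src_r = slice(max(0, -di), min(h, h - di))
    src_c = slice(max(0, -dj), min(w, w - dj))
    dst_r = slice(max(0, di), min(h, h + di))
    dst_c = slice(max(0, dj), min(w, w + dj))
    out[dst_r, dst_c] = mask[src_r, src_c]
    return out


def _offsets(se: np.ndarray):
    a, b = se.shape[0] // 2, se.shape[1] // 2
    for i in range(se.shape[0]):
        for j in range(se.shape[1]):
            if se[i, j]:
                yield (i - a, j - b)


def dilate(mask: np.ndarray, se: np.ndarray, iterations: int = 1) -> np.ndarray:
    out = np.asarray(mask, dtype=bool)
    for _ in range(iterations):
        acc = np.zeros_like(out)
        for di, dj in _offsets(se):
            acc |= _shift(out, di, dj)
        out = acc
    return out


def erode(mask: np.ndarray, se: np.ndarray, iterations: int = 1) -> np.ndarray:
    out = np.asarray(mask, dtype=bool)
    for _ in range(iterations):
        acc = np.ones_like(out)
        for di, dj in _offsets(se):
            acc &= _shift(out, -di, -dj)
        out = acc
    return out


def opening(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    return dilate(erode(mask, se), se)


def refine(mask: np.ndarray, square: np.ndarray, ellipse: np.ndarray, iterations: int = 3) -> np.ndarray:
    """Dilate(3x) -> erode(3x) -> open, all by the set definitions."""
    out = dilate(mask, square, iterations=iterations)
    out = erode(out, square, iterations=iterations)
    return opening(out, ellipse)


def flood_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected components by BFS flood fill, raster-order numbering."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    labels = np.zeros((h, w), dtype=np.int64)
    nxt = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                nxt += 1
                q = deque([(r, c)])
                labels[r, c] = nxt
                while q:
                    rr, cc = q.popleft()
                    for dr, dc in neigh:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2] and labels[r2, c2] == 0:
                            labels[r2, c2] = nxt
                            q.append((r2, c2))
    return labels
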