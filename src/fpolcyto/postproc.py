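"""Post-processing of segmentation probabilities into labeled cell regions.

The high-quality class probability map is binarized at 0.5 and cleaned
with a fixed morphological chain: dilation (3x3 square, 3 iterations) to
close small gaps, the mirroring erosion (3x3, 3 iterations) to restore
boundaries, then a morphological opening with a 15x15 elliptical element
to remove spurious pixel clusters too small to be cells. Individual cells
are then identified by connected-component labeling.

Conventions frozen for bit-exact behaviour: probability exactly 0.5 maps
to foreground; pixels outside the image are background for all operators;
the elliptical element is the discrete filled ellipse with semi-axes 7;
components use 8-connectivity and are numbered in raster-scan order of
their first pixel.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

DEFAULT_THRESHOLD = 0.5
DILATION_ITERATIONS = 3
SQUARE_KERNEL_SIZE = 3
OPENING_KERNEL_SIZE = 15


def square_element(size: int = SQUARE_KERNEL_SIZE) -> np.ndarray:
    return np.ones((size, size), dtype=bool)


def elliptical_element(size: int = OPENING_KERNEL_SIZE) -> np.ndarray:
    """Discrete filled ellipse: (dx/a)^2 + (dy/a)^2 <= 1 with a = (size-1)/2."""
    if size % 2 != 1:
        raise ValueError("elliptical element size must be odd")
    a = (size - 1) / 2
    dy, dx = np.mgrid[-a : a + 1, -a : a + 1]
    return (dx / a) ** 2 + (dy / a) ** 2 <= 1.0


@dataclasses.dataclass(frozen=True)
class LabeledRegions:
    """Connected foreground regions: a label grid plus per-region pixel counts.

    Labels run contiguously from 1 in raster-scan order of each region's
    first pixel; 0 is background.
    """

    labels: np.ndarray
    sizes: tuple[int, ...]

    @property
    def n_regions(self) -> int:
        return len(self.sizes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def binarize(prob: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Foreground iff probability >= threshold (ties go to foreground)."""
    prob = np.asarray(prob, dtype=np.float64)
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return prob >= threshold


def _check_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary (bool or 0/1)")
        arr = arr.astype(bool)
    return arr


def refine_mask(
    mask: np.ndarray,
    iterations: int = DILATION_ITERATIONS,
    square_size: int = SQUARE_KERNEL_SIZE,
    opening_size: int = OPENING_KERNEL_SIZE,
) -> np.ndarray:
    """Dilate, erode back, then open: the fixed mask-cleaning chain."""
    mask = _check_binary(mask)
    sq = square_element(square_size)
    out = ndimage.binary_dilation(mask, structure=sq, iterations=iterations)
    out = ndimage.binary_erosion(out, structure=sq, iterations=iterations, border_value=0)
    ell = elliptical_element(opening_size)
    out = ndimage.binary_opening(out, structure=ell, iterations=1, border_value=0)
    return out


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabeledRegions:
    """Connected-component labeling with deterministic raster ordering."""
    mask = _check_binary(mask)
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    raw, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return LabeledRegions(labels=raw.astype(np.int64), sizes=())
    # renumber by raster order of each region's first pixel
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    # reverse order so earlier indices overwrite later ones
    first[flat[idx[::-1]]] = idx[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int64)
    remap[order + 1] = np.arange(1, n + 1)
    labels = remap[raw]
    sizes = tuple(int(s) for s in np.bincount(labels.ravel(), minlength=n + 1)[1:])
    return LabeledRegions(labels=labels, sizes=sizes)
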