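"""Synthetic polarized-fluorescence cytology phantoms.

Real inputs to the pipeline are pairs of co- and cross-polarized
methylene-blue fluorescence emission images of fine-needle-aspiration
cells, with expert tri-class annotations (background / ambiguous signal /
high-quality cells). No public data set of this kind exists, so this
module fabricates image pairs with known per-cell ground truth:

* high-quality cells are smooth elliptical blobs with an optional
  brighter nuclear core, placed either isolated or clustered;
* the cross channel is derived from the co channel by inverting the
  polarization relation ``Fpol = (I_co - G I_cross)/(I_co + G I_cross)``,
  so each cell's true Fpol is known exactly before 8-bit quantization;
* ambiguous ("low-quality") cells are rendered dimmer and Gaussian-blurred,
  mimicking out-of-focus signal, and never enter the high-quality mask;
* the background sits at a constant level inside the < 3-count exclusion
  band, so the quantification thresholds are exercised.

Generation is fully deterministic given the spec's seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import (
    PolarizedImagePair,
    TriMask,
    write_image,
    write_label_mask,
    write_trimask,
)
from .quant import DEFAULT_G_FACTOR

#: Fpol range observed for thyroid cells (malignant high, benign/normal low).
OBSERVED_FPOL_RANGE = (0.10, 0.33)

#: Group-level Fpol moments used when sampling targets by diagnosis class:
#: malignant cells polarize strongly, benign and normal cells weakly.
CLASS_FPOL_MOMENTS = {
    "malignant": (0.28, 0.02),
    "benign": (0.17, 0.02),
    "normal": (0.18, 0.02),
}


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed inside the image bounds."""


def fpol_to_cross_intensity(i_co: float, fpol: float, g: float = DEFAULT_G_FACTOR):
    """Cross-channel intensity that realizes a target Fpol at a given co intensity.

    Inverts the polarization relation: ``i_cross = i_co (1 - fpol) / (g (1 + fpol))``.
    Substituting back recovers ``fpol`` exactly (before quantization).
    ``fpol = -1`` is rejected (zero denominator); ``fpol = 1`` gives zero
    cross signal.
    """
    if not g > 0:
        raise ValueError("g must be > 0")
    fpol_arr = np.asarray(fpol, dtype=np.float64)
    if np.any(fpol_arr <= -1) or np.any(fpol_arr > 1):
        raise ValueError("fpol must lie in (-1, 1]")
    i_co_arr = np.asarray(i_co, dtype=np.float64)
    if np.any(i_co_arr < 0):
        raise ValueError("i_co must be non-negative")
    out = i_co_arr * (1.0 - fpol_arr) / (g * (1.0 + fpol_arr))
    if np.isscalar(fpol) and np.isscalar(i_co):
        return float(out)
    return out


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic sample.

    ``n_cells`` counts high-quality cells; an additional
    ``round(ambiguous_fraction * n_cells)`` ambiguous cells are rendered.
    ``fpol_targets`` (one per high-quality cell) defaults to draws from the
    observed 0.10-0.33 range when omitted.
    """

    image_size: int = 1000
    pixel_size: float = 0.205
    n_cells: int = 12
    fpol_targets: tuple[float, ...] | None = None
    base_co_intensity: float = 160.0
    g_factor: float = DEFAULT_G_FACTOR
    cell_radius_range: tuple[int, int] = (8, 16)
    cluster_fraction: float = 0.25
    ambiguous_fraction: float = 0.25
    noise_sd: float = 2.0
    background_level: float = 1.0
    quantize: bool = True
    diagnosis: str = "benign"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fpol_targets is not None:
            t = tuple(float(x) for x in self.fpol_targets)
            if len(t) != self.n_cells:
                raise ValueError("fpol_targets must have one entry per cell")
            if any(x < -1 or x > 1 for x in t):
                raise ValueError("fpol_targets must lie in [-1, 1]")
            object.__setattr__(self, "fpol_targets", t)
        if not (3 <= self.base_co_intensity <= 254):
            raise ValueError("base_co_intensity must lie in [3, 254]")
        if self.image_size <= 2 * max(self.cell_radius_range):
            raise ValueError("image_size must exceed twice the maximum cell radius")
        if not 0 <= self.background_level < 3:
            raise ValueError("background_level must sit below the 3-count band")


@dataclasses.dataclass(frozen=True)
class CellTruth:
    cell_id: int
    pixels: frozenset
    fpol: float


@dataclasses.dataclass(frozen=True)
class PhantomSample:
    pair: PolarizedImagePair
    masks: TriMask
    truth: tuple[CellTruth, ...]

    def truth_label_mask(self) -> np.ndarray:
        """Label grid from the ground-truth pixel sets (first id wins on overlap)."""
        labels = np.zeros(self.pair.shape, dtype=np.int64)
        for cell in self.truth:
            for r, c in cell.pixels:
                if labels[r, c] == 0:
                    labels[r, c] = cell.cell_id
        return labels


def sample_fpol_targets(
    diagnosis: str, n: int, rng: np.random.Generator
) -> tuple[float, ...]:
    """Draw per-cell Fpol targets from the diagnosis-class moments."""
    mean, sd = CLASS_FPOL_MOMENTS[diagnosis]
    return tuple(np.clip(rng.normal(mean, sd, size=n), -0.99, 0.99).tolist())


def _quantize(arr: np.ndarray) -> np.ndarray:
    """Round half-up to integer counts and clip to the 8-bit range."""
    return np.clip(np.floor(arr + 0.5), 0, 255)


def _ellipse_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    theta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean support and normalized elliptical radius rho (rho<=1 inside)."""
    h, w = shape
    cy, cx = center
    a, b = axes
    r = max(a, b) + 2
    r0, r1 = max(0, int(np.floor(cy - r))), min(h, int(np.ceil(cy + r)) + 1)
    c0, c1 = max(0, int(np.floor(cx - r))), min(w, int(np.ceil(cx + r)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    rho_local = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    support = np.zeros(shape, dtype=bool)
    rho = np.full(shape, np.inf)
    support[r0:r1, c0:c1] = rho_local <= 1.0
    rho[r0:r1, c0:c1] = rho_local
    return support, rho


def _place_cells(spec: PhantomSpec, n_total: int, rng: np.random.Generator):
    """Pick centers and radii: isolated cells well separated, a cluster
    fraction of the high-quality cells placed adjacent to an earlier cell."""
    rmin, rmax = spec.cell_radius_range
    margin = rmax + 2
    size = spec.image_size
    if size <= 2 * margin:
        raise PlacementError("image too small for the requested cell radii")
    n_cluster = int(round(spec.cluster_fraction * spec.n_cells))
    placed: list[tuple[float, float, float]] = []  # (cy, cx, radius)
    for i in range(n_total):
        radius = float(rng.uniform(rmin, rmax))
        clustered = placed and i < spec.n_cells and (spec.n_cells - i) <= n_cluster
        for _ in range(2000):
            if clustered:
                ay, ax, ar = placed[rng.integers(len(placed))]
                ang = rng.uniform(0, 2 * np.pi)
                d = (ar + radius) * rng.uniform(0.75, 1.05)
                cy, cx = ay + d * np.sin(ang), ax + d * np.cos(ang)
                if not (margin <= cy < size - margin and margin <= cx < size - margin):
                    continue
                break
            cy = float(rng.uniform(margin, size - margin))
            cx = float(rng.uniform(margin, size - margin))
            # keep non-clustered cells separated so components stay disjoint
            if all(np.hypot(cy - py, cx - px) > radius + pr + 4 for py, px, pr in placed):
                break
        else:
            raise PlacementError(
                f"could not place cell {i} inside a {size}x{size} image"
            )
        placed.append((cy, cx, radius))
    return placed


def generate_sample(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom sample with known per-cell Fpol ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_size, spec.image_size)
    n_amb = int(round(spec.ambiguous_fraction * spec.n_cells))
    placed = _place_cells(spec, spec.n_cells + n_amb, rng)

    targets = spec.fpol_targets
    if targets is None:
        lo, hi = OBSERVED_FPOL_RANGE
        targets = tuple(rng.uniform(lo, hi, size=spec.n_cells).tolist())

    co = np.zeros(shape, dtype=np.float64)
    cross = np.zeros(shape, dtype=np.float64)
    hq_mask = np.zeros(shape, dtype=bool)
    truth: list[CellTruth] = []

    for i in range(spec.n_cells):
        cy, cx, radius = placed[i]
        axes = (radius, radius * rng.uniform(0.7, 1.0))
        theta = rng.uniform(0, np.pi)
        support, rho = _ellipse_blob(shape, (cy, cx), axes, theta)
        # smooth dome plus a brighter nuclear core; kept within [3, 254]
        profile = np.zeros(shape)
        profile[support] = 0.72 + 0.22 * (1.0 - rho[support] ** 2)
        core = support & (rho < 0.45)
        profile[core] *= 1.18
        co_cell = spec.base_co_intensity * profile
        cross_cell = fpol_to_cross_intensity(co_cell, targets[i], spec.g_factor)
        co += co_cell
        cross += cross_cell
        hq_mask |= support
        rows, cols = np.nonzero(support)
        truth.append(
            CellTruth(
                cell_id=i + 1,
                pixels=frozenset(zip(rows.tolist(), cols.tolist())),
                fpol=float(targets[i]),
            )
        )

    # ambiguous cells: dim, defocused blobs on both channels
    amb_canvas = np.zeros(shape, dtype=np.float64)
    amb_fpols = rng.uniform(*OBSERVED_FPOL_RANGE, size=n_amb)
    for j in range(n_amb):
        cy, cx, radius = placed[spec.n_cells + j]
        support, rho = _ellipse_blob(shape, (cy, cx), (radius, radius * 0.85), 0.0)
        blob = np.zeros(shape)
        blob[support] = 0.45 * spec.base_co_intensity * (1.0 - rho[support] ** 2)
        amb_canvas += blob
    if n_amb:
        amb_canvas = ndimage.gaussian_filter(amb_canvas, sigma=3.0)
    amb_mask = (amb_canvas > 6.0) & ~hq_mask
    amb_fpol = float(np.mean(amb_fpols)) if n_amb else 0.0
    co += amb_canvas
    cross += fpol_to_cross_intensity(amb_canvas, amb_fpol, spec.g_factor)

    signal = (co > 0) | (cross > 0)
    co = np.where(signal, co, spec.background_level)
    cross = np.where(signal, cross, spec.background_level)

    if spec.noise_sd > 0:
        co = co + rng.normal(0.0, spec.noise_sd, size=shape)
        cross = cross + rng.normal(0.0, spec.noise_sd, size=shape)

    if spec.quantize:
        co8, cross8 = _quantize(co).astype(np.uint8), _quantize(cross).astype(np.uint8)
        pair = PolarizedImagePair(co=co8, cross=cross8, pixel_size=spec.pixel_size)
    else:
        pair = PolarizedImagePair(
            co=np.clip(co, 0, 255), cross=np.clip(cross, 0, 255), pixel_size=spec.pixel_size
        )

    masks = TriMask(
        background=~(hq_mask | amb_mask),
        ambiguous=amb_mask,
        high_quality=hq_mask,
    )
    return PhantomSample(pair=pair, masks=masks, truth=tuple(truth))


def write_fixture_set(
    specs: Sequence[PhantomSpec], out_dir: str | Path
) -> pd.DataFrame:
    """Render a list of specs to disk and return (and write) the manifest.

    Layout per sample ``sNNN``: ``sNNN_co.png`` / ``sNNN_cross.png`` (8-bit
    grayscale), ``sNNN_labels.tif`` (16-bit ground-truth label mask), the
    three class masks as 0/255 PNGs, and one ``manifest.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, spec in enumerate(specs):
        sample = generate_sample(spec)
        sid = f"s{idx:03d}"
        co_path = out_dir / f"{sid}_co.png"
        cross_path = out_dir / f"{sid}_cross.png"
        mask_path = out_dir / f"{sid}_labels.tif"
        write_image(sample.pair.co, co_path)
        write_image(sample.pair.cross, cross_path)
        write_label_mask(sample.truth_label_mask(), mask_path)
        write_trimask(sample.masks, out_dir / sid)
        rows.append(
            {
                "sample_id": sid,
                "class": spec.diagnosis,
                "co_path": co_path.name,
                "cross_path": cross_path.name,
                "mask_path": mask_path.name,
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "class", "co_path", "cross_path", "mask_path", "seed"]
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
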