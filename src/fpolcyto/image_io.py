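"""Reading and writing polarized image pairs, masks, and per-cell tables.

All grids use a single coordinate convention: row-major, origin at the
top-left, 0-based indices. Images are 8-bit single-channel TIFF or PNG;
binary masks are PNG with values 0/255; label masks are 16-bit TIFF;
per-cell result tables are CSV.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

#: Side length of the nominal field of view, micrometres (205 µm across
#: 1000 pixels -> 0.205 µm per pixel).
DEFAULT_PIXEL_SIZE_UM = 0.205


class ImageFormatError(ValueError):
    """Raised when an input image violates the 8-bit single-channel contract."""


@dataclasses.dataclass(frozen=True)
class PolarizedImagePair:
    """A co-polarized / cross-polarized fluorescence emission image pair.

    Parameters
    ----------
    co, cross :
        2-D uint8 intensity grids detected parallel (co) and perpendicular
        (cross) to the excitation polarization. Both channels share the
        same field of view and geometry.
    pixel_size :
        Lateral pixel pitch in µm/pixel.
    """

    co: np.ndarray
    cross: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        co = np.asarray(self.co)
        cross = np.asarray(self.cross)
        if co.ndim != 2 or cross.ndim != 2:
            raise ImageFormatError("channels must be 2-D grids")
        if co.shape != cross.shape:
            raise ImageFormatError(
                f"channel dimension mismatch: co {co.shape} vs cross {cross.shape}"
            )
        for name, arr in (("co", co), ("cross", cross)):
            if arr.min() < 0 or arr.max() > 255:
                raise ImageFormatError(f"{name} channel has values outside [0, 255]")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "co", co)
        object.__setattr__(self, "cross", cross)

    @property
    def shape(self) -> tuple[int, int]:
        return self.co.shape


@dataclasses.dataclass(frozen=True)
class TriMask:
    """Three-class annotation: background / ambiguous cell signal / high-quality cells.

    High-quality cells are the expert-selected, diagnostically relevant
    regions; ambiguous regions are cell-like signal the expert did not
    select (out of focus, uncertain relevance). A pixel in the high-quality
    mask is never in the background mask.
    """

    background: np.ndarray
    ambiguous: np.ndarray
    high_quality: np.ndarray

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=bool)
        am = np.asarray(self.ambiguous, dtype=bool)
        hq = np.asarray(self.high_quality, dtype=bool)
        if not (bg.shape == am.shape == hq.shape):
            raise ValueError("the three masks must share one image geometry")
        if np.any(hq & bg):
            raise ValueError("a pixel cannot be both high-quality and background")
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "ambiguous", am)
        object.__setattr__(self, "high_quality", hq)

    @property
    def shape(self) -> tuple[int, int]:
        return self.background.shape

    def class_map(self) -> np.ndarray:
        """Integer class labels: 0 background, 1 ambiguous, 2 high-quality."""
        out = np.zeros(self.shape, dtype=np.int64)
        out[self.ambiguous] = 1
        out[self.high_quality] = 2
        return out


# ---------------------------------------------------------------------------
# image file I/O
# ---------------------------------------------------------------------------

def _read_8bit(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: expected single-channel image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ImageFormatError(f"{path}: expected 8-bit image, got dtype {arr.dtype}")
    return arr


def read_pair(
    co_path: str | os.PathLike,
    cross_path: str | os.PathLike,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
) -> PolarizedImagePair:
    """Read a co/cross image pair from 8-bit grayscale TIFF or PNG files."""
    co = _read_8bit(co_path)
    cross = _read_8bit(cross_path)
    if co.shape != cross.shape:
        raise ImageFormatError(
            f"dimension mismatch: {co_path} is {co.shape} but {cross_path} is {cross.shape}"
        )
    return PolarizedImagePair(co=co, cross=cross, pixel_size=pixel_size)


def write_image(arr: np.ndarray, path: str | os.PathLike) -> None:
    """Write an 8-bit grayscale image as TIFF or PNG depending on suffix."""
    path = Path(path)
    arr = np.asarray(arr, dtype=np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def read_binary_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a 0/255 PNG (or TIFF) mask as a boolean grid."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    return arr > 0


def write_binary_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    write_image(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8), path)


def read_label_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a label image (0 = background, 1..k = regions) from TIFF."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: label mask must be 2-D")
    return arr.astype(np.int64)


def write_label_mask(labels: np.ndarray, path: str | os.PathLike) -> None:
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 regions cannot be stored as 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_trimask(
    background_path: str | os.PathLike,
    ambiguous_path: str | os.PathLike,
    high_quality_path: str | os.PathLike,
) -> TriMask:
    return TriMask(
        background=read_binary_mask(background_path),
        ambiguous=read_binary_mask(ambiguous_path),
        high_quality=read_binary_mask(high_quality_path),
    )


def write_trimask(masks: TriMask, prefix: str | os.PathLike) -> dict[str, Path]:
    """Write the three binary masks as ``<prefix>_{background,ambiguous,highquality}.png``."""
    prefix = Path(prefix)
    paths = {
        "background": prefix.with_name(prefix.name + "_background.png"),
        "ambiguous": prefix.with_name(prefix.name + "_ambiguous.png"),
        "high_quality": prefix.with_name(prefix.name + "_highquality.png"),
    }
    write_binary_mask(masks.background, paths["background"])
    write_binary_mask(masks.ambiguous, paths["ambiguous"])
    write_binary_mask(masks.high_quality, paths["high_quality"])
    return paths


# ---------------------------------------------------------------------------
# frame averaging
# ---------------------------------------------------------------------------

def average_frames(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Pixel-wise arithmetic mean of repeated acquisition frames.

    The mean is kept at floating precision; quantization to 8 bits happens
    only when an image is written.
    """
    if len(frames) == 0:
        raise ValueError("average_frames requires at least one frame")
    first = np.asarray(frames[0], dtype=np.float64)
    acc = first.copy()
    for f in frames[1:]:
        f = np.asarray(f, dtype=np.float64)
        if f.shape != first.shape:
            raise ValueError("all frames must share one geometry")
        acc += f
    return acc / len(frames)


# ---------------------------------------------------------------------------
# per-cell result tables
# ---------------------------------------------------------------------------

CELL_TABLE_COLUMNS = [
    "sample_id",
    "cell_id",
    "area_px",
    "area_um2",
    "mean_co",
    "mean_cross",
    "fpol",
    "quality_flag",
]


def cells_to_frame(cells: Sequence, sample_id: str = "") -> pd.DataFrame:
    """Convert CellRegion records (see :mod:`fpolcyto.quant`) to a DataFrame."""
    rows = []
    for c in cells:
        rows.append(
            {
                "sample_id": sample_id,
                "cell_id": c.cell_id,
                "area_px": c.area_px,
                "area_um2": c.area_um2,
                "mean_co": c.mean_co,
                "mean_cross": c.mean_cross,
                "fpol": c.fpol,
                "quality_flag": c.quality_flag,
            }
        )
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def write_cell_table(cells: Sequence, path: str | os.PathLike, sample_id: str = "") -> None:
    """Write one CSV row per cell (header always present)."""
    cells_to_frame(cells, sample_id=sample_id).to_csv(path, index=False, float_format="%.6f")


def read_cell_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"sample_id": str})
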