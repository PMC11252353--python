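"""End-to-end orchestration: manifest in, per-sample tables and reports out.

For every sample in the manifest the trained network produces class
probabilities, the high-quality map is post-processed into labeled cells,
each cell's Fpol and area are quantified, and — when a manual (MA) label
mask is available — the automated result is matched against it. Finally
all cells are pooled into the grouped statistical analysis. Every stage
logs one line per sample with its parameters so a run can be audited.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import DEFAULT_OVERLAP_FRACTION, compare_sample, match_cells
from .image_io import (
    DEFAULT_PIXEL_SIZE_UM,
    cells_to_frame,
    read_label_mask,
    read_pair,
    write_cell_table,
)
from .postproc import DEFAULT_THRESHOLD, LabeledRegions, binarize, label_components, refine_mask
from .quant import DEFAULT_G_FACTOR, quantify_sample
from .segnet import UNet, predict
from .stats import DEFAULT_ALPHA, analyze_groups

logger = logging.getLogger("fpolcyto")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    manifest: str
    model: str
    out_dir: str
    g_factor: float = DEFAULT_G_FACTOR
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    threshold: float = DEFAULT_THRESHOLD
    connectivity: int = 8
    match_overlap: float = DEFAULT_OVERLAP_FRACTION
    alpha: float = DEFAULT_ALPHA
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def labels_from_mask(mask: np.ndarray, connectivity: int = 8) -> LabeledRegions:
    """Wrap an externally supplied label or binary mask as LabeledRegions."""
    mask = np.asarray(mask)
    return label_components(mask > 0, connectivity=connectivity)


def segment_pair(net: UNet, pair, cfg: RunConfig) -> LabeledRegions:
    """Probability maps -> refined binary mask -> labeled high-quality cells."""
    probs = predict(net, pair)
    mask = binarize(probs.high_quality, threshold=cfg.threshold)
    mask = refine_mask(mask)
    return label_components(mask, connectivity=cfg.connectivity)


def run_pipeline(cfg: RunConfig) -> dict:
    """Process every manifest sample; returns the combined report dict."""
    manifest_path = Path(cfg.manifest)
    manifest = pd.read_csv(manifest_path, dtype={"sample_id": str})
    if manifest.empty:
        raise ValueError("empty manifest")
    net = UNet.load(cfg.model)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "run start: version=%s seed=%d g=%.3f pixel_size=%.4f threshold=%.2f",
        __version__, cfg.seed, cfg.g_factor, cfg.pixel_size, cfg.threshold,
    )

    all_cells = []
    sample_summaries = {}
    for _, row in manifest.iterrows():
        sid = row["sample_id"]
        try:
            pair = read_pair(
                manifest_path.parent / row["co_path"],
                manifest_path.parent / row["cross_path"],
                pixel_size=cfg.pixel_size,
            )
        except (OSError, ValueError) as exc:
            logger.warning("sample %s skipped: %s", sid, exc)
            continue
        au_labels = segment_pair(net, pair, cfg)
        au_cells = quantify_sample(
            pair, au_labels.labels, g=cfg.g_factor, pixel_size=cfg.pixel_size
        )
        write_cell_table(au_cells, out_dir / f"{sid}_au_cells.csv", sample_id=sid)
        logger.info("sample %s: AU %d cells", sid, len(au_cells))
        au_frame = cells_to_frame(au_cells, sample_id=sid)
        au_frame["method"] = "AU"
        au_frame["diagnosis"] = row.get("class", "unknown")
        all_cells.append(au_frame)

        mask_rel = row.get("mask_path")
        if isinstance(mask_rel, str) and mask_rel:
            ma_labels = labels_from_mask(
                read_label_mask(manifest_path.parent / mask_rel), cfg.connectivity
            )
            ma_cells = quantify_sample(
                pair, ma_labels.labels, g=cfg.g_factor, pixel_size=cfg.pixel_size
            )
            write_cell_table(ma_cells, out_dir / f"{sid}_ma_cells.csv", sample_id=sid)
            pairing = match_cells(au_labels, ma_labels, overlap_fraction=cfg.match_overlap)
            result = compare_sample(au_cells, ma_cells, pairing)
            pairs_frame = pd.DataFrame(
                [dataclasses.asdict(p) for p in result.matched],
                columns=["au_id", "ma_id", "overlap_px", "delta_fpol_pct", "delta_area_pct"],
            )
            pairs_frame.to_csv(out_dir / f"{sid}_matched.csv", index=False)
            sample_summaries[sid] = dict(result.summary)
            logger.info(
                "sample %s: matched=%d au_only=%d ma_only=%d",
                sid, len(result.matched), len(result.au_only), len(result.ma_only),
            )
            ma_frame = cells_to_frame(ma_cells, sample_id=sid)
            ma_frame["method"] = "MA"
            ma_frame["diagnosis"] = row.get("class", "unknown")
            all_cells.append(ma_frame)
        else:
            logger.info("sample %s: no MA mask, comparison skipped", sid)

    if not all_cells:
        raise ValueError("no sample could be processed")
    combined = pd.concat(all_cells, ignore_index=True)
    combined = combined[combined["quality_flag"] == "high"]
    combined.to_csv(out_dir / "all_cells.csv", index=False)
    summaries, reports = analyze_groups(combined, alpha=cfg.alpha)
    report = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "samples": sample_summaries,
        "groups": [dataclasses.asdict(s) for s in summaries],
        "tests": [dataclasses.asdict(t) for t in reports],
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    logger.info("run complete: %d cells in %d groups", len(combined), len(summaries))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if isinstance(obj, float) and math.isnan(obj) else float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
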