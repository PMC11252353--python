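"""Automated-vs-manual agreement: cell matching and percent differences.

Automated (AU) and manual (MA) segmentations of the same field are
compared by pairing cells one-to-one on pixel overlap, then reporting the
symmetric percent difference of Fpol and area for each matched pair
(AU minus MA over their mean), the unmatched cells on each side, and the
excess of AU over MA cell counts.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from .postproc import LabeledRegions
from .quant import CellRegion

#: A pair requires the overlap to exceed this fraction of the smaller region.
DEFAULT_OVERLAP_FRACTION = 0.5


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching conventional report rounding."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def pct_diff(a: float, b: float) -> float:
    """Symmetric percent difference 100 (a - b) / ((a + b)/2).

    Antisymmetric in its arguments and invariant under common rescaling.
    """
    if a + b == 0:
        raise ZeroDivisionError("percent difference undefined when a + b = 0")
    return 100.0 * (a - b) / ((a + b) / 2.0)


def selection_excess(n_matched: int, n_au_only: int, n_ma_only: int) -> float:
    """Percent excess of automated over manual cell counts.

    ``100 * (AU_total - MA_total) / MA_total`` with AU_total = matched +
    AU-only and MA_total = matched + MA-only.
    """
    n_ma = n_matched + n_ma_only
    if n_ma <= 0:
        raise ValueError("selection excess requires at least one manual cell")
    n_au = n_matched + n_au_only
    return 100.0 * (n_au - n_ma) / n_ma


@dataclasses.dataclass(frozen=True)
class MatchedPair:
    au_id: int
    ma_id: int
    overlap_px: int
    delta_fpol_pct: float = math.nan
    delta_area_pct: float = math.nan


@dataclasses.dataclass(frozen=True)
class MatchResult:
    """One-to-one AU/MA pairing with per-pair percent differences.

    Invariants: every AU and MA id appears in at most one pair;
    ``len(matched) + len(au_only)`` equals the AU cell count and
    ``len(matched) + len(ma_only)`` the MA cell count.
    """

    matched: tuple[MatchedPair, ...]
    au_only: tuple[int, ...]
    ma_only: tuple[int, ...]
    summary: Mapping[str, float] = dataclasses.field(default_factory=dict)

    @property
    def n_au(self) -> int:
        return len(self.matched) + len(self.au_only)

    @property
    def n_ma(self) -> int:
        return len(self.matched) + len(self.ma_only)


def match_cells(
    au: LabeledRegions,
    ma: LabeledRegions,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> MatchResult:
    """Pair AU and MA regions greedily by descending pixel overlap.

    A candidate pair must overlap by more than ``overlap_fraction`` of the
    smaller region's area. Ties are broken by smaller AU id, then MA id,
    making the pairing deterministic.
    """
    if au.shape != ma.shape:
        raise ValueError("AU and MA label masks must share one geometry")
    n_au, n_ma = au.n_regions, ma.n_regions
    # joint histogram of (au label, ma label) over foreground pixels
    both = (au.labels > 0) & (ma.labels > 0)
    candidates = []
    if both.any():
        pair_codes = au.labels[both].astype(np.int64) * (n_ma + 1) + ma.labels[both]
        codes, counts = np.unique(pair_codes, return_counts=True)
        for code, cnt in zip(codes.tolist(), counts.tolist()):
            ai, mi = divmod(code, n_ma + 1)
            smaller = min(au.sizes[ai - 1], ma.sizes[mi - 1])
            if cnt > overlap_fraction * smaller:
                candidates.append((-cnt, ai, mi))
    candidates.sort()
    used_au: set[int] = set()
    used_ma: set[int] = set()
    matched = []
    for neg_cnt, ai, mi in candidates:
        if ai in used_au or mi in used_ma:
            continue
        used_au.add(ai)
        used_ma.add(mi)
        matched.append(MatchedPair(au_id=ai, ma_id=mi, overlap_px=-neg_cnt))
    au_only = tuple(i for i in range(1, n_au + 1) if i not in used_au)
    ma_only = tuple(i for i in range(1, n_ma + 1) if i not in used_ma)
    return MatchResult(matched=tuple(matched), au_only=au_only, ma_only=ma_only)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if not math.isnan(v)], dtype=np.float64)
    if arr.size == 0:
        return (math.nan, math.nan)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return (float(arr.mean()), sd)


def compare_sample(
    au_cells: Sequence[CellRegion],
    ma_cells: Sequence[CellRegion],
    pairing: MatchResult,
) -> MatchResult:
    """Fill per-pair Fpol/area percent differences and the sample summary.

    The percent differences take AU as the first argument, so negative
    area differences mean the automated regions are smaller. The summary
    reports mean +/- SD Fpol over all (not only matched) cells per method,
    plus the cell counts and the selection excess.
    """
    au_by_id = {c.cell_id: c for c in au_cells}
    ma_by_id = {c.cell_id: c for c in ma_cells}
    matched = []
    for pair in pairing.matched:
        if pair.au_id not in au_by_id or pair.ma_id not in ma_by_id:
            raise KeyError(f"pairing references unknown cell ids {pair.au_id}/{pair.ma_id}")
        a, m = au_by_id[pair.au_id], ma_by_id[pair.ma_id]
        try:
            d_fpol = pct_diff(a.fpol, m.fpol)
        except ZeroDivisionError:
            d_fpol = math.nan
        d_area = pct_diff(a.area_px, m.area_px)
        matched.append(
            dataclasses.replace(pair, delta_fpol_pct=d_fpol, delta_area_pct=d_area)
        )
    au_mean, au_sd = _mean_sd([c.fpol for c in au_cells])
    ma_mean, ma_sd = _mean_sd([c.fpol for c in ma_cells])
    summary = {
        "n_matched": len(matched),
        "n_au_only": len(pairing.au_only),
        "n_ma_only": len(pairing.ma_only),
        "au_mean_fpol": au_mean,
        "au_sd_fpol": au_sd,
        "ma_mean_fpol": ma_mean,
        "ma_sd_fpol": ma_sd,
    }
    if len(matched) + len(pairing.ma_only) > 0:
        summary["selection_excess_pct"] = selection_excess(
            len(matched), len(pairing.au_only), len(pairing.ma_only)
        )
    return MatchResult(
        matched=tuple(matched),
        au_only=pairing.au_only,
        ma_only=pairing.ma_only,
        summary=summary,
    )
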