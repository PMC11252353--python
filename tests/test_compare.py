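import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpolcyto import compare_sample, match_cells, pct_diff, selection_excess
from fpolcyto.compare import round_half_away
from fpolcyto.postproc import label_components
from fpolcyto.quant import CellRegion


def _regions(mask_values):
    return label_components(np.asarray(mask_values) > 0)


def _cell(cid, fpol, area_px):
    return CellRegion(
        cell_id=cid, pixels=frozenset(), area_px=area_px,
        area_um2=area_px * 0.205**2, mean_co=100.0, mean_cross=50.0,
        fpol=fpol, quality_flag="high",
    )


class TestPctDiff:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (0.139, 0.137, 1.4),   # benign FTA sample
            (0.176, 0.172, 2.3),   # indeterminate benign group
            (0.276, 0.267, 3.3),   # indeterminate malignant group
            (0.3, 0.3, 0.0),
        ],
    )
    def test_printed_values(self, a, b, expected):
        assert round_half_away(pct_diff(a, b), 1) == pytest.approx(expected)

    def test_zero_sum_rejected(self):
        with pytest.raises(ZeroDivisionError):
            pct_diff(1.0, -1.0)

    @given(a=st.floats(0.01, 10), b=st.floats(0.01, 10))
    @settings(deadline=None, max_examples=100)
    def test_antisymmetry(self, a, b):
        assert pct_diff(a, b) == pytest.approx(-pct_diff(b, a), abs=1e-9)

    @given(a=st.floats(0.01, 10), b=st.floats(0.01, 10), k=st.floats(0.1, 100))
    @settings(deadline=None, max_examples=100)
    def test_scale_invariance(self, a, b, k):
        assert pct_diff(k * a, k * b) == pytest.approx(pct_diff(a, b), rel=1e-9)


class TestSelectionExcess:
    def test_printed_counts(self):
        assert round_half_away(selection_excess(426, 125, 50), 1) == pytest.approx(15.8)

    def test_equal_counts_zero(self):
        assert selection_excess(40, 0, 0) == 0.0

    def test_doubling(self):
        assert selection_excess(0, 10, 5) == pytest.approx(100.0)

    def test_no_manual_cells_rejected(self):
        with pytest.raises(ValueError):
            selection_excess(0, 5, 0)


class TestMatchCells:
    def test_identical_masks_all_matched(self):
        mask = np.zeros((16, 16), dtype=int)
        mask[2:6, 2:6] = 1
        mask[10:14, 10:14] = 1
        au = ma = _regions(mask)
        result = match_cells(au, ma)
        assert len(result.matched) == 2
        assert result.au_only == () and result.ma_only == ()
        for pair, size in zip(result.matched, au.sizes):
            assert pair.overlap_px == size

    def test_empty_au_all_ma_unmatched(self):
        empty = _regions(np.zeros((8, 8)))
        mask = np.zeros((8, 8), dtype=int)
        mask[2:5, 2:5] = 1
        result = match_cells(empty, _regions(mask))
        assert result.matched == () and result.ma_only == (1,)

    def test_minority_overlap_of_smaller_region_unmatched(self):
        ma = np.zeros((12, 12), dtype=int)
        ma[0, 0:10] = 1  # 10-px MA cell
        au = np.zeros((12, 12), dtype=int)
        au[0, 6:12] = 1
        au[1, 6:12] = 1  # 12-px AU cell overlapping 4 px (40% of the smaller MA)
        result = match_cells(_regions(au), _regions(ma))
        assert result.matched == ()
        assert result.au_only == (1,) and result.ma_only == (1,)

    def test_contained_region_matches_via_smaller_area_rule(self):
        ma = np.zeros((10, 10), dtype=int)
        ma[2:8, 2:8] = 1
        au = np.zeros((10, 10), dtype=int)
        au[3:6, 3:6] = 1  # fully contained: overlap = 100% of the smaller AU
        result = match_cells(_regions(au), _regions(ma))
        assert len(result.matched) == 1

    def test_counts_conserved(self, rng):
        au = rng.random((64, 64)) < 0.3
        ma = rng.random((64, 64)) < 0.3
        r_au, r_ma = label_components(au), label_components(ma)
        result = match_cells(r_au, r_ma)
        assert len(result.matched) + len(result.au_only) == r_au.n_regions
        assert len(result.matched) + len(result.ma_only) == r_ma.n_regions
        assert len({p.au_id for p in result.matched}) == len(result.matched)
        assert len({p.ma_id for p in result.matched}) == len(result.matched)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_cells(_regions(np.zeros((8, 8))), _regions(np.zeros((4, 4))))


class TestCompareSample:
    def test_delta_arithmetic(self):
        mask = np.zeros((16, 16), dtype=int)
        mask[0:10, 0:10] = 1
        pairing = match_cells(_regions(mask), _regions(mask))
        au = [_cell(1, 0.30, 100)]
        ma = [_cell(1, 0.30, 200)]
        result = compare_sample(au, ma, pairing)
        assert result.matched[0].delta_fpol_pct == pytest.approx(0.0)
        assert result.matched[0].delta_area_pct == pytest.approx(-66.7, abs=0.05)

    def test_no_matches_still_summarized(self):
        empty = _regions(np.zeros((8, 8)))
        result = compare_sample([_cell(1, 0.2, 10)], [], match_cells(empty, empty))
        assert result.matched == ()
        assert result.summary["au_mean_fpol"] == pytest.approx(0.2)
        assert math.isnan(result.summary["ma_mean_fpol"])

    def test_uniform_area_shrinkage_reported(self):
        """AU areas uniformly 6% smaller than MA give a mean area difference
        near -6% (symmetric percent difference of 0.94 vs 1 is -6.2%)."""
        mask = np.zeros((40, 40), dtype=int)
        for k in range(3):
            mask[k * 12 : k * 12 + 8, 0:8] = 1
        pairing = match_cells(_regions(mask), _regions(mask))
        au = [_cell(i, 0.25, round(0.94 * 1000)) for i in (1, 2, 3)]
        ma = [_cell(i, 0.25, 1000) for i in (1, 2, 3)]
        result = compare_sample(au, ma, pairing)
        deltas = [p.delta_area_pct for p in result.matched]
        assert np.mean(deltas) == pytest.approx(-6.0, abs=0.5)

    def test_missing_cell_id_rejected(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[2:6, 2:6] = 1
        pairing = match_cells(_regions(mask), _regions(mask))
        with pytest.raises(KeyError):
            compare_sample([], [_cell(1, 0.2, 16)], pairing)
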