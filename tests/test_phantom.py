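import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpolcyto import fpol_to_cross_intensity, generate_sample, quantify_sample, write_fixture_set
from fpolcyto.phantom import PhantomSpec, PlacementError, sample_fpol_targets
from fpolcyto.postproc import label_components

from .conftest import desk_phantom_spec


class TestCrossIntensityInversion:
    @pytest.mark.parametrize(
        "i_co,fpol,g,expected",
        [
            (200.0, 0.30, 0.75, 200 * 0.7 / (0.75 * 1.3)),  # 143.59 counts
            (150.0, 0.0, 1.0, 150.0),
            (100.0, 1.0, 0.75, 0.0),
        ],
    )
    def test_examples(self, i_co, fpol, g, expected):
        assert fpol_to_cross_intensity(i_co, fpol, g) == pytest.approx(expected, abs=1e-9)

    def test_full_depolarization_rejected(self):
        with pytest.raises(ValueError):
            fpol_to_cross_intensity(100.0, -1.0, 0.75)

    @given(
        i_co=st.floats(1.0, 250.0),
        fpol=st.floats(-0.9, 0.99),
        g=st.floats(0.1, 2.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_substitution_recovers_fpol(self, i_co, fpol, g):
        """Plugging the generated cross intensity back into the polarization
        relation recovers the target exactly (before any quantization)."""
        i_cross = fpol_to_cross_intensity(i_co, fpol, g)
        recovered = (i_co - g * i_cross) / (i_co + g * i_cross)
        assert recovered == pytest.approx(fpol, abs=1e-9)

    def test_monotone_decreasing_in_fpol(self):
        targets = np.linspace(-0.5, 0.9, 20)
        cross = [fpol_to_cross_intensity(200.0, f, 0.75) for f in targets]
        assert all(a > b for a, b in zip(cross, cross[1:]))


class TestGenerateSample:
    def test_no_cells_gives_empty_truth(self):
        sample = generate_sample(desk_phantom_spec(1, n_cells=0, ambiguous_fraction=0.0))
        assert sample.truth == ()
        assert not sample.masks.high_quality.any()

    def test_disjoint_placement_component_count(self):
        spec = desk_phantom_spec(
            2, image_size=256, n_cells=12, cluster_fraction=0.0, noise_sd=0.0
        )
        sample = generate_sample(spec)
        regions = label_components(sample.masks.high_quality)
        assert regions.n_regions == 12

    def test_masks_partition(self):
        sample = generate_sample(desk_phantom_spec(3))
        m = sample.masks
        total = (
            m.background.astype(int) + m.ambiguous.astype(int) + m.high_quality.astype(int)
        )
        assert np.all(total == 1)

    def test_truth_pixels_inside_high_quality_mask(self):
        sample = generate_sample(desk_phantom_spec(4))
        for cell in sample.truth:
            for r, c in cell.pixels:
                assert sample.masks.high_quality[r, c]

    def test_determinism(self):
        spec = desk_phantom_spec(5)
        a, b = generate_sample(spec), generate_sample(spec)
        np.testing.assert_array_equal(a.pair.co, b.pair.co)
        np.testing.assert_array_equal(a.pair.cross, b.pair.cross)
        np.testing.assert_array_equal(a.masks.high_quality, b.masks.high_quality)
        assert a.truth == b.truth

    def test_quantized_round_trip_within_bound(self):
        """Ground-truth-mask quantification recovers the specified Fpol to
        within the 8-bit quantization bound of 0.01."""
        spec = desk_phantom_spec(
            6,
            image_size=256,
            n_cells=3,
            fpol_targets=(0.30, 0.15, 0.25),
            cluster_fraction=0.0,
            ambiguous_fraction=0.0,
            noise_sd=0.0,
        )
        sample = generate_sample(spec)
        cells = quantify_sample(sample.pair, sample.truth_label_mask())
        assert len(cells) == 3
        for cell, truth in zip(cells, sample.truth):
            assert cell.fpol == pytest.approx(truth.fpol, abs=0.01)

    def test_unquantized_round_trip_exact(self):
        spec = desk_phantom_spec(
            7,
            image_size=256,
            n_cells=3,
            fpol_targets=(0.10, 0.22, 0.33),
            cluster_fraction=0.0,
            ambiguous_fraction=0.0,
            noise_sd=0.0,
            quantize=False,
        )
        sample = generate_sample(spec)
        cells = quantify_sample(sample.pair, sample.truth_label_mask())
        for cell, truth in zip(cells, sample.truth):
            assert cell.fpol == pytest.approx(truth.fpol, abs=1e-12)

    def test_impossible_placement_reported(self):
        with pytest.raises((PlacementError, ValueError)):
            generate_sample(
                PhantomSpec(image_size=64, n_cells=200, cell_radius_range=(8, 12),
                            cluster_fraction=0.0)
            )

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(n_cells=2, fpol_targets=(0.5, 1.5))

    def test_class_targets_in_range(self, rng):
        t = sample_fpol_targets("malignant", 200, rng)
        assert 0.2 < np.mean(t) < 0.36
        assert all(-1 <= x <= 1 for x in t)


class TestFixtureSet:
    def test_written_layout(self, tmp_path):
        specs = [desk_phantom_spec(10), desk_phantom_spec(11, diagnosis="malignant")]
        manifest = write_fixture_set(specs, tmp_path)
        assert len(manifest) == 2
        assert sorted(manifest["class"]) == ["benign", "malignant"]
        for _, row in manifest.iterrows():
            for col in ("co_path", "cross_path", "mask_path"):
                assert (tmp_path / row[col]).exists()
        assert (tmp_path / "manifest.csv").exists()

    def test_empty_spec_list(self, tmp_path):
        manifest = write_fixture_set([], tmp_path)
        assert manifest.empty
        assert not list(tmp_path.glob("*.png"))

    def test_byte_identical_rewrite(self, tmp_path):
        spec = desk_phantom_spec(12)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture_set([spec], d1)
        write_fixture_set([spec], d2)
        for name in ("s000_co.png", "s000_cross.png", "s000_labels.tif"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
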