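import math

import numpy as np
import pytest

from reslice3d2d import (
    PROFILE_NAMES,
    VolumeGrid,
    build_parallel_stack,
    plane_from_header,
    profile_weights,
    reslice,
    sample_stack,
    totalize,
)
from reslice3d2d.reslice_core import SampledStack

from oracles import brute_force_reslice, random_volume_and_header


class TestProfileWeights:
    @pytest.mark.parametrize(
        "profile,num,expected",
        [
            ("rectangular", 2, [1, 1, 1, 1, 1]),
            ("triangular", 2, [0, 0.5, 1, 0.5, 0]),
            ("rectangular", 0, [1]),
            ("std_normal_5", 0, [1]),
        ],
    )
    def test_hand_evaluated_weights(self, profile, num, expected):
        np.testing.assert_allclose(profile_weights(profile, num), expected, atol=1e-12)

    def test_std_normal_5_border_decays_rapidly(self):
        w = profile_weights("std_normal_5", 1)
        assert w[0] / w[1] == pytest.approx(math.exp(-12.5), rel=1e-12)

    def test_unknown_profile_lists_valid_names(self):
        with pytest.raises(ValueError, match="rectangular"):
            profile_weights("boxcar", 2)

    @pytest.mark.parametrize("name", PROFILE_NAMES)
    def test_profiles_symmetric_nonnegative_with_positive_center(self, name):
        w = profile_weights(name, 6)
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)
        assert np.all(w >= 0)
        assert w[6] > 0


class TestSampleStack:
    def test_plane_on_grid_slice_samples_exactly(self, validation_ds):
        plane = plane_from_header(validation_ds.parplane)
        stack = build_parallel_stack(0.0, 1.0)
        samples = sample_stack(validation_ds.volume, plane, stack)
        assert samples.values.shape == (11, 11, 1)
        assert samples.valid_mask.all()
        np.testing.assert_array_equal(samples.values[:, :, 0], 100.0)

    def test_two_mm_offsets_land_on_adjacent_grid_slices(self, validation_ds):
        plane = plane_from_header(validation_ds.parplane)
        stack = build_parallel_stack(2.0, 1.0)
        samples = sample_stack(validation_ds.volume, plane, stack)
        # z = -1 and z = +1 grid slices both hold the value 80
        np.testing.assert_allclose(samples.values[:, :, 0], 80.0, atol=1e-12)
        np.testing.assert_allclose(samples.values[:, :, 2], 80.0, atol=1e-12)

    def test_diagonal_offsets_interpolate_between_slices(self, validation_ds):
        plane = plane_from_header(validation_ds.diagplane)
        stack = build_parallel_stack(2.0, 1.0)
        samples = sample_stack(validation_ds.volume, plane, stack)
        expected = 100.0 - 20.0 / math.sqrt(2.0)
        assert samples.values[5, 5, 0] == pytest.approx(expected, abs=1e-9)
        assert samples.values[5, 5, 2] == pytest.approx(expected, abs=1e-9)

    def test_disjoint_plane_raises_no_overlap(self, validation_ds):
        header = validation_ds.parplane
        far = type(header)(
            position=header.position + np.array([0.0, 0.0, 1000.0]),
            row_cosine=header.row_cosine,
            col_cosine=header.col_cosine,
            pixel_spacing_row=header.pixel_spacing_row,
            pixel_spacing_col=header.pixel_spacing_col,
            rows=header.rows,
            cols=header.cols,
            slice_thickness=None,
            series_uid=header.series_uid,
            sop_uid=header.sop_uid,
            study_uid=header.study_uid,
        )
        with pytest.raises(ValueError, match="no overlap"):
            sample_stack(validation_ds.volume, plane_from_header(far), build_parallel_stack(0.0, 1.0))


class TestTotalize:
    def _stack(self, values, valid=None):
        values = np.asarray(values, float)[None, None, :]
        valid = (
            np.ones_like(values, bool)
            if valid is None
            else np.asarray(valid, bool)[None, None, :]
        )
        return SampledStack(values=values, valid_mask=valid)

    def test_rectangular_mean_matches_hand_calculation(self):
        result = totalize(self._stack([80.0, 100.0, 80.0]), np.ones(3))
        assert result.values[0, 0] == 87  # round(260/3)

    def test_constant_samples_give_rounded_constant(self):
        for profile in PROFILE_NAMES:
            w = profile_weights(profile, 1)
            result = totalize(self._stack([42.4, 42.4, 42.4]), w)
            assert result.values[0, 0] == 42

    def test_invalid_samples_excluded_with_renormalization(self):
        result = totalize(
            self._stack([0.0, 10.0, 20.0], valid=[False, True, True]), np.ones(3)
        )
        assert result.float_values[0, 0] == pytest.approx(15.0)

    def test_all_invalid_pixel_zeroed_and_tallied(self):
        result = totalize(
            self._stack([1.0, 2.0, 3.0], valid=[False, False, False]), np.ones(3)
        )
        assert result.values[0, 0] == 0
        assert result.n_outside == 1

    def test_weight_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="stack depth"):
            totalize(self._stack([1.0, 2.0, 3.0]), np.ones(2))


class TestReslice:
    def test_parplane_zero_thickness_is_uniform_100(self, validation_ds):
        result = reslice(validation_ds.volume, validation_ds.parplane, 0.0)
        assert result.values.shape == (11, 11)
        np.testing.assert_array_equal(result.values, 100)

    def test_perplane_zero_thickness_reads_value_law(self, validation_ds):
        result = reslice(validation_ds.volume, validation_ds.perplane, 0.0)
        law = [0, 20, 40, 60, 80, 100, 80, 60, 40, 20, 0]
        for i in range(11):
            np.testing.assert_array_equal(result.values[i], law)

    def test_diagplane_thick_rectangular_center_pixel(self, validation_ds):
        result = reslice(validation_ds.volume, validation_ds.diagplane, 4.23)
        assert result.values[5, 5] == 82

    def test_zero_thickness_output_identical_for_all_profiles(self, validation_ds):
        images = [
            reslice(validation_ds.volume, validation_ds.diagplane, 0.0, p).values
            for p in PROFILE_NAMES
        ]
        for img in images[1:]:
            np.testing.assert_array_equal(img, images[0])

    def test_constant_volume_stays_constant(self, validation_ds):
        volume = VolumeGrid(
            values=np.full((11, 11, 11), 57.0),
            origin=np.array([-5.0, -5.0, -5.0]),
            row_cosine=np.array([1.0, 0, 0]),
            col_cosine=np.array([0, 1.0, 0]),
            normal_cosine=np.array([0, 0, 1.0]),
            spacing=(1.0, 1.0, 1.0),
        )
        header = validation_ds.parplane
        for thickness in (0.0, 2.0, 5.0):
            for profile in PROFILE_NAMES:
                result = reslice(volume, header, thickness, profile)
                np.testing.assert_array_equal(result.values, 57)

    def test_thickness_presets_resolve_against_tags(self, validation_ds):
        by_tag = reslice(validation_ds.volume, validation_ds.parplane, "reference_2d")
        assert by_tag.thickness_used == 2.0
        by_vol = reslice(validation_ds.volume, validation_ds.parplane, "volume_z")
        assert by_vol.thickness_used == 1.0

    def test_reference_preset_requires_thickness_tag(self, validation_ds):
        header = validation_ds.parplane
        stripped = type(header)(
            position=header.position,
            row_cosine=header.row_cosine,
            col_cosine=header.col_cosine,
            pixel_spacing_row=header.pixel_spacing_row,
            pixel_spacing_col=header.pixel_spacing_col,
            rows=header.rows,
            cols=header.cols,
            slice_thickness=None,
            series_uid=header.series_uid,
            sop_uid=header.sop_uid,
            study_uid=header.study_uid,
        )
        with pytest.raises(ValueError, match="SliceThickness"):
            reslice(validation_ds.volume, stripped, "reference_2d")


class TestOracleEquivalence:
    @pytest.mark.filterwarnings("ignore:slice thickness")
    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    @pytest.mark.parametrize("profile", ["rectangular", "std_normal_2"])
    def test_matches_brute_force_on_random_oblique_configs(self, seed, profile):
        rng = np.random.default_rng(seed)
        volume, header = random_volume_and_header(rng)
        thickness = float(rng.uniform(0, 6))
        result = reslice(volume, header, thickness, profile)
        expected, n_outside = brute_force_reslice(volume, header, thickness, profile)
        assert result.n_outside == n_outside
        mask = ~np.isnan(expected)
        np.testing.assert_allclose(
            result.float_values[mask], expected[mask], atol=1e-9
        )
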