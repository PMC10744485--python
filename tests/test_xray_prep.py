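import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vert2ct.types import PairedSample
from vert2ct.xray_prep import (
    AUGMENT_RESIZE,
    EmptyXRayError,
    augment,
    norm_stats,
    package_case,
    preprocess_xray,
    read_case,
    resize_for_augment,
    split_cases,
)


class TestPreprocess:
    def test_uniform_bright_image_gives_zero_frame(self):
        out = preprocess_xray(np.full((50, 60), 0.9))
        assert out.shape == (128, 128)
        assert np.all(out.pixels == 0)

    def test_bright_rectangle_is_cropped_padded_and_resized(self):
        """A tall 40x20 gradient rectangle: crop to its box, pad the narrow
        dimension to square, resize; the lit area spans the central half of
        the columns and the full rows."""
        img = np.zeros((100, 100))
        rows = np.linspace(0.5, 1.0, 40)
        img[30:70, 40:60] = rows[:, None]
        out = preprocess_xray(img).pixels
        cols_lit = np.where(out.max(axis=0) > 0.05)[0]
        # 20 of 40 columns -> central half: [32, 96) up to interpolation
        assert 28 <= cols_lit.min() <= 34
        assert 93 <= cols_lit.max() <= 99
        assert out.max(axis=1).min() > 0.0  # every row intersects the crop
        # gradient orientation preserved: top dimmer than bottom
        assert out[10, 64] < out[117, 64]

    @pytest.mark.parametrize("out_size", [64, 128])
    def test_output_contract(self, rng, out_size):
        img = rng.random((73, 41))
        out = preprocess_xray(img, out_size=out_size)
        assert out.shape == (out_size, out_size)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_multichannel_input_uses_luminance_average(self, rng):
        gray = rng.random((64, 64))
        rgb = np.stack([gray, gray, gray], axis=-1)
        np.testing.assert_allclose(
            preprocess_xray(rgb).pixels, preprocess_xray(gray).pixels
        )

    def test_single_speck_is_removed_and_raises(self):
        img = np.zeros((64, 64))
        img[30, 30] = 1.0  # a lone pixel cannot survive 3x3 opening
        with pytest.raises(EmptyXRayError):
            preprocess_xray(img)

    def test_idempotent_up_to_resampling(self, phantom_pair):
        from vert2ct.drr import ProjectionGeometry, project

        vol, _ = phantom_pair
        raw = project(vol, None, ProjectionGeometry(0.0, (128, 128))).pixels
        once = preprocess_xray(raw).pixels
        twice = preprocess_xray(once).pixels
        assert np.abs(once - twice).max() < 1e-2

    def test_largest_component_wins(self):
        img = np.zeros((100, 100))
        img[10:40, 10:40] = np.linspace(0.6, 1.0, 30)[:, None]  # 900 px
        img[70:80, 70:80] = 0.9  # 100 px
        out = preprocess_xray(img).pixels
        # output is the big component's gradient, not the constant blob
        assert out.std() > 0.1


class TestPackage:
    def test_round_trip_exact(self, tmp_path, rng):
        ct = rng.random((16, 16, 16))
        x1, x2 = rng.random((16, 16)), rng.random((16, 16))
        path = tmp_path / "case.h5"
        package_case(ct, x1, x2, path)
        back = read_case(path)
        np.testing.assert_array_equal(back.ct, ct)
        np.testing.assert_array_equal(back.xray1, x1)
        np.testing.assert_array_equal(back.xray2, x2)

    def test_dataset_names(self, tmp_path, rng):
        import h5py

        path = tmp_path / "case.h5"
        package_case(rng.random((8, 8, 8)), rng.random((8, 8)), rng.random((8, 8)), path)
        with h5py.File(path) as f:
            assert set(f.keys()) == {"ct", "xray1", "xray2"}

    def test_ct_volume_is_normalized_by_scale(self, tmp_path, phantom_pair):
        vol, _ = phantom_pair
        path = tmp_path / "case.h5"
        package_case(vol, np.zeros((8, 8)), np.zeros((8, 8)), path, intensity_scale=2500.0)
        back = read_case(path)
        np.testing.assert_allclose(back.ct, vol.data / 2500.0)

    def test_missing_view_errors_before_file_creation(self, tmp_path, rng):
        path = tmp_path / "case.h5"
        with pytest.raises(ValueError):
            package_case(rng.random((8, 8, 8)), rng.random((8, 8)), None, path)
        assert not path.exists()


class TestSplit:
    def test_cohort_of_440_splits_352_88(self):
        split = split_cases([f"c{i}" for i in range(440)], seed=0)
        assert len(split.train_ids) == 352
        assert len(split.test_ids) == 88

    def test_ten_cases_split_eight_two(self):
        split = split_cases(list(range(10)), seed=1)
        assert (len(split.train_ids), len(split.test_ids)) == (8, 2)

    def test_deterministic_under_seed(self):
        ids = [f"c{i}" for i in range(50)]
        assert split_cases(ids, seed=3) == split_cases(ids, seed=3)
        assert split_cases(ids, seed=3) != split_cases(ids, seed=4)

    @given(n=st.integers(2, 60), seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_partition_conserves_and_disjoint(self, n, seed):
        ids = [f"c{i}" for i in range(n)]
        split = split_cases(ids, seed=seed)
        assert len(split.train_ids) + len(split.test_ids) == n
        assert set(split.train_ids) | set(split.test_ids) == set(ids)
        assert not set(split.train_ids) & set(split.test_ids)
        assert len(split.train_ids) == int(np.floor(0.8 * n + 0.5))

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1])
    def test_invalid_fraction(self, frac):
        with pytest.raises(ValueError):
            split_cases(list(range(10)), train_frac=frac)

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            split_cases(["only"])


class TestAugment:
    @pytest.fixture()
    def sample(self, rng):
        return PairedSample(
            ct=rng.random((16, 16, 16)),
            xray1=rng.random((128, 128)),
            xray2=rng.random((128, 128)),
            case_id="c0",
        )

    def test_intermediate_resize_is_150(self, sample):
        assert resize_for_augment(sample.xray1).shape == (AUGMENT_RESIZE, AUGMENT_RESIZE)

    def test_forced_zero_offset_is_top_left_crop(self, sample):
        out = augment(sample, crop_offset=(0, 0))
        np.testing.assert_array_equal(
            out.xray1, resize_for_augment(sample.xray1)[:128, :128]
        )

    def test_deterministic_under_seed(self, sample):
        a = augment(sample, seed=5)
        b = augment(sample, seed=5)
        np.testing.assert_array_equal(a.xray1, b.xray1)
        np.testing.assert_array_equal(a.xray2, b.xray2)

    def test_standardization_uses_training_stats(self, sample):
        mean, sd = norm_stats([sample])
        out = augment(sample, crop_offset=(0, 0), mean=mean, sd=sd)
        raw = augment(sample, crop_offset=(0, 0))
        np.testing.assert_allclose(out.xray1, (raw.xray1 - mean) / sd)

    def test_ct_passes_through(self, sample):
        out = augment(sample, seed=2)
        np.testing.assert_array_equal(out.ct, sample.ct)

    def test_shape_precondition(self, rng):
        bad = PairedSample(
            ct=rng.random((8, 8, 8)),
            xray1=rng.random((64, 64)),
            xray2=rng.random((64, 64)),
        )
        with pytest.raises(ValueError):
            augment(bad)
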