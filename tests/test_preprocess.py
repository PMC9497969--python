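"""Frame standardization: sizing, bit-depth scaling, channel handling."""

import imageio.v3 as iio
import numpy as np
import pytest

from fluorocad.preprocess import (Frame, LayoutError, extract_fluorescence_gray,
                                  load_and_standardize, split_multiplex_channels,
                                  standardize_array)
from fluorocad.simulate import ChannelLayout, SimConfig, generate_frame


class TestStandardize:
    def test_720_to_480_resize(self, tmp_path):
        img = (np.random.default_rng(0).uniform(0, 255, (720, 720, 3))
               .astype(np.uint8))
        path = tmp_path / "f.png"
        iio.imwrite(path, img)
        frame = load_and_standardize(path, target_size=480)
        assert frame.image.shape == (480, 480, 3)
        assert frame.image.max() <= 1.0

    def test_uniform_255_maps_to_exactly_one(self, tmp_path):
        path = tmp_path / "u.png"
        iio.imwrite(path, np.full((64, 64), 255, np.uint8))
        frame = load_and_standardize(path, target_size=64)
        assert (frame.image == 1.0).all()

    def test_small_speed_variant_target(self, tmp_path):
        img = (np.random.default_rng(1).uniform(0, 255, (720, 720))
               .astype(np.uint8))
        path = tmp_path / "f.png"
        iio.imwrite(path, img)
        frame = load_and_standardize(path, target_size=224)
        assert frame.image.shape == (224, 224, 1)

    def test_16bit_tiff_scaled_by_65535(self, tmp_path):
        import tifffile
        arr = np.full((64, 64), 65535, np.uint16)
        arr[0, 0] = 0
        path = tmp_path / "f.tif"
        tifffile.imwrite(path, arr)
        frame = load_and_standardize(path, target_size=64)
        assert frame.image.max() == pytest.approx(1.0)
        assert frame.image.min() == pytest.approx(0.0)

    def test_idempotent_on_standardized_input(self):
        ph = generate_frame(SimConfig(size=96, seed=2), "suspicious")
        f1 = standardize_array(ph.image, target_size=96, fov_mask=ph.fov_mask)
        f2 = standardize_array(f1.image, target_size=96, fov_mask=f1.fov_mask)
        assert np.array_equal(f1.image, f2.image)
        assert np.array_equal(f1.fov_mask, f2.fov_mask)

    @pytest.mark.parametrize("dtype,maxval", [(np.uint8, 255), (np.uint16, 65535)])
    def test_range_preserved_for_any_depth(self, dtype, maxval):
        rng = np.random.default_rng(3)
        arr = rng.integers(0, maxval + 1, (100, 100), dtype=dtype)
        frame = standardize_array(arr, target_size=64)
        assert 0.0 <= frame.image.min() and frame.image.max() <= 1.0

    def test_unreadable_file_raises_io_error(self, tmp_path):
        bad = tmp_path / "garbage.png"
        bad.write_bytes(b"not an image at all")
        with pytest.raises(IOError):
            load_and_standardize(bad)

    def test_zero_size_image_rejected(self):
        with pytest.raises(ValueError):
            standardize_array(np.empty((0, 0)))

    def test_fov_mask_derived_from_black_border(self):
        ph = generate_frame(SimConfig(size=96, seed=4), "suspicious")
        frame = standardize_array(ph.image, target_size=96)  # no mask given
        # derived FOV should agree with the simulator's circle almost exactly
        agree = (frame.fov_mask == ph.fov_mask).mean()
        assert agree > 0.98


class TestChannels:
    def _dual_probe_frame(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 1, (64, 64, 3))
        return Frame(image=img, fov_mask=np.ones((64, 64), bool),
                     source_id="dual",
                     channel_layout=ChannelLayout.FLUOR_GREEN_REFL_BLUE)

    def test_split_routes_each_probe_to_green(self):
        frame = self._dual_probe_frame()
        f1, f2 = split_multiplex_channels(frame)
        assert np.array_equal(f1.image[:, :, 1], frame.image[:, :, 0])
        assert np.array_equal(f2.image[:, :, 1], frame.image[:, :, 1])
        for f in (f1, f2):
            assert np.array_equal(f.image[:, :, 2], frame.image[:, :, 2])
            assert (f.image[:, :, 0] == 0).all()

    def test_split_roundtrip_recovers_original(self):
        frame = self._dual_probe_frame()
        f1, f2 = split_multiplex_channels(frame)
        rebuilt = np.stack([f1.image[:, :, 1], f2.image[:, :, 1],
                            f1.image[:, :, 2]], axis=-1)
        assert np.array_equal(rebuilt, frame.image)

    def test_split_of_zero_frame_gives_zero_frames(self):
        frame = Frame(image=np.zeros((32, 32, 3)),
                      fov_mask=np.ones((32, 32), bool))
        f1, f2 = split_multiplex_channels(frame)
        assert not f1.image.any() and not f2.image.any()

    def test_split_rejects_single_channel(self):
        frame = Frame(image=np.zeros((32, 32, 1)),
                      fov_mask=np.ones((32, 32), bool))
        with pytest.raises(LayoutError):
            split_multiplex_channels(frame)

    def test_gray_extraction_identity_and_green(self):
        g = np.full((32, 32), 0.7)
        gray_frame = Frame(image=g[:, :, None], fov_mask=np.ones((32, 32), bool))
        assert np.array_equal(extract_fluorescence_gray(gray_frame), g)
        rgb = np.stack([np.zeros_like(g), g, np.ones_like(g) * 0.2], axis=-1)
        frame = Frame(image=rgb, fov_mask=np.ones((32, 32), bool),
                      channel_layout=ChannelLayout.FLUOR_GREEN_REFL_BLUE)
        assert np.array_equal(extract_fluorescence_gray(frame), g)

    def test_brightest_pixel_of_phantom_lies_in_lesion(self):
        cfg = SimConfig(size=96, seed=6, noise_sigma=0.0,
                        channel_layout=ChannelLayout.FLUOR_GREEN_REFL_BLUE)
        ph = generate_frame(cfg, "suspicious")
        frame = standardize_array(ph.image, target_size=96, fov_mask=ph.fov_mask,
                                  channel_layout=ph.image.shape[2] == 3 and
                                  ChannelLayout.FLUOR_GREEN_REFL_BLUE or None)
        gray = extract_fluorescence_gray(frame)
        idx = np.unravel_index(np.argmax(gray), gray.shape)
        assert ph.lesion_mask[idx]
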