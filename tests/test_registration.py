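"""Translation estimation against planted ground truth."""

import numpy as np
import pytest

from mifpipe.dataset import ChannelImage
from mifpipe.preprocess import preprocess_dataset
from mifpipe.registration import (RegistrationConfig, RegistrationResult,
                                  align_cycle_set, apply_shift,
                                  estimate_shift, foreground_mask,
                                  max_project)
from mifpipe.synth import SyntheticConfig, generate_dataset


def _disk_image(shape, center, radius, level=1.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    img[np.hypot(rr - center[0], cc - center[1]) <= radius] = level
    return img


class TestMaxProject:
    def test_single_channel_identity(self, rng):
        x = rng.random((8, 8))
        out = max_project([ChannelImage(x, normalized=True)])
        assert np.array_equal(out.pixels, x)

    def test_two_channel_example(self):
        a = ChannelImage(np.array([[0.0, 5.0]]))
        b = ChannelImage(np.array([[3.0, 2.0]]))
        assert np.array_equal(max_project([a, b]).pixels,
                              np.array([[3.0, 5.0]]))

    def test_matches_per_pixel_loop(self, rng):
        imgs = [ChannelImage(rng.random((6, 7))) for _ in range(5)]
        out = max_project(imgs).pixels
        for r in range(6):
            for c in range(7):
                assert out[r, c] == max(im.pixels[r, c] for im in imgs)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            max_project([])


class TestForegroundMask:
    def test_blank_image_is_empty(self):
        mask, n = foreground_mask(ChannelImage(np.zeros((64, 64))), (50, 500))
        assert n == 0 and not mask.any()

    def test_planted_disk_within_size_band_is_kept(self):
        img = _disk_image((64, 64), (32, 32), 6)  # area ~113
        mask, n = foreground_mask(ChannelImage(img), (50, 500))
        assert n == 1
        rr, cc = np.mgrid[0:64, 0:64]
        inside = np.hypot(rr - 32, cc - 32) <= 4
        assert mask[inside].all()

    def test_small_object_excluded_by_size_filter(self):
        img = _disk_image((64, 64), (32, 32), 1.5)  # area ~10
        mask, n = foreground_mask(ChannelImage(img), (50, 500))
        assert n == 0 and not mask.any()


def _projection_and_mask(image, config):
    ci = ChannelImage(image, normalized=True)
    mask, _ = foreground_mask(ci, config.size_band)
    return ci, mask


class TestEstimateShift:
    def _scene(self, rng, shape=(128, 128), n=25):
        # varied per-cell brightness: constant-intensity disks make the
        # masked correlation degenerate (any disk overlays any other)
        img = np.zeros(shape)
        for _ in range(n):
            r, c = rng.uniform(15, shape[0] - 15, 2)
            img += _disk_image(shape, (r, c), rng.uniform(3, 5),
                               level=rng.uniform(0.3, 1.0))
        return np.clip(img, 0, 1)

    def test_identity_for_equal_images(self, rng):
        cfg = RegistrationConfig(seed=4)
        img = self._scene(rng)
        ci, mask = _projection_and_mask(img, cfg)
        entry = estimate_shift(ci, ci, mask, mask, cfg)
        assert not entry.failed
        assert entry.final_shift == (0.0, 0.0)

    def test_translation_equivariance(self, rng):
        # estimate_shift sees downsampled images; shifts scale back by 2
        cfg = RegistrationConfig(seed=4)
        img = self._scene(rng)
        moved = apply_shift(ChannelImage(img), (-3.0, 5.0)).pixels
        ci, mask = _projection_and_mask(img, cfg)
        cm, mmask = _projection_and_mask(moved, cfg)
        entry = estimate_shift(ci, cm, mask, mmask, cfg)
        assert entry.final_shift == (6.0, -10.0)

    def test_antisymmetry_of_direction(self, rng):
        cfg = RegistrationConfig(seed=4)
        img = self._scene(rng)
        moved = apply_shift(ChannelImage(img), (-4.0, 2.0)).pixels
        ci, mask = _projection_and_mask(img, cfg)
        cm, mmask = _projection_and_mask(moved, cfg)
        fwd = estimate_shift(ci, cm, mask, mmask, cfg).final_shift
        bwd = estimate_shift(cm, ci, mmask, mask, cfg).final_shift
        assert fwd == (-bwd[0], -bwd[1])

    def test_blank_moving_image_fails_low_cellularity(self, rng):
        cfg = RegistrationConfig(seed=4)
        img = self._scene(rng)
        ci, mask = _projection_and_mask(img, cfg)
        blank = ChannelImage(np.zeros_like(img), normalized=True)
        entry = estimate_shift(ci, blank, mask,
                               np.zeros_like(mask, dtype=bool), cfg)
        assert entry.failed and entry.reason == "low cellularity"

    def test_deterministic_under_fixed_seed(self, rng):
        cfg = RegistrationConfig(seed=11, n_trials=3)
        img = self._scene(rng)
        moved = apply_shift(ChannelImage(img), (-6.0, 4.0)).pixels
        ci, mask = _projection_and_mask(img, cfg)
        cm, mmask = _projection_and_mask(moved, cfg)
        e1 = estimate_shift(ci, cm, mask, mmask, cfg)
        e2 = estimate_shift(ci, cm, mask, mmask, cfg)
        assert e1.trial_shifts == e2.trial_shifts
        assert e1.final_shift == e2.final_shift


class TestAlignCycleSet:
    def test_planted_shifts_recovered_for_all_fovs(self, small_dataset,
                                                   small_preprocessed):
        _, gt = small_dataset
        result = align_cycle_set(small_preprocessed, 0,
                                 RegistrationConfig(seed=1))
        for j, (dy, dx) in enumerate(gt.shifts):
            got = result.shift(j)
            assert abs(got[0] - dy) <= 1 and abs(got[1] - dx) <= 1

    def test_single_cycle_dataset_trivially_aligned(self, small_preprocessed):
        from mifpipe.dataset import CyclicDataset
        src = small_preprocessed
        one = CyclicDataset(
            images={k: v for k, v in src.images.items() if k[1] == 0},
            manifest={k: v for k, v in src.manifest.items() if k[0] == 0},
            n_fovs=src.n_fovs, n_cycles=1, n_channels=src.n_channels)
        result = align_cycle_set(one, 0, RegistrationConfig(seed=1))
        assert result.shift(0) == (0.0, 0.0)
        assert list(result.cycles) == [0]

    def test_reference_cycle_convention(self, small_preprocessed):
        result = align_cycle_set(small_preprocessed, 0,
                                 RegistrationConfig(reference_cycle=2,
                                                    seed=1))
        assert result.shift(2) == (0.0, 0.0)
        assert result.reference_cycle == 2

    def test_json_round_trip(self, tmp_path, small_preprocessed):
        result = align_cycle_set(small_preprocessed, 0,
                                 RegistrationConfig(seed=1))
        result.to_json(tmp_path / "shifts.json")
        back = RegistrationResult.from_json(tmp_path / "shifts.json")
        assert back.reference_cycle == result.reference_cycle
        for j in result.cycles:
            assert back.cycles[j].final_shift == result.cycles[j].final_shift
            assert back.cycles[j].trial_shifts == result.cycles[j].trial_shifts


class TestApplyShift:
    def test_zero_shift_identity(self, rng):
        x = rng.random((10, 10))
        assert np.array_equal(apply_shift(ChannelImage(x), (0, 0)).pixels, x)

    def test_inverse_composition_on_interior(self, rng):
        x = rng.random((32, 32))
        fwd = apply_shift(ChannelImage(x), (5.0, -3.0))
        back = apply_shift(fwd, (-5.0, 3.0))
        assert np.array_equal(back.pixels[5:-5, 5:-5], x[5:-5, 5:-5])

    def test_aligned_cycle_matches_reference_on_overlap(self):
        # uniform marker map: every cycle images the same scene, so the
        # aligned noise-free cycle is pixel-identical on the overlap
        uniform = {m: (1000.0, 1000.0, 0.0)
                   for m in ["DAPI", "CD45", "CK56", "CD3", "CD4", "CD8"]}
        cfg = SyntheticConfig(n_cycles=2, n_fovs=1, image_shape=(128, 128),
                              n_cells=12, max_shift=6, noise_sd=0, seed=21,
                              marker_intensity_map=uniform)
        ds, gt = generate_dataset(cfg)
        dy, dx = gt.shifts[1]
        ref = ds.pair(0, 0, 1).stain.pixels
        mov = apply_shift(ChannelImage(ds.pair(0, 1, 1).stain.pixels),
                          (dy, dx)).pixels
        m = 8  # stay clear of the zero-filled border
        assert np.array_equal(mov[m:-m, m:-m], ref[m:-m, m:-m])


class TestShiftRecoveryProperty:
    def test_noise_free_recovery_is_exact_up_to_downsampling(self):
        cfg = SyntheticConfig(n_cycles=3, n_fovs=1, n_channels_per_cycle=2,
                              image_shape=(256, 256), n_cells=50,
                              max_shift=15, noise_sd=0, seed=31)
        ds, gt = generate_dataset(cfg)
        pre = preprocess_dataset(ds)
        result = align_cycle_set(pre, 0, RegistrationConfig(seed=1))
        for j, (dy, dx) in enumerate(gt.shifts):
            got = result.shift(j)
            assert abs(got[0] - dy) <= 1 and abs(got[1] - dx) <= 1
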