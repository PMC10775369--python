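"""Tiling arithmetic, label rasterization <-> instance extraction, and
tiled inference stitching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from mifpipe.network import ArchConfig, build_network
from mifpipe.segmentation import (TrainConfig, Tile, augment_sample,
                                  count_instances_in_tile, extract_instances,
                                  make_training_samples, predict_fov,
                                  rasterize_labels, tile_image, train)


def plant_disks(shape, centers_radii):
    inst = np.zeros(shape, dtype=np.int32)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for k, (r, c, rad) in enumerate(centers_radii, start=1):
        inst[np.hypot(rr - r, cc - c) <= rad] = k
    return inst


class TestTileImage:
    def test_exact_tile_sized_image_is_one_tile(self):
        tiles = tile_image(np.zeros((300, 300)), 300, 0.2)
        assert len(tiles) == 1
        assert (tiles[0].row, tiles[0].col) == (0, 0)

    def test_540_image_gives_stride_240_cover(self):
        tiles = tile_image(np.zeros((540, 540)), 300, 0.2)
        offsets = sorted({(t.row, t.col) for t in tiles})
        assert offsets == [(0, 0), (0, 240), (240, 0), (240, 240)]

    def test_last_tile_anchored_at_image_edge(self):
        tiles = tile_image(np.zeros((310, 300)), 300, 0.2)
        rows = sorted({t.row for t in tiles})
        assert rows == [0, 10]
        assert len(tiles) == 2

    def test_small_image_zero_padded_with_valid_extent(self):
        tiles = tile_image(np.ones((100, 120)), 300, 0.2)
        assert len(tiles) == 1
        assert tiles[0].pixels.shape == (300, 300)
        assert tiles[0].valid == (100, 120)
        assert tiles[0].pixels[:100, :120].all()
        assert not tiles[0].pixels[100:].any()

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(h=st.integers(20, 900), w=st.integers(20, 900),
           tile=st.sampled_from([64, 128, 300]),
           overlap=st.sampled_from([0.0, 0.2, 0.5]))
    def test_every_pixel_covered(self, h, w, tile, overlap):
        cover = np.zeros((h, w), dtype=int)
        for t in tile_image(np.zeros((h, w)), tile, overlap):
            vh, vw = t.valid
            cover[t.row:t.row + vh, t.col:t.col + vw] += 1
        assert (cover >= 1).all()


class TestRasterizeLabels:
    def test_empty_instance_map_is_all_background(self):
        out = rasterize_labels(np.zeros((32, 32), dtype=np.int32))
        assert (out == 0).all()

    def test_disk_boundary_ring_geometry(self):
        inst = plant_disks((64, 64), [(32, 32, 8)])
        out = rasterize_labels(inst, boundary_width=2)
        ring_area = (out == 2).sum()
        interior_area = (out == 1).sum()
        # ring area ~ perimeter x width = 2*pi*8*2 ~ 100 (Chebyshev
        # footprint makes it slightly thicker)
        assert 60 <= ring_area <= 180
        assert interior_area > 0
        # interior strictly inside the instance
        assert (inst[out == 1] > 0).all()
        assert (inst[out == 2] > 0).all()

    def test_touching_disks_separated_by_boundary_ridge(self):
        inst = plant_disks((64, 64), [(32, 24, 8), (32, 39, 8)])
        assert ndimage.label(inst > 0)[1] == 1  # they touch
        classes = rasterize_labels(inst, boundary_width=2)
        four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        n_interior = ndimage.label(classes == 1, structure=four)[1]
        assert n_interior == 2

    def test_labels_only_from_three_classes(self, rng):
        inst = plant_disks((64, 64), [(20, 20, 6), (44, 44, 7)])
        assert set(np.unique(rasterize_labels(inst))) <= {0, 1, 2}


class TestExtractInstances:
    def test_all_background_gives_empty_map(self):
        out = extract_instances(np.zeros((16, 16), dtype=np.uint8))
        assert out.max() == 0

    def test_two_blobs_with_ridge_stay_separate(self):
        inst = plant_disks((64, 64), [(32, 24, 8), (32, 39, 8)])
        out = extract_instances(rasterize_labels(inst))
        assert out.max() == 2

    def test_min_area_filter_removes_small_components(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[4:6, 4:6] = 1  # interior blob of area 4
        out = extract_instances(mask, min_area=20)
        assert out.max() == 0

    def test_round_trip_preserves_instance_count(self):
        """Instance count survives rasterize -> extract for random layouts
        of separated and touching (rims within 1 px) disks."""
        rng = np.random.default_rng(5)
        for trial in range(25):
            centers = []
            attempts = 0
            want = int(rng.integers(2, 9))
            while len(centers) < want and attempts < 500:
                attempts += 1
                r, c = rng.uniform(12, 52, 2)
                rad = rng.uniform(4, 8)
                # allow touching but never engulfing overlap
                if all(np.hypot(r - r0, c - c0) >= rad + rad0 - 1
                       for r0, c0, rad0 in centers):
                    centers.append((r, c, rad))
            inst = plant_disks((64, 64), centers)
            out = extract_instances(rasterize_labels(inst, 2))
            assert out.max() == len(centers)


class TestAugmentation:
    def test_geometric_ops_applied_identically_to_labels(self):
        rng = np.random.default_rng(3)
        y = np.arange(64, dtype=np.uint8).reshape(8, 8) % 3
        x = np.stack([y.astype(np.float32), y.astype(np.float32)])
        xa, ya = augment_sample(x, y, rng, noise_sd=0, mean_shift_sd=0)
        assert np.array_equal(xa[0].astype(np.uint8), ya)
        assert np.array_equal(xa[1].astype(np.uint8), ya)

    def test_intensity_ops_leave_labels_untouched(self):
        rng = np.random.default_rng(4)
        y = np.zeros((8, 8), dtype=np.uint8)
        x = np.zeros((2, 8, 8), dtype=np.float32)
        _, ya = augment_sample(x, y, rng, noise_sd=0.5, mean_shift_sd=0.5)
        assert np.array_equal(ya, y)


class TestTrainingPlumbing:
    def test_empty_tiles_are_excluded(self):
        img = np.zeros((128, 128), dtype=np.float32)
        inst = plant_disks((128, 128), [(20, 20, 6)])
        per_fov = make_training_samples([(img, img)], [inst],
                                        tile_size=64, overlap=0.0)
        assert len(per_fov[0]) == 1  # only the tile containing the cell
        assert per_fov[0][0].count == 1.0

    def test_training_on_no_tiles_raises(self):
        model = build_network(ArchConfig(in_channels=2, base_filters=4,
                                         depth=2, tile_size=16, seed=0))
        with pytest.raises(ValueError, match="no non-empty"):
            train(model, [], [], TrainConfig(tile_size=16, epochs=1))

    def test_count_target_counts_intersecting_instances(self):
        inst = plant_disks((64, 64), [(10, 10, 5), (40, 40, 5)])
        assert count_instances_in_tile(inst, 0, 0, 24) == 1
        assert count_instances_in_tile(inst, 0, 0, 64) == 2


class TestPredictFov:
    def test_single_tile_prediction_matches_stitching(self, rng):
        model = build_network(ArchConfig(in_channels=2, base_filters=4,
                                         depth=2, tile_size=32, seed=1))
        cd45 = rng.random((32, 32)).astype(np.float32)
        dapi = rng.random((32, 32)).astype(np.float32)
        stitched = predict_fov(model, cd45, dapi, tile_size=32, overlap=0.2)
        direct = model.predict_probs(
            np.stack([cd45, dapi])[None]).argmax(axis=1)[0]
        assert np.array_equal(stitched, direct)

    def test_output_shape_equals_input_shape(self, rng):
        model = build_network(ArchConfig(in_channels=2, base_filters=4,
                                         depth=2, tile_size=32, seed=1))
        cd45 = rng.random((75, 90)).astype(np.float32)
        dapi = rng.random((75, 90)).astype(np.float32)
        assert predict_fov(model, cd45, dapi, tile_size=32).shape == (75, 90)

    def test_channel_shape_mismatch_raises(self, rng):
        model = build_network(ArchConfig(in_channels=2, base_filters=4,
                                         depth=2, tile_size=32, seed=1))
        with pytest.raises(ValueError, match="mismatch"):
            predict_fov(model, np.zeros((32, 32)), np.zeros((32, 33)))
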