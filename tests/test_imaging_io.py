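"""Image round-trips, tile grids, binarization, and tile merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasepaint import imaging_io as io
from phasepaint.errors import ConfigurationError, DimensionError


class TestReadWrite:
    @pytest.mark.parametrize("suffix", [".png", ".tif"])
    def test_uint8_round_trip_is_exact(self, tmp_path, suffix):
        arr = np.random.default_rng(0).integers(0, 256, (32, 48), dtype=np.uint8)
        path = tmp_path / f"img{suffix}"
        io.write_image(path, io.RasterImage(arr, "phase"))
        back = io.read_image(path)
        assert back.bit_depth == 8
        np.testing.assert_array_equal(back.pixels, arr)

    def test_uint16_tiff_round_trip(self, tmp_path):
        arr = np.random.default_rng(1).integers(0, 65536, (16, 16), dtype=np.uint16)
        path = tmp_path / "img16.tif"
        io.write_image(path, io.RasterImage(arr, "nuclei", bit_depth=16))
        back = io.read_image(path, "nuclei")
        assert back.bit_depth == 16
        assert back.pixels.max() <= 65535
        np.testing.assert_array_equal(back.pixels, arr)

    def test_all_zero_png_reads_as_zeros(self, tmp_path):
        path = tmp_path / "zero.png"
        io.write_image(path, io.RasterImage(np.zeros((4, 4), np.uint8)))
        assert io.read_image(path).pixels.sum() == 0

    def test_missing_file_and_bad_format(self, tmp_path):
        with pytest.raises(IOError):
            io.read_image(tmp_path / "nope.png")
        with pytest.raises(Exception):
            io.write_image(tmp_path / "x.bmp", np.zeros((4, 4)))


class TestTileGrid:
    def test_full_frame_gives_77_tiles(self):
        grid = io.make_tile_grid(1024, 1536, 256, 0.5)
        rows = sorted({r for r, _ in grid.origins})
        cols = sorted({c for _, c in grid.origins})
        assert rows == list(range(0, 769, 128))
        assert cols == list(range(0, 1281, 128))
        assert len(grid) == 7 * 11 == 77

    def test_single_tile(self):
        grid = io.make_tile_grid(256, 256, 256, 0.5)
        assert grid.origins == [(0, 0)]

    def test_edge_flush_final_origin(self):
        grid = io.make_tile_grid(300, 300, 256, 0.5)
        assert sorted({r for r, _ in grid.origins}) == [0, 44]
        assert len(grid) == 4

    def test_origins_sorted_unique_and_in_bounds(self):
        grid = io.make_tile_grid(500, 700, 128, 0.25)
        assert len(set(grid.origins)) == len(grid.origins)
        assert grid.origins == sorted(grid.origins)
        for r, c in grid.origins:
            assert r + grid.tile_size <= 500
            assert c + grid.tile_size <= 700

    def test_coverage_and_overlap_counts(self):
        grid = io.make_tile_grid(512, 512, 256, 0.5)
        counts = np.zeros((512, 512), int)
        for r, c in grid.origins:
            counts[r : r + 256, c : c + 256] += 1
        assert counts.min() >= 1
        # interior pixels belong to exactly 4 tiles at 50% overlap
        assert (counts[256 - 64 : 256 + 64, 256 - 64 : 256 + 64] == 4).all()

    def test_tile_larger_than_image_raises(self):
        with pytest.raises(DimensionError):
            io.make_tile_grid(100, 100, 256, 0.5)

    def test_json_round_trip(self):
        grid = io.make_tile_grid(300, 300, 256, 0.5)
        assert io.TileGrid.from_json(grid.to_json()) == grid


class TestExtractMerge:
    def test_constant_image_gives_constant_tiles(self):
        grid = io.make_tile_grid(300, 300, 256, 0.5)
        tiles = io.extract_tiles(np.full((300, 300), 7.0), grid)
        assert len(tiles) == 4
        assert all((t == 7.0).all() and t.shape == (256, 256) for t in tiles)

    def test_ramp_tiles_equal_hand_slices(self):
        img = np.arange(300 * 300, dtype=float).reshape(300, 300)
        grid = io.make_tile_grid(300, 300, 256, 0.5)
        tiles = io.extract_tiles(img, grid)
        for (r, c), tile in zip(grid.origins, tiles):
            np.testing.assert_array_equal(tile, img[r : r + 256, c : c + 256])

    def test_merge_of_fully_overlapping_zero_and_one_tiles(self):
        grid = io.TileGrid(4, 4, 4, 4, origins=[(0, 0), (0, 0)])
        merged = io.merge_tiles([np.zeros((4, 4)), np.ones((4, 4))], grid)
        np.testing.assert_allclose(merged, 0.5)

    def test_max_aggregation(self):
        grid = io.TileGrid(4, 4, 4, 4, origins=[(0, 0), (0, 0)])
        merged = io.merge_tiles([np.zeros((4, 4)), np.ones((4, 4))], grid, "max")
        np.testing.assert_allclose(merged, 1.0)

    def test_mismatched_tile_count_raises(self):
        grid = io.make_tile_grid(300, 300, 256, 0.5)
        with pytest.raises(DimensionError):
            io.merge_tiles([np.zeros((256, 256))], grid)
        with pytest.raises(DimensionError):
            io.extract_tiles(np.zeros((100, 100)), grid)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        h=st.integers(64, 200),
        w=st.integers(64, 200),
        tile=st.sampled_from([32, 64]),
        overlap=st.sampled_from([0.0, 0.5, 0.75]),
        seed=st.integers(0, 10_000),
    )
    def test_merge_extract_identity(self, h, w, tile, overlap, seed):
        """merge(extract(img)) == img for arbitrary sizes including
        non-divisible ones handled by the edge-flush rule."""
        img = np.random.default_rng(seed).random((h, w))
        grid = io.make_tile_grid(h, w, tile, overlap)
        merged = io.merge_tiles(io.extract_tiles(img, grid), grid)
        np.testing.assert_allclose(merged, img, atol=1e-12)


class TestBinarize:
    def test_all_background_and_all_signal(self):
        spec = io.ChannelSpec("nuclei", background_threshold=10)
        lo = io.RasterImage(np.full((4, 4), 5, np.uint8), "nuclei")
        hi = io.RasterImage(np.full((4, 4), 200, np.uint8), "nuclei")
        assert io.binarize_target(lo, spec).pixels.sum() == 0
        assert io.binarize_target(hi, spec).pixels.sum() == 16

    def test_ramp_counts_strictly_above_threshold(self):
        img = io.RasterImage(np.arange(9, dtype=np.uint8).reshape(3, 3), "nuclei")
        spec = io.ChannelSpec("nuclei", background_threshold=4)
        assert io.binarize_target(img, spec).pixels.sum() == 4

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(3)
        img = io.RasterImage(rng.integers(0, 256, (8, 8), np.uint8), "nuclei")
        spec = io.ChannelSpec("nuclei", background_threshold=127)
        m1 = io.binarize_target(img, spec)
        spec01 = io.ChannelSpec("nuclei", background_threshold=0)
        m2 = io.binarize_target(
            io.RasterImage(m1.pixels.astype(np.uint8), "nuclei"), spec01
        )
        np.testing.assert_array_equal(m1.pixels, m2.pixels)

    def test_threshold_out_of_range_and_wrong_channel(self):
        img = io.RasterImage(np.zeros((4, 4), np.uint8), "nuclei")
        with pytest.raises(ConfigurationError):
            io.binarize_target(img, io.ChannelSpec("nuclei", background_threshold=300))
        with pytest.raises(ConfigurationError):
            io.binarize_target(img, io.ChannelSpec("lgr5", background_threshold=10))

    def test_otsu_default_separates_bimodal_image(self):
        rng = np.random.default_rng(4)
        arr = np.full((20, 20), 20, np.uint8)
        arr[5:10, 5:10] = 220
        mask = io.binarize_target(io.RasterImage(arr, "lgr5"), io.ChannelSpec("lgr5"))
        assert mask.pixels.sum() == 25
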