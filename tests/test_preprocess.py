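"""Tiling, optical density and Macenko stain normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moma.preprocess import (InsufficientStainError, PreprocessConfig,
                             TilePatch, estimate_stain_profile, normalize_tile,
                             od_to_rgb, rgb_to_od, tile_slide)
from moma.synthesis import (DEFAULT_STAIN_MATRIX, concentrations_to_rgb,
                            make_stain_gradient_concentrations)


def _cosine_match(estimated: np.ndarray, planted: np.ndarray) -> float:
    """Best worst-column cosine over the two column orderings."""
    return max(min(abs(estimated[:, i] @ planted[:, p])
                   for i, p in enumerate(perm))
               for perm in ([0, 1], [1, 0]))


def _gradient_image(stain_matrix=DEFAULT_STAIN_MATRIX, noise_sd=0.0, seed=0):
    conc = make_stain_gradient_concentrations(64, 64)
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    return concentrations_to_rgb(conc, stain_matrix, noise_sd=noise_sd, rng=rng)


class TestTiling:
    def test_exact_grid_division(self):
        img = np.full((2000, 3000, 3), 128, dtype=np.uint8)
        tiles = tile_slide(img, PreprocessConfig(tile_size_px=1000))
        assert len(tiles) == 6
        assert {(t.grid_row, t.grid_col) for t in tiles} == {
            (r, c) for r in range(2) for c in range(3)}

    def test_edge_remainder_dropped(self):
        img = np.zeros((1999, 1000, 3), dtype=np.uint8)
        tiles = tile_slide(img, PreprocessConfig(tile_size_px=1000))
        assert len(tiles) == 1

    def test_image_smaller_than_tile_yields_empty_list(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        assert tile_slide(img, PreprocessConfig(tile_size_px=64)) == []

    def test_all_white_image_is_background(self):
        img = np.full((128, 128, 3), 255, dtype=np.uint8)
        tiles = tile_slide(img, PreprocessConfig(tile_size_px=64))
        assert tiles and all(not t.is_tissue for t in tiles)

    def test_stained_image_is_tissue(self):
        img = _gradient_image()
        tiles = tile_slide(img, PreprocessConfig(tile_size_px=32))
        assert all(t.is_tissue for t in tiles)

    def test_tiles_do_not_overlap(self):
        img = np.arange(64 * 64 * 3, dtype=np.uint8).reshape(64, 64, 3)
        tiles = tile_slide(img, PreprocessConfig(tile_size_px=32))
        coords = {(t.grid_row, t.grid_col) for t in tiles}
        assert len(coords) == len(tiles) == 4


class TestOpticalDensity:
    def test_illuminant_maps_to_zero(self):
        px = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert np.all(rgb_to_od(px) == 0.0)

    def test_log10_definition(self):
        # (v + 1) / (I0 + 1) = 0.1  ->  OD exactly 1
        v = 0.1 * 256.0 - 1.0
        od = rgb_to_od(np.full((1, 1, 3), v))
        assert np.allclose(od, 1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 255), min_size=3, max_size=3))
    def test_round_trip_within_one_level(self, values):
        px = np.array(values, dtype=np.uint8).reshape(1, 1, 3)
        back = od_to_rgb(rgb_to_od(px))
        assert np.all(np.abs(back.astype(int) - px.astype(int)) <= 1)

    def test_order_reversing(self):
        od = rgb_to_od(np.arange(256).reshape(-1, 1, 1).repeat(3, axis=-1))
        flat = od[:, 0, 0]
        assert np.all(np.diff(flat) < 0)


class TestStainEstimation:
    def test_recovers_planted_matrix_noiseless(self):
        prof = estimate_stain_profile(rgb_to_od(_gradient_image()))
        assert _cosine_match(prof.stain_vectors, DEFAULT_STAIN_MATRIX) >= 0.999

    def test_recovers_planted_matrix_under_noise(self):
        img = _gradient_image(noise_sd=0.02, seed=1)
        prof = estimate_stain_profile(rgb_to_od(img))
        assert _cosine_match(prof.stain_vectors, DEFAULT_STAIN_MATRIX) >= 0.99

    def test_hematoxylin_listed_first(self):
        prof = estimate_stain_profile(rgb_to_od(_gradient_image()))
        assert prof.stain_vectors[2, 0] >= prof.stain_vectors[2, 1]
        assert np.allclose(np.linalg.norm(prof.stain_vectors, axis=0), 1.0)
        assert np.all(prof.stain_vectors >= 0)

    def test_single_stain_is_rank_deficient(self):
        conc = np.zeros((2, 32, 32))
        conc[0] = np.linspace(0.5, 2.0, 32)[None, :]
        img = concentrations_to_rgb(conc, DEFAULT_STAIN_MATRIX)
        with pytest.raises(InsufficientStainError, match="rank deficient"):
            estimate_stain_profile(rgb_to_od(img))

    def test_too_few_pixels_rejected(self):
        with pytest.raises(InsufficientStainError, match="fewer than 2"):
            estimate_stain_profile(np.zeros((4, 3)))

    def test_percentile_insensitive_on_clean_mixture(self):
        od = rgb_to_od(_gradient_image())
        p1 = estimate_stain_profile(od, PreprocessConfig(alpha_percentile=1.0))
        p5 = estimate_stain_profile(od, PreprocessConfig(alpha_percentile=5.0))
        assert _cosine_match(p1.stain_vectors, p5.stain_vectors) >= 0.999

    def test_profile_json_roundtrip(self, tmp_path):
        from moma.preprocess import StainProfile
        prof = estimate_stain_profile(rgb_to_od(_gradient_image()))
        prof.save(tmp_path / "p.json")
        back = StainProfile.load(tmp_path / "p.json")
        assert np.allclose(back.stain_vectors, prof.stain_vectors)
        assert np.allclose(back.max_concentrations, prof.max_concentrations)


class TestNormalization:
    def test_identity_normalization(self):
        img = _gradient_image()
        prof = estimate_stain_profile(rgb_to_od(img))
        tile = TilePatch("s", 0, 0, img, True)
        out = normalize_tile(tile, prof, prof)
        assert np.abs(out.pixels.astype(float) - img.astype(float)).mean() <= 1.0

    def test_idempotent_within_two_levels(self):
        img = _gradient_image()
        src = estimate_stain_profile(rgb_to_od(img))
        M2 = np.array([[0.60, 0.25], [0.65, 0.95], [0.47, 0.15]])
        ref = estimate_stain_profile(
            rgb_to_od(concentrations_to_rgb(
                make_stain_gradient_concentrations(64, 64),
                M2 / np.linalg.norm(M2, axis=0))))
        once = normalize_tile(TilePatch("s", 0, 0, img, True), src, ref)
        prof_once = estimate_stain_profile(rgb_to_od(once.pixels))
        twice = normalize_tile(once, prof_once, prof_once)
        assert np.abs(twice.pixels.astype(float)
                      - once.pixels.astype(float)).mean() <= 2.0

    def test_normalization_collapses_stain_variation(self):
        """Two renderings of identical concentration maps under different
        stain matrices agree after normalizing both to one reference."""
        conc = make_stain_gradient_concentrations(64, 64)
        M2 = np.array([[0.60, 0.25], [0.65, 0.95], [0.47, 0.15]])
        M2 = M2 / np.linalg.norm(M2, axis=0)
        img_a = concentrations_to_rgb(conc, DEFAULT_STAIN_MATRIX)
        img_b = concentrations_to_rgb(conc, M2)
        prof_a = estimate_stain_profile(rgb_to_od(img_a))
        prof_b = estimate_stain_profile(rgb_to_od(img_b))
        out_a = normalize_tile(TilePatch("a", 0, 0, img_a, True), prof_a, prof_a)
        out_b = normalize_tile(TilePatch("b", 0, 0, img_b, True), prof_b, prof_a)
        diff = np.abs(out_a.pixels.astype(float) - out_b.pixels.astype(float))
        assert diff.mean() <= 2.0

    def test_background_tile_returned_with_warning_flag(self):
        img = _gradient_image()
        prof = estimate_stain_profile(rgb_to_od(img))
        white = TilePatch("s", 0, 0, np.full((8, 8, 3), 255, np.uint8), False)
        out = normalize_tile(white, prof, prof)
        assert out.warning is not None
        assert np.array_equal(out.pixels, white.pixels)
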