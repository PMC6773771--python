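"""Tiling geometry, test-time averaging, heat-map reconstruction oracle."""

import numpy as np
import pytest

from histopatch.augment import dihedral_apply, dihedral_inverse
from histopatch.infer import reconstruct_heatmap, tile_slide, tta_predict
from histopatch.slide_io import Slide


class TestTileSlide:
    def test_width_201_gives_three_columns(self):
        grid = tile_slide((201, 201))
        assert grid.col_origins.tolist() == [0, 50, 100]
        assert len(grid) == 9

    def test_adjacent_patches_share_51_pixels(self):
        grid = tile_slide((300, 300))
        c0, c1 = grid.col_origins[0], grid.col_origins[1]
        shared = set(range(c0, c0 + 101)) & set(range(c1, c1 + 101))
        assert len(shared) == 51

    def test_single_patch_slide(self):
        grid = tile_slide((101, 101))
        assert grid.origins == [(0, 0)]

    def test_undersized_slide_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            tile_slide((100, 300))

    def test_every_footprint_inside_slide(self):
        grid = tile_slide((487, 333))
        for r, c in grid.origins:
            assert r + 101 <= 487 and c + 101 <= 333


class _ConstantModel:
    """Stub classifier returning a fixed cancer probability."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, batch, batch_size=128):
        return np.full(len(batch), self.p)


class TestTtaPredict:
    def test_constant_model_mean_is_constant(self, asym_patch):
        pred = tta_predict(_ConstantModel(0.7), asym_patch)
        assert pred.p_bar == pytest.approx(0.7)
        assert len(pred.per_orientation) == 8

    def test_half_and_half_orientations_average(self, asym_patch):
        class HalfModel:
            def predict_proba(self, batch, batch_size=128):
                return np.array([1, 1, 1, 1, 0, 0, 0, 0], float)

        assert tta_predict(HalfModel(), asym_patch).p_bar == pytest.approx(0.5)

    def test_no_jitter_tta_invariant_to_prerotation(self, micro_model, asym_patch):
        # the variant set is closed under the dihedral group, so pre-rotating
        # the input permutes the 8 orientation probabilities only
        base = tta_predict(micro_model, asym_patch)
        for k in (1, 5):
            rotated = tta_predict(micro_model, dihedral_apply(asym_patch, k))
            assert rotated.p_bar == pytest.approx(base.p_bar, abs=1e-6)
            assert sorted(rotated.per_orientation) == pytest.approx(
                sorted(base.per_orientation), abs=1e-6
            )

    def test_inverse_indices_are_inverses(self, asym_patch):
        for k in range(8):
            back = dihedral_apply(dihedral_apply(asym_patch, k), dihedral_inverse(k))
            assert np.array_equal(back, asym_patch)


def _brute_force_blocks(p_bar, slide_shape, patch=101, stride=50, block=50):
    """Independent oracle: per block, enumerate all patches containing it."""
    grid = tile_slide(slide_shape, patch, stride)
    rows, cols = grid.row_origins, grid.col_origins
    n_u = (rows[-1] + (patch // block) * block) // block
    n_v = (cols[-1] + (patch // block) * block) // block
    out = np.zeros((n_u, n_v))
    for u in range(n_u):
        for v in range(n_v):
            vals = []
            for i, r in enumerate(rows):
                for j, c in enumerate(cols):
                    contains_rows = r <= block * u and block * u + block - 1 <= r + patch - 1
                    contains_cols = c <= block * v and block * v + block - 1 <= c + patch - 1
                    if contains_rows and contains_cols:
                        vals.append(p_bar[i, j])
            out[u, v] = np.mean(vals)
    return out


class TestReconstructHeatmap:
    def test_interior_block_is_quarter_sum(self):
        grid = tile_slide((201, 201))
        p = np.zeros((3, 3))
        p[0, 0], p[0, 1], p[1, 0], p[1, 1] = 0.2, 0.4, 0.6, 0.8
        hm = reconstruct_heatmap(p, (201, 201))
        # block (1,1) is covered by exactly those four patches
        assert hm.blocks[1, 1] == pytest.approx(0.5)

    def test_corner_block_covered_once(self):
        p = np.full((3, 3), 0.1)
        p[0, 0] = 0.9
        hm = reconstruct_heatmap(p, (201, 201))
        assert hm.blocks[0, 0] == pytest.approx(0.9)  # free-edge rule

    def test_all_zero_predictions_give_zero_map(self):
        hm = reconstruct_heatmap(np.zeros((4, 4)), (251, 251))
        assert (hm.blocks == 0).all()

    def test_matches_brute_force_on_100_random_slides(self, rng):
        for _ in range(100):
            h = int(rng.integers(101, 420))
            w = int(rng.integers(101, 420))
            grid = tile_slide((h, w))
            p = rng.random((len(grid.row_origins), len(grid.col_origins)))
            fast = reconstruct_heatmap(p, (h, w)).blocks
            slow = _brute_force_blocks(p, (h, w))
            assert fast.shape == slow.shape
            assert np.allclose(fast, slow, atol=1e-12)

    def test_values_in_convex_hull_of_predictions(self, rng):
        p = rng.random((5, 7))
        hm = reconstruct_heatmap(p, (301, 401))
        assert hm.blocks.min() >= p.min() - 1e-12
        assert hm.blocks.max() <= p.max() + 1e-12

    def test_missing_prediction_rejected(self):
        with pytest.raises(ValueError, match="per tile origin"):
            reconstruct_heatmap(np.zeros((2, 2)), (201, 201))
        with pytest.raises(ValueError, match="NaN"):
            p = np.zeros((3, 3))
            p[1, 1] = np.nan
            reconstruct_heatmap(p, (201, 201))

    def test_block_size_recorded(self):
        hm = reconstruct_heatmap(np.zeros((3, 3)), (201, 201))
        assert hm.block_size == 50


def test_predict_slide_background_masked(micro_model):
    # an all-white slide yields an all-zero heat-map without model calls
    from histopatch.infer import predict_slide

    slide = Slide(pixels=np.ones((220, 220, 3), np.float32), slide_id="white")
    sp = predict_slide(micro_model, slide, tissue_mask=True)
    assert (sp.p_bar == 0).all()
    assert (sp.heatmap.blocks == 0).all()
    assert not sp.tissue.any()
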