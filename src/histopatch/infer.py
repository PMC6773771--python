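"""Slide tiling, test-time-averaged patch classification, and heat-map
reconstruction.

A slide is tiled into 101x101 patches at stride 50 (adjacent patches share
51 pixels per axis).  Each patch is classified in all 8 dihedral
orientations — each orientation with an independent random HSV/contrast
jitter draw — and the 8 probabilities are averaged into a single patch
prediction p-bar.  Overlapping patch predictions are then averaged per
50x50-pixel block: an interior block is covered by exactly 4 patches; free
edges are covered by fewer and averaged over what exists.

Background handling: patches whose footprint fails the tissue filter are
assigned probability 0 without evaluating the model (switchable).  The
network never sees non-tissue during training, so masking keeps both the
heat-map and the slide-level maximum-probability score meaningful.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .augment import JitterProfile, color_jitter, dihedral_variants, rgb_to_hsv
from .model import Model
from .patch_sampler import PATCH_SIZE, PatchSet, tissue_origin_map
from .slide_io import HEATMAP_BLOCK, HeatMap, Slide

STRIDE = 50


@dataclass
class TileGrid:
    """Patch origins covering a slide at stride 50."""

    row_origins: np.ndarray
    col_origins: np.ndarray
    patch_size: int
    slide_shape: tuple[int, int]

    @property
    def origins(self) -> list[tuple[int, int]]:
        return [(int(r), int(c)) for r in self.row_origins for c in self.col_origins]

    def __len__(self) -> int:
        return len(self.row_origins) * len(self.col_origins)


@dataclass
class PatchPrediction:
    origin: tuple[int, int]
    p_bar: float
    per_orientation: tuple[float, ...] = ()


@dataclass
class SlidePrediction:
    """All patch predictions for one slide plus the reconstructed heat-map."""

    slide_ref: str
    grid: TileGrid
    p_bar: np.ndarray  # (n_rows, n_cols) mean orientation-averaged probabilities
    heatmap: HeatMap
    tissue: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), bool))

    @property
    def max_probability(self) -> float:
        return float(self.p_bar.max())


def tile_slide(slide, patch_size: int = PATCH_SIZE, stride: int = STRIDE) -> TileGrid:
    """Tile a slide (or an (H, W) shape) into overlapping patch origins.

    Origins run 0, 50, 100, ... up to the last position with a full
    footprint; adjacent patches overlap by ``patch_size - stride`` pixels.
    """
    shape = slide.shape[:2] if hasattr(slide, "shape") else tuple(slide)
    h, w = shape[0], shape[1]
    if h < patch_size or w < patch_size:
        raise ValueError(f"slide {h}x{w} smaller than one {patch_size}-pixel patch")
    rows = np.arange(0, h - patch_size + 1, stride)
    cols = np.arange(0, w - patch_size + 1, stride)
    return TileGrid(rows, cols, patch_size, (h, w))


# ---------------------------------------------------------------- prediction

def _orientation_rng(seed: int, slide_ref: str, origin, s: int) -> np.random.Generator:
    """Independent, reproducible jitter stream per (slide, origin, orientation)."""
    tag = zlib.crc32(slide_ref.encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed, tag, int(origin[0]), int(origin[1]), s])


def tta_predict(
    model: Model,
    patch: np.ndarray,
    jitter: JitterProfile | None = None,
    seed: int = 0,
    slide_ref: str = "",
    origin: tuple[int, int] = (0, 0),
) -> PatchPrediction:
    """8-orientation test-time-averaged cancer probability of one RGB patch."""
    variants = dihedral_variants(patch)
    batch = np.empty((8,) + patch.shape, dtype=np.float32)
    for s, var in enumerate(variants):
        hsv = rgb_to_hsv(var)
        if jitter is not None and not jitter.is_identity:
            hsv = color_jitter(hsv, jitter, _orientation_rng(seed, slide_ref, origin, s))
        batch[s] = hsv
    probs = model.predict_proba(batch)
    return PatchPrediction(origin=origin, p_bar=float(probs.mean()), per_orientation=tuple(probs))


def predict_patches(
    model: Model,
    patches: PatchSet,
    tta: bool = False,
    jitter: JitterProfile | None = None,
    seed: int = 0,
    batch_size: int = 128,
) -> np.ndarray:
    """Cancer probabilities for a patch set (RGB pixels).

    With ``tta`` every patch is averaged over its 8 orientations; otherwise
    a single eval-mode forward pass per patch.
    """
    if not tta:
        hsv = np.empty_like(patches.pixels)
        for i in range(len(patches)):
            hsv[i] = rgb_to_hsv(patches.pixels[i])
        return model.predict_proba(hsv, batch_size=batch_size)
    return np.array(
        [
            tta_predict(
                model, patches.pixels[i], jitter, seed,
                patches.slide_refs[i], tuple(patches.origins[i]),
            ).p_bar
            for i in range(len(patches))
        ]
    )


def predict_slide(
    model: Model,
    slide: Slide,
    jitter: JitterProfile | None = None,
    seed: int = 0,
    tissue_mask: bool = True,
    batch_size: int = 128,
) -> SlidePrediction:
    """Classify every tile of a slide with 8-orientation TTA and reconstruct
    the overlap-averaged heat-map."""
    grid = tile_slide(slide)
    n_r, n_c = len(grid.row_origins), len(grid.col_origins)
    p_bar = np.zeros((n_r, n_c), dtype=np.float64)

    if tissue_mask:
        origin_ok = tissue_origin_map(slide, grid.patch_size)
        tissue = origin_ok[np.ix_(grid.row_origins, grid.col_origins)]
    else:
        tissue = np.ones((n_r, n_c), dtype=bool)

    # Batch all 8 orientations of every tissue patch through the network.
    jobs = [(i, j) for i in range(n_r) for j in range(n_c) if tissue[i, j]]
    hsv_batch = []
    for i, j in jobs:
        r, c = int(grid.row_origins[i]), int(grid.col_origins[j])
        patch = slide.pixels[r : r + grid.patch_size, c : c + grid.patch_size]
        for s, var in enumerate(dihedral_variants(patch)):
            hsv = rgb_to_hsv(var)
            if jitter is not None and not jitter.is_identity:
                hsv = color_jitter(hsv, jitter, _orientation_rng(seed, slide.slide_id, (r, c), s))
            hsv_batch.append(hsv)
    if jobs:
        probs = model.predict_proba(np.asarray(hsv_batch, np.float32), batch_size=batch_size)
        probs = probs.reshape(len(jobs), 8).mean(axis=1)
        for (i, j), p in zip(jobs, probs):
            p_bar[i, j] = p

    heatmap = reconstruct_heatmap(p_bar, slide.shape, slide_ref=slide.slide_id)
    return SlidePrediction(slide.slide_id, grid, p_bar, heatmap, tissue)


# ------------------------------------------------------------ reconstruction

def reconstruct_heatmap(
    p_bar: np.ndarray,
    slide_shape: tuple[int, int],
    patch_size: int = PATCH_SIZE,
    stride: int = STRIDE,
    block: int = HEATMAP_BLOCK,
    slide_ref: str = "",
) -> HeatMap:
    """Average overlapping patch predictions into 50x50-pixel blocks.

    ``p_bar`` is the full (n_rows, n_cols) grid of orientation-averaged
    patch probabilities (one per tile origin — a missing value is a shape
    error).  Block (u, v) covers pixels [block*u, block*u + block - 1] per
    axis and averages every patch whose footprint fully contains it: 4 in
    the interior, fewer on free edges.
    """
    grid = tile_slide(slide_shape, patch_size, stride)
    n_r, n_c = len(grid.row_origins), len(grid.col_origins)
    p_bar = np.asarray(p_bar, dtype=np.float64)
    if p_bar.shape != (n_r, n_c):
        raise ValueError(
            f"need one prediction per tile origin: expected shape {(n_r, n_c)}, got {p_bar.shape}"
        )
    if np.any(np.isnan(p_bar)):
        raise ValueError("missing (NaN) prediction in the tile grid")

    blocks_per_patch = patch_size // block  # full blocks inside one footprint
    n_u = (int(grid.row_origins[-1]) + blocks_per_patch * block) // block
    n_v = (int(grid.col_origins[-1]) + blocks_per_patch * block) // block
    acc = np.zeros((n_u, n_v), dtype=np.float64)
    cnt = np.zeros((n_u, n_v), dtype=np.int64)
    for i in range(n_r):
        u0 = int(grid.row_origins[i]) // block
        for j in range(n_c):
            v0 = int(grid.col_origins[j]) // block
            acc[u0 : u0 + blocks_per_patch, v0 : v0 + blocks_per_patch] += p_bar[i, j]
            cnt[u0 : u0 + blocks_per_patch, v0 : v0 + blocks_per_patch] += 1
    blocks = acc / cnt
    return HeatMap(blocks=blocks, block_size=block, slide_ref=slide_ref)
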