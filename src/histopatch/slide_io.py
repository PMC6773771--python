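"""Slide/mask I/O, nearest-neighbour downsampling and heat-map serialization.

Slides are plain raster images (PNG/TIFF) with intensities rescaled to
[0, 1]; masks are 8-bit PNGs binarized on load (any nonzero pixel becomes
1).  Whole-slide pyramidal formats are out of scope: a reader for them can
be slotted in behind :func:`load_pair` without touching the pipeline.

The nominal full-resolution pixel pitch is 0.23 um (a 40x-objective scan);
the standard working resolution is a 4x nearest-neighbour downsample, i.e.
about 0.92 um per pixel, at which a 101-pixel patch spans ~92 um of tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

#: Nominal full-resolution pixel pitch in microns (40x objective scan).
NOMINAL_MICRONS_PER_PIXEL = 0.23

#: The standard working downsample factor.
DEFAULT_DOWNSAMPLE = 4

HEATMAP_BLOCK = 50
_U16_MAX = 65535


@dataclass
class Slide:
    """An RGB slide in memory, with physical-size and cohort metadata."""

    pixels: np.ndarray  # (H, W, 3) float32 in [0, 1]
    microns_per_pixel: float = NOMINAL_MICRONS_PER_PIXEL
    downsample_factor: int = 1
    patient_id: str = ""
    role: str = ""
    split: str = ""
    slide_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def effective_microns_per_pixel(self) -> float:
        return self.microns_per_pixel * self.downsample_factor


@dataclass
class AnnotationMask:
    """Binary cancer ground truth congruent with its slide."""

    labels: np.ndarray  # (H, W) uint8 in {0, 1}

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class HeatMap:
    """Reconstructed cancer-probability grid at 50x50-pixel block detail."""

    blocks: np.ndarray  # (R, C) float in [0, 1]
    block_size: int = HEATMAP_BLOCK
    origin: tuple[int, int] = (0, 0)
    slide_ref: str = ""


def patch_span_microns(patch_size: int, microns_per_pixel: float) -> float:
    """Physical extent of a square patch along one axis, in microns."""
    return patch_size * microns_per_pixel


# ----------------------------------------------------------------------- I/O

def read_image(path) -> np.ndarray:
    """Read an RGB image as float32 in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return (arr / 255.0).astype(np.float32)
    if arr.dtype == np.uint16:
        return (arr / _U16_MAX).astype(np.float32)
    return np.clip(arr, 0.0, 1.0).astype(np.float32)


def write_image(path, pixels: np.ndarray) -> None:
    """Write a [0,1] float RGB image as 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(pixels), 0.0, 1.0)
    iio.imwrite(path, np.floor(arr * 255.0 + 0.5).astype(np.uint8))


def write_mask(path, labels: np.ndarray) -> None:
    """Write a binary mask as single-channel 8-bit PNG with values {0, 255}."""
    iio.imwrite(path, np.where(np.asarray(labels) > 0, 255, 0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def load_pair(slide_path, mask_path, manifest_row=None) -> tuple[Slide, AnnotationMask]:
    """Load a slide and its mask; intensities in [0,1], mask binarized.

    Raises ``ValueError`` naming both shapes on a dimension mismatch.
    """
    pixels = read_image(slide_path)
    labels = read_mask(mask_path)
    if pixels.shape[:2] != labels.shape:
        raise ValueError(
            f"slide {Path(slide_path).name} has shape {pixels.shape[:2]} but mask "
            f"{Path(mask_path).name} has shape {labels.shape}"
        )
    meta = {}
    if manifest_row is not None:
        meta = dict(
            patient_id=manifest_row.patient_id,
            role=manifest_row.role,
            split=manifest_row.split,
            slide_id=Path(manifest_row.slide).stem,
        )
    else:
        meta = dict(slide_id=Path(slide_path).stem)
    return Slide(pixels=pixels, **meta), AnnotationMask(labels=labels)


def load_cohort(manifest, downsample_factor: int = DEFAULT_DOWNSAMPLE):
    """Yield ``(Slide, AnnotationMask)`` pairs for every manifest row,
    downsampled to the working resolution."""
    root = manifest.root if manifest.root is not None else Path(".")
    for row in manifest.rows:
        slide, mask = load_pair(root / row.slide, root / row.mask, row)
        if downsample_factor != 1:
            slide, mask = downsample(slide, mask, downsample_factor)
        yield slide, mask


# ---------------------------------------------------------------- resampling

def downsample(
    slide: Slide, mask: AnnotationMask | None, factor: int = DEFAULT_DOWNSAMPLE
) -> tuple[Slide, AnnotationMask | None]:
    """Nearest-neighbour downsample of slide and mask by an integer factor.

    Convention: output pixel (i, j) takes input pixel (i*factor, j*factor),
    0-based.  The mask stays strictly binary; physical pixel size is
    multiplied by the factor.
    """
    if not (isinstance(factor, (int, np.integer)) and factor >= 1):
        raise ValueError(f"downsample factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    if factor == 1:
        return slide, mask
    px = slide.pixels[::factor, ::factor]
    out_slide = replace(
        slide,
        pixels=np.ascontiguousarray(px),
        downsample_factor=slide.downsample_factor * factor,
    )
    out_mask = None
    if mask is not None:
        out_mask = AnnotationMask(np.ascontiguousarray(mask.labels[::factor, ::factor]))
    return out_slide, out_mask


# ------------------------------------------------------------------ heat-maps

def write_heatmap(heatmap: HeatMap, path) -> None:
    """Serialize a heat-map as 16-bit grayscale PNG plus a sidecar CSV.

    PNG value = round(probability * 65535), half up; round-trip error is at
    most 1/65535 per block.  Out-of-range probabilities are rejected.
    """
    blocks = np.asarray(heatmap.blocks, dtype=np.float64)
    if blocks.size == 0:
        raise ValueError("empty heat-map")
    if blocks.min() < 0.0 or blocks.max() > 1.0:
        raise ValueError(
            f"heat-map probabilities outside [0, 1]: min {blocks.min()}, max {blocks.max()}"
        )
    path = Path(path)
    iio.imwrite(path, np.floor(blocks * _U16_MAX + 0.5).astype(np.uint16))
    np.savetxt(path.with_suffix(".csv"), blocks, delimiter=",", fmt="%.6f")


def read_heatmap(path, slide_ref: str = "") -> HeatMap:
    arr = iio.imread(path)
    if arr.dtype != np.uint16:
        raise ValueError(f"heat-map PNG must be 16-bit, got {arr.dtype}")
    return HeatMap(blocks=(arr / _U16_MAX).astype(np.float64), slide_ref=slide_ref)
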