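"""Labeled patch extraction from annotated slides.

Patches are 101x101 windows labeled by their *center pixel* against the
binary cancer mask — the ground truth is regional, so a patch is "cancer"
exactly when its central pixel falls inside the marked cancer area.
Training patches come only from tumor and normal slides (interface slides
are reserved for validation/testing); origins are drawn uniformly at random
from tissue positions, per-slide per-class caps are enforced ("up to N per
slide"), and the two classes are approximately balanced by subsampling the
majority class.

Tissue positions are found with a cheap white-background filter (mean
saturation / brightness thresholds over the patch footprint), evaluated in
O(1) per candidate origin via integral images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .augment import rgb_to_hsv
from .slide_io import AnnotationMask, Slide

log = logging.getLogger(__name__)

PATCH_SIZE = 101

#: Tissue filter thresholds (mean over the patch footprint, inclusive).
MIN_MEAN_SATURATION = 0.05
MAX_MEAN_BRIGHTNESS = 0.95

#: Imbalance tolerance of the "approximately balanced" rule.
BALANCE_TOLERANCE = 0.01


@dataclass(frozen=True)
class SamplingPolicy:
    """How patches are drawn from a cohort."""

    patch_size: int = PATCH_SIZE
    max_cancer_per_slide: int | None = 5000
    max_normal_per_slide: int | None = 1000
    balance: bool = True
    tissue_filter: bool = True
    roles_included: tuple[str, ...] = ("tumor", "normal")
    seed: int = 0

    def __post_init__(self):
        if self.patch_size % 2 != 1:
            raise ValueError(f"patch_size must be odd, got {self.patch_size}")
        for cap in (self.max_cancer_per_slide, self.max_normal_per_slide):
            if cap is not None and cap < 0:
                raise ValueError("per-slide caps must be >= 0")


@dataclass
class Patch:
    """One labeled patch; label 1 = cancer-positive, 0 = cancer-negative."""

    pixels: np.ndarray
    origin: tuple[int, int]
    label: int
    slide_ref: str = ""


@dataclass
class PatchSet:
    """Array-backed collection of same-size labeled patches."""

    pixels: np.ndarray  # (N, ps, ps, 3) float32
    origins: np.ndarray  # (N, 2) int32
    labels: np.ndarray  # (N,) uint8
    slide_refs: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> Patch:
        return Patch(self.pixels[i], tuple(self.origins[i]), int(self.labels[i]), self.slide_refs[i])

    @classmethod
    def empty(cls, patch_size: int = PATCH_SIZE) -> "PatchSet":
        return cls(
            pixels=np.zeros((0, patch_size, patch_size, 3), np.float32),
            origins=np.zeros((0, 2), np.int32),
            labels=np.zeros((0,), np.uint8),
            slide_refs=[],
        )

    @classmethod
    def concatenate(cls, parts: list["PatchSet"]) -> "PatchSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(
            pixels=np.concatenate([p.pixels for p in parts]),
            origins=np.concatenate([p.origins for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            slide_refs=[r for p in parts for r in p.slide_refs],
        )

    def subset(self, idx) -> "PatchSet":
        idx = np.asarray(idx)
        return PatchSet(
            pixels=self.pixels[idx],
            origins=self.origins[idx],
            labels=self.labels[idx],
            slide_refs=[self.slide_refs[int(i)] for i in idx],
        )


# ------------------------------------------------------------------ labeling

def label_at(mask, origin: tuple[int, int], patch_size: int = PATCH_SIZE) -> int:
    """Label of the patch at ``origin``: the mask value at its center pixel."""
    labels = mask.labels if isinstance(mask, AnnotationMask) else np.asarray(mask)
    r, c = origin
    h, w = labels.shape
    if r < 0 or c < 0 or r + patch_size > h or c + patch_size > w:
        raise ValueError(
            f"patch footprint at {origin} size {patch_size} exceeds mask shape {labels.shape}"
        )
    half = patch_size // 2
    return int(labels[r + half, c + half] > 0)


# ------------------------------------------------------------- tissue filter

def tissue_filter(patch: np.ndarray) -> bool:
    """True iff the RGB patch looks like tissue rather than background.

    Mean saturation >= 0.05 (inclusive) and mean brightness <= 0.95.
    """
    hsv = rgb_to_hsv(patch)
    return bool(
        hsv[..., 1].mean() >= MIN_MEAN_SATURATION and hsv[..., 2].mean() <= MAX_MEAN_BRIGHTNESS
    )


def _integral(img: np.ndarray) -> np.ndarray:
    out = np.zeros((img.shape[0] + 1, img.shape[1] + 1), np.float64)
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=out[1:, 1:])
    return out


def _window_means(img: np.ndarray, k: int) -> np.ndarray:
    """Mean of every k x k window (valid positions), via an integral image."""
    ii = _integral(img)
    s = ii[k:, k:] - ii[:-k, k:] - ii[k:, :-k] + ii[:-k, :-k]
    return s / (k * k)


def tissue_origin_map(slide: Slide, patch_size: int = PATCH_SIZE) -> np.ndarray:
    """Boolean map over all valid patch origins passing the tissue filter."""
    hsv = rgb_to_hsv(slide.pixels)
    sat = _window_means(hsv[..., 1], patch_size)
    val = _window_means(hsv[..., 2], patch_size)
    return (sat >= MIN_MEAN_SATURATION) & (val <= MAX_MEAN_BRIGHTNESS)


# ------------------------------------------------------------------ sampling

def _extract(slide: Slide, origins: np.ndarray, labels: np.ndarray, ps: int) -> PatchSet:
    px = np.empty((len(origins), ps, ps, 3), np.float32)
    for i, (r, c) in enumerate(origins):
        px[i] = slide.pixels[r : r + ps, c : c + ps]
    return PatchSet(
        pixels=px,
        origins=np.asarray(origins, np.int32).reshape(-1, 2),
        labels=np.asarray(labels, np.uint8),
        slide_refs=[slide.slide_id] * len(origins),
    )


def sample_slide_patches(
    slide: Slide,
    mask: AnnotationMask,
    policy: SamplingPolicy,
    rng: np.random.Generator,
    cap_cancer: int | None,
    cap_normal: int | None,
) -> PatchSet:
    """Draw up to the per-class caps of tissue patches from one slide,
    origins uniform at random without replacement."""
    ps = policy.patch_size
    h, w = slide.shape
    if h < ps or w < ps:
        log.warning(
            "slide %s (%dx%d) smaller than the %d-pixel patch footprint; skipped",
            slide.slide_id, h, w, ps,
        )
        return PatchSet.empty(ps)
    if policy.tissue_filter:
        ok = tissue_origin_map(slide, ps)
    else:
        ok = np.ones((h - ps + 1, w - ps + 1), bool)
    half = ps // 2
    center_cancer = mask.labels[half : half + ok.shape[0], half : half + ok.shape[1]] > 0

    parts = []
    for is_cancer, cap in ((True, cap_cancer), (False, cap_normal)):
        cand = np.flatnonzero(ok & (center_cancer == is_cancer))
        if cand.size == 0:
            continue
        n = cand.size if cap is None else min(cap, cand.size)
        if n == 0:
            continue
        chosen = rng.choice(cand, size=n, replace=False)
        chosen.sort()
        origins = np.stack(np.unravel_index(chosen, ok.shape), axis=1)
        parts.append(_extract(slide, origins, np.full(n, int(is_cancer)), ps))
    return PatchSet.concatenate(parts)


def balance_classes(patches: PatchSet, rng: np.random.Generator) -> PatchSet:
    """Subsample the majority class so counts differ by at most 1%."""
    n_pos = int(patches.labels.sum())
    n_neg = len(patches) - n_pos
    if n_pos == 0 or n_neg == 0:
        return patches
    minority, majority = min(n_pos, n_neg), max(n_pos, n_neg)
    keep_major = min(majority, int(np.floor(minority * (1.0 + BALANCE_TOLERANCE))))
    if keep_major == majority:
        return patches
    major_label = 1 if n_pos > n_neg else 0
    major_idx = np.flatnonzero(patches.labels == major_label)
    minor_idx = np.flatnonzero(patches.labels != major_label)
    kept = rng.choice(major_idx, size=keep_major, replace=False)
    idx = np.sort(np.concatenate([minor_idx, kept]))
    return patches.subset(idx)


def sample_patches(
    pairs: list[tuple[Slide, AnnotationMask]],
    policy: SamplingPolicy,
    roles: tuple[str, ...] | None = None,
    balance: bool | None = None,
) -> PatchSet:
    """Sample patches from ``(slide, mask)`` pairs per the policy.

    ``roles`` restricts contributing slide roles (default: the policy's);
    ``balance`` overrides the policy's balancing flag.  Fully seeded by the
    policy seed and the order of ``pairs``.
    """
    rng = np.random.default_rng(policy.seed)
    roles = policy.roles_included if roles is None else roles
    do_balance = policy.balance if balance is None else balance
    parts = []
    for slide, mask in pairs:
        if slide.role and slide.role not in roles:
            continue
        parts.append(
            sample_slide_patches(
                slide, mask, policy, rng, policy.max_cancer_per_slide, policy.max_normal_per_slide
            )
        )
    patches = PatchSet.concatenate(parts)
    if do_balance:
        patches = balance_classes(patches, rng)
    return patches


def sample_training_patches(
    pairs: list[tuple[Slide, AnnotationMask]], policy: SamplingPolicy
) -> PatchSet:
    """Training recipe: tumor/normal slides only, caps, approximate balance."""
    train_pairs = [(s, m) for s, m in pairs if s.split in ("", "train")]
    return sample_patches(train_pairs, policy, roles=policy.roles_included, balance=policy.balance)


# -------------------------------------------------------------- serialization

def save_patchset(patches: PatchSet, out_dir) -> None:
    """Write a patch set as a directory of PNGs plus an index CSV."""
    from pathlib import Path

    from .slide_io import write_image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "index.csv", "w") as fh:
        fh.write("file,row,col,label,slide_ref\n")
        for i in range(len(patches)):
            name = f"patch_{i:06d}.png"
            write_image(out_dir / name, patches.pixels[i])
            r, c = patches.origins[i]
            fh.write(f"{name},{r},{c},{int(patches.labels[i])},{patches.slide_refs[i]}\n")


def load_patchset(in_dir) -> PatchSet:
    import csv as _csv
    from pathlib import Path

    from .slide_io import read_image

    in_dir = Path(in_dir)
    rows = list(_csv.DictReader(open(in_dir / "index.csv")))
    if not rows:
        return PatchSet.empty()
    pixels = np.stack([read_image(in_dir / r["file"]) for r in rows])
    return PatchSet(
        pixels=pixels.astype(np.float32),
        origins=np.array([[int(r["row"]), int(r["col"])] for r in rows], np.int32),
        labels=np.array([int(r["label"]) for r in rows], np.uint8),
        slide_refs=[r["slide_ref"] for r in rows],
    )
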