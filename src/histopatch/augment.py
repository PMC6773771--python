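"""Dihedral (8-fold) orientation augmentation and HSV color jitter.

Histology has no canonical orientation, so the eight symmetries of the
square — four 90-degree rotations and their mirror images — are all valid
views of a patch.  Stain variability between slides is emulated by jittering
hue, saturation, brightness and contrast in HSV space.  The same two
transforms serve training augmentation and test-time averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv

#: Named jitter presets: (hue, saturation, brightness, contrast) half-widths
#: as fractions of the channel range, per tissue type.
JITTER_PRESETS = {
    "scc": (0.04, 0.15, 0.08, 0.02),
    "thyroid": (0.05, 0.05, 0.08, 0.05),
    "lymph_node": (0.10, 0.10, 0.10, 0.10),
}


@dataclass(frozen=True)
class JitterProfile:
    """Half-widths of the uniform HSV/contrast perturbations, in [0, 1]."""

    hue_pct: float = 0.0
    sat_pct: float = 0.0
    bright_pct: float = 0.0
    contrast_pct: float = 0.0

    def __post_init__(self):
        for name in ("hue_pct", "sat_pct", "bright_pct", "contrast_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def preset(cls, name: str) -> "JitterProfile":
        if name not in JITTER_PRESETS:
            raise ValueError(
                f"unknown jitter preset {name!r}; valid: {sorted(JITTER_PRESETS)}"
            )
        return cls(*JITTER_PRESETS[name])

    @property
    def is_identity(self) -> bool:
        return (self.hue_pct, self.sat_pct, self.bright_pct, self.contrast_pct) == (
            0.0,
            0.0,
            0.0,
            0.0,
        )


# ------------------------------------------------------------- dihedral group

N_ORIENTATIONS = 8


def dihedral_apply(patch: np.ndarray, k: int) -> np.ndarray:
    """Apply dihedral element ``k`` of 8 to a square image.

    Order: k in 0..3 are counterclockwise rotations by 90k degrees
    (k=0 identity); k in 4..7 are a horizontal flip followed by the
    rotation of ``k - 4``.
    """
    if patch.shape[0] != patch.shape[1]:
        raise ValueError(f"dihedral transforms need a square patch, got {patch.shape}")
    if not 0 <= k < N_ORIENTATIONS:
        raise ValueError(f"orientation index {k} outside 0..7")
    if k >= 4:
        patch = patch[:, ::-1]
        k -= 4
    return np.rot90(patch, k) if k else patch


def dihedral_inverse(k: int) -> int:
    """Index of the inverse group element (reflections are involutions)."""
    if not 0 <= k < N_ORIENTATIONS:
        raise ValueError(f"orientation index {k} outside 0..7")
    return (4 - k) % 4 if k < 4 else k


def dihedral_variants(patch: np.ndarray) -> list[np.ndarray]:
    """All 8 orientations of a square patch; variant 0 is the identity."""
    return [np.ascontiguousarray(dihedral_apply(patch, k)) for k in range(N_ORIENTATIONS)]


# ------------------------------------------------------------------ HSV space

def rgb_to_hsv(patch: np.ndarray) -> np.ndarray:
    """RGB [0,1] -> hexcone HSV with every channel scaled to [0,1]."""
    return rgb2hsv(np.asarray(patch, dtype=np.float64)).astype(np.float32)


def hsv_to_rgb(patch: np.ndarray) -> np.ndarray:
    return hsv2rgb(np.asarray(patch, dtype=np.float64)).astype(np.float32)


def color_jitter(
    patch_hsv: np.ndarray, profile: JitterProfile, rng: np.random.Generator
) -> np.ndarray:
    """Randomly perturb an HSV patch per the jitter profile.

    Hue is shifted additively (circular, modulo 1); saturation and
    brightness are scaled by ``1 + u`` with ``u`` drawn per channel from the
    respective ±half-width; contrast rescales brightness about its patch
    mean.  Saturation and brightness are clipped to [0, 1].
    """
    out = np.array(patch_hsv, dtype=np.float32, copy=True)
    if profile.is_identity:
        return out
    du_h = rng.uniform(-profile.hue_pct, profile.hue_pct)
    du_s = rng.uniform(-profile.sat_pct, profile.sat_pct)
    du_v = rng.uniform(-profile.bright_pct, profile.bright_pct)
    du_c = rng.uniform(-profile.contrast_pct, profile.contrast_pct)
    out[..., 0] = (out[..., 0] + du_h) % 1.0
    out[..., 1] = np.clip(out[..., 1] * (1.0 + du_s), 0.0, 1.0)
    v = out[..., 2] * (1.0 + du_v)
    v = v.mean() + (1.0 + du_c) * (v - v.mean())
    out[..., 2] = np.clip(v, 0.0, 1.0)
    return out
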