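"""Grad-CAM class-evidence maps for individual patches.

Gradients are traced from a class logit back to the last stem convolution
(the stride-2 convolution just before the Inception stack).  Channel
weights are the spatial means of that gradient; the map is the rectified
weighted sum of the layer's activations, bilinearly upsampled to the patch
size and max-normalized.  Cancer and normal maps are computed independently
(per-class normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import _autodiff as ad
from ._autodiff import Tensor
from .augment import rgb_to_hsv

CLASS_INDEX = {"normal": 0, "cancer": 1}


@dataclass
class CamMap:
    """Normalized class-evidence map over a patch."""

    values: np.ndarray  # (ps, ps) in [0, 1]
    class_name: str
    patch_ref: str = ""
    zero_map: bool = False  # True when the raw map was identically zero


def grad_cam(model, patch: np.ndarray, target_class, input_is_hsv: bool = False) -> CamMap:
    """Grad-CAM map of ``target_class`` ('cancer'/'normal' or 0/1) for one
    RGB patch.

    Works on any model exposing ``stem`` / ``blocks`` / ``gap`` / ``head``;
    the target layer is the last stem convolution's output.
    """
    if isinstance(target_class, str):
        if target_class not in CLASS_INDEX:
            raise ValueError(f"unknown class {target_class!r}; valid: {sorted(CLASS_INDEX)}")
        cls_idx, cls_name = CLASS_INDEX[target_class], target_class
    else:
        cls_idx = int(target_class)
        cls_name = {v: k for k, v in CLASS_INDEX.items()}.get(cls_idx, str(cls_idx))
    if not getattr(model, "stem", None):
        raise ValueError("model has no stem layers; build/load a model first")

    patch = np.asarray(patch, dtype=np.float32)
    hsv = patch if input_is_hsv else rgb_to_hsv(patch)

    with ad.precision(np.float64):  # analytic-grade arithmetic
        x = Tensor(hsv[None])
        for layer in model.stem:
            x = layer(x)
        target = x  # (1, h, w, c) activations of the last stem conv
        for blk in model.blocks:
            x = blk(x)
        x = model.gap(x)
        logits = model.head(x)
        ad.pick(logits, (0, cls_idx)).backward()

    if target.grad is None:
        grad = np.zeros_like(target.data)
    else:
        grad = target.grad
    weights = grad[0].mean(axis=(0, 1))  # spatial mean per channel
    cam = np.maximum((target.data[0] * weights).sum(axis=-1), 0.0)

    ps = patch.shape[0]
    cam_up = resize(cam.astype(np.float64), (ps, ps), order=1, mode="edge",
                    anti_aliasing=False)
    cam_up = np.maximum(cam_up, 0.0)
    peak = cam_up.max()
    if peak <= 0.0:
        return CamMap(np.zeros((ps, ps)), cls_name, zero_map=True)
    return CamMap(cam_up / peak, cls_name, zero_map=False)


def render_overlay(patch: np.ndarray, cam: CamMap, alpha: float = 0.45) -> np.ndarray:
    """Blend a CAM over its RGB patch (red = strong evidence) for display."""
    heat = np.zeros_like(patch)
    heat[..., 0] = cam.values
    heat[..., 2] = 1.0 - cam.values
    return np.clip((1 - alpha) * patch + alpha * heat, 0.0, 1.0)
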