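"""Grad-CAM saliency over the network's spatial stages.

Channel weights are the spatial mean of the gradient of the pneumonia
probability with respect to the target stage's activations; the map is
the rectified weighted channel sum, min-max normalized and bilinearly
upsampled to input resolution.  An identically-zero pre-normalization
map (e.g. a dead classifier head) stays all-zero and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.transform import resize as _resize

from .model import PneuNet

__all__ = ["GradCAMMap", "grad_cam", "overlay", "save_png"]


@dataclass
class GradCAMMap:
    heatmap: np.ndarray  # (H, W) in [0, 1] at input resolution
    target_layer: str
    class_index: int = 1  # saliency for the pneumonia (sigmoid) output
    flagged_zero: bool = False


def grad_cam(model: PneuNet, image: np.ndarray, target_layer: str = "aspp") -> GradCAMMap:
    """Compute a Grad-CAM heatmap for one preprocessed image (H, W, C)."""
    if target_layer not in PneuNet.SPATIAL_STAGES:
        raise ValueError(
            f"unknown layer {target_layer!r}; available: {list(PneuNet.SPATIAL_STAGES)}")
    image = np.asarray(image, dtype=model.dtype)
    if image.ndim != 3:
        raise ValueError("image must be (H, W, C)")
    p = model.forward(image[None], train=False)
    act = model.activations[target_layer][0]  # (h, w, C)
    # d prob / d logit = p (1 - p) for the sigmoid head
    model.backward(np.asarray(p * (1.0 - p), dtype=model.dtype), capture=target_layer)
    grad = model._stage_grads[target_layer][0]
    weights = grad.mean(axis=(0, 1))                       # (C,)
    cam = np.maximum(np.tensordot(act, weights, axes=([2], [0])), 0.0)
    peak = cam.max()
    flagged = bool(peak <= 0.0)
    if not flagged:
        cam = cam / peak
    full = _resize(cam.astype(np.float64), image.shape[:2], order=1,
                   mode="edge", anti_aliasing=False)
    return GradCAMMap(heatmap=np.clip(full, 0.0, 1.0), target_layer=target_layer,
                      flagged_zero=flagged)


def overlay(image: np.ndarray, cam: GradCAMMap, alpha: float = 0.4,
            colormap: str = "jet") -> np.ndarray:
    """Alpha-blend the colorized heatmap over the grayscale radiograph.

    ``image`` is 2-D grayscale in [0, 1] or [0, 255]; returns an (H, W, 3)
    uint8 RGB image.  alpha=0 reproduces the gray image, alpha=1 the pure
    colorized heatmap.
    """
    from matplotlib import colormaps

    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3 and img.shape[2] == 3:
        img = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    if img.shape != cam.heatmap.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs heatmap {cam.heatmap.shape}")
    if img.max() > 1.0:
        img = img / 255.0
    heat = colormaps[colormap](cam.heatmap)[..., :3]
    gray = np.repeat(img[:, :, None], 3, axis=2)
    blend = (1.0 - alpha) * gray + alpha * heat
    return np.clip(np.round(blend * 255.0), 0, 255).astype(np.uint8)


def save_png(array: np.ndarray, path) -> None:
    """Write a heatmap (float in [0,1]) or RGB uint8 array as PNG."""
    arr = np.asarray(array)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
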