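"""Grad-CAM saliency maps and their ensemble average.

Grad-CAM explains one class score of a CNN: each channel of the chosen
convolutional feature layer is weighted by the spatial mean of the gradient
of that class's logit with respect to the channel, the weighted sum is
rectified (negative evidence zeroed), upsampled bilinearly to the image
size, and min-max normalized into [0, 1] (an all-zero map stays all-zero).

The ensemble map is the pixel-wise arithmetic mean of the per-model maps.
Because each per-model map is normalized before averaging, every model
contributes equally regardless of its raw gradient magnitude; a region that
only one of n models attends to is attenuated to 1/n, which is what makes
spurious background attention fade in the ensemble view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from . import _nn
from .backbone import CLASS_TO_INDEX, TrainedModel, resize_to_input
from .synthgen import CLASSES, PhantomImage


@dataclass(frozen=True)
class HeatMap:
    values: np.ndarray                   # H x W in [0, 1]
    source_models: tuple[str, ...]
    target_class: str

    def __post_init__(self):
        v = self.values
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("heat map values must lie in [0, 1]")


def cam_from_features(features: np.ndarray, grads: np.ndarray) -> np.ndarray:
    """Core Grad-CAM combination on raw arrays (C, h, w) -> (h, w) in [0,1].

    weights = spatial mean of grads per channel; map = ReLU(sum_c w_c A_c),
    then min-max normalized (all-zero maps pass through unchanged).
    """
    if features.shape != grads.shape:
        raise ValueError("features and grads must share a shape")
    weights = grads.mean(axis=(1, 2))
    raw = np.tensordot(weights, features, axes=(0, 0))
    raw = np.maximum(raw, 0.0)
    peak = raw.max()
    if peak > 0:
        lo = raw.min()
        raw = (raw - lo) / (peak - lo) if peak > lo else np.ones_like(raw)
    return raw


def gradcam_heatmap(model: TrainedModel, image: PhantomImage,
                    target_class: str) -> HeatMap:
    """Grad-CAM map for one model/image/class at the image's resolution."""
    if target_class not in CLASSES:
        raise ValueError(f"unknown class {target_class!r}")
    layer = model.spec.target_layer
    if layer not in model.network.stage_names:
        raise ValueError(f"unknown target_layer {layer!r}; "
                         f"stages are {model.network.stage_names}")
    x = resize_to_input(image, model.spec)[None] * 2.0 - 1.0
    logits, feats = model.network.forward(x, capture=layer)
    glogits = np.zeros_like(logits)
    glogits[0, CLASS_TO_INDEX[target_class]] = 1.0
    gfeats = model.network.backward(glogits, stop_at=layer)
    cam = cam_from_features(feats[0].astype(np.float64),
                            gfeats[0].astype(np.float64))
    h, w = image.pixels.shape
    if cam.shape != (h, w):
        cam = _sk_resize(cam, (h, w), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    return HeatMap(values=np.clip(cam, 0.0, 1.0),
                   source_models=(model.name,), target_class=target_class)


def ensemble_heatmap(maps: list[HeatMap],
                     size: tuple[int, int] | None = None) -> HeatMap:
    """Superimpose-and-average: resize each map to a common resolution and
    take the pixel-wise mean (inputs are already in [0, 1], so no
    re-normalization is applied)."""
    if not maps:
        raise ValueError("at least one heat map is required")
    classes = {m.target_class for m in maps}
    if len(classes) > 1:
        raise ValueError(f"maps explain different classes: {sorted(classes)}")
    if size is None:
        size = maps[0].values.shape
    resized = []
    for m in maps:
        v = m.values
        if v.shape != tuple(size):
            v = np.clip(_sk_resize(v, size, order=1, mode="edge",
                                   anti_aliasing=False, preserve_range=True),
                        0.0, 1.0)
        resized.append(v)
    mean = np.mean(resized, axis=0)
    sources = tuple(s for m in maps for s in m.source_models)
    return HeatMap(values=mean, source_models=sources,
                   target_class=maps[0].target_class)


#: fixed overlay colormap (perceptually ordered, common in saliency figures)
OVERLAY_COLORMAP = "jet"


def overlay_heatmap(image: PhantomImage, heat: HeatMap,
                    alpha: float = 0.4) -> np.ndarray:
    """Blend the grayscale image with the colormapped heat map.

    Returns an (H, W, 3) RGB array in [0, 1]:
    out = (1 - alpha) * gray + alpha * colormap(heat).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if image.pixels.shape != heat.values.shape:
        raise ValueError(f"image {image.pixels.shape} and heat map "
                         f"{heat.values.shape} dimensions differ")
    gray = np.repeat(image.pixels[:, :, None], 3, axis=2)
    cmap = colormaps[OVERLAY_COLORMAP]
    colored = cmap(heat.values)[:, :, :3]
    return np.clip((1.0 - alpha) * gray + alpha * colored, 0.0, 1.0)


def save_heatmap_png(heat: HeatMap, path) -> None:
    from PIL import Image
    arr = np.round(heat.values * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_overlay_png(rgb: np.ndarray, path) -> None:
    from PIL import Image
    arr = np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)
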