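"""Class-activation heatmaps and hotspot-region classification.

Gradient-weighted class activation mapping (Grad-CAM) localises the image
evidence behind a node's metastasis score: each feature map of the last
convolutional stage is weighted by the spatial mean of the metastasis-logit
gradient with respect to it, the weighted sum is rectified, upsampled to
the patch grid and min-max normalised.

The hotspot classifier then assigns each heatmap to the anatomical region
carrying most of its supra-threshold mass: *intranodal* (inside the node
mask), *perinodal* (a thin dilation ring around the mask, by default 3 mm
of surrounding tissue) or *outside*; an everywhere-zero map is labelled
*none*. Only the convolutional intensity network yields a spatial map —
the feature-fusion perceptron has no spatial structure to attribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, generate_binary_structure, iterate_structure
from skimage.transform import resize

from .errors import MeasurementError, UnsupportedModelError
from .features import normalize_intensity

__all__ = ["Heatmap", "gradcam", "classify_hotspot", "explain_node"]

HOTSPOT_LABELS = ("intranodal", "perinodal", "outside", "none")


@dataclass
class Heatmap:
    """A normalised relevance map plus its hotspot-region call."""

    map: np.ndarray
    hotspot_label: str
    hotspot_fractions: dict


def _intensity_net_of(model):
    net = getattr(model, "intensity_net", None)
    if net is None and hasattr(type(model), "feature_maps"):
        net = model
    if net is None or not hasattr(net, "forward") or not hasattr(net, "backward"):
        raise UnsupportedModelError(
            "gradcam: model exposes no convolutional feature maps "
            "(fusion-only scorers cannot be spatially attributed)"
        )
    return net


def gradcam(model, patch: np.ndarray, normalize_input: bool = True) -> np.ndarray:
    """Grad-CAM relevance map of the metastasis logit over one patch.

    Parameters
    ----------
    model : WisdomResults or IntensityNet
        A fitted model (its intensity network is used) or the network
        itself.
    patch : 2-D array
        The node patch; robust-normalised first unless
        ``normalize_input=False`` (the network was trained on normalised
        patches).

    Returns
    -------
    2-D array with values in [0, 1], the same shape as ``patch``; an
    all-zero pre-normalisation map stays all-zero.
    """
    net = _intensity_net_of(model)
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2:
        raise MeasurementError(f"gradcam: patch must be 2-D, got {patch.ndim}-D")
    x = normalize_intensity(patch) if normalize_input else patch
    x = x.astype(np.float32)[None, None, :, :]
    net.forward(x)
    feats = net.feature_maps[0]  # (C, h, w)
    dfeat = net.backward(np.ones(1, dtype=np.float32), to_features_only=True)[0]
    weights = dfeat.mean(axis=(1, 2))  # spatial mean of gradients
    cam = np.maximum((weights[:, None, None] * feats).sum(axis=0), 0.0)
    cam = resize(
        cam, patch.shape, order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    top = cam.max()
    if top <= 0:
        return np.zeros(patch.shape)
    return np.clip(cam / top, 0.0, 1.0)


def _disk(radius_px: int) -> np.ndarray:
    struct = generate_binary_structure(2, 1)
    return iterate_structure(struct, radius_px)


def classify_hotspot(
    map: np.ndarray,
    mask: np.ndarray,
    ring_px: int = 6,
    level: float = 0.5,
) -> tuple[str, dict]:
    """Assign a heatmap to the region holding most supra-threshold pixels.

    Pixels with ``map >= level * max(map)`` form the hotspot set; the
    intranodal region is the mask, the perinodal region is a morphological
    dilation of the mask by ``ring_px`` minus the mask, and everything else
    is outside. Ties break ``intranodal > perinodal > outside``; a map with
    no positive values is labelled ``"none"``. Fractions over the three
    regions are reported and sum to 1 unless the label is ``"none"``.
    """
    map = np.asarray(map, dtype=float)
    mask = np.asarray(mask) > 0.5
    if map.shape != mask.shape:
        raise MeasurementError(
            f"classify_hotspot: shape mismatch map {map.shape} vs mask {mask.shape}"
        )
    if ring_px < 1:
        raise MeasurementError(f"classify_hotspot: ring_px must be >= 1, got {ring_px}")
    if not 0.0 < level < 1.0:
        raise MeasurementError(f"classify_hotspot: level must be in (0, 1), got {level}")
    fractions = {"intranodal": 0.0, "perinodal": 0.0, "outside": 0.0}
    top = map.max()
    if top <= 0:
        return "none", fractions
    hot = map >= level * top
    n_hot = int(hot.sum())
    ring = binary_dilation(mask, structure=_disk(ring_px)) & ~mask
    fractions["intranodal"] = float((hot & mask).sum()) / n_hot
    fractions["perinodal"] = float((hot & ring).sum()) / n_hot
    fractions["outside"] = float((hot & ~mask & ~ring).sum()) / n_hot
    label = max(
        ("intranodal", "perinodal", "outside"),
        key=lambda k: (fractions[k], -("intranodal", "perinodal", "outside").index(k)),
    )
    return label, fractions


def ring_px_for_spacing(spacing_mm: float, ring_mm: float = 3.0) -> int:
    """Dilation radius in pixels covering ``ring_mm`` of perinodal tissue."""
    return max(int(math.ceil(ring_mm / spacing_mm)), 1)


def explain_node(model, node, spacing_mm: float = 0.5, level: float = 0.5) -> Heatmap:
    """Grad-CAM plus hotspot classification for one lymph-node instance."""
    cam = gradcam(model, node.patch)
    label, fractions = classify_hotspot(
        cam, node.mask, ring_px=ring_px_for_spacing(spacing_mm), level=level
    )
    return Heatmap(map=cam, hotspot_label=label, hotspot_fractions=fractions)
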