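"""Squeeze-and-excitation channel attention and Grad-CAM map combination.

Pure array math, framework-free: feature maps are H x W x C tensors and
gradients are supplied by the caller (e.g. analytic gradients of a toy
scorer) rather than back-propagated through a network.

The SE block squeezes a feature map to per-channel spatial means, passes
them through a two-layer bottleneck gate s = sigmoid(W2 relu(W1 z)) and
rescales each channel by its gate.  Grad-CAM reduces a gradient tensor to
per-channel importance scores (spatial means) and forms the heatmap
relu(sum_m gamma_m F^m).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "SEWeights",
    "squeeze",
    "excite",
    "se_recalibrate",
    "gradcam_channel_weights",
    "gradcam_map",
    "minmax_scale_map",
    "export_heatmap_png",
]


def _check_feature_map(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 3 or min(u.shape) < 1:
        raise ValueError("feature map must be an H x W x C tensor")
    if not np.all(np.isfinite(u)):
        raise ValueError("feature map must be finite")
    return u


@dataclass(frozen=True)
class SEWeights:
    """Excitation-MLP weights with channel bottleneck C -> C/r -> C.

    No bias terms by default; the reduced width is max(1, floor(C/r)) so
    small fixture channel counts remain valid.  ``reduction`` defaults to 16.
    """

    w1: np.ndarray  # (C/r) x C
    w2: np.ndarray  # C x (C/r)
    reduction: int = 16
    b1: Optional[np.ndarray] = None
    b2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        w1 = np.asarray(self.w1, dtype=float)
        w2 = np.asarray(self.w2, dtype=float)
        if w1.ndim != 2 or w2.ndim != 2 or w2.shape != w1.shape[::-1]:
            raise ValueError("w2 must be the transposed shape of w1 (C x C/r)")
        object.__setattr__(self, "w1", w1)
        object.__setattr__(self, "w2", w2)

    @property
    def n_channels(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def random(
        cls,
        n_channels: int,
        reduction: int = 16,
        rng: Optional[np.random.Generator] = None,
        scale: float = 1.0,
        bias: bool = False,
    ) -> "SEWeights":
        """Gaussian-initialized gate weights for fixtures and demos."""
        rng = rng or np.random.default_rng()
        hidden = max(1, n_channels // reduction)
        w1 = rng.normal(0.0, scale, size=(hidden, n_channels))
        w2 = rng.normal(0.0, scale, size=(n_channels, hidden))
        b1 = rng.normal(0.0, scale, size=hidden) if bias else None
        b2 = rng.normal(0.0, scale, size=n_channels) if bias else None
        return cls(w1=w1, w2=w2, reduction=reduction, b1=b1, b2=b2)


def squeeze(u: np.ndarray) -> np.ndarray:
    """Global average pooling: z_c = spatial mean of channel c."""
    return _check_feature_map(u).mean(axis=(0, 1))


def excite(z: np.ndarray, weights: SEWeights) -> np.ndarray:
    """Gate vector s = sigmoid(W2 relu(W1 z)), strictly inside (0, 1)."""
    z = np.asarray(z, dtype=float)
    if z.shape != (weights.n_channels,):
        raise ValueError("descriptor length must equal the channel count")
    h = weights.w1 @ z
    if weights.b1 is not None:
        h = h + weights.b1
    h = np.maximum(h, 0.0)
    a = weights.w2 @ h
    if weights.b2 is not None:
        a = a + weights.b2
    return 1.0 / (1.0 + np.exp(-a))


def se_recalibrate(u: np.ndarray, weights: SEWeights) -> np.ndarray:
    """Rescale each channel of U by its excitation gate."""
    u = _check_feature_map(u)
    if u.shape[2] != weights.n_channels:
        raise ValueError("weights were built for a different channel count")
    s = excite(squeeze(u), weights)
    return u * s[None, None, :]


def gradcam_channel_weights(grads: np.ndarray) -> np.ndarray:
    """Per-channel importance: spatial mean of the class-score gradient."""
    grads = _check_feature_map(grads)
    return grads.mean(axis=(0, 1))


def gradcam_map(u: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Class activation heatmap relu(sum_m gamma_m F^m); nonnegative H x W."""
    u = _check_feature_map(u)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (u.shape[2],):
        raise ValueError("gamma length must equal the channel count")
    return np.maximum(np.tensordot(u, gamma, axes=([2], [0])), 0.0)


def minmax_scale_map(heatmap: np.ndarray) -> np.ndarray:
    """Presentation-only rescale of a heatmap to [0, 1] (constant maps -> 0)."""
    h = np.asarray(heatmap, dtype=float)
    lo, hi = h.min(), h.max()
    if hi == lo:
        return np.zeros_like(h)
    return (h - lo) / (hi - lo)


def export_heatmap_png(heatmap: np.ndarray, path: Union[str, Path]) -> None:
    """Write a heatmap as an 8-bit grayscale PNG (min-max scaled)."""
    from PIL import Image

    scaled = (minmax_scale_map(heatmap) * 255.0).round().astype(np.uint8)
    Image.fromarray(scaled, mode="L").save(Path(path))
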