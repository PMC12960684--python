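"""Image preprocessing, augmentation, SMOTE class balancing and manifests.

Grayscale images are plain H x W float arrays.  The augmentation suite
mirrors a CT-style training pipeline: small random rotations (within ±10
degrees), translations up to 10% per axis, horizontal flips and 5x5 Gaussian
blurring.  SMOTE brings every class up to the majority count by
interpolating between a minority sample and one of its k nearest same-class
neighbors.  A :class:`ClassManifest` holds per-class / per-image-size sample
counts for dataset accounting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import ndimage
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "FeatureTable",
    "ClassManifest",
    "LUNG_CT_MANIFEST",
    "PRE_SMOTE_COUNTS",
    "minmax_normalize",
    "augment",
    "AUGMENT_OPS",
    "gaussian_kernel_sigma",
    "smote_balance",
    "summarize_manifest",
]

logger = logging.getLogger(__name__)

AUGMENT_OPS = ("rotate", "translate", "hflip", "gaussian_blur")

MAX_ROTATION_DEG = 10.0
MAX_TRANSLATE_FRAC = 0.1
BLUR_KERNEL_SIZE = 5


def minmax_normalize(
    image: np.ndarray, out_min: float = 0.0, out_max: float = 1.0
) -> np.ndarray:
    """Affine rescale of the image's intensity range onto [out_min, out_max].

    A constant image has no intensity range; it maps to all-``out_min`` with
    a warning (documented convention).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 1:
        raise ValueError("image must be a 2-D H x W array")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if not out_min < out_max:
        raise ValueError("out_min must be < out_max")
    lo, hi = img.min(), img.max()
    if hi == lo:
        warnings.warn(
            "constant image has no intensity range; returning all-out_min",
            stacklevel=2,
        )
        return np.full_like(img, out_min)
    return (img - lo) * (out_max - out_min) / (hi - lo) + out_min


def gaussian_kernel_sigma(ksize: int = BLUR_KERNEL_SIZE) -> float:
    """Kernel-derived automatic blur sigma: 0.3*((ksize-1)*0.5 - 1) + 0.8."""
    return 0.3 * ((ksize - 1) * 0.5 - 1.0) + 0.8


def _gaussian_kernel(ksize: int, sigma: float) -> np.ndarray:
    half = (ksize - 1) / 2.0
    ax = np.arange(ksize) - half
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def augment(
    image: np.ndarray,
    op_name: str,
    params: Optional[Mapping[str, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Apply one augmentation transform; output has the input's shape.

    Rotation angle must lie within ±10 degrees and translations within 10%
    of each axis (values outside those ranges are rejected); when a needed
    parameter is absent it is drawn uniformly from the allowed range using
    ``rng``.  Rotation and translation use bilinear interpolation with zero
    fill outside the frame; the blur uses a 5x5 Gaussian kernel with the
    automatic sigma and reflective borders.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be a 2-D H x W array")
    params = dict(params or {})
    rng = rng or np.random.default_rng()

    if op_name == "rotate":
        theta = params.get("angle")
        if theta is None:
            theta = rng.uniform(-MAX_ROTATION_DEG, MAX_ROTATION_DEG)
        if abs(theta) > MAX_ROTATION_DEG:
            raise ValueError(
                f"rotation angle {theta} outside ±{MAX_ROTATION_DEG} degrees"
            )
        return ndimage.rotate(
            img, theta, reshape=False, order=1, mode="constant", cval=0.0
        )
    if op_name == "translate":
        h, w = img.shape
        dx = params.get("dx")
        dy = params.get("dy")
        if dx is None:
            dx = rng.uniform(-MAX_TRANSLATE_FRAC, MAX_TRANSLATE_FRAC) * w
        if dy is None:
            dy = rng.uniform(-MAX_TRANSLATE_FRAC, MAX_TRANSLATE_FRAC) * h
        if abs(dx) > MAX_TRANSLATE_FRAC * w or abs(dy) > MAX_TRANSLATE_FRAC * h:
            raise ValueError(
                f"translation ({dx}, {dy}) exceeds {MAX_TRANSLATE_FRAC:.0%} "
                "of the image size"
            )
        return ndimage.shift(
            img, (dy, dx), order=1, mode="constant", cval=0.0
        )
    if op_name == "hflip":
        return np.fliplr(img)
    if op_name == "gaussian_blur":
        sigma = params.get("sigma", gaussian_kernel_sigma())
        kernel = _gaussian_kernel(BLUR_KERNEL_SIZE, sigma)
        return ndimage.convolve(img, kernel, mode="reflect")
    raise ValueError(f"unknown augmentation {op_name!r}; choose from {AUGMENT_OPS}")


@dataclass
class FeatureTable:
    """n x D feature matrix with aligned integer class labels."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if x.ndim != 2 or x.shape[0] < 1:
            raise ValueError("features must be an n x D matrix with n >= 1")
        if y.shape != (x.shape[0],):
            raise ValueError("labels must align with feature rows")
        self.features = x
        self.labels = y

    def class_counts(self) -> Dict[int, int]:
        classes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))


def smote_balance(
    table: FeatureTable,
    k: int = 5,
    rng: Optional[np.random.Generator] = None,
) -> FeatureTable:
    """Oversample every minority class up to the majority count.

    Each synthetic point is x_i + lambda (x_nn - x_i) with lambda ~ U(0,1)
    and x_nn one of x_i's k nearest same-class neighbors (Euclidean); k is
    reduced to class_size - 1 when a class is smaller than k + 1.  Original
    rows are preserved verbatim, synthetics are appended after them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = rng or np.random.default_rng()
    counts = table.class_counts()
    target = max(counts.values())
    for cls, n in counts.items():
        if n < target and n < 2:
            raise ValueError(
                f"class {cls} has a single sample; SMOTE interpolation "
                "is undefined"
            )
    new_features = [table.features]
    new_labels = [table.labels]
    for cls, n in sorted(counts.items()):
        deficit = target - n
        if deficit == 0:
            continue
        pts = table.features[table.labels == cls]
        k_eff = min(k, n - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pts)
        # first neighbor is the point itself; drop it
        neighbors = nn.kneighbors(pts, return_distance=False)[:, 1:]
        parents = rng.integers(0, n, size=deficit)
        picks = rng.integers(0, k_eff, size=deficit)
        lam = rng.random(deficit)
        base = pts[parents]
        partner = pts[neighbors[parents, picks]]
        synthetic = base + lam[:, None] * (partner - base)
        new_features.append(synthetic)
        new_labels.append(np.full(deficit, cls, dtype=int))
        logger.info("SMOTE: class %s %d -> %d samples", cls, n, target)
    return FeatureTable(
        features=np.vstack(new_features), labels=np.concatenate(new_labels)
    )


@dataclass
class ClassManifest:
    """Per-class, per-image-size sample counts.

    ``entries`` maps class name -> {image-size string -> count}.
    """

    entries: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def add(self, class_name: str, image_size: str, count: int) -> None:
        if count < 0 or count != int(count):
            raise ValueError("counts must be nonnegative integers")
        self.entries.setdefault(class_name, {})[image_size] = int(count)


def summarize_manifest(manifest: ClassManifest) -> Dict[str, object]:
    """Per-class totals and the grand total of a dataset manifest."""
    per_class = {
        cls: sum(sizes.values()) for cls, sizes in manifest.entries.items()
    }
    return {"per_class": per_class, "total": sum(per_class.values())}


# Published class / image-size distribution of the IQ-OTH/NCCD lung-CT
# collection, used for manifest accounting (no image data is consumed).
LUNG_CT_MANIFEST = ClassManifest(
    entries={
        "Benign": {"512x512": 120},
        "Malignant": {"512x512": 501, "512x623": 31, "512x801": 28, "404x511": 1},
        "Normal": {"512x512": 415, "331x506": 1},
    }
)

# Published pre-balancing class counts used by the SMOTE worked example.
PRE_SMOTE_COUNTS = {"Benign": 420, "Malignant": 312, "Normal": 90}
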