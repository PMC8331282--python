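"""Ground-truthed synthetic phantoms for intensity-based segmentation.

The phantom mimics the concentric tissue arrangement of an axial brain MRI
slice with nested ellipses: an outer tissue shell (class 1), an annulus
(class 2), a central blob (class 3), and so on for higher class counts;
everything outside the outer ellipse is background 0.  The nested ellipse
radii are chosen so every tissue class covers the same in-brain area.  Each
class has a constant mean intensity; pixelwise Gaussian noise and an
optional smooth multiplicative bias field are added on top, and the image is
clipped to [0, 1].  The geometry depends only on the shape and class count;
the seed drives noise alone, so two seeds share identical ground truth.

Partial supervision is sampled from the ground truth, stratified per class,
to stand in for the expert-labeled pixels that drive the semisupervised
membership update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .clustering import SupervisionInfo
from .image import ImageVolume, InputError, SegmentationMap

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "sample_supervision"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    ``class_intensities`` are the noise-free per-class means on the [0, 1]
    intensity scale and must be strictly increasing; ``noise_sigma`` is the
    SD of the additive Gaussian noise; ``bias_amplitude`` scales a smooth
    multiplicative field ``1 + a*g(x, y)`` with ``g`` in [-1, 1] (0 turns
    the bias off).
    """

    shape: tuple = (128, 128)
    n_classes: int = 3
    class_intensities: tuple = (0.3, 0.55, 0.8)
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 2 or any(s < 8 for s in self.shape):
            raise InputError("shape must be 2-D with sides >= 8")
        if self.n_classes < 1:
            raise InputError("need at least one tissue class")
        vals = tuple(float(v) for v in self.class_intensities)
        if len(vals) != self.n_classes:
            raise InputError(
                f"{self.n_classes} classes need {self.n_classes} intensities"
            )
        if any(not 0 < v < 1 for v in vals):
            raise InputError("class intensities must lie in (0, 1)")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise InputError("class intensities must be strictly increasing")
        if self.noise_sigma < 0:
            raise InputError("noise_sigma must be nonnegative")
        object.__setattr__(self, "class_intensities", vals)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))


@dataclass(frozen=True)
class Phantom:
    """A synthetic image with its exact ground-truth label map."""

    image: ImageVolume
    truth: SegmentationMap
    spec: PhantomSpec


def _ellipse_param(shape: tuple) -> np.ndarray:
    """Normalized squared elliptical radius; <= 1 inside the outer ellipse."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = 0.42 * h, 0.38 * w
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the phantom image and its ground-truth segmentation."""
    c = spec.n_classes
    r2 = _ellipse_param(spec.shape)
    truth = np.zeros(spec.shape, dtype=np.int64)
    # nested ellipses with equal-area annuli: class j fills r2 <= (c-j+1)/c
    for j in range(1, c + 1):
        truth[r2 <= (c - j + 1) / c] = j
    counts = np.bincount(truth.ravel(), minlength=c + 1)[1:]
    in_brain = counts.sum()
    if (counts == 0).any() or (counts < 0.01 * in_brain).any():
        raise InputError(
            "phantom geometry leaves a tissue class under 1% of the brain; "
            "use a larger shape or fewer classes"
        )

    image = np.zeros(spec.shape, dtype=float)
    for j, v in enumerate(spec.class_intensities, start=1):
        image[truth == j] = v
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    if spec.bias_amplitude != 0.0:
        image = image * (1.0 + spec.bias_amplitude * _bias_field(spec.shape))
    image = np.clip(image, 0.0, 1.0)
    return Phantom(
        image=ImageVolume(image, provenance="synthetic"),
        truth=SegmentationMap(truth),
        spec=spec,
    )


def _bias_field(shape: tuple) -> np.ndarray:
    """Smooth low-frequency field g(x, y) in [-1, 1]."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    g = np.sin(np.pi * yy / (h - 1)) * np.sin(np.pi * xx / (w - 1))
    return 2.0 * g - 1.0


def sample_supervision(
    truth: SegmentationMap, fraction: float, seed: int = 0
) -> SupervisionInfo:
    """Sample crisp partial labels from the ground truth.

    Selects ``ceil(fraction * n)`` of the n in-brain pixels uniformly at
    random, stratified per class with a largest-remainder allocation so
    per-class counts stay within one of proportionality and every class gets
    at least one labeled pixel.  The returned columns are ordered like the
    rows of ``extract_features(image, mask=truth.labels > 0)``, i.e.
    row-major over in-brain pixels.
    """
    if not 0 < fraction <= 1:
        raise InputError("supervision fraction must lie in (0, 1]")
    flat = truth.labels[truth.labels > 0]  # row-major in-brain labels
    n = flat.size
    if n == 0:
        raise InputError("ground truth has no in-brain pixels")
    c = int(flat.max())
    counts = np.bincount(flat, minlength=c + 1)[1:]
    if (counts == 0).any():
        raise InputError("every class needs at least one in-brain pixel")

    m = math.ceil(fraction * n)
    quota = _stratified_quota(counts, m)
    rng = np.random.default_rng(seed)
    labels = np.full(n, -1, dtype=np.int64)
    for j in range(1, c + 1):
        pool = np.flatnonzero(flat == j)
        chosen = rng.choice(pool, size=quota[j - 1], replace=False)
        labels[chosen] = j - 1
    return SupervisionInfo.from_labels(labels, n_clusters=c)


def _stratified_quota(counts: np.ndarray, m: int) -> np.ndarray:
    """Largest-remainder apportionment of m picks, each class >= 1."""
    c = counts.size
    m = max(m, c)
    share = m * counts / counts.sum()
    quota = np.floor(share).astype(np.int64)
    remainder = share - quota
    for idx in np.argsort(-remainder, kind="stable")[: m - quota.sum()]:
        quota[idx] += 1
    # enforce the floor of one, taking from the largest other quota
    for i in np.flatnonzero(quota == 0):
        quota[i] = 1
        donors = np.flatnonzero(quota >= 2)
        if donors.size:
            quota[donors[np.argmax(quota[donors])]] -= 1
    return np.minimum(quota, counts)
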