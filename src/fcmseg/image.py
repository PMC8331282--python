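"""Image I/O and the pixel <-> feature-matrix plumbing around the clustering.

Reads 2-D grayscale images (PNG/TIFF) and 3-D volumes (NIfTI), min-max
normalizes intensities, flattens in-mask pixels to a feature matrix in
row-major order, and scatters hard cluster labels back into a label map
(background reserved as 0, tissue classes 1..c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "InputError",
    "ImageVolume",
    "SegmentationMap",
    "load_image",
    "normalize",
    "extract_features",
    "labels_to_map",
    "save_segmentation",
    "load_segmentation",
]


class InputError(ValueError):
    """Unreadable, unsupported or inconsistent user input."""


_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_SLICE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass
class ImageVolume:
    """A 2-D image or 3-D volume of real-valued intensities."""

    intensities: np.ndarray
    spacing: Optional[tuple] = None
    provenance: str = "memory"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim not in (2, 3):
            raise InputError("intensities must be 2-D or 3-D")
        if not np.isfinite(arr).all():
            raise InputError("intensities must be finite")
        self.intensities = arr

    @property
    def shape(self) -> tuple:
        return self.intensities.shape


@dataclass
class SegmentationMap:
    """Integer label map; 0 is background, classes are 1..c."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            raise InputError("labels must be integers")
        if (arr < 0).any():
            raise InputError("labels must be nonnegative")
        self.labels = arr

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def load_image(path) -> ImageVolume:
    """Load a PNG/TIFF slice or a NIfTI volume as real intensities.

    RGB(A) slices are converted to grayscale by the mean of the color
    channels.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such image: {path}")
    try:
        if _is_nifti(path):
            import nibabel as nib

            img = nib.load(str(path))
            arr = np.asarray(img.get_fdata(), dtype=float)
            spacing = tuple(float(z) for z in img.header.get_zooms()[: arr.ndim])
            return ImageVolume(arr, spacing=spacing, provenance=str(path))
        if path.suffix.lower() in _SLICE_SUFFIXES:
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path), dtype=float)
            if arr.ndim == 3:  # RGB(A) -> grayscale via channel mean
                arr = arr[..., :3].mean(axis=-1)
            return ImageVolume(arr, provenance=str(path))
    except InputError:
        raise
    except Exception as exc:
        raise InputError(f"could not read image {path}: {exc}") from exc
    raise InputError(
        f"unsupported image format {path.suffix!r} for {path} "
        "(expected PNG/TIFF or NIfTI)"
    )


def normalize(image: ImageVolume) -> ImageVolume:
    """Min-max scale intensities to [0, 1].

    A constant image cannot be rescaled; it maps to all zeros with a
    warning.
    """
    arr = image.intensities
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        warnings.warn(
            "constant image: normalization returns all zeros", stacklevel=2
        )
        out = np.zeros_like(arr)
    else:
        out = (arr - lo) / (hi - lo)
    return ImageVolume(out, spacing=image.spacing, provenance=image.provenance)


def extract_features(
    image: ImageVolume,
    mask: Optional[np.ndarray] = None,
    neighborhood_mean: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten in-mask pixels into an n x d feature matrix.

    Features are intensity only (d=1) or intensity plus the edge-replicated
    3x3 (3x3x3 for volumes) neighborhood mean (d=2).  Returns the feature
    matrix and an index map of pixel coordinates, both in row-major pixel
    order, so the k-th matrix row corresponds to pixel
    ``tuple(index_map[k])``.
    """
    arr = image.intensities
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape:
        raise InputError(
            f"mask shape {mask.shape} does not match image shape {arr.shape}"
        )
    if not mask.any():
        raise InputError("mask selects no pixels")
    cols = [arr[mask]]
    if neighborhood_mean:
        smoothed = ndimage.uniform_filter(arr, size=3, mode="nearest")
        cols.append(smoothed[mask])
    features = np.column_stack(cols)
    index_map = np.argwhere(mask)  # row-major by construction
    return features, index_map


def labels_to_map(
    labels: np.ndarray,
    index_map: np.ndarray,
    shape: tuple,
    mask: Optional[np.ndarray] = None,
) -> SegmentationMap:
    """Scatter cluster labels back to pixel positions.

    In-mask pixels receive ``cluster label + 1``; everything else is
    background 0.
    """
    labels = np.asarray(labels)
    index_map = np.asarray(index_map)
    if labels.shape[0] != index_map.shape[0]:
        raise ValueError(
            f"{labels.shape[0]} labels for {index_map.shape[0]} pixel "
            "coordinates"
        )
    if mask is not None and int(np.asarray(mask, bool).sum()) != labels.shape[0]:
        raise ValueError("mask pixel count does not match label count")
    out = np.zeros(shape, dtype=np.int64)
    out[tuple(index_map.T)] = labels + 1
    return SegmentationMap(out)


def save_segmentation(segmap: SegmentationMap, path) -> Path:
    """Write a label map: indexed PNG for 2-D, integer NIfTI for 3-D.

    Loading the file back with :func:`load_segmentation` recovers the exact
    label array.
    """
    path = Path(path)
    labels = segmap.labels
    try:
        if labels.ndim == 2:
            if not _is_nifti(path) and path.suffix.lower() != ".png":
                raise InputError(f"2-D label maps are written as PNG: {path}")
            if labels.max() > 255:
                raise InputError("indexed PNG supports at most 255 classes")
            from PIL import Image

            img = Image.fromarray(labels.astype(np.uint8), mode="P")
            img.putpalette(_label_palette())
            img.save(path, format="PNG")
        else:
            if not _is_nifti(path):
                raise InputError(f"3-D label maps are written as NIfTI: {path}")
            import nibabel as nib

            nib.Nifti1Image(labels.astype(np.int16), np.eye(4)).to_filename(
                str(path)
            )
    except InputError:
        raise
    except Exception as exc:
        raise InputError(f"could not write {path}: {exc}") from exc
    return path


def load_segmentation(path) -> SegmentationMap:
    """Read a label map written by :func:`save_segmentation`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such label map: {path}")
    if _is_nifti(path):
        import nibabel as nib

        arr = np.asarray(nib.load(str(path)).dataobj).astype(np.int64)
        return SegmentationMap(arr)
    from PIL import Image

    with Image.open(path) as img:
        arr = np.asarray(img, dtype=np.int64)
    return SegmentationMap(arr)


def _label_palette(n: int = 256) -> list[int]:
    """Distinct, deterministic RGB palette; index 0 is black background."""
    rng = np.random.default_rng(12345)
    base = np.array(
        [
            [0, 0, 0],
            [230, 80, 60],
            [70, 160, 230],
            [90, 200, 120],
            [240, 200, 60],
            [170, 110, 220],
            [240, 140, 40],
            [110, 220, 220],
        ]
    )
    extra = rng.integers(30, 255, size=(n - len(base), 3))
    return np.vstack([base, extra])[:n].astype(np.uint8).ravel().tolist()
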