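"""Radiograph preprocessing: lung segmentation, tight crop, resize, scaling.

The pipeline turns an 8-bit grayscale chest radiograph plus a binary
lung-field mask into the fixed backbone input: the tightest axis-aligned
bounding box around all lung pixels is cropped (inclusive bounds), resized
to 224x224 with bilinear interpolation, replicated to three channels and
scaled to [-1, 1] via x/127.5 - 1.

Segmentation itself is a pluggable backend.  Two backends ship:

* ``OracleMaskBackend`` — returns a mask supplied alongside the image
  (e.g. a ``*_mask.png`` file); used for fixtures and for externally
  produced masks.
* ``ThresholdBackend`` — Otsu threshold plus the two largest connected
  components; adequate for synthetic fixtures, not for clinical images.

A deep-learning mask model (or an anatomical rib-based segmenter) can be
registered as another backend without touching the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from PIL import Image

__all__ = [
    "DEFAULT_IMAGE_SIZE",
    "DEFAULT_MASK_SUFFIX",
    "BoundingBox",
    "SegmentationBackend",
    "OracleMaskBackend",
    "ThresholdBackend",
    "load_gray_image",
    "load_mask",
    "segment_lungs",
    "lung_bounding_box",
    "crop_resize_normalize",
    "preprocess",
]

DEFAULT_IMAGE_SIZE = 224
DEFAULT_MASK_SUFFIX = "_mask"


def load_gray_image(path: str | Path) -> np.ndarray:
    """Read an image file as a 2-D uint8 array (DICOM supported if pydicom is installed)."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading DICOM requires pydicom") from exc
        arr = pydicom.dcmread(str(path)).pixel_array.astype(float)
        lo, hi = arr.min(), arr.max()
        if hi > lo:
            arr = (arr - lo) / (hi - lo) * 255.0
        return np.round(arr).astype(np.uint8)
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask file; nonzero pixels are lung."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 0


@runtime_checkable
class SegmentationBackend(Protocol):
    """Contract: map a grayscale image to a boolean lung mask of equal shape."""

    def segment(self, image: np.ndarray) -> np.ndarray: ...


@dataclass
class OracleMaskBackend:
    """Returns a pre-supplied mask (array or mask-file path) verbatim."""

    mask: np.ndarray | str | Path

    def segment(self, image: np.ndarray) -> np.ndarray:
        if isinstance(self.mask, (str, Path)):
            return load_mask(self.mask)
        return np.asarray(self.mask, dtype=bool)


@dataclass
class ThresholdBackend:
    """Otsu threshold + up to two largest connected components.

    ``polarity='bright'`` keeps above-threshold pixels (synthetic fixtures
    render lung fields bright); ``'dark'`` keeps below-threshold pixels.
    """

    polarity: str = "bright"

    def segment(self, image: np.ndarray) -> np.ndarray:
        from skimage.filters import threshold_otsu
        from skimage.measure import label

        thr = threshold_otsu(image)
        fg = image > thr if self.polarity == "bright" else image < thr
        lab = label(fg)
        if lab.max() == 0:
            return np.zeros_like(fg)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        keep = np.argsort(sizes)[::-1][:2]
        keep = [k for k in keep if sizes[k] > 0]
        return np.isin(lab, keep)


def segment_lungs(image: np.ndarray, backend: SegmentationBackend) -> np.ndarray:
    """Run a segmentation backend and validate its output contract."""
    image = np.asarray(image)
    mask = np.asarray(backend.segment(image), dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(
            f"segmentation backend returned shape {mask.shape}, expected {image.shape}"
        )
    if not mask.any():
        raise ValueError("segmentation produced an empty lung mask (degenerate segmentation)")
    return mask


@dataclass(frozen=True)
class BoundingBox:
    """0-based inclusive pixel bounds of the lung fields."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self):
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError(f"degenerate bounding box {self}")
        if min(self.row_min, self.col_min) < 0:
            raise ValueError(f"negative bounding box coordinate in {self}")


def lung_bounding_box(mask: np.ndarray) -> BoundingBox:
    """Tightest axis-aligned box containing every true pixel (both lungs jointly)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot compute bounding box of an empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return BoundingBox(int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1]))


def crop_resize_normalize(
    image: np.ndarray, box: BoundingBox, size: int = DEFAULT_IMAGE_SIZE
) -> np.ndarray:
    """Crop to ``box`` (inclusive), resize bilinearly, replicate channels, scale.

    Output is ``size x size x 3`` float64 in [-1, 1] (x/127.5 - 1), with all
    three channels identical.
    """
    image = np.asarray(image)
    if box.row_max >= image.shape[0] or box.col_max >= image.shape[1]:
        raise ValueError(f"bounding box {box} exceeds image shape {image.shape}")
    crop = image[box.row_min : box.row_max + 1, box.col_min : box.col_max + 1]
    # float32 'F' mode keeps bilinear interpolation unquantized (no antialias)
    resized = np.asarray(
        Image.fromarray(crop.astype(np.float32), mode="F").resize(
            (size, size), Image.BILINEAR
        ),
        dtype=float,
    )
    scaled = resized / 127.5 - 1.0
    np.clip(scaled, -1.0, 1.0, out=scaled)
    return np.repeat(scaled[:, :, None], 3, axis=2)


def preprocess(
    image: np.ndarray,
    backend: SegmentationBackend,
    size: int = DEFAULT_IMAGE_SIZE,
) -> np.ndarray:
    """Full pipeline: segment -> bounding box -> crop/resize/normalize."""
    mask = segment_lungs(image, backend)
    box = lung_bounding_box(mask)
    return crop_resize_normalize(image, box, size=size)
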