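"""Image preprocessing: ROI extraction, size normalization, gray normalization.

The internal intensity convention is real-valued [0, 1]; 8-bit files are
divided by 255 on read.  The chain ``extract_roi -> normalize_size ->
normalize_gray`` turns a raw near-infrared finger frame (nominally 320x240)
into the fixed-size normalized region (default 96x64) that feature
extraction consumes.

The finger appears as a bright blob on a dark background in transmitted
near-infrared light, so the ROI is found by Otsu thresholding followed by a
largest-connected-component bounding-box crop; degenerate frames fall back
to a central crop.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import measure, transform
from skimage.filters import threshold_otsu

from .exceptions import InvalidInputError

__all__ = ["load_image", "extract_roi", "normalize_size", "normalize_gray", "preprocess"]

logger = logging.getLogger(__name__)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/BMP/PGM file as a float [0, 1] grayscale array.

    Color inputs are luma-converted.
    """
    with Image.open(path) as im:
        gray = im.convert("L")
        return np.asarray(gray, dtype=np.float64) / 255.0


def _check_2d(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    return arr


def _central_crop(arr: np.ndarray, fraction: float = 0.75) -> np.ndarray:
    h, w = arr.shape
    ch, cw = int(round(h * fraction)), int(round(w * fraction))
    top, left = (h - ch) // 2, (w - cw) // 2
    return arr[top : top + ch, left : left + cw]


def extract_roi(raw: np.ndarray) -> np.ndarray:
    """Crop the finger region out of a raw frame.

    Threshold at Otsu's level, keep the largest connected foreground
    component, and return its tight bounding-box crop.  If the foreground
    mask is empty or covers the whole frame (e.g. a constant image), fall
    back to the central crop occupying the middle 75% of each dimension and
    log a warning.
    """
    arr = _check_2d(raw)
    h, w = arr.shape
    if h < 32 or w < 32:
        raise InvalidInputError(f"raw frame {h}x{w} smaller than 32x32")
    if np.ptp(arr) == 0:
        logger.warning("constant image: ROI detection impossible, using central crop")
        return _central_crop(arr)
    mask = arr > threshold_otsu(arr)
    if not mask.any() or mask.all():
        logger.warning("degenerate foreground mask, using central crop")
        return _central_crop(arr)
    labels = measure.label(mask)
    regions = measure.regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    top, left, bottom, right = largest.bbox
    return arr[top:bottom, left:right]


def normalize_size(img: np.ndarray, out_h: int = 96, out_w: int = 64) -> np.ndarray:
    """Bilinear resample to exactly ``out_h x out_w``; output values stay
    within the input's range."""
    arr = _check_2d(img)
    if out_h < 1 or out_w < 1:
        raise InvalidInputError(f"target size {out_h}x{out_w} must be positive")
    if arr.shape == (out_h, out_w):
        return arr.copy()
    out = transform.resize(
        arr, (out_h, out_w), order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, arr.min(), arr.max())


def normalize_gray(img: np.ndarray) -> np.ndarray:
    """Linear min-max stretch to [0, 1]; a constant image maps to all 0.5.

    Idempotent on non-constant images and invariant under global affine
    intensity changes; pixel-value ordering is preserved.
    """
    arr = _check_2d(img)
    if arr.size == 0:
        raise InvalidInputError("empty image")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


def preprocess(
    raw: np.ndarray,
    out_h: int = 96,
    out_w: int = 64,
    roi_enabled: bool = True,
) -> np.ndarray:
    """Full chain: optional ROI crop, resize, gray normalization.

    ``roi_enabled=False`` supports pre-cropped datasets.
    """
    arr = _check_2d(raw)
    if roi_enabled:
        arr = extract_roi(arr)
    arr = normalize_size(arr, out_h, out_w)
    return normalize_gray(arr)
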