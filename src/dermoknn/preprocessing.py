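"""Hair removal and image enhancement.

The preprocessing chain is: RGB -> luminance grayscale -> hair removal by
grayscale morphological closing with oriented line structuring elements ->
global histogram equalization.  Closing with a line longer than a hair's
width fills the hair (a thin dark curvilinear structure) up to the local
background wherever the line crosses it; taking the pixel-wise maximum over
several orientations removes hairs of any direction while leaving the wide,
compact lesion essentially untouched.  PSNR between the grayscale input and
the preprocessed output quantifies how much the enhancement altered the
image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .types import LesionImage, ValidationError

__all__ = [
    "StructuringElement",
    "to_grayscale",
    "morphological_close",
    "remove_hair",
    "equalize_histogram",
    "psnr",
    "preprocess",
]

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class StructuringElement:
    """A morphological probe: a disk of given radius or a line of given
    length at an angle in [0, 180) degrees."""

    shape: str = "disk"
    size: int = 3
    angle: float = 0.0

    def __post_init__(self):
        if self.shape not in ("disk", "line"):
            raise ValidationError("shape", "must be 'disk' or 'line'")
        if self.size < 1:
            raise ValidationError("size", "must be >= 1")
        if self.shape == "line" and not (0.0 <= self.angle < 180.0):
            raise ValidationError("angle", "must lie in [0, 180)")

    def footprint(self) -> np.ndarray:
        if self.shape == "disk":
            r = self.size
            yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
            return (yy * yy + xx * xx) <= r * r
        # line: Bresenham raster of a centred segment of the given length
        half = (self.size - 1) / 2.0
        rad = np.deg2rad(self.angle)
        dy, dx = -np.sin(rad), np.cos(rad)  # rows grow downward
        t = np.arange(self.size) - half
        rows = np.rint(t * dy).astype(int)
        cols = np.rint(t * dx).astype(int)
        r0, c0 = rows.min(), cols.min()
        fp = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
        fp[rows - r0, cols - c0] = True
        return fp


def _as_gray_array(img) -> np.ndarray:
    arr = img.pixels if isinstance(img, LesionImage) else np.asarray(img)
    if arr.ndim != 2:
        raise ValidationError("img", "expected a single-plane raster")
    return arr


def to_grayscale(img: LesionImage) -> LesionImage:
    """Convert an RGB image to luminance grayscale.

    Uses the fixed weights 0.299 R + 0.587 G + 0.114 B, rounded to the
    nearest integer in [0, 255].
    """
    arr = img.pixels if isinstance(img, LesionImage) else np.asarray(img)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValidationError("img", "grayscale conversion requires (H, W, 3) input")
    gray = np.rint(arr.astype(float) @ _LUMA)
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    source = img.source_id if isinstance(img, LesionImage) else ""
    return LesionImage(gray, stage_tag="gray", source_id=source)


def morphological_close(img, se: StructuringElement) -> np.ndarray:
    """Grayscale closing: dilation followed by erosion with the same
    structuring element.

    At the image border the min/max windows are restricted to in-bounds
    pixels (the finite-domain adjunction).  This is the only border rule
    under which closing keeps its defining algebra — extensive, increasing
    and idempotent — exactly; stage-wise edge replication violates
    extensivity at the border for diagonal elements.
    """
    arr = _as_gray_array(img)
    fp = se.footprint()
    if fp.shape[0] > arr.shape[0] or fp.shape[1] > arr.shape[1]:
        raise ValidationError("se", "structuring element larger than the image")
    # constant pads at the identity elements make out-of-bounds neighbours
    # drop out of the max (cval 0) and min (cval 255) windows
    dil = ndi.grey_dilation(arr, footprint=fp, mode="constant", cval=0)
    return ndi.grey_erosion(dil, footprint=fp, mode="constant", cval=255)


def remove_hair(img, line_length: int = 15, n_angles: int = 8) -> np.ndarray:
    """Suppress thin dark curvilinear structures (hairs).

    Pixel-wise maximum over grayscale closings with line structuring
    elements at ``n_angles`` evenly spaced orientations.  Each closing
    fills dark structures narrower than the line along its direction; the
    maximum keeps, per pixel, the orientation that best bridged the hair.
    Structures wider than ``line_length`` (the lesion) are preserved.
    """
    if n_angles < 1:
        raise ValidationError("n_angles", "must be >= 1")
    arr = _as_gray_array(img)
    out = None
    for i in range(n_angles):
        se = StructuringElement("line", line_length, 180.0 * i / n_angles)
        closed = morphological_close(arr, se)
        out = closed if out is None else np.maximum(out, closed)
    return out


def equalize_histogram(img) -> np.ndarray:
    """Global histogram equalization of an 8-bit raster.

    Standard CDF remapping to [0, 255]: v -> round(255 * CDF(v)).  The map
    is monotone non-decreasing, so pixel rank order is preserved.
    """
    arr = _as_gray_array(img).astype(np.uint8)
    hist = np.bincount(arr.ravel(), minlength=256)
    cdf = np.cumsum(hist) / arr.size
    lut = np.rint(255.0 * cdf).astype(np.uint8)
    return lut[arr]


def psnr(reference, test) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(255^2 / MSE).

    Returns ``inf`` when the images are identical (MSE = 0).
    """
    a = _as_gray_array(reference).astype(float)
    b = _as_gray_array(test).astype(float)
    if a.shape != b.shape:
        raise ValidationError("test", "shape mismatch with reference")
    mse = np.mean((a - b) ** 2)
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(255.0**2 / mse))


def preprocess(gray, line_length: int = 15, n_angles: int = 8,
               equalize: bool = True) -> LesionImage:
    """Full enhancement chain on a grayscale image: hair removal, then
    (optionally) histogram equalization."""
    arr = _as_gray_array(gray)
    dehaired = remove_hair(arr, line_length=line_length, n_angles=n_angles)
    out = equalize_histogram(dehaired) if equalize else dehaired
    source = gray.source_id if isinstance(gray, LesionImage) else ""
    return LesionImage(out, stage_tag="preprocessed", source_id=source)
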