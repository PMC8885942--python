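"""Lesion segmentation by adaptive (locally adaptive mean) thresholding.

Each pixel is compared against the mean of its local window rather than a
single global threshold, which tolerates uneven illumination.  Lesions are
darker than the surrounding skin, so the default polarity marks pixels
*below* ``local mean - offset`` as foreground.  Minimal cleanup keeps only
the largest connected component; interior holes are deliberately left open
because the hole pixel count is a downstream feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .types import LesionMask, ValidationError

__all__ = [
    "SegmentationError",
    "adaptive_threshold",
    "largest_component",
    "segment",
    "default_window",
]


class SegmentationError(RuntimeError):
    """No lesion detected; carries per-stage diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def default_window(shape: tuple[int, int]) -> int:
    """Default local-window side: odd, ~1/4 of the smaller image side.

    Wide enough to straddle hairs and reach past the lesion border from
    most interior pixels, narrow enough to stay below lesion diameter."""
    return 2 * (min(shape) // 8) + 1


def adaptive_threshold(img, window: int | None = None, offset: float = 10.0,
                       polarity: str = "dark_foreground") -> LesionMask:
    """Threshold against the local-mean surface.

    Under ``dark_foreground`` a pixel is foreground iff its value is below
    (local mean - offset); under ``bright_foreground`` iff above
    (local mean + offset).  The window is edge-replicated.
    """
    arr = np.asarray(img.pixels if hasattr(img, "pixels") else img)
    if arr.ndim != 2:
        raise ValidationError("img", "expected a single-plane raster")
    if window is None:
        window = default_window(arr.shape)
    if window % 2 == 0 or window < 3:
        raise ValidationError("window", "must be odd and >= 3")
    if window > min(arr.shape):
        raise ValidationError("window", "must not exceed the image")
    if polarity not in ("dark_foreground", "bright_foreground"):
        raise ValidationError("polarity", f"unknown polarity {polarity!r}")

    local_mean = ndi.uniform_filter(arr.astype(float), size=window, mode="nearest")
    if polarity == "dark_foreground":
        fg = arr < local_mean - offset
    else:
        fg = arr > local_mean + offset
    return LesionMask(fg)


def largest_component(mask: LesionMask, connectivity: int = 8) -> LesionMask:
    """Keep only the largest connected foreground component.

    Ties are broken toward the component whose label comes first in raster
    scan order (the top-left-most one).  An empty mask passes through with
    a warning flag.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity", "must be 4 or 8")
    arr = mask.pixels if isinstance(mask, LesionMask) else np.asarray(mask) > 0
    structure = ndi.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndi.label(arr, structure=structure)
    if n == 0:
        return LesionMask(np.zeros_like(arr), warning="empty mask")
    sizes = np.bincount(labels.ravel())[1:]
    # argmax returns the first maximum; ndi.label assigns labels in raster
    # scan order, so ties already resolve to the top-left-most component
    keep = int(np.argmax(sizes)) + 1
    return LesionMask(labels == keep)


def segment(img, window: int | None = None, offset: float = 10.0,
            polarity: str = "dark_foreground",
            connectivity: int = 8) -> LesionMask:
    """Adaptive threshold followed by largest-component cleanup.

    Raises :class:`SegmentationError` when nothing is detected.  Holes are
    not filled.
    """
    thresholded = adaptive_threshold(img, window=window, offset=offset,
                                     polarity=polarity)
    mask = largest_component(thresholded, connectivity=connectivity)
    if mask.foreground_count == 0:
        raise SegmentationError(
            "no lesion detected",
            diagnostics={
                "window": window,
                "offset": offset,
                "polarity": polarity,
                "thresholded_pixels": thresholded.foreground_count,
            },
        )
    return mask
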