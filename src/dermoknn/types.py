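"""Core containers shared across the pipeline stages.

The pipeline passes three kinds of objects between stages: RGB or grayscale
rasters with a stage tag (:class:`LesionImage`), binary lesion masks
(:class:`LesionMask`), and the generative parameters of a synthetic lesion
(:class:`LesionSpec`).  All rasters are 8-bit; masks are boolean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "LesionSpec",
    "LesionImage",
    "LesionMask",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition.

    ``field`` names the offending parameter so callers (and the CLI) can
    report exactly what was wrong.
    """

    def __init__(self, fieldname: str, message: str):
        self.field = fieldname
        super().__init__(f"{fieldname}: {message}")


def _luminance(rgb: Sequence[float]) -> float:
    r, g, b = rgb
    return 0.299 * r + 0.587 * g + 0.114 * b


@dataclass(frozen=True)
class LesionSpec:
    """Generative parameters for one synthetic dermoscopic-style lesion.

    The lesion outline is a star-convex radial-harmonic blob:

        r(theta) = base_radius * (1 + asymmetry_level * A(theta)
                                    + border_irregularity * B(theta))

    where ``A`` sums low-order harmonics (k = 2, 3) that break mirror
    symmetry and ``B`` sums high-order harmonics (k = 8..12) that wrinkle
    the border.  Amplitudes within each group are normalised so the two
    levels are directly the maximum fractional radial excursion.

    Parameters are validated eagerly by :meth:`validate`; generation is
    bit-reproducible from (spec, seed).
    """

    label: int = 0
    image_size: tuple[int, int] = (256, 256)
    center: tuple[float, float] = (128.0, 128.0)
    base_radius: float = 30.0
    asymmetry_level: float = 0.0
    border_irregularity: float = 0.0
    lesion_colors: tuple[tuple[int, int, int], ...] = ((110, 70, 50),)
    color_weights: tuple[float, ...] = (1.0,)
    skin_color: tuple[int, int, int] = (225, 185, 160)
    hair_count: int = 0
    hair_width: int = 2
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError("label", "must be 0 (normal) or 1 (melanoma)")
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValidationError("image_size", "must be at least 8x8")
        if self.base_radius < 4:
            raise ValidationError("base_radius", "must be >= 4 px")
        if not (0.0 <= self.asymmetry_level <= 1.0):
            raise ValidationError("asymmetry_level", "must lie in [0, 1]")
        if not (0.0 <= self.border_irregularity <= 1.0):
            raise ValidationError("border_irregularity", "must lie in [0, 1]")
        if self.asymmetry_level + self.border_irregularity >= 1.0:
            raise ValidationError(
                "asymmetry_level",
                "asymmetry_level + border_irregularity must be < 1 "
                "(outline radius must stay positive)",
            )
        # worst-case radius must keep a >= 2 px margin inside the image
        rmax = self.base_radius * (
            1.0 + self.asymmetry_level + self.border_irregularity
        )
        cy, cx = self.center
        if (
            cy - rmax < 2
            or cx - rmax < 2
            or cy + rmax > h - 3
            or cx + rmax > w - 3
        ):
            raise ValidationError(
                "center", "lesion must fit inside the image with a >= 2 px margin"
            )
        if not (1 <= len(self.lesion_colors) <= 4):
            raise ValidationError("lesion_colors", "needs 1-4 RGB triplets")
        if len(self.color_weights) != len(self.lesion_colors):
            raise ValidationError(
                "color_weights", "must have one weight per lesion color"
            )
        if any(wgt <= 0 for wgt in self.color_weights):
            raise ValidationError("color_weights", "weights must be positive")
        for name, colors in (
            ("lesion_colors", self.lesion_colors),
            ("skin_color", (self.skin_color,)),
        ):
            for c in colors:
                if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                    raise ValidationError(name, "channels must lie in [0, 255]")
        # lesion must read darker than skin, else segmentation polarity breaks
        wsum = float(sum(self.color_weights))
        lesion_lum = sum(
            wgt / wsum * _luminance(c)
            for wgt, c in zip(self.color_weights, self.lesion_colors)
        )
        if lesion_lum >= _luminance(self.skin_color):
            raise ValidationError(
                "lesion_colors", "mean lesion luminance must be below skin luminance"
            )
        if self.hair_count < 0:
            raise ValidationError("hair_count", "must be non-negative")
        if self.hair_width < 1:
            raise ValidationError("hair_width", "must be >= 1 px")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma", "must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LesionImage:
    """An 8-bit raster plus provenance.

    ``stage_tag`` records where in the pipeline the raster was produced:
    ``raw`` (H, W, 3 RGB), ``gray`` or ``preprocessed`` (single plane).
    """

    pixels: np.ndarray
    stage_tag: str = "raw"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.stage_tag not in ("raw", "gray", "preprocessed"):
            raise ValidationError("stage_tag", f"unknown stage {self.stage_tag!r}")
        if self.stage_tag == "raw":
            if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
                raise ValidationError("pixels", "raw stage requires an (H, W, 3) raster")
        else:
            if self.pixels.ndim != 2:
                raise ValidationError(
                    "pixels", f"{self.stage_tag} stage requires a single-plane raster"
                )
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValidationError("pixels", "values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass
class LesionMask:
    """Binary foreground mask of a segmented lesion."""

    pixels: np.ndarray
    warning: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValidationError("pixels", "mask must be 2-D")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1, 255))):
                raise ValidationError("pixels", "mask must be strictly two-valued")
            arr = arr > 0
        self.pixels = arr

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
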