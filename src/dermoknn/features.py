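"""Feature extraction: statistical, shape and colour descriptors.

The descriptor set mirrors the clinical ABCD rule plus the pipeline's own
statistical summaries:

* Asymmetry index ``AI``: the mask is reflected about each of its two
  principal axes (eigenvectors of the second-order central moments); the
  non-overlap (XOR) pixel counts, averaged and normalised by area, give a
  value in [0, 1] — 0 for a perfectly mirror-symmetric shape.
* Compactness index ``CI = P^2 / (4 pi A)``: 1 for a disk, growing with
  border irregularity.  ``P`` is the length of the 8-connected outer
  contour (Moore boundary trace), with unit steps for axial moves and
  sqrt(2) for diagonal moves.
* Diameter: the maximum Feret (caliper) diameter — the largest pairwise
  Euclidean distance between boundary pixel centres, taken over the convex
  hull of the boundary.
* Colour: per-channel within-mask mean and population standard deviation.
* Area and hole pixel counts of the segmented region, plus ln(1 + count)
  versions; within-mask intensity statistics computed both directly and
  from the 256-bin histogram; the whole-image mean read off the
  zero-frequency coefficient of the 2-D FFT; and the preprocessing PSNR.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .preprocessing import psnr
from .types import LesionImage, LesionMask, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "mean_via_fft",
    "masked_stats",
    "area_and_holes",
    "asymmetry_index",
    "compactness_index",
    "lesion_diameter",
    "color_features",
    "trace_boundary",
    "boundary_length",
    "extract_features",
]

#: Frozen order of the feature vector (also the CSV header).
FEATURE_NAMES = (
    "mean_fft",
    "std_intensity",
    "hist_mean",
    "hist_std",
    "area_count",
    "hole_count",
    "log_area",
    "log_hole",
    "asymmetry_index",
    "compactness_index",
    "diameter",
    "color_mean_r",
    "color_mean_g",
    "color_mean_b",
    "color_std_r",
    "color_std_g",
    "color_std_b",
    "psnr_value",
)

# finite stand-in for an infinite PSNR (identical images) so the feature
# vector stays usable in Euclidean distance
_PSNR_CAP = 100.0


@dataclass(frozen=True)
class FeatureVector:
    """One lesion's descriptors, in the frozen :data:`FEATURE_NAMES` order."""

    mean_fft: float
    std_intensity: float
    hist_mean: float
    hist_std: float
    area_count: float
    hole_count: float
    log_area: float
    log_hole: float
    asymmetry_index: float
    compactness_index: float
    diameter: float
    color_mean_r: float
    color_mean_g: float
    color_mean_b: float
    color_std_r: float
    color_std_g: float
    color_std_b: float
    psnr_value: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "FeatureVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(FEATURE_NAMES),):
            raise ValidationError("arr", f"expected {len(FEATURE_NAMES)} values")
        return cls(**dict(zip(FEATURE_NAMES, (float(v) for v in arr))))

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in FEATURE_NAMES}


assert tuple(f.name for f in dataclass_fields(FeatureVector)) == FEATURE_NAMES


def _mask_array(mask) -> np.ndarray:
    arr = mask.pixels if isinstance(mask, LesionMask) else np.asarray(mask) > 0
    if arr.ndim != 2:
        raise ValidationError("mask", "mask must be 2-D")
    return arr


def _gray_array(img) -> np.ndarray:
    arr = img.pixels if isinstance(img, LesionImage) else np.asarray(img)
    if arr.ndim != 2:
        raise ValidationError("img", "expected a single-plane raster")
    return arr


def mean_via_fft(img) -> float:
    """Whole-image mean read off the DC coefficient of the 2-D FFT.

    F(0, 0) is the sum of all pixels, so F(0, 0).real / N is exactly the
    arithmetic mean (up to floating-point round-off).
    """
    arr = _gray_array(img).astype(float)
    if arr.size == 0:
        raise ValidationError("img", "empty raster")
    return float(np.fft.fft2(arr)[0, 0].real / arr.size)


def masked_stats(img, mask) -> tuple[float, float, float]:
    """Within-mask intensity statistics.

    Returns ``(std_intensity, hist_mean, hist_std)``: the population
    standard deviation of the masked pixel values, and the mean/std
    recomputed from the 256-bin integer histogram using bin centres — for
    8-bit integer data these equal the direct statistics exactly.
    """
    arr = _gray_array(img)
    m = _mask_array(mask)
    vals = arr[m]
    if vals.size == 0:
        raise ValidationError("mask", "mask is empty")
    std_direct = float(np.std(vals))
    hist = np.bincount(vals.astype(np.intp).ravel(), minlength=256)
    centers = np.arange(256, dtype=float)
    n = hist.sum()
    hmean = float((hist * centers).sum() / n)
    hstd = float(np.sqrt((hist * (centers - hmean) ** 2).sum() / n))
    return std_direct, hmean, hstd


def area_and_holes(mask) -> tuple[int, int]:
    """Foreground pixel count and enclosed-hole pixel count.

    A hole is a background pixel not reachable from the image border by a
    4-connected background flood fill (the standard dual of 8-connected
    foreground).
    """
    m = _mask_array(mask)
    filled = ndi.binary_fill_holes(m)  # default structure = 4-connectivity
    area = int(m.sum())
    holes = int(filled.sum()) - area
    return area, holes


def _principal_axes(m: np.ndarray):
    ys, xs = np.nonzero(m)
    n = ys.size
    cy, cx = ys.mean(), xs.mean()
    y = ys - cy
    x = xs - cx
    mu20 = (y * y).mean()
    mu02 = (x * x).mean()
    mu11 = (y * x).mean()
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    eigvals, eigvecs = np.linalg.eigh(cov)
    return (cy, cx), (y, x), eigvals, eigvecs


def asymmetry_index(mask) -> float:
    """Normalised non-overlap between the mask and its principal-axis
    reflections, clamped to [0, 1]."""
    m = _mask_array(mask)
    area = int(m.sum())
    if area < 4:
        raise ValidationError("mask", "asymmetry needs >= 4 foreground pixels")
    (cy, cx), (y, x), eigvals, eigvecs = _principal_axes(m)
    if eigvals[0] < 1e-9:
        raise ValidationError("mask", "degenerate (collinear) mask")
    pts = set(zip(np.nonzero(m)[0].tolist(), np.nonzero(m)[1].tolist()))
    xor_total = 0
    for axis in range(2):
        uy, ux = eigvecs[:, axis]
        proj = y * uy + x * ux
        ry = 2.0 * proj * uy - y + cy
        rx = 2.0 * proj * ux - x + cx
        refl = set(zip(np.rint(ry).astype(int).tolist(),
                       np.rint(rx).astype(int).tolist()))
        xor_total += len(pts ^ refl)
    return float(np.clip(xor_total / (2.0 * area), 0.0, 1.0))


# clockwise Moore neighbourhood, starting at West, for row-down coordinates
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_MOORE_INDEX = {o: i for i, o in enumerate(_MOORE)}


def trace_boundary(mask) -> np.ndarray:
    """Outer 8-connected contour of the mask's first raster-order blob.

    Moore-neighbour tracing with Jacob's stopping criterion; returns the
    ordered (row, col) contour pixels.  A single-pixel mask returns that
    pixel alone.
    """
    m = _mask_array(mask)
    if not m.any():
        raise ValidationError("mask", "mask is empty")
    pad = np.pad(m, 1)
    rows, cols = np.nonzero(pad)
    start = (int(rows[0]), int(cols[0]))  # top-most then left-most
    b0 = (start[0], start[1] - 1)  # west of start: background by scan order
    contour = [start]
    p, b = start, b0
    # the (pixel, backtrack) transition is deterministic, so the walk closes
    # the contour exactly when a state repeats (more robust than stopping on
    # the first revisit of the start pixel, which 1-px-wide limbs defeat)
    seen = {(p, b)}
    while True:
        i0 = _MOORE_INDEX[(b[0] - p[0], b[1] - p[1])]
        nxt = None
        prev = b
        for k in range(1, 9):
            idx = (i0 + k) % 8
            q = (p[0] + _MOORE[idx][0], p[1] + _MOORE[idx][1])
            if pad[q]:
                nxt = q
                break
            prev = q
        if nxt is None:  # isolated pixel
            break
        p, b = nxt, prev
        if (p, b) in seen:
            break
        seen.add((p, b))
        contour.append(p)
    return np.asarray(contour) - 1


def boundary_length(mask) -> float:
    """Closed-contour length: 1 per axial step, sqrt(2) per diagonal."""
    contour = trace_boundary(mask)
    if len(contour) > 1 and (contour[0] == contour[-1]).all():
        contour = contour[:-1]
    if len(contour) < 2:
        return 0.0
    diffs = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    steps = np.abs(diffs)
    return float(np.where((steps == 1).all(axis=1), np.sqrt(2.0), 1.0).sum())


def compactness_index(mask) -> float:
    """``P^2 / (4 pi A)``; 1 for a disk, larger for ragged borders."""
    m = _mask_array(mask)
    area = int(m.sum())
    if area < 4:
        raise ValidationError("mask", "compactness needs >= 4 foreground pixels")
    p = boundary_length(m)
    return float(p * p / (4.0 * np.pi * area))


def lesion_diameter(mask) -> float:
    """Maximum Feret diameter in pixels.

    Largest pairwise Euclidean distance between boundary pixel centres;
    computed over the convex hull of the boundary for speed, which is
    exact because the farthest pair is always a pair of hull vertices.
    """
    m = _mask_array(mask)
    if not m.any():
        raise ValidationError("mask", "mask is empty")
    boundary = m & ~ndi.binary_erosion(m)
    pts = np.argwhere(boundary).astype(float)
    if len(pts) == 1:
        return 0.0
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError:
        pass  # degenerate (collinear) boundary: brute-force the few points
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def color_features(img, mask) -> tuple[float, ...]:
    """Within-mask per-channel mean and population std, order R G B."""
    arr = img.pixels if isinstance(img, LesionImage) else np.asarray(img)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValidationError("img", "colour features require (H, W, 3) input")
    m = _mask_array(mask)
    if not m.any():
        raise ValidationError("mask", "mask is empty")
    vals = arr[m].astype(float)
    means = vals.mean(axis=0)
    stds = vals.std(axis=0)
    return tuple(float(v) for v in means) + tuple(float(v) for v in stds)


def extract_features(raw, preprocessed, gray, mask) -> FeatureVector:
    """Assemble the full descriptor vector for one case.

    ``raw`` is the RGB image, ``gray`` its luminance conversion,
    ``preprocessed`` the enhanced grayscale raster the mask was segmented
    from.  Intensity statistics are computed on the preprocessed raster;
    colour on the raw RGB; the PSNR compares gray vs preprocessed.
    """
    pre = _gray_array(preprocessed)
    gr = _gray_array(gray)
    m = _mask_array(mask)
    raw_arr = raw.pixels if isinstance(raw, LesionImage) else np.asarray(raw)
    if not (pre.shape == gr.shape == m.shape == raw_arr.shape[:2]):
        raise ValidationError("mask", "stage shapes are inconsistent")

    std_i, hmean, hstd = masked_stats(pre, m)
    area, holes = area_and_holes(m)
    cfeat = color_features(raw_arr, m)
    p = psnr(gr, pre)
    return FeatureVector(
        mean_fft=mean_via_fft(pre),
        std_intensity=std_i,
        hist_mean=hmean,
        hist_std=hstd,
        area_count=float(area),
        hole_count=float(holes),
        log_area=float(np.log1p(area)),
        log_hole=float(np.log1p(holes)),
        asymmetry_index=asymmetry_index(m),
        compactness_index=compactness_index(m),
        diameter=lesion_diameter(m),
        color_mean_r=cfeat[0],
        color_mean_g=cfeat[1],
        color_mean_b=cfeat[2],
        color_std_r=cfeat[3],
        color_std_g=cfeat[4],
        color_std_b=cfeat[5],
        psnr_value=min(p, _PSNR_CAP),
    )
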