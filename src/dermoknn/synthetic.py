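"""Synthetic dermoscopic-style lesion images with ground-truth masks.

Real dermoscopy collections are rarely redistributable, so every downstream
stage here is exercised against generated images whose ground truth is known
exactly.  A lesion is a star-convex blob darker than the surrounding skin:

    r(theta) = R * (1 + a * A(theta) + b * B(theta))

with ``A`` a sum of low-order radial harmonics (k = 2, 3; breaks mirror
symmetry, the ABCD "A") and ``B`` a sum of high-order harmonics
(k = 8..12; wrinkles the border, the ABCD "B").  Colour variegation (the
ABCD "C") comes from partitioning the lesion into 1-4 colour zones along a
smoothed random field; diameter (the ABCD "D") is set by ``base_radius``.
Hair-like dark line segments and Gaussian pixel noise are overlaid *after*
the ground-truth mask is frozen, so hair-removal quality is measurable
against truth.

The default class profiles make malignant lesions stochastically larger,
more asymmetric, more irregular and more colour-variegated than normal
ones; the margins are deliberately generous so the end-to-end classifier
faces a clean two-class problem at desk scale.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .types import LesionImage, LesionMask, LesionSpec, ValidationError

__all__ = [
    "generate_lesion_image",
    "generate_dataset",
    "draw_spec",
    "default_profile",
    "save_dataset",
]

_ASYM_HARMONICS = (2, 3)
_BORDER_HARMONICS = (8, 9, 10, 11, 12)

# candidate lesion pigments (R, G, B): browns, red-brown, blue-gray, near-black
_PIGMENTS = np.array(
    [
        (130, 90, 70),
        (110, 60, 50),
        (80, 55, 40),
        (85, 75, 90),
        (55, 40, 35),
        (150, 105, 80),
    ],
    dtype=float,
)

_HAIR_COLOR = np.array((45.0, 35.0, 25.0))


def _radial_profile(spec: LesionSpec, rng: np.random.Generator):
    """Return a callable r(theta) for the lesion outline.

    Per-harmonic amplitudes and phases are drawn from ``rng``; amplitudes
    are L1-normalised within each group so ``asymmetry_level`` and
    ``border_irregularity`` bound the fractional radial excursion.
    """

    def _group(orders):
        amps = rng.uniform(0.5, 1.0, size=len(orders))
        amps /= amps.sum()
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(orders))
        return np.asarray(orders), amps, phases

    ka, aa, pa = _group(_ASYM_HARMONICS)
    kb, ab, pb = _group(_BORDER_HARMONICS)

    def r_of_theta(theta: np.ndarray) -> np.ndarray:
        t = np.asarray(theta)[..., None]
        mod = spec.asymmetry_level * np.sum(aa * np.sin(ka * t + pa), axis=-1)
        mod = mod + spec.border_irregularity * np.sum(
            ab * np.sin(kb * t + pb), axis=-1
        )
        return spec.base_radius * (1.0 + mod)

    return r_of_theta


def _color_zones(mask: np.ndarray, n_zones: int, weights: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Partition the mask into colour zones along a smoothed random field."""
    if n_zones == 1:
        return np.zeros(mask.shape, dtype=int)
    field = rng.normal(size=mask.shape)
    field = ndi.gaussian_filter(field, sigma=8.0)
    inside = field[mask]
    # cut the field at weight quantiles so zone areas follow the weights
    cum = np.cumsum(weights) / np.sum(weights)
    cuts = np.quantile(inside, cum[:-1])
    zones = np.zeros(mask.shape, dtype=int)
    zones[mask] = np.searchsorted(cuts, inside, side="right")
    return zones


def generate_lesion_image(spec: LesionSpec):
    """Render one synthetic lesion.

    Returns ``(image, mask, label)`` where ``image`` is the raw RGB
    :class:`LesionImage`, ``mask`` the ground-truth :class:`LesionMask`
    (frozen before hair and noise are overlaid) and ``label`` the class.
    Identical ``spec`` (including its ``seed``) gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    cy, cx = spec.center

    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    r_of_theta = _radial_profile(spec, rng)
    mask = dist <= r_of_theta(theta)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(spec.skin_color, dtype=float)

    weights = np.asarray(spec.color_weights, dtype=float)
    zones = _color_zones(mask, len(spec.lesion_colors), weights, rng)
    colors = np.asarray(spec.lesion_colors, dtype=float)
    img[mask] = colors[zones[mask]]

    # hairs: thin dark segments over the whole image, after the mask froze
    for _ in range(spec.hair_count):
        y0 = rng.integers(0, h)
        x0 = rng.integers(0, w)
        angle = rng.uniform(0.0, np.pi)
        length = rng.uniform(0.4, 1.0) * min(h, w)
        y1 = int(np.clip(round(y0 + length * np.sin(angle)), 0, h - 1))
        x1 = int(np.clip(round(x0 + length * np.cos(angle)), 0, w - 1))
        rr, cc = draw_line(int(y0), int(x0), y1, x1)
        hair = np.zeros((h, w), dtype=bool)
        hair[rr, cc] = True
        if spec.hair_width > 1:
            hair = ndi.binary_dilation(
                hair, structure=disk_footprint(spec.hair_width // 2)
            )
        shade = _HAIR_COLOR + rng.uniform(-10.0, 10.0)
        img[hair] = shade

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    image = LesionImage(img, stage_tag="raw", source_id=f"synthetic-{spec.seed}")
    return image, LesionMask(mask), spec.label


def default_profile() -> dict:
    """Per-class sampling ranges for :func:`draw_spec`.

    Malignant lesions are larger, more asymmetric, more border-irregular
    and more colour-variegated than normal ones; both classes share skin
    tone, hair statistics and pixel noise.  Ranges are (low, high) for
    uniform draws; ``n_colors`` is an inclusive integer range.
    """
    common = {
        "noise_sigma": 4.0,
        "hair_count": (0, 4),
        "hair_width": 2,
        "center_jitter": 12.0,
        "image_size": (256, 256),
    }
    return {
        "normal": {
            **common,
            "base_radius": (16.0, 26.0),
            "asymmetry_level": (0.02, 0.12),
            "border_irregularity": (0.02, 0.10),
            "n_colors": (1, 2),
            "pigment_jitter": 8.0,
        },
        "malignant": {
            **common,
            "base_radius": (26.0, 40.0),
            "asymmetry_level": (0.25, 0.55),
            "border_irregularity": (0.22, 0.42),
            "n_colors": (2, 4),
            "pigment_jitter": 12.0,
        },
    }


def _merge_profile(profile: dict | None) -> dict:
    prof = default_profile()
    if profile:
        for cls in ("normal", "malignant"):
            prof[cls].update(profile.get(cls, {}))
    return prof


def draw_spec(label: int, rng: np.random.Generator,
              profile: dict | None = None) -> LesionSpec:
    """Draw one :class:`LesionSpec` from the per-class profile."""
    prof = _merge_profile(profile)["malignant" if label else "normal"]
    h, w = prof["image_size"]

    radius = rng.uniform(*prof["base_radius"])
    asym = rng.uniform(*prof["asymmetry_level"])
    border = rng.uniform(*prof["border_irregularity"])

    jit = prof["center_jitter"]
    cy = h / 2.0 + rng.uniform(-jit, jit)
    cx = w / 2.0 + rng.uniform(-jit, jit)

    n_colors = int(rng.integers(prof["n_colors"][0], prof["n_colors"][1] + 1))
    picks = rng.choice(len(_PIGMENTS), size=n_colors, replace=False)
    pj = prof["pigment_jitter"]
    colors = tuple(
        tuple(
            int(np.clip(round(v + rng.uniform(-pj, pj)), 0, 200))
            for v in _PIGMENTS[p]
        )
        for p in picks
    )
    wts = rng.uniform(0.5, 1.5, size=n_colors)
    wts = tuple(float(v) for v in wts / wts.sum())

    skin = tuple(
        int(np.clip(round(v + rng.uniform(-8, 8)), 180, 255))
        for v in (225.0, 185.0, 160.0)
    )

    lo, hi = prof["hair_count"]
    return LesionSpec(
        label=label,
        image_size=(h, w),
        center=(cy, cx),
        base_radius=radius,
        asymmetry_level=asym,
        border_irregularity=border,
        lesion_colors=colors,
        color_weights=wts,
        skin_color=skin,
        hair_count=int(rng.integers(lo, hi + 1)),
        hair_width=int(prof["hair_width"]),
        noise_sigma=float(prof["noise_sigma"]),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(n_normal: int, n_malignant: int,
                     profile: dict | None = None, seed: int = 0):
    """Generate a labelled dataset of (image, mask, label) triples.

    Normal cases come first, then malignant; the whole dataset is
    bit-reproducible from the arguments and ``seed``.
    """
    if n_normal < 0 or n_malignant < 0:
        raise ValidationError("n_normal", "sample counts must be non-negative")
    rng = np.random.default_rng(seed)
    items = []
    for label, count in ((0, n_normal), (1, n_malignant)):
        for _ in range(count):
            spec = draw_spec(label, rng, profile)
            items.append(generate_lesion_image(spec) + (spec,))
    # keep (image, mask, label) as the public triple; spec rides along
    return [(img, mask, lab, spec) for img, mask, lab, spec in items]


def save_dataset(items, out_dir: str | Path) -> pd.DataFrame:
    """Write images/masks as PNG plus a manifest CSV; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, mask, label, spec) in enumerate(items):
        name = f"case_{i:04d}"
        img_file = f"{name}.png"
        mask_file = f"{name}_mask.png"
        iio.imwrite(out / img_file, img.pixels)
        iio.imwrite(out / mask_file, (mask.pixels * np.uint8(255)))
        row = {"file": img_file, "mask_file": mask_file, "label": label}
        sd = copy.deepcopy(spec.to_dict())
        sd.pop("label")
        row.update({k: str(v) if isinstance(v, (tuple, list)) else v
                    for k, v in sd.items()})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
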