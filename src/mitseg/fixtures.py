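"""Synthetic labeled pseudo-histology specimens.

Real slides in the corpus are background-dominant (the slide glass is ~59%
of all pixels) with a connected tissue section whose anatomy is layered:
keratin and epidermis at the surface, papillary then reticular dermis
beneath, hypodermis deepest, with glands, hair follicles and inflammation
scattered inside the dermis and carcinoma lesions growing from the
epidermal side.  The generator emulates exactly that statistical structure
— a smooth tissue blob, depth-ordered bands, lesion and island blobs —
with per-class base colors plus spatially correlated noise, so that every
pipeline stage (codec, tiling, augmentation, training, metrics) can be
exercised without any external download.  Textures are flat color + blurred
Gaussian noise, not a stain-physics simulation: fixtures exist to exercise
code paths and learnability, not to mimic pathology.

Masks are exact generating labels; everything is deterministic given the
recipe seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datapipe import (BKG_INDEX, CLASS_NAMES, LabeledSpecimen,
                       largest_remainder)

__all__ = ["FixtureRecipe", "TABLE_FREQUENCIES", "generate_specimen",
           "generate_dataset", "CANCER_MIX", "BIOPSY_MIX"]

#: Default per-class pixel-frequency targets: the class distribution of the
#: 290-slide corpus (fractions of all pixels).
TABLE_FREQUENCIES = {
    "FOL": 0.002, "GLD": 0.004, "EPI": 0.006, "IEC": 0.010, "BCC": 0.011,
    "PAP": 0.017, "KER": 0.021, "SCC": 0.024, "INF": 0.028, "HYP": 0.093,
    "RET": 0.198, "BKG": 0.586,
}

#: Slide counts per cancer type (BCC:SCC:IEC = 140:60:90) and biopsy type
#: (shave:punch:excision = 100:58:132) in the emulated corpus.
CANCER_MIX = {"BCC": 140, "SCC": 60, "IEC": 90}
BIOPSY_MIX = {"shave": 100, "punch": 58, "excision": 132}

# H&E-inspired distinct base colors (RGB) per class for the rendered image.
_BASE_COLORS = {
    "BCC": (120, 60, 150), "SCC": (160, 70, 120), "IEC": (100, 90, 170),
    "GLD": (200, 140, 190), "FOL": (90, 50, 60), "INF": (70, 40, 120),
    "RET": (230, 160, 180), "HYP": (245, 210, 220), "PAP": (215, 130, 160),
    "EPI": (150, 80, 140), "KER": (240, 190, 150), "BKG": (244, 244, 244),
}


@dataclass
class FixtureRecipe:
    """Parameters of one synthetic specimen."""
    seed: int = 0
    size: tuple[int, int] = (256, 256)
    class_frequencies: dict = field(
        default_factory=lambda: dict(TABLE_FREQUENCIES))
    n_lesions: int = 2
    noise_scale: float = 10.0       # sd of the correlated texture noise (8-bit units)
    noise_sigma: float = 2.0        # blur radius of the texture noise, pixels
    cancer_type: str | None = None  # None: include every cancer with freq > 0

    def __post_init__(self):
        H, W = self.size
        if H < 64 or W < 64:
            raise ValueError("canvas must be at least 64x64")
        freqs = self.class_frequencies
        unknown = set(freqs) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown classes in frequency vector: {unknown}")
        if any(v < 0 for v in freqs.values()):
            raise ValueError("class frequencies must be non-negative")
        total = sum(freqs.values())
        if not 0.9 <= total <= 1.1:
            raise ValueError(f"class frequencies must sum to ~1, got {total:.3f}")
        if freqs.get("BKG", 0.0) <= 0.0:
            raise ValueError("infeasible frequency vector: BKG must be positive")


def _smooth_noise(rng, shape, sigma):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / (f.std() + 1e-9)


def _blob_mask(rng, shape, area_fraction, sigma):
    """Smooth connected-ish region covering ~area_fraction of the canvas."""
    field = _smooth_noise(rng, shape, sigma)
    # bias toward the canvas centre so the blob is interior
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    r2 = ((yy - cy) / shape[0]) ** 2 + ((xx - cx) / shape[1]) ** 2
    field = field - 3.0 * r2
    thr = np.quantile(field, 1.0 - area_fraction)
    return field >= thr


def _stamp_disc(mask_out, rng, label, area, inside, min_radius=2):
    """Place one noisy disc of ~area pixels at a random location within
    ``inside``; returns True if anything was stamped."""
    candidates = np.flatnonzero(inside.ravel())
    if candidates.size == 0:
        candidates = np.flatnonzero(np.ones(mask_out.size, dtype=bool))
    pos = candidates[rng.integers(candidates.size)]
    cy, cx = np.unravel_index(pos, mask_out.shape)
    radius = max(min_radius, int(np.sqrt(max(area, 1) / np.pi)))
    yy, xx = np.mgrid[0:mask_out.shape[0], 0:mask_out.shape[1]]
    wobble = _smooth_noise(rng, mask_out.shape, 4.0) * radius * 0.3
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= (radius + wobble) ** 2
    disc &= inside if inside.any() else True
    if not disc.any():
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= min_radius ** 2
    mask_out[disc] = label
    return True


def generate_specimen(recipe: FixtureRecipe) -> LabeledSpecimen:
    """Render one specimen (image + exact mask) from a recipe.

    Background-dominant canvas; a smooth tissue blob with depth-ordered
    bands (KER/EPI at the rim, PAP/RET inside, HYP deepest); carcinoma
    lesion blobs near the epidermal side; small FOL/GLD/INF islands in the
    dermis.  The realized BKG fraction tracks the recipe target to within a
    few percentage points; every class with positive target frequency is
    guaranteed at least one pixel.
    """
    rng = np.random.default_rng(recipe.seed)
    H, W = recipe.size
    freqs = dict(recipe.class_frequencies)

    cancers = ("BCC", "SCC", "IEC")
    if recipe.cancer_type is not None:
        if recipe.cancer_type not in cancers:
            raise ValueError(f"unknown cancer type {recipe.cancer_type!r}")
        # the specimen carries a single carcinoma: fold the other cancer
        # budgets into its own
        total_cancer = sum(freqs.get(c, 0.0) for c in cancers)
        for c in cancers:
            freqs[c] = total_cancer if c == recipe.cancer_type else 0.0

    tissue_frac = 1.0 - freqs["BKG"]
    mask = np.full((H, W), BKG_INDEX, dtype=np.uint8)
    blob = _blob_mask(rng, (H, W), tissue_frac, sigma=min(H, W) / 6)

    # depth-ordered anatomical bands inside the blob (rim -> deep)
    band_order = ["KER", "EPI", "PAP", "RET", "HYP"]
    band_freqs = np.array([max(freqs.get(c, 0.0), 1e-6) for c in band_order])
    band_freqs /= band_freqs.sum()
    depth = ndimage.distance_transform_edt(blob)
    dvals = depth[blob]
    cuts = np.quantile(dvals, np.cumsum(band_freqs)[:-1])
    band_idx = np.searchsorted(cuts, dvals, side="right")
    labels = np.array([CLASS_NAMES.index(c) for c in band_order], dtype=np.uint8)
    mask[blob] = labels[band_idx]

    tissue_area = int(blob.sum())
    dermis = blob & np.isin(mask, [CLASS_NAMES.index("RET"),
                                   CLASS_NAMES.index("HYP")])
    upper = blob & np.isin(mask, [CLASS_NAMES.index("EPI"),
                                  CLASS_NAMES.index("PAP"),
                                  CLASS_NAMES.index("RET")])

    # carcinoma lesions grow from the epidermal side
    for c in cancers:
        f = freqs.get(c, 0.0)
        if f <= 0:
            continue
        area = f * H * W
        n = max(1, recipe.n_lesions)
        for _ in range(n):
            _stamp_disc(mask, rng, CLASS_NAMES.index(c), area / n, upper)

    # small glands / follicles / inflammation islands in the dermis
    for c in ("GLD", "FOL", "INF"):
        f = freqs.get(c, 0.0)
        if f <= 0:
            continue
        _stamp_disc(mask, rng, CLASS_NAMES.index(c), f * H * W, dermis)

    # guarantee presence of every requested class
    for i, c in enumerate(CLASS_NAMES):
        if freqs.get(c, 0.0) > 0 and not (mask == i).any():
            _stamp_disc(mask, rng, i, 9, blob)

    base = np.array([_BASE_COLORS[c] for c in CLASS_NAMES], dtype=np.float32)
    img = base[mask]
    noise = np.stack([
        ndimage.gaussian_filter(rng.standard_normal((H, W)), recipe.noise_sigma)
        for _ in range(3)], axis=-1)
    noise *= recipe.noise_scale / (noise.std() + 1e-9)
    img = np.clip(img + noise, 0, 255).astype(np.uint8)

    cancer = recipe.cancer_type or "BCC"
    return LabeledSpecimen(image=img, mask=mask, cancer_type=cancer,
                           biopsy_type="excision", resolution_factor=1,
                           specimen_id=f"fixture-{recipe.seed:06d}")


def _assign_types(n, mix, rng):
    names = sorted(mix)
    total = sum(mix.values())
    counts = largest_remainder(n, [mix[k] / total for k in names])
    out = sum(([name] * c for name, c in zip(names, counts)), [])
    rng.shuffle(out)
    return out


def generate_dataset(n: int, seed: int = 0,
                     mix: dict | None = None,
                     size: tuple[int, int] = (256, 256),
                     **recipe_kwargs) -> list[LabeledSpecimen]:
    """Generate ``n`` specimens with corpus-like metadata.

    Cancer types follow ``mix`` (default BCC:SCC:IEC = 140:60:90) and biopsy
    types the 100:58:132 shave/punch/excision proportions, both apportioned
    by largest remainder and shuffled reproducibly by ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(mix or CANCER_MIX)
    rng = np.random.default_rng(seed)
    cancer_types = _assign_types(n, mix, rng)
    biopsy_types = _assign_types(n, BIOPSY_MIX, rng)
    out = []
    for i in range(n):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        recipe = FixtureRecipe(seed=sub_seed, size=size,
                               cancer_type=cancer_types[i], **recipe_kwargs)
        spec = generate_specimen(recipe)
        spec.biopsy_type = biopsy_types[i]
        spec.specimen_id = f"fixture-{i:04d}"
        out.append(spec)
    return out
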