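"""Dataset handling for the 12-class skin-histopathology corpus.

The corpus couples flat RGB TIFF specimen images (native pitch 0.67 um per
pixel) with palette-indexed PNG masks over twelve tissue/lesion classes:
the three non-melanoma carcinomas (BCC, SCC, IEC), glands (GLD), hair
follicles (FOL), inflammation (INF), reticular and papillary dermis
(RET, PAP), hypodermis (HYP), epidermis (EPI), keratin (KER), and slide
background (BKG).

This module provides the palette codec (PNG color <-> class index, a strict
bijection), resolution variants (2x/5x/10x downsampling), tiling of large
specimens into fixed-size training patches with lossless stitching,
stratified train/val/test splitting, and the 8-fold dihedral augmentation
used during training.  Geometric operations always apply the same transform
to image and mask, with nearest-neighbour resampling for labels so class
indices are never blended.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "CLASS_NAMES", "BKG_INDEX", "ClassPalette", "LabeledSpecimen",
    "SplitManifest", "Tile", "MICRONS_PER_PIXEL",
    "decode_mask", "encode_mask", "downsample", "tile", "stitch",
    "split_dataset", "augment", "largest_remainder",
    "read_specimen", "write_specimen",
]

#: Class order fixes the integer label of every class for a run.
CLASS_NAMES = ("BCC", "SCC", "IEC", "GLD", "FOL", "INF",
               "RET", "HYP", "PAP", "EPI", "KER", "BKG")
BKG_INDEX = CLASS_NAMES.index("BKG")
MICRONS_PER_PIXEL = 0.67  # native tissue pitch of the scans

#: Padded pixels in tiles carry this mask value and are excluded from loss
#: and metrics via the tile's validity mask.
PAD_LABEL = BKG_INDEX

# Maximally distinct default colors (the published masks use a fixed palette
# whose exact RGB values are not recoverable; any bijective palette works).
_DEFAULT_COLORS = (
    (228, 26, 28),    # BCC  red
    (55, 126, 184),   # SCC  blue
    (77, 175, 74),    # IEC  green
    (152, 78, 163),   # GLD  purple
    (255, 127, 0),    # FOL  orange
    (255, 255, 51),   # INF  yellow
    (166, 86, 40),    # RET  brown
    (247, 129, 191),  # HYP  pink
    (153, 153, 153),  # PAP  grey
    (0, 206, 209),    # EPI  teal
    (0, 0, 128),      # KER  navy
    (255, 255, 255),  # BKG  white
)


@dataclass(frozen=True)
class ClassPalette:
    """Ordered (class name, RGB color) pairs defining the mask codec."""
    entries: tuple = tuple(zip(CLASS_NAMES, _DEFAULT_COLORS))

    def __post_init__(self):
        names = tuple(n for n, _ in self.entries)
        if names != CLASS_NAMES:
            raise ValueError(f"palette classes must be exactly {CLASS_NAMES}")
        colors = [tuple(c) for _, c in self.entries]
        if len(set(colors)) != len(colors):
            raise ValueError("palette colors must be pairwise distinct")

    @property
    def colors(self) -> np.ndarray:
        return np.array([c for _, c in self.entries], dtype=np.uint8)

    @property
    def names(self) -> tuple:
        return tuple(n for n, _ in self.entries)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_PALETTE = ClassPalette()


@dataclass
class LabeledSpecimen:
    """One specimen: RGB image, integer class mask, and slide metadata."""
    image: np.ndarray                 # (H, W, 3) uint8
    mask: np.ndarray                  # (H, W) uint8, values in 0..11
    cancer_type: str                  # BCC | SCC | IEC
    biopsy_type: str                  # shave | punch | excision
    resolution_factor: int = 1        # 1 (native), 2, 5 or 10
    specimen_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be (H, W, 3)")
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions must match")
        if self.mask.size and self.mask.max() >= len(CLASS_NAMES):
            raise ValueError("mask values must be < 12")
        if self.cancer_type not in ("BCC", "SCC", "IEC"):
            raise ValueError(f"unknown cancer type {self.cancer_type!r}")
        if self.biopsy_type not in ("shave", "punch", "excision"):
            raise ValueError(f"unknown biopsy type {self.biopsy_type!r}")
        if self.resolution_factor not in (1, 2, 5, 10):
            raise ValueError("resolution_factor must be one of 1, 2, 5, 10")

    @property
    def microns_per_pixel(self) -> float:
        return MICRONS_PER_PIXEL * self.resolution_factor


@dataclass
class SplitManifest:
    """Disjoint train/val/test id lists with the stratification recipe."""
    train: list
    val: list
    test: list
    seed: int
    stratify_keys: tuple = ("cancer_type", "biopsy_type")

    def __post_init__(self):
        all_ids = self.train + self.val + self.test
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split lists must be pairwise disjoint")

    def split_of(self, specimen_id) -> str:
        for name in ("train", "val", "test"):
            if specimen_id in getattr(self, name):
                return name
        raise KeyError(specimen_id)

    def save_csv(self, path, metadata: dict | None = None):
        """Write id,split[,cancer_type,biopsy_type] as CSV."""
        metadata = metadata or {}
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "split", "cancer_type", "biopsy_type"])
            for name in ("train", "val", "test"):
                for sid in getattr(self, name):
                    meta = metadata.get(sid, {})
                    w.writerow([sid, name, meta.get("cancer_type", ""),
                                meta.get("biopsy_type", "")])

    @classmethod
    def load_csv(cls, path, seed: int = 0) -> "SplitManifest":
        splits = {"train": [], "val": [], "test": []}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                splits[row["split"]].append(row["id"])
        return cls(seed=seed, **splits)


# -- palette codec ------------------------------------------------------------

def _to_rgb_array(png_mask) -> np.ndarray:
    if isinstance(png_mask, Image.Image):
        return np.asarray(png_mask.convert("RGB"))
    arr = np.asarray(png_mask)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("mask must be an RGB array or a PIL image")
    return arr


def decode_mask(png_mask, palette: ClassPalette = DEFAULT_PALETTE) -> np.ndarray:
    """Map a palette-colored mask (PIL image or RGB array) to class indices.

    Raises ``ValueError`` naming every off-palette color (with pixel counts)
    if any pixel color is not in the palette.
    """
    rgb = _to_rgb_array(png_mask).astype(np.uint32)
    packed = (rgb[..., 0] << 16) | (rgb[..., 1] << 8) | rgb[..., 2]
    colors = palette.colors.astype(np.uint32)
    pal_packed = (colors[:, 0] << 16) | (colors[:, 1] << 8) | colors[:, 2]
    lut = {int(c): i for i, c in enumerate(pal_packed)}
    out = np.full(packed.shape, 255, dtype=np.uint8)
    for c, i in lut.items():
        out[packed == c] = i
    bad = out == 255
    if bad.any():
        counts = Counter(packed[bad].ravel().tolist())
        desc = ", ".join(
            f"#{c:06x} x{n}" for c, n in sorted(counts.items())[:10])
        raise ValueError(
            f"{len(counts)} unknown color(s) not in palette: {desc}")
    return out


def encode_mask(mask: np.ndarray, palette: ClassPalette = DEFAULT_PALETTE) -> Image.Image:
    """Encode an integer mask as a paletted ('P' mode) PNG image."""
    mask = np.asarray(mask)
    if mask.size and mask.max() >= len(palette.entries):
        raise ValueError("mask contains indices outside the palette")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    pal = palette.colors.ravel().tolist()
    img.putpalette(pal + [0] * (768 - len(pal)))
    return img


# -- resolution variants ------------------------------------------------------

def downsample(spec: LabeledSpecimen, factor: int) -> LabeledSpecimen:
    """Produce the 2x/5x/10x variant of a specimen.

    The image is resized by area (box) interpolation, the mask by nearest
    neighbour; the physical pitch becomes ``0.67 * factor`` um/pixel.
    """
    if factor not in (2, 5, 10):
        raise ValueError(f"factor must be one of 2, 5, 10, got {factor}")
    if spec.resolution_factor != 1:
        raise ValueError("downsample expects a native-resolution specimen")
    H, W = spec.mask.shape
    h, w = max(H // factor, 1), max(W // factor, 1)
    img = Image.fromarray(spec.image).resize((w, h), Image.BOX)
    msk = Image.fromarray(spec.mask).resize((w, h), Image.NEAREST)
    return replace(spec, image=np.asarray(img), mask=np.asarray(msk),
                   resolution_factor=factor)


# -- tiling / stitching -------------------------------------------------------

@dataclass
class Tile:
    image: np.ndarray        # (rescale_to, rescale_to, 3) uint8
    mask: np.ndarray         # (rescale_to, rescale_to) uint8
    valid: np.ndarray        # (rescale_to, rescale_to) bool, False on padding
    row: int                 # top-left corner in the source image (0-based)
    col: int
    size: int                # tile edge in source pixels (pre-rescale)


def _resize(arr: np.ndarray, edge: int, nearest: bool) -> np.ndarray:
    if arr.shape[0] == edge and arr.shape[1] == edge:
        return arr
    mode = Image.NEAREST if nearest else Image.BILINEAR
    return np.asarray(Image.fromarray(arr).resize((edge, edge), mode))


def tile(spec: LabeledSpecimen, size: int = 256, rescale_to: int = 512) -> list[Tile]:
    """Cut a specimen into a non-overlapping grid of ``size`` x ``size``
    tiles (edge tiles padded with white pixels / BKG labels, padding tracked
    in the validity mask), each rescaled to ``rescale_to``.
    """
    H, W = spec.mask.shape
    if H == 0 or W == 0:
        raise ValueError("cannot tile an empty image")
    ny = -(-H // size)
    nx = -(-W // size)
    tiles = []
    for iy in range(ny):
        for ix in range(nx):
            r, c = iy * size, ix * size
            img = np.full((size, size, 3), 255, dtype=np.uint8)
            msk = np.full((size, size), PAD_LABEL, dtype=np.uint8)
            val = np.zeros((size, size), dtype=bool)
            h = min(size, H - r)
            w = min(size, W - c)
            img[:h, :w] = spec.image[r:r + h, c:c + w]
            msk[:h, :w] = spec.mask[r:r + h, c:c + w]
            val[:h, :w] = True
            tiles.append(Tile(
                image=_resize(img, rescale_to, nearest=False),
                mask=_resize(msk, rescale_to, nearest=True),
                valid=_resize(val.astype(np.uint8), rescale_to,
                              nearest=True).astype(bool),
                row=r, col=c, size=size))
    return tiles


def stitch(pred_tiles: list, full_size: tuple[int, int],
           masks: list[np.ndarray] | None = None) -> np.ndarray:
    """Reassemble per-tile predicted masks into a full-resolution mask.

    ``pred_tiles`` is a list of :class:`Tile`; ``masks`` optionally replaces
    each tile's stored mask with a predicted one of the same (rescaled)
    shape.  Tiles are resized back to their source edge with nearest
    neighbour, placed at their coordinates and the padding cropped away.
    Raises on coverage gaps.
    """
    H, W = full_size
    out = np.full((H, W), 255, dtype=np.uint8)
    for i, t in enumerate(pred_tiles):
        m = t.mask if masks is None else np.asarray(masks[i])
        if m.shape != t.mask.shape:
            raise ValueError("predicted tile shape does not match tile")
        src = _resize(m.astype(np.uint8), t.size, nearest=True)
        h = min(t.size, H - t.row)
        w = min(t.size, W - t.col)
        if h <= 0 or w <= 0:
            raise ValueError("tile lies outside the stitched canvas")
        out[t.row:t.row + h, t.col:t.col + w] = src[:h, :w]
    if (out == 255).any():
        raise ValueError("tiles do not cover the full image (coverage gap)")
    return out


# -- splitting ----------------------------------------------------------------

def largest_remainder(n: int, ratios) -> list[int]:
    """Apportion ``n`` items to ``ratios`` (summing to 1) by largest remainder."""
    quotas = [n * r for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    rem = n - sum(counts)
    order = np.argsort([c - q for c, q in zip(counts, quotas)])  # biggest deficit first
    for i in order[:rem]:
        counts[i] += 1
    return counts


def split_dataset(items: list, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> SplitManifest:
    """Stratified train/val/test split of specimen metadata.

    ``items`` is a list of objects (or dicts) with ``specimen_id``,
    ``cancer_type`` and ``biopsy_type``.  Within each (cancer x biopsy)
    stratum the ratios are honoured by largest-remainder rounding; a global
    correction pass then enforces the largest-remainder totals for the whole
    set so e.g. 290 items always yield 232/29/29.
    """
    if len(items) < 10:
        raise ValueError("need at least 10 items to split")
    if abs(sum(ratios) - 1.0) > 1e-9 or len(ratios) != 3:
        raise ValueError("ratios must be three values summing to 1")

    def get(it, key):
        return it[key] if isinstance(it, dict) else getattr(it, key)

    rng = np.random.default_rng(seed)
    strata: dict[tuple, list] = {}
    for it in items:
        key = (get(it, "cancer_type"), get(it, "biopsy_type"))
        strata.setdefault(key, []).append(get(it, "specimen_id"))

    assigned: dict = {}
    for key in sorted(strata):
        ids = sorted(strata[key])
        rng.shuffle(ids)
        counts = largest_remainder(len(ids), ratios)
        pos = 0
        for split_i, c in enumerate(counts):
            for sid in ids[pos:pos + c]:
                assigned[sid] = split_i
            pos += c

    # global correction toward the whole-set largest-remainder totals
    targets = largest_remainder(len(items), ratios)
    totals = [sum(1 for v in assigned.values() if v == i) for i in range(3)]
    ids_sorted = sorted(assigned)
    while totals != targets:
        over = max(range(3), key=lambda i: totals[i] - targets[i])
        under = min(range(3), key=lambda i: totals[i] - targets[i])
        moved = next(sid for sid in ids_sorted if assigned[sid] == over)
        assigned[moved] = under
        totals[over] -= 1
        totals[under] += 1

    splits = {0: [], 1: [], 2: []}
    for sid in ids_sorted:
        splits[assigned[sid]].append(sid)
    return SplitManifest(train=splits[0], val=splits[1], test=splits[2],
                         seed=seed)


# -- augmentation -------------------------------------------------------------

def _dihedral(arr: np.ndarray, k: int) -> np.ndarray:
    """Element k of the dihedral group D4: k<4 rotations, k>=4 flip then rotate."""
    if k >= 4:
        arr = arr[:, ::-1]
    return np.ascontiguousarray(np.rot90(arr, k % 4))


def augment(pair: LabeledSpecimen) -> list[LabeledSpecimen]:
    """The 8 square symmetries (identity, rotations by 90/180/270, and the
    same after a horizontal flip) applied identically to image and mask.

    Requires a square input; the original is first and the order is fixed.
    """
    H, W = pair.mask.shape
    if H != W:
        raise ValueError("augmentation requires square tiles")
    out = []
    for k in range(8):
        out.append(replace(
            pair,
            image=_dihedral(pair.image, k),
            mask=_dihedral(pair.mask, k),
            specimen_id=f"{pair.specimen_id}+d{k}" if pair.specimen_id else "",
        ))
    return out


# -- file IO ------------------------------------------------------------------

def write_specimen(spec: LabeledSpecimen, image_path, mask_path,
                   palette: ClassPalette = DEFAULT_PALETTE):
    """Write the image as TIFF and the mask as a paletted PNG."""
    tifffile.imwrite(image_path, spec.image)
    encode_mask(spec.mask, palette).save(mask_path)


def read_specimen(image_path, mask_path, cancer_type: str, biopsy_type: str,
                  resolution_factor: int = 1, specimen_id: str = "",
                  palette: ClassPalette = DEFAULT_PALETTE) -> LabeledSpecimen:
    image = tifffile.imread(image_path)
    mask = decode_mask(Image.open(mask_path), palette)
    return LabeledSpecimen(image=image, mask=mask, cancer_type=cancer_type,
                           biopsy_type=biopsy_type,
                           resolution_factor=resolution_factor,
                           specimen_id=specimen_id)
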