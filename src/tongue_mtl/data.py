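"""Reading images and tongue annotations, the preprocessing chain, and
stratified train/validation/test splitting.

Preprocessing mirrors the clinical pipeline: polygon annotations (Labelme
JSON) are rasterized to binary masks, the tongue is optionally extracted by
zeroing the background, images are resized to the network side (default
224) with bilinear interpolation and channel-normalized, and training pairs
are augmented with a shared random translation/rotation.

Coordinate convention (Labelme's): 0-based, x = column, y = row, origin at
the top-left pixel *corner*, so the center of pixel (row y, col x) is at
(x + 0.5, y + 0.5).  A pixel belongs to a polygon iff its center is inside
(even-odd rule).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class Polygon:
    """An annotation polygon: (N, 2) array of (x, y) pixel coordinates."""

    vertices: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 \
                or len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 (x, y) vertices")


@dataclass
class PreprocessedSample:
    """Network-ready sample: 3 x side x side image + binary mask."""

    image: np.ndarray             # 3 x S x S float32
    mask: np.ndarray              # S x S uint8
    quality: Optional[str] = None


@dataclass
class SplitIndex:
    """Disjoint, exhaustive id partition with its provenance."""

    train: list
    val: list
    test: list
    fractions: tuple = (0.70, 0.15, 0.15)
    seed: int = 0
    stratified: bool = True

    def to_json(self) -> str:
        return json.dumps({"train": list(self.train), "val": list(self.val),
                           "test": list(self.test),
                           "fractions": list(self.fractions),
                           "seed": self.seed, "stratified": self.stratified})

    @classmethod
    def from_json(cls, text: str) -> "SplitIndex":
        d = json.loads(text)
        return cls(train=d["train"], val=d["val"], test=d["test"],
                   fractions=tuple(d["fractions"]), seed=d["seed"],
                   stratified=d["stratified"])


class LabelmeFormatError(ValueError):
    pass


def read_labelme(document) -> list[Polygon]:
    """Parse a Labelme JSON document (text, dict, or path) into polygons.

    Coordinates pass through unmodified.  Non-polygon shapes raise a format
    error naming the offending shape.
    """
    if isinstance(document, dict):
        doc = document
    else:
        text = str(document)
        if "{" not in text:          # looks like a path
            with open(text) as fh:
                doc = json.load(fh)
        else:
            doc = json.loads(text)
    if "shapes" not in doc:
        raise LabelmeFormatError("document has no 'shapes' key")
    polys = []
    for i, shape in enumerate(doc["shapes"]):
        stype = shape.get("shape_type", "polygon")
        if stype != "polygon":
            label = shape.get("label", f"#{i}")
            raise LabelmeFormatError(
                f"shape {label!r} has shape_type {stype!r}; only polygons "
                f"are supported")
        polys.append(Polygon(np.asarray(shape["points"], dtype=float)))
    return polys


def polygons_to_mask(polys: Sequence[Polygon], size) -> np.ndarray:
    """Rasterize the union of filled polygons onto an H x W binary mask.

    A pixel is inside iff its center (x + 0.5, y + 0.5) lies inside the
    polygon (even-odd rule).
    """
    from matplotlib.path import Path

    if not polys:
        raise ValueError("at least one polygon is required")
    H, W = int(size[0]), int(size[1])
    yy, xx = np.mgrid[0:H, 0:W]
    centers = np.stack([xx.ravel() + 0.5, yy.ravel() + 0.5], axis=1)
    mask = np.zeros(H * W, dtype=bool)
    for poly in polys:
        mask |= Path(poly.vertices).contains_points(centers)
    mask = mask.reshape(H, W).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError("all polygons rasterized to an empty mask")
    return mask


def extract_tongue(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out background pixels (black fill), keeping tongue pixels.

    Idempotent: extracting twice equals extracting once.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} disagree")
    m = mask.astype(image.dtype)
    return image * (m[:, :, None] if image.ndim == 3 else m)


def resize_normalize(image: np.ndarray, mask: np.ndarray, side: int = 224,
                     normalize: Optional[str] = "imagenet") -> PreprocessedSample:
    """Resize to ``side`` (image bilinear, mask nearest-neighbor) and
    channel-normalize.

    ``normalize``: "imagenet" ((v - mean_c)/std_c with the ImageNet channel
    statistics), "unit" (pass through, values stay in [0, 1]), or None
    (alias for "unit").
    """
    from skimage.transform import resize

    image = np.asarray(image, dtype=np.float32)
    if not np.isfinite(image).all():
        raise ValueError("non-finite pixel values")
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise ValueError("input image too small to resize meaningfully")
    if image.shape[:2] != (side, side):
        image = resize(image, (side, side), order=1, anti_aliasing=False,
                       preserve_range=True).astype(np.float32)
    mask = np.asarray(mask)
    if mask.shape != (side, side):
        mask = resize(mask.astype(np.uint8), (side, side), order=0,
                      anti_aliasing=False, preserve_range=True)
    mask = (mask > 0.5).astype(np.uint8)
    chw = np.ascontiguousarray(image.transpose(2, 0, 1))
    if normalize == "imagenet":
        chw = (chw - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]
    elif normalize in (None, "unit"):
        pass
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return PreprocessedSample(image=chw.astype(np.float32), mask=mask)


def normalize_batch(batch_chw: np.ndarray, normalize: Optional[str]) -> np.ndarray:
    """Apply the channel normalization of ``resize_normalize`` to a
    B x 3 x H x W batch already in [0, 1]."""
    if normalize == "imagenet":
        return ((batch_chw - IMAGENET_MEAN[None, :, None, None])
                / IMAGENET_STD[None, :, None, None]).astype(np.float32)
    if normalize in (None, "unit"):
        return np.asarray(batch_chw, dtype=np.float32)
    raise ValueError(f"unknown normalization {normalize!r}")


def augment_pair(image: np.ndarray, mask: np.ndarray, seed: int,
                 max_translate: float = 0.10,
                 max_rotate_deg: float = 15.0) -> tuple[np.ndarray, np.ndarray]:
    """Apply one shared random rigid transform to an (image, mask) pair.

    Translation is sampled up to ``max_translate`` of the side, rotation up
    to ``max_rotate_deg`` degrees; the image is interpolated bilinearly, the
    mask with nearest-neighbor.  Deterministic given ``seed``.  ``image`` is
    H x W x 3 (channels-last) or H x W.
    """
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError("image/mask shapes disagree")
    rng = np.random.default_rng(seed)
    angle = np.deg2rad(rng.uniform(-max_rotate_deg, max_rotate_deg))
    H, W = mask.shape
    ty = rng.uniform(-max_translate, max_translate) * H
    tx = rng.uniform(-max_translate, max_translate) * W
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    # affine_transform maps output coords -> input coords
    offset = center - rot @ (center + np.array([ty, tx]))

    def warp(arr, order):
        return ndimage.affine_transform(arr, rot, offset=offset, order=order,
                                        mode="constant", cval=0.0,
                                        prefilter=False)

    if image.ndim == 3:
        out = np.stack([warp(image[:, :, ch], 1) for ch in range(image.shape[2])],
                       axis=2)
    else:
        out = warp(image, 1)
    out_mask = warp(mask.astype(np.float32), 0)
    return out.astype(np.float32), (out_mask > 0.5).astype(mask.dtype)


def split_dataset(labelled_ids, fractions=(0.70, 0.15, 0.15), seed: int = 0,
                  stratified: bool = True) -> SplitIndex:
    """Partition ids into train/val/test.

    ``labelled_ids``: sequence of (id, label) pairs.  Per class (or
    globally when not stratified): shuffle with ``seed``, allocate
    floor(f_train * n) to train, floor(f_val * n) to val, remainder to
    test.  A class with fewer than 3 members cannot be split and goes
    entirely to train (with a warning).
    """
    pairs = list(labelled_ids)
    if len(pairs) < 3:
        raise ValueError("need at least 3 items to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    groups: dict = {}
    if stratified:
        for id_, lab in pairs:
            groups.setdefault(lab, []).append(id_)
    else:
        groups[None] = [id_ for id_, _ in pairs]
    train, val, test = [], [], []
    for lab in sorted(groups, key=str):
        ids = groups[lab]
        if stratified and len(ids) < 3:
            warnings.warn(f"class {lab!r} has {len(ids)} item(s); "
                          f"placed entirely in train")
            train += ids
            continue
        order = rng.permutation(len(ids))
        ids = [ids[i] for i in order]
        n_tr = int(np.floor(fractions[0] * len(ids)))
        n_val = int(np.floor(fractions[1] * len(ids)))
        train += ids[:n_tr]
        val += ids[n_tr:n_tr + n_val]
        test += ids[n_tr + n_val:]
    return SplitIndex(train=train, val=val, test=test,
                      fractions=tuple(fractions), seed=seed,
                      stratified=stratified)


# -- manifest / image reading ---------------------------------------------

def read_manifest(path: str) -> list[dict]:
    import csv

    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def load_annotated(record: dict, root: str):
    """Rebuild an AnnotatedImage from a manifest row and its PNG files."""
    import os

    import imageio.v3 as iio

    from .synthetic import AnnotatedImage, DefectSpec

    pixels = np.asarray(iio.imread(os.path.join(root, record["file"])),
                        dtype=np.float32) / 255.0
    mask_raw = np.asarray(iio.imread(os.path.join(root, record["mask_file"])))
    mask = (mask_raw >= 128).astype(np.uint8)
    kind = record["defect_kind"]
    spec = DefectSpec() if kind == "none" else DefectSpec(
        kind, float(record["magnitude"]))
    return AnnotatedImage(pixels=pixels, mask=mask, quality=record["quality"],
                          defect=spec, id=record["id"],
                          rng_seed=int(record["seed"]))
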