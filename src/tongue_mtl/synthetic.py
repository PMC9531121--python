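"""Synthetic tongue-scene generator.

Clinical tongue photographs cannot be redistributed, so this module renders
labelled stand-in scenes that preserve the features the quality-assessment
task depends on: a skin-textured background, a smooth convex tongue-like
region (an ellipse with a rounded lower tip) with an exact binary mask, and
the four defect classes seen in practice —

* ``blur``              — Gaussian smoothing (camera shake / missed focus),
* ``overexposed``       — multiplicative brightening, clipped at white,
* ``underexposed``      — multiplicative darkening,
* ``partial_extension`` — the lower part of the tongue is missing (the
  subject did not extend the tongue past the lower lip); the mask is
  truncated consistently and the removed area is filled with background.

A scene is ``quality="high"`` iff it carries no defect.  All generation is
deterministic: every image derives its own sub-seed from the dataset seed by
a counter-based scheme, so any single scene can be regenerated in isolation.

The module also provides a deliberately simple luminance/sharpness/shape
heuristic classifier used to demonstrate that the benchmark is separable
(and hence learnable by small networks).
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

DEFECT_KINDS = ("blur", "overexposed", "underexposed", "partial_extension")
QUALITY_HIGH = "high"
QUALITY_LOW = "low"

MIN_SIDE = 32


@dataclass(frozen=True)
class DefectSpec:
    """A quality defect and its severity.

    ``magnitude`` is the Gaussian sigma in pixels for ``blur``, the
    multiplicative brightness factor for ``overexposed`` (> 1) and
    ``underexposed`` (< 1), and the retained area fraction in (0, 1) for
    ``partial_extension``.  ``kind="none"`` marks a defect-free image and
    ignores the magnitude.
    """

    kind: str = "none"
    magnitude: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none",) + DEFECT_KINDS:
            raise ValueError(f"unknown defect kind {self.kind!r}")
        if self.kind == "none":
            return
        if self.magnitude <= 0:
            raise ValueError("defect magnitude must be positive")
        if self.kind == "overexposed" and self.magnitude <= 1:
            raise ValueError("overexposure factor must exceed 1")
        if self.kind == "underexposed" and not self.magnitude < 1:
            raise ValueError("underexposure factor must be below 1")
        if self.kind == "partial_extension" and not self.magnitude < 1:
            raise ValueError("retained extension fraction must be below 1")


@dataclass
class AnnotatedImage:
    """An RGB scene, its binary tongue mask, and its quality annotation."""

    pixels: np.ndarray            # H x W x 3 float32 in [0, 1]
    mask: np.ndarray              # H x W uint8 (1 = tongue)
    quality: str                  # "high" | "low"
    defect: DefectSpec
    id: str
    rng_seed: int
    background: Optional[np.ndarray] = None   # pre-composite background layer

    def __post_init__(self):
        if self.mask.sum() == 0 or self.mask.sum() == self.mask.size:
            raise ValueError("mask must contain both tongue and background pixels")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixels must lie in [0, 1]")
        if (self.quality == QUALITY_HIGH) != (self.defect.kind == "none"):
            raise ValueError("quality=high iff defect.kind=none")


@dataclass(frozen=True)
class SceneParams:
    """Tunable geometry/photometry of generated scenes (defaults are the
    study conditions; see docs/methods.md)."""

    # tongue geometry: horizontal semi-axis as a fraction of the half-width,
    # vertical/horizontal axis ratio, and the rounded-tip extension
    semi_axis_range: tuple = (0.50, 0.78)
    axis_ratio_range: tuple = (0.6, 1.2)
    tip_strength_range: tuple = (0.10, 0.30)
    # photometry: mean tongue luminance band for defect-free scenes.
    # Background lighting/texture vary widely and independently of the
    # tongue (ambient illumination, skin tone, shadows), so whole-frame
    # statistics are not a reliable quality cue — judging quality requires
    # attending to the tongue region, as in clinical scenes
    tongue_luminance_range: tuple = (0.42, 0.62)
    background_luminance_range: tuple = (0.15, 0.45)
    texture_amplitude: float = 0.035
    background_texture_amplitude_range: tuple = (0.03, 0.12)
    background_gradient_max: float = 0.15
    # defect severities
    blur_sigma_range: tuple = (1.5, 4.0)
    overexposure_range: tuple = (1.6, 2.4)
    underexposure_range: tuple = (0.3, 0.6)
    extension_fraction_range: tuple = (0.35, 0.65)
    # acceptable measured mask-area fraction for full-extension scenes
    area_fraction_range: tuple = (0.10, 0.60)


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Scene luminance: the per-pixel RGB mean (documented convention)."""
    return pixels.mean(axis=-1)


def _value_noise(rng: np.random.Generator, shape, cells: int,
                 amplitude: float) -> np.ndarray:
    """Low-frequency value noise: a coarse random grid smoothly upsampled."""
    grid = rng.random((cells, cells)).astype(np.float32)
    zoom = (shape[0] / cells, shape[1] / cells)
    noise = ndimage.zoom(grid, zoom, order=3, mode="nearest",
                         grid_mode=True)[:shape[0], :shape[1]]
    return (noise - noise.mean()) * (2.0 * amplitude)


def _tongue_polygon(rng: np.random.Generator, size, params: SceneParams,
                    n_vertices: int = 72) -> np.ndarray:
    """Ellipse-with-tip outline in (x, y) pixel-corner coordinates."""
    H, W = size
    ra = rng.uniform(*params.semi_axis_range)
    q = rng.uniform(*params.axis_ratio_range)
    a = ra * W / 2.0
    b = np.clip(q * a, 0.12 * H, 0.40 * H)
    tip = rng.uniform(*params.tip_strength_range)
    cx = W / 2.0 + rng.uniform(-0.04, 0.04) * W
    cy = H * 0.48 + rng.uniform(-0.04, 0.02) * H
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    # y grows downward; theta = pi/2 points at the tongue tip (bottom)
    bump = np.exp(-((theta - np.pi / 2.0) / 0.55) ** 2)
    r = r * (1.0 + tip * bump)
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    xs = np.clip(xs, 1.0, W - 1.0)
    ys = np.clip(ys, 1.0, H - 1.0)
    return np.stack([xs, ys], axis=1)


def _rasterize(polygon: np.ndarray, size) -> np.ndarray:
    from matplotlib.path import Path

    H, W = size
    yy, xx = np.mgrid[0:H, 0:W]
    centers = np.stack([xx.ravel() + 0.5, yy.ravel() + 0.5], axis=1)
    inside = Path(polygon).contains_points(centers)
    return inside.reshape(H, W).astype(np.uint8)


def generate_scene(seed: int, image_size=(64, 64),
                   params: SceneParams = SceneParams()) -> AnnotatedImage:
    """Render one defect-free (high-quality) scene; deterministic in
    ``(seed, image_size, params)``.

    The tongue mask area lands in ``params.area_fraction_range`` (rejection
    sampling on the measured mask) and the mean tongue luminance within
    ``params.tongue_luminance_range``.
    """
    H, W = int(image_size[0]), int(image_size[1])
    if H < MIN_SIDE or W < MIN_SIDE:
        raise ValueError(f"image_size must be at least {MIN_SIDE}x{MIN_SIDE}, "
                         f"got {H}x{W}")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=abs(int(seed)), spawn_key=(int(seed) < 0,)))

    lo, hi = params.area_fraction_range
    for _ in range(64):
        poly = _tongue_polygon(rng, (H, W), params)
        mask = _rasterize(poly, (H, W))
        frac = mask.mean()
        if lo + 0.01 <= frac <= hi - 0.03:
            break
    else:  # pragma: no cover - parameter ranges make this unreachable
        raise RuntimeError("could not sample a tongue within the area band")

    # background: skin-toned texture under scene-specific ambient lighting
    lb = rng.uniform(*params.background_luminance_range)
    hue_jitter = rng.uniform(0.9, 1.1, 3).astype(np.float32)
    bg_tint = np.array([1.25, 0.95, 0.80], dtype=np.float32) * hue_jitter
    bg = lb * bg_tint / bg_tint.mean()
    background = np.empty((H, W, 3), dtype=np.float32)
    amp = rng.uniform(*params.background_texture_amplitude_range)
    noise_bg = _value_noise(rng, (H, W), 6, amp)
    # smooth directional lighting gradient across the frame
    gmag = rng.uniform(0.0, params.background_gradient_max)
    gdir = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0:H, 0:W]
    ramp = ((xx / W - 0.5) * np.cos(gdir) + (yy / H - 0.5) * np.sin(gdir))
    grad_field = (gmag * ramp).astype(np.float32)
    for c in range(3):
        background[:, :, c] = bg[c] + noise_bg + grad_field
    # tongue: pinkish-red body with fine texture
    lt = rng.uniform(*params.tongue_luminance_range)
    tint = np.array([1.40, 0.90, 0.70], dtype=np.float32)
    col = lt * tint / tint.mean()
    fine = rng.normal(0.0, 1.0, (H, W)).astype(np.float32)
    fine = ndimage.gaussian_filter(fine, 0.8)
    fine *= params.texture_amplitude / (fine.std() + 1e-8)
    shading = _value_noise(rng, (H, W), 5, 0.03)
    tongue = np.empty_like(background)
    for c in range(3):
        tongue[:, :, c] = col[c] + fine + shading

    m3 = mask[:, :, None].astype(np.float32)
    pixels = np.clip(background * (1.0 - m3) + tongue * m3, 0.0, 1.0)
    background = np.clip(background, 0.0, 1.0)
    return AnnotatedImage(pixels=pixels.astype(np.float32), mask=mask,
                          quality=QUALITY_HIGH, defect=DefectSpec(),
                          id=f"scene-{seed}", rng_seed=int(seed),
                          background=background)


def apply_defect(img: AnnotatedImage, spec: DefectSpec,
                 seed: int = 0) -> AnnotatedImage:
    """Degrade a high-quality scene with one defect; returns a new image
    with ``quality="low"`` and ``defect=spec``."""
    if img.quality != QUALITY_HIGH:
        raise ValueError("defects are applied to high-quality scenes only")
    if spec.kind == "none":
        raise ValueError("apply_defect requires an actual defect kind")
    pixels, mask = img.pixels, img.mask
    if spec.kind == "blur":
        out = np.empty_like(pixels)
        for c in range(3):
            out[:, :, c] = ndimage.gaussian_filter(pixels[:, :, c],
                                                   spec.magnitude)
        new_pixels, new_mask = out, mask.copy()
    elif spec.kind in ("overexposed", "underexposed"):
        # exposure errors hit the lit subject hardest: full factor on the
        # tongue surface, smoothly decaying into the surrounding face
        profile = ndimage.gaussian_filter(mask.astype(np.float32), 4.0)
        profile = np.clip(profile / max(profile.max(), 1e-6), 0.0, 1.0)
        gain = 1.0 + (spec.magnitude - 1.0) * (0.25 + 0.75 * profile)
        new_pixels = np.clip(pixels * gain[:, :, None], 0.0, 1.0)
        new_mask = mask.copy()
    else:  # partial_extension: keep the top `magnitude` fraction of the area
        area = int(mask.sum())
        row_counts = mask.sum(axis=1)
        cum = np.cumsum(row_counts)
        cut = int(np.searchsorted(cum, spec.magnitude * area, side="left")) + 1
        new_mask = mask.copy()
        new_mask[cut:, :] = 0
        if new_mask.sum() == 0:
            raise ValueError("extension fraction removes the whole tongue")
        removed = (mask == 1) & (new_mask == 0)
        new_pixels = pixels.copy()
        if img.background is not None:
            fill = img.background
        else:
            bg_mean = pixels[mask == 0].mean(axis=0)
            fill = np.broadcast_to(bg_mean, pixels.shape)
        new_pixels[removed] = fill[removed]
    return AnnotatedImage(pixels=np.clip(new_pixels, 0.0, 1.0).astype(np.float32),
                          mask=new_mask, quality=QUALITY_LOW, defect=spec,
                          id=f"{img.id}:{spec.kind}", rng_seed=img.rng_seed,
                          background=img.background)


def _sub_seed(dataset_seed: int, index: int) -> int:
    """Counter-based per-image sub-seed (independent regeneration)."""
    ss = np.random.SeedSequence(entropy=abs(int(dataset_seed)),
                                spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_dataset(n_high: int, n_low: int, seed: int,
                     defect_mix: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                     image_size=(64, 64),
                     params: SceneParams = SceneParams()) -> list[AnnotatedImage]:
    """Generate ``n_high`` defect-free and ``n_low`` defective scenes.

    Defective scenes draw their kind from ``defect_mix`` (ordered as
    ``DEFECT_KINDS``) and their magnitude from the per-kind severity range
    in ``params``.  Fully reproducible given ``seed``.
    """
    if n_high < 0 or n_low < 0 or n_high + n_low < 1:
        raise ValueError("need at least one image")
    mix = np.asarray(defect_mix, dtype=float)
    if mix.shape != (4,) or abs(mix.sum() - 1.0) > 1e-8 or (mix < 0).any():
        raise ValueError("defect_mix must be 4 nonnegative proportions summing to 1")
    master = np.random.default_rng(np.random.SeedSequence(
        entropy=abs(int(seed)), spawn_key=(9999,)))
    images: list[AnnotatedImage] = []
    for i in range(n_high + n_low):
        sub = _sub_seed(seed, i)
        scene = generate_scene(sub, image_size, params)
        scene.id = f"img-{i:04d}"
        if i >= n_high:
            kind = DEFECT_KINDS[master.choice(4, p=mix)]
            rng_ranges = {
                "blur": params.blur_sigma_range,
                "overexposed": params.overexposure_range,
                "underexposed": params.underexposure_range,
                "partial_extension": params.extension_fraction_range,
            }
            mag = float(master.uniform(*rng_ranges[kind]))
            scene = apply_defect(scene, DefectSpec(kind, mag), seed=sub)
            scene.id = f"img-{i:04d}"
        images.append(scene)
    return images


# -- separability heuristic ------------------------------------------------

@dataclass(frozen=True)
class HeuristicThresholds:
    """Decision thresholds of the luminance/sharpness/shape heuristic,
    calibrated once against the generator's default severity ranges."""

    luminance_high: float = 0.66
    luminance_low: float = 0.38
    laplacian_var_min: float = 2.0e-3
    bottom_width_ratio: float = 0.55


def heuristic_quality(img: AnnotatedImage,
                      thresholds: HeuristicThresholds = HeuristicThresholds()
                      ) -> str:
    """Rule-based quality call from three cheap image statistics.

    Over/under-exposure from the mean tongue luminance, blur from the
    variance of the image Laplacian, and incomplete extension from the
    width of the lowest mask row (a truncated tongue ends in a wide flat
    edge instead of a narrow tip).  Exists to certify that the synthetic
    benchmark is separable; it is not the trained model.
    """
    lum = luminance(img.pixels)
    tongue_lum = float(lum[img.mask == 1].mean())
    if tongue_lum > thresholds.luminance_high:
        return QUALITY_LOW
    if tongue_lum < thresholds.luminance_low:
        return QUALITY_LOW
    rows = np.flatnonzero(img.mask.sum(axis=1))
    bottom_width = img.mask[rows[-1]].sum()
    if bottom_width >= thresholds.bottom_width_ratio * img.mask.sum(axis=1).max():
        return QUALITY_LOW
    lap_var = float(ndimage.laplace(lum)[img.mask == 1].var())
    if lap_var < thresholds.laplacian_var_min:
        return QUALITY_LOW
    return QUALITY_HIGH


# -- disk I/O --------------------------------------------------------------

MANIFEST_COLUMNS = ["id", "file", "mask_file", "quality", "defect_kind",
                    "magnitude", "seed"]


def mask_to_labelme(mask: np.ndarray, image_path: str = "",
                    every: int = 2) -> dict:
    """Labelme-style JSON document with one polygon traced from the mask
    contour (sub-pixel, via marching squares)."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    contour = max(contours, key=len)[::every]
    points = [[float(c + 0.5), float(r + 0.5)] for r, c in contour]
    return {
        "version": "5.0.0",
        "shapes": [{"label": "tongue", "points": points,
                    "shape_type": "polygon", "group_id": None, "flags": {}}],
        "imagePath": image_path,
        "imageHeight": int(mask.shape[0]),
        "imageWidth": int(mask.shape[1]),
    }


def write_dataset(images: Sequence[AnnotatedImage], outdir: str,
                  labelme: bool = False) -> str:
    """Write PNG images, 0/255 mask PNGs, optional Labelme JSONs, and a CSV
    manifest; returns the manifest path."""
    import imageio.v3 as iio

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for img in images:
        stem = img.id.replace(":", "_")
        file, mask_file = f"{stem}.png", f"{stem}_mask.png"
        iio.imwrite(os.path.join(outdir, file),
                    (img.pixels * 255.0).round().astype(np.uint8))
        iio.imwrite(os.path.join(outdir, mask_file),
                    (img.mask * 255).astype(np.uint8))
        if labelme:
            doc = mask_to_labelme(img.mask, image_path=file)
            with open(os.path.join(outdir, f"{stem}.json"), "w") as fh:
                json.dump(doc, fh)
        rows.append([img.id, file, mask_file, img.quality, img.defect.kind,
                     f"{img.defect.magnitude:g}", img.rng_seed])
    manifest = os.path.join(outdir, "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        writer.writerows(rows)
    return manifest
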