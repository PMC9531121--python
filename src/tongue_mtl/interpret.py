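"""Model interpretation: Grad-CAM saliency for the quality classifier and
Monte-Carlo-dropout uncertainty for the segmentation branch.

Grad-CAM weights the channels of the last shared convolutional activation
by the spatially-pooled gradient of the target-class score, rectifies the
weighted sum, upsamples it to the input size, and min-max normalizes.

MC-dropout keeps the bottleneck dropout active at inference and averages T
stochastic forward passes; the per-pixel uncertainty is the base-2
predictive entropy of the mean tongue probability p,
H(p) = -p log2 p - (1-p) log2(1-p), which lies in [0, 1] by construction
(maximal, 1, at p = 0.5; 0 where the model is saturated).  A variance-based
alternative (per-pixel sample variance scaled by 4 so 0.25 -> 1) is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import CLS_HIGH, CLS_LOW, MtlModel
from .nn import no_grad

TARGET_CLASSES = {"low": CLS_LOW, "high": CLS_HIGH}


@dataclass
class SaliencyMap:
    values: np.ndarray            # H x W in [0, 1]
    target_class: str             # "low" | "high"
    predicted_prob: float         # model probability of the target class


@dataclass
class UncertaintyMap:
    values: np.ndarray            # H x W in [0, 1]
    n_samples: int
    dropout_rate: float
    statistic: str = "entropy"


def gradcam_raw(activation: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """The Grad-CAM core on explicit arrays: per-channel weights are the
    spatial mean of ``grad``; the map is relu(sum_c w_c * A_c).

    ``activation``/``grad``: H x W x C (channels-last)."""
    weights = grad.mean(axis=(0, 1))
    return np.maximum((activation * weights).sum(axis=-1), 0.0)


def _minmax(raw: np.ndarray) -> np.ndarray:
    hi, lo = raw.max(), raw.min()
    if hi <= 0.0:
        return np.zeros_like(raw)
    if hi == lo:
        return np.ones_like(raw)
    return (raw - lo) / (hi - lo)


def grad_cam(model: MtlModel, image: np.ndarray, target_class: str = "high"
             ) -> SaliencyMap:
    """Saliency map of the classification head for one 3 x S x S image.

    The tap point is the last shared convolutional stage (the encoder
    bottleneck); the class score is the pre-softmax logit.
    """
    if model.classifier is None:
        raise ValueError("Grad-CAM needs a model with a classification head")
    if target_class not in TARGET_CLASSES:
        raise ValueError(f"target_class must be 'low' or 'high', "
                         f"got {target_class!r}")
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError("expected one 3 x S x S image")
    # the activation gradient only flows if upstream parameters require
    # grad; lift any encoder freeze for the duration of this pass
    was_frozen = model.encoder_frozen
    model.set_encoder_frozen(False)
    try:
        out = model.forward(image[None])
        idx = TARGET_CLASSES[target_class]
        score = out.cls_logits[0, idx]
        score.backward()
        act = out.tapped.data[0]          # h x w x C, channels-last
        grad = out.tapped.grad[0]
    finally:
        model.set_encoder_frozen(was_frozen)
    raw = gradcam_raw(act, grad)
    from skimage.transform import resize

    side = image.shape[1]
    values = resize(raw, (side, side), order=1, anti_aliasing=False,
                    preserve_range=True)
    return SaliencyMap(values=_minmax(values).astype(np.float32),
                       target_class=target_class,
                       predicted_prob=float(out.cls_array[0, idx]))


def mc_dropout_uncertainty(model: MtlModel, image: np.ndarray, T: int = 16,
                           seed: int = 0, statistic: str = "entropy"
                           ) -> UncertaintyMap:
    """Per-pixel segmentation uncertainty from T dropout-active passes."""
    if model.decoder is None:
        raise ValueError("uncertainty needs a model with a segmentation head")
    if model.cfg.dropout_rate <= 0.0:
        raise ValueError("model has no dropout; MC-dropout uncertainty "
                         "is undefined")
    if T < 2:
        raise ValueError("need at least T=2 stochastic passes")
    if statistic not in ("entropy", "variance"):
        raise ValueError(f"unknown statistic {statistic!r}")
    image = np.asarray(image, dtype=np.float32)
    rng = np.random.default_rng(seed)
    samples = []
    with no_grad():
        for _ in range(T):
            out = model.forward(image[None], mc_dropout=True, dropout_rng=rng)
            samples.append(out.seg_array[0, 1])       # tongue channel
    stack = np.stack(samples)
    if statistic == "entropy":
        p = stack.mean(axis=0)
        eps = 1e-12
        values = -(p * np.log2(p + eps) + (1.0 - p) * np.log2(1.0 - p + eps))
        values = np.clip(values, 0.0, 1.0)
    else:
        values = np.clip(4.0 * stack.var(axis=0), 0.0, 1.0)
    return UncertaintyMap(values=values.astype(np.float32), n_samples=T,
                          dropout_rate=model.cfg.dropout_rate,
                          statistic=statistic)


def render_panel(image: np.ndarray, mask_pred: np.ndarray,
                 overlay_values: np.ndarray, path: str,
                 pad: int = 2) -> np.ndarray:
    """Side-by-side PNG panel: input | predicted mask | overlay.

    The overlay blends red into the input proportionally to the map value
    (higher = redder).  Returns the composed H x (3W + 2*pad) x 3 array and
    writes it to ``path``.
    """
    import imageio.v3 as iio

    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3 and image.shape[0] == 3:
        image = image.transpose(1, 2, 0)
    H, W = image.shape[:2]
    if mask_pred.shape != (H, W) or overlay_values.shape != (H, W):
        raise ValueError("mask/overlay spatial sizes must match the image")
    mask_rgb = np.repeat(mask_pred.astype(np.float32)[:, :, None], 3, axis=2)
    alpha = overlay_values[:, :, None].astype(np.float32)
    red = np.zeros_like(image)
    red[:, :, 0] = 1.0
    overlay = image * (1.0 - alpha) + red * alpha
    gap = np.ones((H, pad, 3), dtype=np.float32)
    panel = np.concatenate([image, gap, mask_rgb, gap, overlay], axis=1)
    panel8 = (np.clip(panel, 0, 1) * 255.0).round().astype(np.uint8)
    iio.imwrite(path, panel8)
    return panel
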