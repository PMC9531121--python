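"""Task losses and multi-task objectives.

Segmentation is trained with binary cross-entropy plus a Dice term,

    L_CE   = -(1/N) sum_i [ y_i log(p_tongue,i) + (1-y_i) log(p_bg,i) ]
    L_Dice = 1 - 2 sum_i y_i p_i / (sum_i p_i^2 + sum_i y_i^2)
    L_Seg  = L_CE + L_Dice

and classification with per-image binary cross-entropy on the high-quality
probability.  The two tasks are combined either with equal weights,

    L_total = L_Cla + L_Seg,

or adaptively through trainable task-uncertainty scalars sigma_1
(classification) and sigma_2 (segmentation),

    L_total = sum_i [ L_i / (2 sigma_i^2) + log(1 + sigma_i^2) ],

where the log(1 + sigma^2) regularizer keeps the penalty nonnegative.  The
sigmas are optimized jointly with the network weights; positivity is
guaranteed by parametrizing sigma = 1e-3 + softplus(u) with u unconstrained.

Cross-entropy terms use mean reduction (over pixels and over the batch) so
the loss scale is independent of image resolution and batch size; the Dice
term uses the global-sum form above.  Probabilities are clamped to
[1e-7, 1 - 1e-7] and the Dice ratio is smoothed with eps = 1e-6 so every
loss is finite even for saturated predictions or empty masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .nn import Tensor, softplus

__all__ = [
    "SigmaParams", "LossBreakdown", "ce_pixel_loss", "dice_loss", "seg_loss",
    "cla_loss", "total_equal", "total_adaptive", "optimal_sigma",
    "adaptive_sigma_gradient",
]

PROB_EPS = 1e-7
DICE_EPS = 1e-6
SIGMA_FLOOR = 1e-3

Scalar = Union[float, Tensor]


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _check_binary(mask: np.ndarray, name: str) -> None:
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")


def _inv_softplus(y: float) -> float:
    # solves softplus(u) = y for y > 0
    return float(np.log(np.expm1(y)))


class SigmaParams:
    """The two trainable task-uncertainty scalars.

    ``sigma_cla`` weights the classification loss, ``sigma_seg`` the
    segmentation loss; both start at 1.0.  The underlying free parameters
    ``u_*`` are what the optimizer updates; sigma = 1e-3 + softplus(u) > 0
    always.
    """

    def __init__(self, init: float = 1.0, trainable: bool = True):
        if init <= SIGMA_FLOOR:
            raise ValueError(f"initial sigma must exceed the floor {SIGMA_FLOOR}")
        u0 = _inv_softplus(init - SIGMA_FLOOR)
        self.u_cla = Tensor(np.float32(u0), requires_grad=trainable)
        self.u_seg = Tensor(np.float32(u0), requires_grad=trainable)
        self.trainable = trainable

    def sigma_tensors(self) -> tuple[Tensor, Tensor]:
        return (softplus(self.u_cla) + SIGMA_FLOOR,
                softplus(self.u_seg) + SIGMA_FLOOR)

    @property
    def sigma_cla(self) -> float:
        return float(np.logaddexp(0.0, self.u_cla.data) + SIGMA_FLOOR)

    @property
    def sigma_seg(self) -> float:
        return float(np.logaddexp(0.0, self.u_seg.data) + SIGMA_FLOOR)

    def parameters(self):
        return [self.u_cla, self.u_seg]

    def assert_positive(self) -> None:
        assert self.sigma_cla > 0 and self.sigma_seg > 0


@dataclass
class LossBreakdown:
    """All loss components of one step/epoch, for logging.

    Invariant: ``l_seg == l_ce + l_dice`` exactly as computed.
    ``weights_effective`` holds (1/(2 sigma_cla^2), 1/(2 sigma_seg^2)) in
    adaptive mode, (1.0, 1.0) otherwise.
    """

    l_ce: float = float("nan")
    l_dice: float = float("nan")
    l_seg: float = float("nan")
    l_cla: float = float("nan")
    l_total: float = float("nan")
    weights_effective: tuple = (1.0, 1.0)

    def as_dict(self) -> dict:
        return {"l_ce": self.l_ce, "l_dice": self.l_dice, "l_seg": self.l_seg,
                "l_cla": self.l_cla, "l_total": self.l_total,
                "w_cla": self.weights_effective[0],
                "w_seg": self.weights_effective[1]}


def ce_pixel_loss(seg_probs: Tensor | np.ndarray, mask: np.ndarray) -> Tensor:
    """Per-pixel binary cross-entropy, mean over all pixels (and batch).

    ``seg_probs``: (..., 2, H, W) softmax probabilities, channel 1 = tongue;
    ``mask``: (..., H, W) binary ground truth.
    """
    probs = _lift(seg_probs)
    mask = np.asarray(mask)
    if probs.shape[-2:] != mask.shape[-2:] or probs.shape[:-3] != mask.shape[:-2]:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs mask {mask.shape}")
    _check_binary(mask, "mask")
    y = mask.astype(np.float32)
    p = probs.clip(PROB_EPS, 1.0 - PROB_EPS)
    ch = probs.ndim - 3
    idx_t = (slice(None),) * ch + (1,)
    idx_b = (slice(None),) * ch + (0,)
    p_t, p_b = p[idx_t], p[idx_b]
    ll = Tensor(y) * p_t.log() + Tensor(1.0 - y) * p_b.log()
    return -ll.mean()


def dice_loss(seg_probs: Tensor | np.ndarray, mask: np.ndarray) -> Tensor:
    """Dice loss on the tongue channel, global-sum form with eps smoothing.

    ``seg_probs`` may be the full (..., 2, H, W) softmax output or already
    the tongue-channel probabilities with the same shape as ``mask``.
    """
    probs = _lift(seg_probs)
    mask = np.asarray(mask)
    if probs.ndim == mask.ndim + 1:
        idx = (slice(None),) * (probs.ndim - 3) + (1,)
        probs = probs[idx]
    if probs.shape != mask.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs mask {mask.shape}")
    _check_binary(mask, "mask")
    y = Tensor(mask.astype(np.float32))
    inter = (probs * y).sum()
    denom = (probs * probs).sum() + (y * y).sum()
    return 1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)


def seg_loss(seg_probs: Tensor | np.ndarray, mask: np.ndarray) -> LossBreakdown:
    """Combined segmentation loss; returns a LossBreakdown fragment whose
    tensor total is kept on the ``l_seg_tensor`` attribute for backprop."""
    ce = ce_pixel_loss(seg_probs, mask)
    dc = dice_loss(seg_probs, mask)
    total = ce + dc
    frag = LossBreakdown(l_ce=float(ce.data), l_dice=float(dc.data),
                         l_seg=float(ce.data) + float(dc.data))
    frag.l_seg_tensor = total  # type: ignore[attr-defined]
    return frag


def cla_loss(cls_probs: Tensor | np.ndarray, labels: np.ndarray) -> Tensor:
    """Per-image binary cross-entropy on the high-quality probability,
    averaged over the batch.

    ``cls_probs``: (B, 2) softmax output (column 1 = high quality) or a
    (B,) vector of high-quality probabilities; ``labels``: (B,) in {0, 1}
    with 1 = high quality.
    """
    probs = _lift(cls_probs)
    labels = np.asarray(labels)
    _check_binary(labels, "labels")
    if probs.ndim == 2:
        probs = probs[:, 1]
    if probs.shape != labels.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs labels {labels.shape}")
    y = labels.astype(np.float32)
    p = probs.clip(PROB_EPS, 1.0 - PROB_EPS)
    ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -ll.mean()


def total_equal(l_cla: Scalar, l_seg: Scalar) -> Tensor:
    """Equal-weight multi-task objective: plain sum of the task losses."""
    return _lift(l_cla) + _lift(l_seg)


def total_adaptive(l_cla: Scalar, l_seg: Scalar, sigmas: SigmaParams) -> Tensor:
    """Adaptive multi-task objective
    ``sum_i [ L_i/(2 sigma_i^2) + log(1 + sigma_i^2) ]`` with i=1 the
    classification task and i=2 the segmentation task; differentiable in
    the losses and in the sigma free parameters."""
    s1, s2 = sigmas.sigma_tensors()
    l1, l2 = _lift(l_cla), _lift(l_seg)
    term1 = l1 / (2.0 * s1 * s1) + (1.0 + s1 * s1).log()
    term2 = l2 / (2.0 * s2 * s2) + (1.0 + s2 * s2).log()
    return term1 + term2


def adaptive_sigma_gradient(loss_value: float, sigma: float) -> float:
    """Analytic d/d sigma of one adaptive term: -L/sigma^3 + 2 sigma/(1+sigma^2)."""
    return -loss_value / sigma ** 3 + 2.0 * sigma / (1.0 + sigma ** 2)


def optimal_sigma(loss_value: float) -> float:
    """The unique positive stationary sigma for a fixed task loss L > 0.

    Setting the sigma-gradient to zero gives 2 sigma^4 = L (1 + sigma^2);
    with s = sigma^2 this is 2 s^2 - L s - L = 0, whose positive root is
    s = (L + sqrt(L^2 + 8 L)) / 4.
    """
    if loss_value <= 0:
        raise ValueError("stationary sigma requires a positive loss")
    s = (loss_value + np.sqrt(loss_value ** 2 + 8.0 * loss_value)) / 4.0
    return float(np.sqrt(s))
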