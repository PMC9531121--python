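"""Training strategy and the four-arm ablation harness.

The reference training recipe: Adam (learning rate 1e-4, weight decay
5e-4), batch size 4, encoder frozen for the first 10 epochs (only decoder
and classification branch update), then 40 more epochs with all weights
free at the same learning rate and without resetting the Adam state.  In
adaptive mode the two task-uncertainty scalars are optimized jointly with
the network weights, start at 1.0, are excluded from weight decay, and are
logged every epoch.

The ablation arms:

=============  ==============  ======================
arm            tasks           input images
=============  ==============  ======================
STL_OTI        classification  original scenes
STL_ETI        classification  background-removed (extracted) tongue
MTL_equal      cls + seg       original scenes
MTL_adaptive   cls + seg       original scenes
=============  ==============  ======================

All arms share the same stratified 70/15/15 split and seed.  Model
selection keeps the epoch with the best validation accuracy
(classification-bearing arms) or best validation DSC (segmentation-only).

Desk-scale defaults trade width for wall-clock so the whole ablation runs
on one CPU core; the clinical-scale recipe is preserved in the "paper"
profile (see ``tongue_mtl.config``).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import losses as L
from . import metrics as M
from .data import augment_pair, extract_tongue, normalize_batch, split_dataset
from .model import (ModelConfig, MtlModel, TASK_BOTH, TASK_CLASSIFICATION,
                    TASK_SEGMENTATION, build_model, single_task_variant)
from .nn import Adam, no_grad
from .synthetic import AnnotatedImage, QUALITY_HIGH

logger = logging.getLogger("tongue_mtl")

LOSS_MODES = ("single_cla", "single_seg", "mtl_equal", "mtl_adaptive")
ARMS = ("STL_OTI", "STL_ETI", "MTL_equal", "MTL_adaptive")
ARM_SPECS = {
    # arm -> (loss_mode, input_variant)
    "STL_OTI": ("single_cla", "original"),
    "STL_ETI": ("single_cla", "extracted"),
    "MTL_equal": ("mtl_equal", "original"),
    "MTL_adaptive": ("mtl_adaptive", "original"),
}


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    lr: float = 1e-4
    sigma_lr: float = 1e-2        # the two uncertainty scalars are O(1)
    weight_decay: float = 5e-4
    batch_size: int = 4
    freeze_epochs: int = 10
    total_epochs: int = 50
    loss_mode: str = "mtl_adaptive"
    input_variant: str = "original"
    seed: int = 0
    device: str = "cpu"            # tag only; the engine is CPU-native
    augment: bool = True
    normalize: str = "unit"
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.freeze_epochs > self.total_epochs:
            raise ValueError("freeze_epochs cannot exceed total_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")
        if self.input_variant not in ("original", "extracted"):
            raise ValueError(f"unknown input_variant {self.input_variant!r}")


@dataclass
class SplitArrays:
    """One split's arrays: raw [0,1] images (N x 3 x S x S), binary masks,
    quality labels (1 = high), and ids."""

    images: np.ndarray
    masks: np.ndarray
    labels: np.ndarray
    ids: list


@dataclass
class TrainLog:
    loss_mode: str
    records: list = field(default_factory=list)
    best_epoch: int = -1

    COLUMNS = ["epoch", "l_ce", "l_dice", "l_seg", "l_cla", "l_total",
               "sigma_cla", "sigma_seg", "sigma_cla_pre", "sigma_seg_pre",
               "val_loss", "val_acc", "val_dsc", "seconds"]

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=self.COLUMNS, extrasaction="ignore")
            w.writeheader()
            w.writerows(self.records)


def arrays_from_annotated(images: Sequence[AnnotatedImage],
                          variant: str = "original") -> SplitArrays:
    """Stack scenes into network-ready raw arrays (channels-first, [0, 1])."""
    pix = []
    for im in images:
        p = extract_tongue(im.pixels, im.mask) if variant == "extracted" else im.pixels
        pix.append(p.transpose(2, 0, 1))
    return SplitArrays(
        images=np.ascontiguousarray(np.stack(pix), dtype=np.float32),
        masks=np.stack([im.mask for im in images]).astype(np.uint8),
        labels=np.array([1 if im.quality == QUALITY_HIGH else 0 for im in images],
                        dtype=np.uint8),
        ids=[im.id for im in images])


def _batch_losses(out, masks, labels, cfg: TrainConfig, sigmas):
    """Returns (total loss tensor, LossBreakdown)."""
    bd = L.LossBreakdown()
    l_cla_t = l_seg_t = None
    if cfg.loss_mode != "single_seg":
        l_cla_t = L.cla_loss(out.cls_probs, labels)
        bd.l_cla = float(l_cla_t.data)
    if cfg.loss_mode != "single_cla":
        frag = L.seg_loss(out.seg_probs, masks)
        bd.l_ce, bd.l_dice, bd.l_seg = frag.l_ce, frag.l_dice, frag.l_seg
        l_seg_t = frag.l_seg_tensor
    if cfg.loss_mode == "single_cla":
        total = l_cla_t
    elif cfg.loss_mode == "single_seg":
        total = l_seg_t
    elif cfg.loss_mode == "mtl_equal":
        total = L.total_equal(l_cla_t, l_seg_t)
    else:
        total = L.total_adaptive(l_cla_t, l_seg_t, sigmas)
        bd.weights_effective = (1.0 / (2.0 * sigmas.sigma_cla ** 2),
                                1.0 / (2.0 * sigmas.sigma_seg ** 2))
    bd.l_total = float(total.data)
    return total, bd


def _quick_val(model, data: SplitArrays, cfg: TrainConfig, batch: int = 32):
    """Validation loss / accuracy / mean DSC in evaluation mode."""
    n = len(data.images)
    tot, acc_hits, dscs = 0.0, 0, []
    sig_eval = L.SigmaParams(trainable=False)
    with no_grad():
        for lo in range(0, n, batch):
            x = normalize_batch(data.images[lo:lo + batch], cfg.normalize)
            out = model.forward(x)
            total, _ = _batch_losses(out, data.masks[lo:lo + batch],
                                     data.labels[lo:lo + batch], cfg, sig_eval)
            tot += float(total.data) * (len(x) / n)
            if out.cls_probs is not None and cfg.loss_mode != "single_seg":
                pred = (out.cls_array[:, 1] >= out.cls_array[:, 0]).astype(np.uint8)
                acc_hits += int((pred == data.labels[lo:lo + batch]).sum())
            if out.seg_probs is not None and cfg.loss_mode != "single_cla":
                seg_pred = (out.seg_array[:, 1] > out.seg_array[:, 0]).astype(np.uint8)
                for b in range(len(seg_pred)):
                    c = M.confusion(seg_pred[b], data.masks[lo + b])
                    dscs.append(M.segmentation_metrics(c)["dsc"])
    val_acc = acc_hits / n if cfg.loss_mode != "single_seg" else float("nan")
    val_dsc = float(np.mean(dscs)) if dscs else float("nan")
    return tot, val_acc, val_dsc


def train(model: MtlModel, data: dict, cfg: TrainConfig,
          sigmas: Optional[L.SigmaParams] = None):
    """Train ``model`` on ``data["train"]`` with per-epoch validation on
    ``data["val"]``; returns ``(model, TrainLog, sigmas)``.

    The model is left holding the best-validation-epoch weights.  Fully
    deterministic given ``cfg.seed``.
    """
    tr, va = data["train"], data["val"]
    if len(tr.images) == 0 or len(va.images) == 0:
        raise ValueError("train and val splits must be nonempty")
    if cfg.loss_mode != "single_seg" and model.classifier is None:
        raise ValueError(f"loss_mode {cfg.loss_mode} needs a classification head")
    if cfg.loss_mode != "single_cla" and model.decoder is None:
        raise ValueError(f"loss_mode {cfg.loss_mode} needs a segmentation head")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    dropout_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(1,)))
    if sigmas is None:
        sigmas = L.SigmaParams()
    opt = Adam(list(model.parameters()), lr=cfg.lr,
               weight_decay=cfg.weight_decay)
    # sigma scalars: own learning rate, never weight-decayed (decay would
    # bias the objective toward sigma = 0)
    sig_opt = (Adam(sigmas.parameters(), lr=cfg.sigma_lr)
               if cfg.loss_mode == "mtl_adaptive" else None)

    select_by_acc = cfg.loss_mode != "single_seg"
    best_score, best_state = -np.inf, None
    log = TrainLog(loss_mode=cfg.loss_mode)
    n = len(tr.images)
    for epoch in range(cfg.total_epochs):
        t0 = time.time()
        model.set_encoder_frozen(epoch < cfg.freeze_epochs)
        sig_pre = (sigmas.sigma_cla, sigmas.sigma_seg)
        order = rng.permutation(n)
        sums: dict[str, float] = {}
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            imgs = tr.images[idx]
            masks = tr.masks[idx]
            if cfg.augment:
                aug_i, aug_m = [], []
                for b in range(len(idx)):
                    seed_b = int(rng.integers(0, 2 ** 31 - 1))
                    ai, am = augment_pair(imgs[b].transpose(1, 2, 0),
                                          masks[b], seed_b)
                    aug_i.append(ai.transpose(2, 0, 1))
                    aug_m.append(am)
                imgs = np.stack(aug_i)
                masks = np.stack(aug_m)
                # a rotation can push a small tongue fully out of frame;
                # keep the pre-augmentation pair in that rare case
                for b in range(len(idx)):
                    if masks[b].sum() == 0 or masks[b].sum() == masks[b].size:
                        imgs[b] = tr.images[idx[b]]
                        masks[b] = tr.masks[idx[b]]
            x = normalize_batch(imgs, cfg.normalize)
            out = model.forward(x, training=True, dropout_rng=dropout_rng)
            total, bd = _batch_losses(out, masks, tr.labels[idx], cfg, sigmas)
            for k, v in bd.as_dict().items():
                if np.isfinite(v) or k not in sums:
                    sums[k] = sums.get(k, 0.0) + v
            n_batches += 1
            if not np.isfinite(total.data):
                bad = [k for k, v in bd.as_dict().items() if not np.isfinite(v)]
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} (components: {bad})")
            opt.zero_grad()
            if sig_opt is not None:
                sig_opt.zero_grad()
            total.backward()
            opt.step()
            if sig_opt is not None:
                sig_opt.step()
        if cfg.loss_mode == "mtl_adaptive":
            sigmas.assert_positive()
        val_loss, val_acc, val_dsc = _quick_val(model, va, cfg)
        rec = {k: v / n_batches for k, v in sums.items()}
        rec.update(epoch=epoch, sigma_cla=sigmas.sigma_cla,
                   sigma_seg=sigmas.sigma_seg, sigma_cla_pre=sig_pre[0],
                   sigma_seg_pre=sig_pre[1], val_loss=val_loss,
                   val_acc=val_acc, val_dsc=val_dsc,
                   seconds=time.time() - t0)
        log.records.append(rec)
        score = val_acc if select_by_acc else val_dsc
        if score > best_score:
            best_score = score
            best_state = [a.copy() for a in model.state_arrays()]
            log.best_epoch = epoch
        logger.info("epoch %d: train %.4f val %.4f acc %.3f dsc %.3f",
                    epoch, rec.get("l_total", float("nan")), val_loss,
                    val_acc, val_dsc)
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.set_encoder_frozen(False)
    return model, log, sigmas


# -- sigma dynamics --------------------------------------------------------

def sigma_trajectory(log: TrainLog, tail: int = 5):
    """Per-epoch (epoch, sigma_cla, sigma_seg) triples plus the converged
    values (mean of the last ``tail`` end-of-epoch sigmas)."""
    if log.loss_mode != "mtl_adaptive":
        raise ValueError("sigma trajectory requires an mtl_adaptive log")
    if not log.records:
        raise ValueError("empty training log: no epochs were run")
    traj = [(r["epoch"], r["sigma_cla"], r["sigma_seg"]) for r in log.records]
    tail_recs = traj[-tail:]
    conv = (float(np.mean([t[1] for t in tail_recs])),
            float(np.mean([t[2] for t in tail_recs])))
    return traj, conv


def fit_sigmas_to_constant_losses(l_cla: float, l_seg: float, steps: int = 500,
                                  lr: float = 0.02, init: float = 1.0):
    """Optimize only the sigma pair against frozen task losses.

    Isolates the sigma dynamics of the adaptive objective from network
    training; the end point should approach the analytic stationary sigma
    for each task loss (``losses.optimal_sigma``).
    """
    sig = L.SigmaParams(init=init)
    opt = Adam(sig.parameters(), lr=lr)
    traj = []
    for _ in range(steps):
        total = L.total_adaptive(l_cla, l_seg, sig)
        opt.zero_grad()
        total.backward()
        opt.step()
        traj.append((sig.sigma_cla, sig.sigma_seg))
    return sig, traj


# -- ablation harness ------------------------------------------------------

@dataclass
class ArmResult:
    arm: str
    report: M.MetricsReport
    log: TrainLog
    sigmas: Optional[L.SigmaParams] = None


def _split_bundle(images: Sequence[AnnotatedImage], variant: str,
                  split) -> dict:
    by_id = {im.id: im for im in images}
    return {name: arrays_from_annotated([by_id[i] for i in ids], variant)
            for name, ids in (("train", split.train), ("val", split.val),
                              ("test", split.test))}


def run_ablation(images: Sequence[AnnotatedImage], base_cfg: TrainConfig,
                 arms: Sequence[str] = ARMS) -> dict[str, ArmResult]:
    """Train and evaluate the requested ablation arms on one dataset.

    Every arm shares the stratified split derived from ``base_cfg.seed``
    and the same initialization seed; each arm trains on its designated
    input variant and is scored on the held-out test split.
    """
    for arm in arms:
        if arm not in ARM_SPECS:
            raise ValueError(f"unknown ablation arm {arm!r}")
    if "STL_ETI" in arms and any(im.mask is None for im in images):
        raise ValueError("STL_ETI requires ground-truth masks for extraction")
    split = split_dataset([(im.id, im.quality) for im in images],
                          seed=base_cfg.seed, stratified=True)
    results: dict[str, ArmResult] = {}
    for arm in arms:
        loss_mode, variant = ARM_SPECS[arm]
        cfg = replace(base_cfg, loss_mode=loss_mode, input_variant=variant)
        bundle = _split_bundle(images, variant, split)
        if loss_mode.startswith("single"):
            task = (TASK_CLASSIFICATION if loss_mode == "single_cla"
                    else TASK_SEGMENTATION)
            model = single_task_variant(cfg.model, task, init_seed=cfg.seed)
        else:
            model = build_model(cfg.model, init_seed=cfg.seed)
        logger.info("ablation arm %s (%s on %s images)", arm, loss_mode, variant)
        model, log, sigmas = train(model, bundle, cfg)
        te = bundle["test"]
        mode = "classification" if loss_mode == "single_cla" else \
            ("segmentation" if loss_mode == "single_seg" else "both")
        report = M.evaluate_split(
            model, normalize_batch(te.images, cfg.normalize), te.masks,
            te.labels, mode=mode)
        results[arm] = ArmResult(
            arm=arm, report=report, log=log,
            sigmas=sigmas if loss_mode == "mtl_adaptive" else None)
    return results
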