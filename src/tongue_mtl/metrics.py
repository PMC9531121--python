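"""Evaluation measures for quality classification and tongue segmentation.

Classification (per image, positive class = high quality):
    accuracy  = (TP + TN) / total
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 / (1/precision + 1/recall)

Segmentation (per pixel, positive class = tongue):
    DSC   = 2 TP / (2 TP + FP + FN)
    JI    = TP / (TP + FP + FN)
    MIoU  = (IoU_tongue + IoU_background) / 2
    FWIoU = sum over classes of prevalence * IoU

Conventions (flagged in reports): a precision/recall/F1 with a zero
denominator is 0; a class absent from both prediction and truth has IoU 1
in MIoU (its FWIoU weight is zero anyway); segmentation metrics are
computed per image then reported as mean +/- population standard deviation,
with a dataset-pooled variant behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

CLS_METRICS = ("accuracy", "precision", "recall", "f1")
SEG_METRICS = ("dsc", "ji", "miou", "fwiou")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    """The eight evaluation numbers for one model on one data split.

    Classification metrics are pooled over images; segmentation metrics are
    per-image means with population standard deviations (``*_sd``).
    Fields left as ``None`` were not evaluated (single-task arms).
    """

    accuracy: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    dsc: Optional[float] = None
    ji: Optional[float] = None
    miou: Optional[float] = None
    fwiou: Optional[float] = None
    dsc_sd: Optional[float] = None
    ji_sd: Optional[float] = None
    miou_sd: Optional[float] = None
    fwiou_sd: Optional[float] = None
    n_items: int = 0
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact TP/FP/TN/FN counts for binary arrays of any (equal) shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(tp=int((p & t).sum()), fp=int((p & ~t).sum()),
                           tn=int((~p & ~t).sum()), fn=int((~p & t).sum()))


def classification_metrics(c: ConfusionCounts) -> dict:
    """Accuracy / precision / recall / F1 with zero-denominator -> 0."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = (c.tp + c.tn) / c.total
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = (2.0 * prec * rec / (prec + rec)) if (prec + rec) else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def segmentation_metrics(c: ConfusionCounts) -> dict:
    """DSC / JI / MIoU / FWIoU from one pixel-level confusion quadruple."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    denom_fg = 2 * c.tp + c.fp + c.fn
    dsc = 2.0 * c.tp / denom_fg if denom_fg else 1.0
    iou_fg = c.tp / (c.tp + c.fp + c.fn) if (c.tp + c.fp + c.fn) else 1.0
    iou_bg = c.tn / (c.tn + c.fp + c.fn) if (c.tn + c.fp + c.fn) else 1.0
    ji = iou_fg
    miou = 0.5 * (iou_fg + iou_bg)
    fwiou = ((c.tp + c.fn) * iou_fg + (c.tn + c.fp) * iou_bg) / c.total
    return {"dsc": dsc, "ji": ji, "miou": miou, "fwiou": fwiou}


def evaluate_split(model, images: np.ndarray, masks: Optional[np.ndarray],
                   labels: Optional[np.ndarray], mode: str = "both",
                   batch_size: int = 16, pooled_segmentation: bool = False
                   ) -> MetricsReport:
    """Run ``model`` over a split and compute the requested metric block.

    ``images``: N x 3 x S x S float32 (already normalized); ``masks``:
    N x S x S binary (segmentation modes); ``labels``: N binary with 1 =
    high quality (classification modes).  Classification predictions take
    the argmax of the 2-way output with ties resolved to high quality
    (flagged); segmentation predictions take the per-pixel channel argmax.
    """
    from .nn import no_grad

    if mode not in ("classification", "segmentation", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(images)
    if n == 0:
        raise ValueError("empty sample list")
    want_cls = mode in ("classification", "both")
    want_seg = mode in ("segmentation", "both")
    report = MetricsReport(n_items=n)
    cls_probs = []
    per_image: list[dict] = []
    pooled = ConfusionCounts()
    with no_grad():
        for lo in range(0, n, batch_size):
            out = model.forward(images[lo:lo + batch_size])
            if want_cls:
                if out.cls_probs is None:
                    raise ValueError("model has no classification head")
                cls_probs.append(out.cls_array)
            if want_seg:
                if out.seg_probs is None:
                    raise ValueError("model has no segmentation head")
                seg_pred = (out.seg_array[:, 1] > out.seg_array[:, 0]).astype(np.uint8)
                for b in range(seg_pred.shape[0]):
                    c = confusion(seg_pred[b], masks[lo + b])
                    per_image.append(segmentation_metrics(c))
                    pooled = pooled + c
    if want_cls:
        probs = np.concatenate(cls_probs, axis=0)
        ties = probs[:, 1] == probs[:, 0]
        if ties.any():
            report.flags.append(f"{int(ties.sum())} tie(s) resolved to high quality")
        pred = (probs[:, 1] >= probs[:, 0]).astype(np.uint8)
        cm = classification_metrics(confusion(pred, np.asarray(labels)))
        report.accuracy, report.precision = cm["accuracy"], cm["precision"]
        report.recall, report.f1 = cm["recall"], cm["f1"]
    if want_seg:
        if pooled_segmentation:
            sm = segmentation_metrics(pooled)
            for k in SEG_METRICS:
                setattr(report, k, sm[k])
                setattr(report, f"{k}_sd", 0.0)
            report.flags.append("segmentation metrics pooled over pixels")
        else:
            for k in SEG_METRICS:
                vals = np.array([d[k] for d in per_image])
                setattr(report, k, float(vals.mean()))
                setattr(report, f"{k}_sd", float(vals.std()))  # population sd
    return report


def report_table(reports: dict[str, MetricsReport]) -> str:
    """Markdown table in the standard column order (classification block,
    then segmentation block, mean +/- sd)."""
    header = ("| Model | Accuracy | Precision | Recall | F1-score "
              "| DSC | JI | MIoU | FWIoU |")
    sep = "|" + "---|" * 9
    lines = [header, sep]

    def fmt(v, sd=None):
        if v is None:
            return "--"
        return f"{v:.4f}" if sd is None else f"{v:.4f} ± {sd:.4f}"

    for name, r in reports.items():
        cells = [fmt(r.accuracy), fmt(r.precision), fmt(r.recall), fmt(r.f1),
                 fmt(r.dsc, r.dsc_sd), fmt(r.ji, r.ji_sd),
                 fmt(r.miou, r.miou_sd), fmt(r.fwiou, r.fwiou_sd)]
        lines.append("| " + " | ".join([name] + cells) + " |")
    return "\n".join(lines)
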