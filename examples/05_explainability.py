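"""Grad-CAM saliency and MC-dropout uncertainty on a trained model.

Grad-CAM shows where the classifier found its evidence; the uncertainty
map is the base-2 predictive entropy of the mean tongue probability over T
dropout-active passes (1 = maximally uncertain, 0 = saturated), which
concentrates at the segmentation boundary.
"""

import numpy as np

from tongue_mtl.config import build_train_config
from tongue_mtl.interpret import grad_cam, mc_dropout_uncertainty, render_panel
from tongue_mtl.model import build_model
from tongue_mtl.nn import no_grad
from tongue_mtl.synthetic import DefectSpec, apply_defect, generate_dataset
from tongue_mtl.trainer import arrays_from_annotated, train

from tongue_mtl.data import split_dataset

images = generate_dataset(n_high=30, n_low=24, seed=6)
cfg = build_train_config("desk", seed=0)
split = split_dataset([(im.id, im.quality) for im in images], seed=0)
by_id = {im.id: im for im in images}
data = {"train": arrays_from_annotated([by_id[i] for i in split.train]),
        "val": arrays_from_annotated([by_id[i] for i in split.val])}
model, _, _ = train(build_model(cfg.model, 0), data, cfg)

clean = next(im for im in images if im.quality == "high")
img = clean.pixels.transpose(2, 0, 1)

sal = grad_cam(model, img, target_class="high")
print(f"Grad-CAM: P(high) = {sal.predicted_prob:.3f}, "
      f"map range [{sal.values.min():.2f}, {sal.values.max():.2f}]")

unc = mc_dropout_uncertainty(model, img, T=16, seed=0)
print(f"mean uncertainty (clean scene): {unc.values.mean():.4f}")

blurred = apply_defect(clean, DefectSpec("blur", 3.0))
unc_b = mc_dropout_uncertainty(model, blurred.pixels.transpose(2, 0, 1),
                               T=16, seed=0)
print(f"mean uncertainty (blurred copy): {unc_b.values.mean():.4f}")
# degraded inputs typically raise boundary uncertainty

with no_grad():
    out = model.forward(img[None])
mask_pred = (out.seg_array[0, 1] > out.seg_array[0, 0]).astype(np.uint8)
render_panel(img, mask_pred, unc.values, "scratch_uncertainty_panel.png")
print("wrote scratch_uncertainty_panel.png (input | mask | red=uncertain)")
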