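"""Train the adaptive multi-task model on a small synthetic set and watch
the task-uncertainty weights move.

The joint objective is sum_i [ L_i/(2 sigma_i^2) + log(1 + sigma_i^2) ]
with trainable sigma_1 (classification) and sigma_2 (segmentation), both
starting at 1.  A converged sigma below 1 means the task earned a weight
above the equal-weight baseline.
"""

from tongue_mtl.config import build_train_config
from tongue_mtl.data import split_dataset
from tongue_mtl.model import build_model
from tongue_mtl.synthetic import generate_dataset
from tongue_mtl.trainer import arrays_from_annotated, sigma_trajectory, train

images = generate_dataset(n_high=40, n_low=34, seed=2)
cfg = build_train_config("desk", seed=0)
split = split_dataset([(im.id, im.quality) for im in images], seed=0)
by_id = {im.id: im for im in images}
data = {"train": arrays_from_annotated([by_id[i] for i in split.train]),
        "val": arrays_from_annotated([by_id[i] for i in split.val])}

model, log, sigmas = train(build_model(cfg.model, init_seed=0), data, cfg)

print("epoch  l_cla   l_seg   val_acc  val_dsc  sigma_cla  sigma_seg")
for r in log.records:
    print(f"{r['epoch']:>5}  {r['l_cla']:.4f}  {r['l_seg']:.4f}  "
          f"{r['val_acc']:.3f}    {r['val_dsc']:.3f}    "
          f"{r['sigma_cla']:.3f}      {r['sigma_seg']:.3f}")

traj, (conv_cla, conv_seg) = sigma_trajectory(log)
print(f"\nconverged sigma (last-5 mean): classification {conv_cla:.3f}, "
      f"segmentation {conv_seg:.3f}")
print(f"best epoch by validation accuracy: {log.best_epoch}")
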