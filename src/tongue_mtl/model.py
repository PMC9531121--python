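"""Multi-task network: shared convolutional encoder feeding a U-Net-style
segmentation decoder (auxiliary task) and a residual-block quality
classification head (main task).

Architecture
------------
* Encoder (shared): ``encoder_depth`` VGG-style stages of two 3x3
  convolutions + ReLU followed by 2x2 max-pooling, channel width doubling
  per stage, then a two-convolution bottleneck with channel dropout
  (default rate 0.5).
* Segmentation branch: mirror-image decoder — bilinear 2x upsampling,
  concatenation with the matching encoder stage (skip connection), two 3x3
  convolutions — ending in a 1x1 convolution and a 2-channel softmax
  (background, tongue) at input resolution.
* Classification branch: ``cls_blocks`` ResNet-style residual blocks on the
  bottleneck feature map, global average pooling, and a fully connected
  2-way softmax (low-quality, high-quality).

Single-task variants attach only one branch to the same encoder; they are
used by the ablation harness.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor

SEG_BACKGROUND, SEG_TONGUE = 0, 1
CLS_LOW, CLS_HIGH = 0, 1

TASK_BOTH = "both"
TASK_SEGMENTATION = "segmentation"
TASK_CLASSIFICATION = "classification"


@dataclass
class ModelConfig:
    """Hyperparameters of the multi-task network.

    ``input_side`` must be divisible by ``2**encoder_depth`` so that the
    decoder can mirror the encoder exactly.
    """

    encoder_depth: int = 4
    base_channels: int = 16
    dropout_rate: float = 0.5
    cls_blocks: int = 2
    pretrained: bool = False
    input_side: int = 224
    heads: str = TASK_BOTH

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.input_side % (2 ** self.encoder_depth) != 0:
            raise ValueError(
                f"input_side={self.input_side} is not divisible by "
                f"2^encoder_depth={2 ** self.encoder_depth}")
        if self.heads not in (TASK_BOTH, TASK_SEGMENTATION, TASK_CLASSIFICATION):
            raise ValueError(f"unknown heads tag {self.heads!r}")


@dataclass
class MtlOutput:
    """Paired network outputs.

    seg_probs: B x 2 x H x W softmax over channels (background, tongue);
    ``None`` for classification-only models.
    cls_probs: B x 2 softmax (low-quality, high-quality); ``None`` for
    segmentation-only models.
    """

    seg_probs: Optional[Tensor] = None
    cls_probs: Optional[Tensor] = None
    cls_logits: Optional[Tensor] = None   # pre-softmax 2-way scores
    tapped: Optional[Tensor] = None       # last shared activation (B,H,W,C),
                                          # channels-last; Grad-CAM tap point

    @property
    def seg_array(self) -> Optional[np.ndarray]:
        return None if self.seg_probs is None else self.seg_probs.data

    @property
    def cls_array(self) -> Optional[np.ndarray]:
        return None if self.cls_probs is None else self.cls_probs.data


class _ConvBlock(nn.Module):
    def __init__(self, c_in, c_out, rng):
        self.c1 = nn.Conv2d(c_in, c_out, 3, rng)
        self.c2 = nn.Conv2d(c_out, c_out, 3, rng)

    def __call__(self, x):
        return nn.relu(self.c2(nn.relu(self.c1(x))))


class _ResBlock(nn.Module):
    def __init__(self, ch, rng):
        self.c1 = nn.Conv2d(ch, ch, 3, rng)
        self.c2 = nn.Conv2d(ch, ch, 3, rng)

    def __call__(self, x):
        return nn.relu(x + self.c2(nn.relu(self.c1(x))))


class _Encoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        chans = [cfg.base_channels * 2 ** s for s in range(cfg.encoder_depth)]
        self.stages = [_ConvBlock(3 if s == 0 else chans[s - 1], chans[s], rng)
                       for s in range(cfg.encoder_depth)]
        self.bottleneck = _ConvBlock(chans[-1], chans[-1] * 2, rng)
        self.out_channels = chans[-1] * 2
        self.skip_channels = chans

    def __call__(self, x):
        skips = []
        for stage in self.stages:
            x = stage(x)
            skips.append(x)
            x = nn.maxpool2x2(x)
        return self.bottleneck(x), skips


class _Decoder(nn.Module):
    def __init__(self, cfg: ModelConfig, skip_channels, bottom_channels, rng):
        self.blocks = []
        c = bottom_channels
        for s in reversed(range(cfg.encoder_depth)):
            self.blocks.append(_ConvBlock(c + skip_channels[s],
                                          skip_channels[s], rng))
            c = skip_channels[s]
        self.head = nn.Conv2d(c, 2, 1, rng)

    def __call__(self, x, skips):
        for block, skip in zip(self.blocks, reversed(skips)):
            x = nn.upsample_bilinear2x(x)
            x = block(nn.concat([x, skip], axis=3))
        return nn.softmax(self.head(x), axis=3)


class _Classifier(nn.Module):
    def __init__(self, cfg: ModelConfig, in_channels, rng):
        self.blocks = [_ResBlock(in_channels, rng) for _ in range(cfg.cls_blocks)]
        self.fc = nn.Linear(in_channels, 2, rng)

    def __call__(self, x):
        for block in self.blocks:
            x = block(x)
        pooled = x.mean(axis=(1, 2))          # global average pool -> B x C
        logits = self.fc(pooled)
        return nn.softmax(logits, axis=1), logits


class MtlModel(nn.Module):
    """The assembled network; see the module docstring for the topology."""

    def __init__(self, cfg: ModelConfig, init_seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(init_seed)
        self.encoder = _Encoder(cfg, rng)
        self.decoder = (_Decoder(cfg, self.encoder.skip_channels,
                                 self.encoder.out_channels, rng)
                        if cfg.heads in (TASK_BOTH, TASK_SEGMENTATION) else None)
        self.classifier = (_Classifier(cfg, self.encoder.out_channels, rng)
                           if cfg.heads in (TASK_BOTH, TASK_CLASSIFICATION) else None)
        self.encoder_frozen = False

    # -- forward ----------------------------------------------------------
    def forward(self, batch: np.ndarray | Tensor, training: bool = False,
                mc_dropout: bool = False,
                dropout_rng: Optional[np.random.Generator] = None) -> MtlOutput:
        """Run the network on a ``B x 3 x side x side`` batch.

        Dropout is active when ``training`` or when ``mc_dropout`` is
        explicitly requested; evaluation mode is deterministic.
        """
        x = batch if isinstance(batch, Tensor) else Tensor(batch)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected B x 3 x H x W batch, got {x.shape}")
        if x.shape[2] != self.cfg.input_side or x.shape[3] != self.cfg.input_side:
            raise ValueError(
                f"spatial size {x.shape[2]}x{x.shape[3]} does not match the "
                f"configured input_side={self.cfg.input_side}; resize upstream")
        if not np.all(np.isfinite(x.data)):
            raise ValueError("non-finite values in input batch")
        dropout_active = training or mc_dropout
        if dropout_active and dropout_rng is None:
            raise ValueError("dropout is active but no dropout_rng was given")

        # activations run channels-last internally (faster convolutions);
        # the public contract stays B x C x H x W at both ends
        x = x.permute(0, 2, 3, 1)
        bottom, skips = self.encoder(x)
        tapped = bottom
        seg = None
        if self.decoder is not None:
            # dropout belongs to the segmentation subnetwork: it regularizes
            # the decoder and drives MC-dropout uncertainty, while the
            # classification branch reads the undropped shared features
            dropped = nn.dropout_channels(bottom, self.cfg.dropout_rate,
                                          dropout_rng, dropout_active)
            seg = self.decoder(dropped, skips).permute(0, 3, 1, 2)
        cls = logits = None
        if self.classifier is not None:
            cls, logits = self.classifier(bottom)
        return MtlOutput(seg_probs=seg, cls_probs=cls, cls_logits=logits,
                         tapped=tapped)

    __call__ = forward

    # -- freezing ---------------------------------------------------------
    def set_encoder_frozen(self, frozen: bool) -> None:
        self.encoder.set_trainable(not frozen)
        self.encoder_frozen = frozen

    def encoder_parameters(self):
        return list(self.encoder.parameters())

    def head_parameters(self):
        params = []
        if self.decoder is not None:
            params += list(self.decoder.parameters())
        if self.classifier is not None:
            params += list(self.classifier.parameters())
        return params


def build_model(cfg: ModelConfig, init_seed: int = 0) -> MtlModel:
    """Construct the multi-task (or single-task) network; deterministic in
    ``init_seed``."""
    return MtlModel(cfg, init_seed=init_seed)


def single_task_variant(cfg: ModelConfig, task: str, init_seed: int = 0) -> MtlModel:
    """Same encoder with only the requested head attached."""
    if task not in (TASK_SEGMENTATION, TASK_CLASSIFICATION):
        raise ValueError(f"unknown task tag {task!r}")
    solo = ModelConfig(**{**asdict(cfg), "heads": task})
    return MtlModel(solo, init_seed=init_seed)


def set_encoder_frozen(model: MtlModel, frozen: bool) -> None:
    model.set_encoder_frozen(frozen)


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(path, model: MtlModel, sigmas=None, extra: dict | None = None):
    """Single-archive checkpoint: weights + ModelConfig (+ sigma state)."""
    meta = {"config": asdict(model.cfg), "extra": extra or {}}
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    if sigmas is not None:
        arrays["sigma_u"] = np.array([sigmas.u_cla.data, sigmas.u_seg.data],
                                     dtype=np.float32)
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Returns (model, sigmas-or-None, extra dict)."""
    from .losses import SigmaParams  # local import to avoid a cycle
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        cfg = ModelConfig(**meta["config"])
        model = MtlModel(cfg)
        n = sum(1 for k in z.files if k.startswith("p"))
        model.load_state_arrays([z[f"p{i}"] for i in range(n)])
        sigmas = None
        if "sigma_u" in z.files:
            sigmas = SigmaParams()
            sigmas.u_cla.data = np.float32(z["sigma_u"][0])
            sigmas.u_seg.data = np.float32(z["sigma_u"][1])
    return model, sigmas, meta["extra"]
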