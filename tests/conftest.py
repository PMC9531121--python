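import numpy as np
import pytest

try:
    # pin BLAS to one thread: keeps floating-point reductions in a fixed
    # order so training trajectories are identical across machines with
    # different core counts
    import threadpoolctl

    threadpoolctl.threadpool_limits(1)
except ImportError:  # pragma: no cover
    pass

from tongue_mtl.model import ModelConfig, build_model
from tongue_mtl.synthetic import generate_dataset


TINY_CFG = ModelConfig(encoder_depth=2, base_channels=2, input_side=32)


@pytest.fixture(scope="session")
def small_dataset():
    """40 scenes (22 high / 18 low), 64x64, shared across tests."""
    return generate_dataset(22, 18, seed=5)


@pytest.fixture(scope="session")
def tiny_model():
    return build_model(TINY_CFG, init_seed=0)


@pytest.fixture(scope="session")
def trained_tiny():
    """A briefly trained small multi-task model on a small scene set."""
    from tongue_mtl.trainer import TrainConfig, arrays_from_annotated, train

    images = generate_dataset(14, 10, seed=21)
    cfg = TrainConfig(lr=3e-4, batch_size=4, freeze_epochs=1, total_epochs=3,
                      seed=0, model=ModelConfig(encoder_depth=3,
                                                base_channels=4,
                                                input_side=64))
    data = {"train": arrays_from_annotated(images[:18]),
            "val": arrays_from_annotated(images[18:])}
    model, log, sigmas = train(build_model(cfg.model, 0), data, cfg)
    return model, log, sigmas, images
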