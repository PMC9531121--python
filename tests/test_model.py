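"""Network topology contracts: shapes, softmax invariants, freezing,
single-task variants, gradient flow through the shared encoder."""

import numpy as np
import pytest

from tongue_mtl import losses as L
from tongue_mtl import nn
from tongue_mtl.model import (ModelConfig, build_model, single_task_variant,
                              set_encoder_frozen)

CFG = ModelConfig(encoder_depth=2, base_channels=2, input_side=32)


def batch(n=2, side=32, seed=0):
    return np.random.default_rng(seed).random((n, 3, side, side),
                                              dtype=np.float32)


class TestBuildAndForward:
    def test_output_shapes_match_contract(self):
        cfg = ModelConfig(encoder_depth=4, base_channels=2, input_side=64)
        model = build_model(cfg)
        out = model.forward(batch(3, 64))
        assert out.seg_probs.shape == (3, 2, 64, 64)
        assert out.cls_probs.shape == (3, 2)

    def test_input_side_must_divide_by_pool_factor(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(encoder_depth=4, input_side=100)

    def test_same_init_seed_gives_identical_parameters(self):
        a = build_model(CFG, init_seed=7)
        b = build_model(CFG, init_seed=7)
        for pa, pb in zip(a.state_arrays(), b.state_arrays()):
            np.testing.assert_array_equal(pa, pb)

    def test_wrong_spatial_size_is_an_error_not_a_resize(self):
        model = build_model(CFG)
        with pytest.raises(ValueError, match="input_side"):
            model.forward(batch(1, 64))

    def test_nonfinite_input_rejected(self):
        model = build_model(CFG)
        x = batch(1)
        x[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            model.forward(x)

    def test_seg_channels_and_cls_entries_sum_to_one(self):
        model = build_model(CFG)
        out = model.forward(batch(2))
        np.testing.assert_allclose(out.seg_array.sum(axis=1), 1.0, atol=1e-5)
        np.testing.assert_allclose(out.cls_array.sum(axis=1), 1.0, atol=1e-5)
        assert out.seg_array.min() >= 0 and out.cls_array.min() >= 0

    def test_softmax_invariants_hold_for_random_weights(self):
        """50 random models/batches; probability outputs stay normalized."""
        for trial in range(50):
            cfg = ModelConfig(encoder_depth=2, base_channels=2, input_side=16)
            model = build_model(cfg, init_seed=trial)
            out = model.forward(batch(1, 16, seed=trial))
            np.testing.assert_allclose(out.seg_array.sum(axis=1), 1.0, atol=1e-5)
            np.testing.assert_allclose(out.cls_array.sum(axis=1), 1.0, atol=1e-5)

    def test_duplicate_inputs_give_identical_outputs_in_eval(self):
        model = build_model(CFG)
        x = batch(1)
        out = model.forward(np.concatenate([x, x]))
        np.testing.assert_array_equal(out.cls_array[0], out.cls_array[1])
        np.testing.assert_array_equal(out.seg_array[0], out.seg_array[1])

    def test_batch_permutation_equivariance(self):
        model = build_model(CFG)
        x = batch(4)
        perm = [2, 0, 3, 1]
        out = model.forward(x)
        out_p = model.forward(x[perm])
        np.testing.assert_allclose(out_p.cls_array, out.cls_array[perm],
                                   atol=1e-6)
        np.testing.assert_allclose(out_p.seg_array, out.seg_array[perm],
                                   atol=1e-6)

    def test_network_is_not_constant(self):
        model = build_model(CFG)
        a = model.forward(np.zeros((1, 3, 32, 32), np.float32))
        b = model.forward(np.ones((1, 3, 32, 32), np.float32))
        assert not np.allclose(a.cls_array, b.cls_array)


class TestFreezing:
    def _step(self, model, opt):
        out = model.forward(batch(2, seed=3), training=True,
                            dropout_rng=np.random.default_rng(0))
        mask = (np.random.default_rng(1).random((2, 32, 32)) > 0.5).astype(np.uint8)
        total = L.total_equal(L.cla_loss(out.cls_probs, [0, 1]),
                              L.seg_loss(out.seg_probs, mask).l_seg_tensor)
        opt.zero_grad()
        total.backward()
        opt.step()

    def test_frozen_encoder_is_bit_identical_after_steps(self):
        model = build_model(CFG)
        set_encoder_frozen(model, True)
        opt = nn.Adam(list(model.parameters()), lr=1e-2)
        before = [p.data.copy() for p in model.encoder_parameters()]
        dec_before = [p.data.copy() for p in model.head_parameters()]
        for _ in range(3):
            self._step(model, opt)
        for a, b in zip(before, model.encoder_parameters()):
            np.testing.assert_array_equal(a, b.data)
        # decoder and classifier still train
        changed = [not np.array_equal(a, b.data)
                   for a, b in zip(dec_before, model.head_parameters())]
        assert all(changed)

    def test_unfreezing_lets_encoder_move(self):
        model = build_model(CFG)
        set_encoder_frozen(model, True)
        set_encoder_frozen(model, False)
        opt = nn.Adam(list(model.parameters()), lr=1e-2)
        before = [p.data.copy() for p in model.encoder_parameters()]
        self._step(model, opt)
        assert any(not np.array_equal(a, b.data)
                   for a, b in zip(before, model.encoder_parameters()))


class TestSingleTaskVariants:
    def test_classification_only_has_no_seg_output(self):
        model = single_task_variant(CFG, "classification")
        out = model.forward(batch(2))
        assert out.seg_probs is None and out.cls_probs.shape == (2, 2)

    def test_segmentation_only_has_no_cls_output(self):
        model = single_task_variant(CFG, "segmentation")
        out = model.forward(batch(2))
        assert out.cls_probs is None and out.seg_probs.shape == (2, 2, 32, 32)

    def test_single_task_models_are_smaller(self):
        full = build_model(CFG).n_parameters()
        assert single_task_variant(CFG, "classification").n_parameters() < full
        assert single_task_variant(CFG, "segmentation").n_parameters() < full

    def test_unknown_task_tag_rejected(self):
        with pytest.raises(ValueError, match="task"):
            single_task_variant(CFG, "detection")


def test_gradient_reaches_every_trainable_parameter():
    """With both losses active, encoder, decoder, and classifier all
    receive nonzero gradients (the shared-trunk wiring is intact)."""
    model = build_model(ModelConfig(encoder_depth=2, base_channels=4,
                                    input_side=32), init_seed=1)
    x = batch(4, seed=9)
    mask = (np.random.default_rng(2).random((4, 32, 32)) > 0.5).astype(np.uint8)
    out = model.forward(x, training=True,
                        dropout_rng=np.random.default_rng(0))
    total = L.total_equal(L.cla_loss(out.cls_probs, [0, 1, 1, 0]),
                          L.seg_loss(out.seg_probs, mask).l_seg_tensor)
    total.backward()
    for p in model.parameters():
        assert p.grad is not None
        assert np.abs(p.grad).max() > 0


def test_checkpoint_roundtrip(tmp_path):
    from tongue_mtl.model import load_checkpoint, save_checkpoint

    model = build_model(CFG, init_seed=4)
    sig = L.SigmaParams()
    sig.u_seg.data = np.float32(0.77)
    path = tmp_path / "ck.npz"
    save_checkpoint(path, model, sig, extra={"arm": "MTL_adaptive"})
    back, sig2, extra = load_checkpoint(path)
    assert extra["arm"] == "MTL_adaptive"
    assert back.cfg == model.cfg
    for a, b in zip(model.state_arrays(), back.state_arrays()):
        np.testing.assert_array_equal(a, b)
    assert sig2.u_seg.data == pytest.approx(0.77)
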