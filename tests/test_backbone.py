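"""Backbone construction, shape bookkeeping, transfer and freeze contracts."""

import numpy as np
import pytest

import tianet as tn
from tianet._autograd import SGD, cross_entropy
from tianet.backbone import N_WEIGHTED_LAYERS, TransferError


def test_same_seed_builds_identical_parameters(tiny_cfg):
    a = tn.build_backbone(tiny_cfg, seed=3)
    b = tn.build_backbone(tiny_cfg, seed=3)
    np.testing.assert_array_equal(a.parameter_vector(), b.parameter_vector())
    c = tn.build_backbone(tiny_cfg, seed=4)
    assert not np.array_equal(a.parameter_vector(), c.parameter_vector())


def test_forward_returns_logits_per_class(tiny_cfg, rng):
    model = tn.build_backbone(tiny_cfg, seed=0)
    x = rng.random((3, 3, 32, 32)).astype(np.float32)
    logits = model.forward(x)
    assert logits.shape == (3, tiny_cfg.n_classes)
    assert np.isfinite(logits.data).all()


def test_parameter_count_matches_closed_form(tiny_cfg):
    model = tn.build_backbone(tiny_cfg, seed=0)
    # hand-computed from the config arithmetic
    c = (4 * 3 * 25 + 4) + (6 * 4 * 9 + 6) + (8 * 6 * 9 + 8) + (8 * 8 * 9 + 8) \
        + (8 * 8 * 9 + 8)
    flat = 8 * (32 // 2 // 2 // 2) ** 2
    c += (flat * 16 + 16) + (16 * 4 + 4)
    assert tiny_cfg.parameter_count() == c
    assert model.parameter_vector().size == c


def test_forward_features_spatial_bookkeeping(tiny_cfg, rng):
    model = tn.build_backbone(tiny_cfg, seed=0)
    x = rng.random((2, 3, 32, 32)).astype(np.float32)
    sizes = {1: 16, 2: 8, 3: 8, 4: 8, 5: 4}  # pools after conv 1, 2, 5
    for layer, side in sizes.items():
        fm = tn.forward_features(model, x, layer)
        assert fm.shape == (2, tiny_cfg.channels_per_conv[layer - 1], side, side)
    with pytest.raises(ValueError, match="1..5"):
        tn.forward_features(model, x, 6)


def test_zero_input_zero_bias_gives_zero_features(tiny_cfg):
    from dataclasses import replace
    model = tn.build_backbone(replace(tiny_cfg, conv_bias_init=0.0), seed=0)
    x = np.zeros((1, 3, 32, 32), dtype=np.float32)
    fm = tn.forward_features(model, x, 5)
    assert (fm.data == 0).all()


def test_config_rejects_collapsing_feature_map():
    with pytest.raises(ValueError, match="collapses|odd spatial"):
        tn.BackboneConfig(input_size=8, pool_after=(1, 2, 3, 4, 5))


class TestTransfer:
    def test_k0_leaves_target_unchanged(self, tiny_cfg):
        src = tn.build_backbone(tiny_cfg, seed=1)
        tgt = tn.build_backbone(tiny_cfg, seed=2)
        before = tgt.parameter_vector()
        tn.transfer_weights(src, tgt, 0)
        np.testing.assert_array_equal(tgt.parameter_vector(), before)

    def test_k3_copies_exactly_three_layers(self, tiny_cfg):
        src = tn.build_backbone(tiny_cfg, seed=1)
        tgt = tn.build_backbone(tiny_cfg, seed=2)
        tn.transfer_weights(src, tgt, 3)
        for i in range(1, 4):
            ws, bs = src.layer_parameters(i)
            wt, bt = tgt.layer_parameters(i)
            assert (ws.data == wt.data).all() and (bs.data == bt.data).all()
        w4s, _ = src.layer_parameters(4)
        w4t, _ = tgt.layer_parameters(4)
        assert not np.array_equal(w4s.data, w4t.data)

    def test_transfer_is_a_copy_not_a_view(self, tiny_cfg):
        src = tn.build_backbone(tiny_cfg, seed=1)
        tgt = tn.build_backbone(tiny_cfg, seed=2)
        tn.transfer_weights(src, tgt, 1)
        tgt.layer_parameters(1)[0].data[...] = 99.0
        assert not np.array_equal(src.layer_parameters(1)[0].data,
                                  tgt.layer_parameters(1)[0].data)

    def test_k7_with_differing_class_counts_raises(self, tiny_cfg):
        from dataclasses import replace
        src = tn.build_backbone(tiny_cfg, seed=1)
        tgt = tn.build_backbone(replace(tiny_cfg, fc_widths=(16, 2)), seed=2)
        with pytest.raises(TransferError, match="layer 7"):
            tn.transfer_weights(src, tgt, 7)
        tn.transfer_weights(src, tgt, 6)  # final FC exempt


class TestFreeze:
    def _sgd_steps(self, model, params, rng, n_steps=5):
        opt = SGD(params, lr=0.05, momentum=0.9)
        x = rng.random((4, 3, 32, 32)).astype(np.float32)
        y = np.array([0, 1, 2, 3])
        for _ in range(n_steps):
            opt.zero_grad()
            loss = cross_entropy(model.forward(x), y)
            loss.backward()
            opt.step()
        return loss

    def test_unfrozen_training_changes_every_layer(self, tiny_cfg, rng):
        model = tn.build_backbone(tiny_cfg, seed=0)
        snaps = [model.layer_parameters(i)[0].data.copy()
                 for i in range(1, N_WEIGHTED_LAYERS + 1)]
        self._sgd_steps(model, tn.freeze_layers(model, 0), rng, n_steps=1)
        for i, snap in enumerate(snaps, start=1):
            assert not np.array_equal(model.layer_parameters(i)[0].data, snap)

    def test_frozen_layers_stay_bit_identical(self, tiny_cfg, rng):
        model = tn.build_backbone(tiny_cfg, seed=0)
        snaps = [model.layer_parameters(i)[0].data.copy() for i in range(1, 5)]
        self._sgd_steps(model, tn.freeze_layers(model, 4), rng, n_steps=5)
        for i, snap in enumerate(snaps, start=1):
            assert (model.layer_parameters(i)[0].data == snap).all()
        assert not np.array_equal(model.layer_parameters(5)[0].data.copy(),
                                  tn.build_backbone(tiny_cfg, 0).layer_parameters(5)[0].data)

    def test_all_frozen_means_constant_loss(self, tiny_cfg, rng):
        model = tn.build_backbone(tiny_cfg, seed=0)
        opt = SGD(tn.freeze_layers(model, 7), lr=0.05)
        x = rng.random((2, 3, 32, 32)).astype(np.float32)
        y = np.array([0, 1])
        losses = []
        for _ in range(3):
            opt.zero_grad()
            loss = cross_entropy(model.forward(x), y)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[0] == losses[1] == losses[2]


def test_checkpoint_roundtrip(tmp_path, tiny_cfg, rng):
    model = tn.build_backbone(tiny_cfg, seed=9)
    path = tmp_path / "model.npz"
    tn.save_checkpoint(model, path)
    loaded = tn.load_checkpoint(path)
    np.testing.assert_array_equal(model.parameter_vector(), loaded.parameter_vector())
    assert loaded.config == tiny_cfg
    x = rng.random((2, 3, 32, 32)).astype(np.float32)
    np.testing.assert_array_equal(model.forward(x).data, loaded.forward(x).data)
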