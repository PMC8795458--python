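"""Architecture construction, parameter counting, forward contract, transfer."""

import numpy as np
import pytest

from neurograde import (
    ArchitectureKind,
    NetworkConfig,
    architecture_summary,
    build_network,
    classify,
    count_trainable_parameters,
    load_pretrained,
    midplanes_2p1d,
)
from neurograde.metrics import ClassWeights, weighted_cross_entropy_grad
from neurograde.models import load_checkpoint, save_checkpoint, state_dict
from neurograde.nn import Adam, ShapeError


def tiny_cfg(kind, **kw):
    return NetworkConfig(kind=kind, base_width=4, seed=3, **kw)


ALL_KINDS = list(ArchitectureKind)


class TestArchitectureStructure:
    def test_stage_conv_modes(self):
        modes = {
            ArchitectureKind.RESNET3D: ["3d", "3d", "3d", "3d"],
            ArchitectureKind.RESNET_MIXED: ["3d", "2d", "2d", "2d"],
            ArchitectureKind.RESNET_2P1D: ["2p1d", "2p1d", "2p1d", "2p1d"],
        }
        for kind, expected in modes.items():
            summary = architecture_summary(tiny_cfg(kind))
            assert summary["stage_conv_modes"] == expected

    def test_2p1d_stem_channel_progression(self):
        summary = architecture_summary(NetworkConfig(kind=ArchitectureKind.RESNET_2P1D))
        stem_convs = [r for r in summary["layers"]
                      if r["name"].startswith("stem") and r["type"] == "conv3d"]
        assert [(r["in_channels"], r["out_channels"]) for r in stem_convs] == [(1, 45), (45, 64)]

    def test_downsample_present_only_in_later_stages(self):
        summary = architecture_summary(tiny_cfg(ArchitectureKind.RESNET3D))
        ds = {r["name"] for r in summary["layers"] if "downsample" in r["name"]}
        assert any(n.startswith("layer2") for n in ds)
        assert any(n.startswith("layer4") for n in ds)
        assert not any(n.startswith("layer1") for n in ds)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(kind="not_an_architecture")
        with pytest.raises(ValueError):
            NetworkConfig(kind=ArchitectureKind.RESNET3D, n_classes=1)
        with pytest.raises(ValueError):
            NetworkConfig(kind=ArchitectureKind.RESNET3D, dropout_p=1.0)


class TestMidplanes:
    @pytest.mark.parametrize("n_in,n_out,expected", [
        (64, 64, 144),
        (1, 1, 2),
        (256, 512, 921),
    ])
    def test_factorization_width(self, n_in, n_out, expected):
        assert midplanes_2p1d(n_in, n_out) == expected

    def test_invalid_channels_rejected(self):
        with pytest.raises(ValueError):
            midplanes_2p1d(0, 4)


class TestParameterCounting:
    @pytest.mark.parametrize("kind,expected", [
        (ArchitectureKind.RESNET_MIXED, 11_472_963),
        (ArchitectureKind.RESNET_2P1D, 31_297_254),
        (ArchitectureKind.RESNET3D, 33_148_995),
    ])
    def test_full_width_totals(self, kind, expected):
        net = build_network(NetworkConfig(kind=kind))
        assert count_trainable_parameters(net) == expected

    def test_single_conv_count_formula(self, rng):
        from neurograde.nn import Conv3d

        conv = Conv3d(2, 4, (3, 3, 3), rng=rng)
        assert conv.weight.size == 2 * 4 * 27 == 216

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_summary_table_is_an_independent_oracle(self, kind):
        """Recompute the total from the structural fields of each layer row:
        in*out*prod(kernel) for convs, 2c for batch-norms, in*out+out for the
        head; the sum must equal the direct parameter count."""
        summary = architecture_summary(NetworkConfig(kind=kind))
        total = 0
        for row in summary["layers"]:
            if row["type"] == "conv3d":
                total += row["in_channels"] * row["out_channels"] * int(np.prod(row["kernel"]))
            elif row["type"] == "batchnorm3d":
                total += 2 * row["in_channels"]
            elif row["type"] == "linear":
                total += row["in_channels"] * row["out_channels"] + row["out_channels"]
        net = build_network(NetworkConfig(kind=kind))
        assert total == count_trainable_parameters(net) == summary["total_parameters"]

    def test_count_ordering_matches_published_table(self):
        counts = {k: count_trainable_parameters(build_network(NetworkConfig(kind=k)))
                  for k in ALL_KINDS}
        assert (counts[ArchitectureKind.RESNET_MIXED]
                < counts[ArchitectureKind.RESNET_2P1D]
                < counts[ArchitectureKind.RESNET3D])


class TestForwardContract:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_logit_shape_and_finiteness(self, kind, rng):
        net = build_network(tiny_cfg(kind))
        batch = rng.random((1, 1, 16, 32, 32), dtype=np.float32)
        logits = classify(net, batch)
        assert logits.shape == (1, 3)
        assert np.all(np.isfinite(logits))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert probs.sum(axis=1) == pytest.approx(1.0, abs=1e-6)

    def test_adaptive_pooling_makes_output_shape_size_independent(self, rng):
        net = build_network(tiny_cfg(ArchitectureKind.RESNET_MIXED))
        a = classify(net, rng.random((1, 1, 16, 32, 32), dtype=np.float32))
        b = classify(net, rng.random((1, 1, 24, 48, 48), dtype=np.float32))
        assert a.shape == b.shape == (1, 3)

    def test_empty_input_names_offending_stage(self, rng):
        net = build_network(tiny_cfg(ArchitectureKind.RESNET3D))
        with pytest.raises(ShapeError, match="stem"):
            classify(net, np.zeros((1, 1, 0, 8, 8), dtype=np.float32))

    def test_eval_mode_is_deterministic(self, rng):
        net = build_network(tiny_cfg(ArchitectureKind.RESNET_2P1D))
        x = rng.random((1, 1, 16, 32, 32), dtype=np.float32)
        assert np.array_equal(classify(net, x), classify(net, x))

    def test_same_seed_builds_identical_networks(self):
        a = build_network(tiny_cfg(ArchitectureKind.RESNET_MIXED))
        b = build_network(tiny_cfg(ArchitectureKind.RESNET_MIXED))
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            assert np.array_equal(pa.value, pb.value)


class TestGradientFlow:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_every_parameter_receives_gradient(self, kind, rng):
        """After one optimization step on a random sample, no parameter group
        is dead (the stem's input gradient is legitimately not computed)."""
        net = build_network(tiny_cfg(kind))
        x = rng.random((1, 16, 32, 32), dtype=np.float32)
        w = ClassWeights(np.ones(3), np.array([1, 1, 1]))
        logits = net.forward(x, training=True)
        _, grad = weighted_cross_entropy_grad(logits[None], [0], w)
        net.zero_grad()
        net.backward(grad[0].astype(np.float32))
        for name, p in net.named_parameters():
            assert np.any(p.grad != 0), f"dead parameter group: {name}"
        opt = Adam(net.parameters(), lr=1e-3)
        before = state_dict(net)
        opt.step()
        changed = [n for n, p in net.named_parameters()
                   if not np.array_equal(before[n], p.value)]
        assert len(changed) == len(before)


class TestPretrainedTransfer:
    def test_transfer_copies_stages_not_stem_or_head(self):
        donor = build_network(NetworkConfig(kind=ArchitectureKind.RESNET_MIXED,
                                            base_width=4, seed=11))
        net = build_network(NetworkConfig(kind=ArchitectureKind.RESNET_MIXED,
                                          base_width=4, seed=22))
        fresh = state_dict(net)
        load_pretrained(net, state_dict(donor))
        donor_params = state_dict(donor)
        for name, p in net.named_parameters():
            if name.startswith(("stem.", "fc.")):
                assert np.array_equal(p.value, fresh[name]), name
            else:
                assert np.array_equal(p.value, donor_params[name]), name

    def test_transfer_preserves_parameter_count(self):
        donor = build_network(tiny_cfg(ArchitectureKind.RESNET3D))
        net = build_network(tiny_cfg(ArchitectureKind.RESNET3D))
        before = count_trainable_parameters(net)
        load_pretrained(net, state_dict(donor))
        assert count_trainable_parameters(net) == before

    def test_shape_mismatch_names_parameter(self):
        donor = build_network(NetworkConfig(kind=ArchitectureKind.RESNET_MIXED,
                                            base_width=8, seed=0))
        net = build_network(tiny_cfg(ArchitectureKind.RESNET_MIXED))
        with pytest.raises(ValueError, match="layer1"):
            load_pretrained(net, state_dict(donor))

    def test_missing_parameter_rejected(self):
        net = build_network(tiny_cfg(ArchitectureKind.RESNET_MIXED))
        with pytest.raises(KeyError, match="missing"):
            load_pretrained(net, {})


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, rng):
        net = build_network(tiny_cfg(ArchitectureKind.RESNET_MIXED))
        x = rng.random((1, 1, 16, 32, 32), dtype=np.float32)
        # push some running stats through BN
        net.forward(x[0], training=True)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        back = load_checkpoint(path)
        assert back.config == net.config
        assert np.array_equal(classify(back, x), classify(net, x))
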