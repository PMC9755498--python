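"""DBSN architecture contracts, losses, ablations, and checkpoints."""

import numpy as np
import pytest

from aopnet.model import (
    CheckpointMismatchError,
    NetworkConfig,
    build_dbsn,
    collaborative_loss,
    dice_loss,
    downsample_mask_majority,
    load_checkpoint,
    save_checkpoint,
)
from aopnet.nn.autograd import Tensor


def small_cfg(**kw):
    return NetworkConfig(base_channels=8, **kw)


@pytest.fixture(scope="module")
def tiny_net():
    return build_dbsn(small_cfg(), seed=0)


class TestConfig:
    def test_gate_requires_lower_branch(self):
        with pytest.raises(ValueError):
            NetworkConfig(use_lower_branch=False, use_attention_gates=True)

    def test_gn_divisibility(self):
        with pytest.raises(ValueError):
            NetworkConfig(base_channels=12, gn_groups=8)

    def test_round_trip_dict(self):
        cfg = small_cfg(w_lower=0.3)
        assert NetworkConfig.from_dict(cfg.to_dict()) == cfg


class TestShapes:
    def test_standard_input_output_sizes(self, tiny_net):
        out = tiny_net.forward(np.zeros((384, 512), dtype=np.float32))
        assert out.upper.shape == (384, 512, 3)
        assert out.lower.shape == (24, 32, 3)
        for m in (out.upper, out.lower):
            np.testing.assert_allclose(m.sum(axis=-1), 1.0, atol=1e-5)
            assert np.isfinite(m).all()

    def test_small_input_shape_arithmetic(self, tiny_net):
        out = tiny_net.forward(np.zeros((48, 64), dtype=np.float32))
        assert out.upper.shape == (48, 64, 3)
        assert out.lower.shape == (3, 4, 3)

    def test_indivisible_input_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            tiny_net.forward(np.zeros((50, 64), dtype=np.float32))

    def test_forward_determinism(self, tiny_net, rng):
        img = rng.normal(size=(48, 64)).astype(np.float32)
        a = tiny_net.forward(img)
        b = tiny_net.forward(img)
        np.testing.assert_array_equal(a.upper, b.upper)
        np.testing.assert_array_equal(a.lower, b.lower)


class TestAblations:
    def test_no_lower_branch_returns_upper_only(self):
        net = build_dbsn(small_cfg(use_lower_branch=False, use_attention_gates=False), seed=0)
        out = net.forward(np.zeros((48, 64), dtype=np.float32))
        assert out.lower is None
        assert out.upper.shape == (48, 64, 3)

    def test_parameter_count_ordering(self):
        full = build_dbsn(small_cfg(), seed=0)
        no_ag = build_dbsn(small_cfg(use_attention_gates=False), seed=0)
        no_lb = build_dbsn(small_cfg(use_attention_gates=False, use_lower_branch=False), seed=0)
        no_dc = build_dbsn(small_cfg(use_deformable=False), seed=0)
        assert no_lb.num_parameters() < no_ag.num_parameters() <= full.num_parameters()
        assert no_dc.num_parameters() == full.num_parameters() - full.deformable_offset_param_count()
        assert full.deformable_offset_param_count() > 0
        assert no_dc.deformable_offset_param_count() == 0

    def test_gradient_coverage_all_variants(self):
        for kw in ({}, {"use_attention_gates": False},
                   {"use_attention_gates": False, "use_lower_branch": False},
                   {"use_deformable": False}):
            net = build_dbsn(small_cfg(**kw), seed=0)
            mask = np.zeros((48, 64), dtype=np.uint8)
            mask[10:20, 12:30] = 2
            mask[25:29, 8:16] = 1
            img = np.random.default_rng(0).normal(size=(48, 64)).astype(np.float32)
            out = net.forward_tensors(Tensor(img[None, None]))
            loss = collaborative_loss(out, mask, net.cfg)
            loss.backward()
            missing = [n for n, p in net.named_parameters() if p.grad is None]
            assert missing == []


class TestDiceLoss:
    def test_perfect_one_hot_is_zero(self):
        truth = np.zeros((4, 4), dtype=np.uint8)
        truth[1:3, 1:3] = 1
        pred = np.zeros((1, 3, 4, 4), np.float32)
        for c in range(3):
            pred[0, c] = truth == c
        assert dice_loss(Tensor(pred), truth).item() == pytest.approx(0.0, abs=1e-7)

    def test_disjoint_one_hot_is_one(self):
        truth = np.zeros((4, 4), dtype=np.uint8)
        truth[0, 0] = 1
        pred = np.zeros((1, 3, 4, 4), np.float32)
        pred[0, 2, 3, 3] = 1.0  # foreground predicted, zero overlap
        pred[0, 0] = 1.0 - pred[0, 1] - pred[0, 2]
        assert dice_loss(Tensor(pred), truth).item() == pytest.approx(1.0, abs=1e-7)

    def test_half_credit_two_pixel_case(self):
        # one foreground class, two pixels: y = (1, 0), p = (0.5, 0.5)
        truth = np.array([[1, 0]], dtype=np.uint8)
        pred = np.zeros((1, 2, 1, 2), np.float32)
        pred[0, 1] = [[0.5, 0.5]]
        pred[0, 0] = [[0.5, 0.5]]
        assert dice_loss(Tensor(pred), truth).item() == pytest.approx(0.5)

    def test_bounded_on_random_maps(self, rng):
        for _ in range(10):
            logits = rng.normal(size=(1, 3, 8, 8)).astype(np.float32)
            p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
            truth = rng.integers(0, 3, size=(8, 8)).astype(np.uint8)
            val = dice_loss(Tensor(p.astype(np.float32)), truth).item()
            assert 0.0 <= val <= 1.0


class TestCollaborativeLoss:
    def _random_dual(self, rng, cfg, h=32, w=32):
        up = rng.normal(size=(1, 3, h, w)).astype(np.float32)
        up = np.exp(up) / np.exp(up).sum(axis=1, keepdims=True)
        low = rng.normal(size=(1, 3, h // 16, w // 16)).astype(np.float32)
        low = np.exp(low) / np.exp(low).sum(axis=1, keepdims=True)
        truth = rng.integers(0, 3, size=(h, w)).astype(np.uint8)
        return Tensor(up), Tensor(low), truth

    def test_weighted_sum_identity(self, rng):
        cfg = small_cfg()
        for _ in range(5):
            up, low, truth = self._random_dual(rng, cfg)
            combined = collaborative_loss((up, low), truth, cfg).item()
            d_u = dice_loss(up, truth).item()
            d_l = dice_loss(low, downsample_mask_majority(truth, 16)).item()
            assert combined == pytest.approx(1.0 * d_u + 0.2 * d_l, abs=1e-12)

    def test_zero_lower_weight_equals_upper_term(self, rng):
        cfg = small_cfg(w_lower=0.0)
        up, low, truth = self._random_dual(rng, cfg)
        assert collaborative_loss((up, low), truth, cfg).item() == pytest.approx(
            dice_loss(up, truth).item(), abs=1e-12
        )

    def test_arithmetic_example(self):
        # upper loss 0.4 and lower loss 0.3 with weights (1.0, 0.2) -> 0.46
        assert 1.0 * 0.4 + 0.2 * 0.3 == pytest.approx(0.46)

    def test_one_step_decreases_loss_majority_of_seeds(self):
        from aopnet.nn import Adam

        decreased = 0
        mask = np.zeros((48, 64), dtype=np.uint8)
        mask[12:24, 20:44] = 2
        mask[30:34, 10:20] = 1
        for seed in range(20):
            net = build_dbsn(NetworkConfig(base_channels=4, gn_groups=4), seed=seed)
            img = np.random.default_rng(seed).normal(size=(48, 64)).astype(np.float32)
            opt = Adam(net.parameters(), lr=1e-3)
            out = net.forward_tensors(Tensor(img[None, None]))
            loss0 = collaborative_loss(out, mask, net.cfg)
            loss0.backward()
            opt.step()
            out = net.forward_tensors(Tensor(img[None, None]))
            loss1 = collaborative_loss(out, mask, net.cfg)
            if loss1.item() < loss0.item():
                decreased += 1
        assert decreased > 10


class TestDownsampleMajority:
    def test_uniform_blocks(self):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[:16, :] = 2
        low = downsample_mask_majority(mask, 16)
        assert low.shape == (2, 2)
        assert low[0].tolist() == [2, 2] and low[1].tolist() == [0, 0]

    def test_majority_wins(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[:, :9] = 1  # 144 of 256 pixels
        assert downsample_mask_majority(mask, 16)[0, 0] == 1


class TestCheckpoint:
    def test_round_trip(self, tmp_path, tiny_net, rng):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, tiny_net)
        loaded = load_checkpoint(path, expected_cfg=tiny_net.cfg)
        img = rng.normal(size=(48, 64)).astype(np.float32)
        np.testing.assert_array_equal(
            tiny_net.forward(img).upper, loaded.forward(img).upper
        )

    def test_config_mismatch_rejected(self, tmp_path, tiny_net):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, tiny_net)
        with pytest.raises(CheckpointMismatchError):
            load_checkpoint(path, expected_cfg=small_cfg(w_lower=0.5))
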