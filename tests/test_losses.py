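"""Loss stack: closed forms, loop oracles, weighting semantics, training."""

import numpy as np
import pytest

import mscdunet as M
from mscdunet.losses import final_loss, fuse_loss, side_loss, total_side_loss
from mscdunet.network import BranchOutputs
from mscdunet.nn import Var
from mscdunet.nn import functional as F
from mscdunet.train import schedule_lr


def ce_loop_oracle(logits, target, omega):
    """Per-voxel explicit weighted cross-entropy (softmax by hand)."""
    b, c = logits.shape[:2]
    total = 0.0
    n = 0
    for bi in range(b):
        for d in range(logits.shape[2]):
            for h in range(logits.shape[3]):
                for w in range(logits.shape[4]):
                    z = logits[bi, :, d, h, w]
                    p = np.exp(z - z.max())
                    p /= p.sum()
                    t = target[bi, d, h, w]
                    total += -omega[t] * np.log(p[t])
                    n += 1
    return total / n


OMEGA = np.array([1.0, 1.0, 2.0, 2.0])


class TestSideLoss:
    def test_perfect_prediction_tends_to_zero(self):
        target = np.array([[[[2]]]])
        logits = np.full((1, 4, 1, 1, 1), -50.0)
        logits[0, 2] = 50.0
        assert side_loss(logits, target, OMEGA).value < 1e-12

    @pytest.mark.parametrize("c", [0, 1, 2, 3])
    def test_uniform_logits_single_voxel_closed_form(self, c):
        logits = np.zeros((1, 4, 1, 1, 1))
        target = np.full((1, 1, 1, 1), c)
        loss = side_loss(logits, target, OMEGA).value
        assert loss == pytest.approx(OMEGA[c] * np.log(4), abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        logits = rng.standard_normal((2, 4, 3, 3, 3))
        target = rng.integers(0, 4, (2, 3, 3, 3))
        expect = ce_loop_oracle(logits, target, OMEGA)
        assert side_loss(logits, target, OMEGA).value == pytest.approx(expect, abs=1e-6)

    def test_label_out_of_range_rejected(self, rng):
        logits = rng.standard_normal((1, 4, 2, 2, 2))
        target = np.full((1, 2, 2, 2), 4)
        with pytest.raises(ValueError, match="labels"):
            side_loss(logits, target, OMEGA)

    def test_voxel_permutation_invariance(self, rng):
        logits = rng.standard_normal((1, 4, 2, 2, 2))
        target = rng.integers(0, 4, (1, 2, 2, 2))
        base = side_loss(logits, target, OMEGA).value
        perm = rng.permutation(8)
        lp = logits.reshape(1, 4, 8)[:, :, perm].reshape(1, 4, 2, 2, 2)
        tp = target.reshape(1, 8)[:, perm].reshape(1, 2, 2, 2)
        assert side_loss(lp, tp, OMEGA).value == pytest.approx(base, abs=1e-6)

    def test_omega_scales_class_contribution_linearly(self, rng):
        logits = rng.standard_normal((1, 4, 2, 2, 2))
        target = np.full((1, 2, 2, 2), 3)  # class-3-only target
        base = side_loss(logits, target, np.array([1.0, 1, 1, 1])).value
        doubled = side_loss(logits, target, np.array([1.0, 1, 1, 2])).value
        assert doubled == pytest.approx(2 * base, rel=1e-9)


class TestTotalSideLoss:
    def _sides(self, rng):
        return [rng.standard_normal((1, 4, 2, 2, 2)) for _ in range(3)]

    def test_zero_beta_gives_zero(self, rng):
        cfg = M.LossConfig(beta=[0.0, 0.0, 0.0])
        t = rng.integers(0, 4, (1, 2, 2, 2))
        assert total_side_loss(self._sides(rng), t, cfg).value == 0

    def test_beta_selects_single_branch(self, rng):
        sides = self._sides(rng)
        t = rng.integers(0, 4, (1, 2, 2, 2))
        cfg = M.LossConfig(beta=[1.0, 0.0, 0.0])
        expect = side_loss(sides[0], t, cfg.omega).value
        assert total_side_loss(sides, t, cfg).value == pytest.approx(expect, rel=1e-12)

    def test_equal_branches_triple_single_loss(self, rng):
        s = rng.standard_normal((1, 4, 2, 2, 2))
        t = rng.integers(0, 4, (1, 2, 2, 2))
        cfg = M.LossConfig()
        total = total_side_loss([s, s, s], t, cfg).value
        single = side_loss(s, t, cfg.omega).value
        assert total == pytest.approx(3 * single, rel=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="beta"):
            total_side_loss(self._sides(rng)[:2], np.zeros((1, 2, 2, 2), int), M.LossConfig())


class TestFuseLoss:
    def test_f_selects_single_activation(self, rng):
        acts = [rng.standard_normal((1, 4, 2, 2, 2)) for _ in range(3)]
        t = rng.integers(0, 4, (1, 2, 2, 2))
        got = fuse_loss(acts, t, np.array([1.0, 0, 0]), OMEGA).value
        expect = side_loss(acts[0], t, OMEGA).value
        assert got == pytest.approx(expect, rel=1e-12)

    def test_identical_activations_scale_invariant_split(self, rng):
        a = rng.standard_normal((1, 4, 2, 2, 2))
        t = rng.integers(0, 4, (1, 2, 2, 2))
        l1 = fuse_loss([a, a, a], t, np.array([1.0, 1, 1]), OMEGA).value
        l2 = fuse_loss([a, a, a], t, np.array([1 / 3, 1 / 3, 1 / 3]) * 3, OMEGA).value
        assert l1 == pytest.approx(l2, rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        acts = [rng.standard_normal((1, 4, 2, 2, 2)) for _ in range(3)]
        f = np.array([0.5, 1.5, -0.3])
        t = rng.integers(0, 4, (1, 2, 2, 2))
        fused = f[0] * acts[0] + f[1] * acts[1] + f[2] * acts[2]
        expect = ce_loop_oracle(fused, t, OMEGA)
        assert fuse_loss(acts, t, f, OMEGA).value == pytest.approx(expect, abs=1e-6)


class TestFinalLoss:
    def _outputs(self, rng):
        sides = [Var(rng.standard_normal((1, 4, 2, 2, 2))) for _ in range(3)]
        f = Var(np.array([1.0, 1.0, 1.0]))
        return BranchOutputs(side_logits=sides, fused_logits=F.weighted_sum(sides, f))

    def test_total_is_exact_sum_of_components(self, rng):
        out = self._outputs(rng)
        t = rng.integers(0, 4, (1, 2, 2, 2))
        total, fuse, side = final_loss(out, t, M.LossConfig())
        assert total.value == fuse.value + side.value

    def test_zero_beta_leaves_fuse_term_only(self, rng):
        out = self._outputs(rng)
        t = rng.integers(0, 4, (1, 2, 2, 2))
        total, fuse, side = final_loss(out, t, M.LossConfig(beta=[0.0, 0.0, 0.0]))
        assert side.value == 0
        assert total.value == fuse.value

    def test_recomputable_from_public_components(self, rng):
        out = self._outputs(rng)
        t = rng.integers(0, 4, (1, 2, 2, 2))
        cfg = M.LossConfig()
        total, _, _ = final_loss(out, t, cfg)
        manual = (
            side_loss(out.fused_logits.value, t, cfg.omega).value
            + total_side_loss([s.value for s in out.side_logits], t, cfg).value
        )
        assert total.value == pytest.approx(manual, rel=1e-12)

    def test_gradient_reaches_every_head(self, tiny_net_cfg, rng):
        model = M.build_model(tiny_net_cfg)
        model.train()
        x = rng.standard_normal((1, 1, 16, 16, 16)).astype(np.float32)
        t = rng.integers(0, 4, (1, 16, 16, 16))
        out = model.forward(x)
        total, _, _ = final_loss(out, t, M.LossConfig())
        model.zero_grad()
        total.backward()
        for h, head in enumerate(model.heads):
            grads = [p.grad for _, p in head.named_parameters()]
            assert any(g is not None and np.abs(g).max() > 0 for g in grads), f"head {h}"


class TestFit:
    def test_lr_schedule_arithmetic(self):
        tcfg = M.TrainConfig(lr=1e-3, lr_decay_every=5000, lr_decay_factor=0.1)
        expect = {0: 1e-3, 4999: 1e-3, 5000: 1e-4, 10000: 1e-5}
        for step, lr in expect.items():
            assert schedule_lr(tcfg, step) == pytest.approx(lr)

    def _tiny_dataset(self, n_mod=1):
        spec = M.PhantomSpec(n_modalities=n_mod, grid_shape=(32, 32, 32),
                             shell_radii=(14.0, 10.0, 6.0), seed=1)
        vols, labels = M.generate_phantom(spec)
        vols = [M.Volume((v.data - v.data.mean()) / v.data.std(), v.spacing, v.modality) for v in vols]
        return [(vols, labels)]

    def test_zero_iterations_leaves_weights_unchanged(self, tiny_net_cfg):
        model = M.build_model(tiny_net_cfg)
        before = {k: v.value.copy() for k, v in model.named_parameters()}
        model, history = M.fit(
            model, self._tiny_dataset(), M.TrainConfig(iterations=0), M.LossConfig()
        )
        assert len(history) == 0
        for k, v in model.named_parameters():
            assert np.array_equal(before[k], v.value)

    def test_loss_decreases_over_short_training(self, tiny_net_cfg):
        model = M.build_model(tiny_net_cfg)
        tcfg = M.TrainConfig(iterations=200, batch_size=2, seed=3)
        model, history = M.fit(model, self._tiny_dataset(), tcfg, M.LossConfig())
        start = history.loss_total.iloc[:10].mean()
        end = history.loss_total.iloc[-10:].mean()
        assert end < start
        assert set(history.columns) >= {"iteration", "lr", "loss_total", "loss_fuse", "loss_side"}

    def test_subvolume_budget_caps_iterations(self, tiny_net_cfg):
        model = M.build_model(tiny_net_cfg)
        tcfg = M.TrainConfig(iterations=50, batch_size=2, n_subvolumes=20, seed=0)
        _, history = M.fit(model, self._tiny_dataset(), tcfg, M.LossConfig())
        assert len(history) == 10
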