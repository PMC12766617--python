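"""De-noising networks: architecture contracts, WGAN-GP, augmentation,
splitting, training, ensembling."""

import dataclasses

import numpy as np
import pytest

from cdtikit import _autograd as ag
from cdtikit import denoise as dn
from cdtikit import tensor_fit
from cdtikit._autograd import Tensor


class TestGenerator:
    def test_untrained_generator_is_identity(self, rng):
        gen = dn.build_generator(dn.GENERATOR_PRESETS["tiny"], seed=0)
        x = Tensor(rng.normal(size=(2, 6, 32, 32)))
        np.testing.assert_array_equal(gen(x).data, x.data)

    def test_spatial_size_preserved_at_128(self):
        gen = dn.build_generator(dn.GENERATOR_PRESETS["tiny"], seed=0)
        out = gen(Tensor(np.zeros((1, 6, 128, 128))))
        assert out.shape == (1, 6, 128, 128)

    def test_tiny_parameter_count_matches_analytic_formula(self):
        cfg = dn.GENERATOR_PRESETS["tiny"]
        gen = dn.build_generator(cfg, seed=0)

        def conv(ci, co, k):
            return co * ci * k * k + co

        def lin(ci, co):
            return ci * co + co

        def block(dim):
            hidden = int(dim * cfg.mlp_ratio)
            return (4 * dim + lin(dim, 3 * dim) + lin(dim, dim)
                    + lin(dim, hidden) + lin(hidden, dim))

        w = cfg.base_width
        expected = (conv(6, w, 3)                     # input projection
                    + cfg.depths[0] * block(w)        # encoder level
                    + conv(w, 2 * w, 3)               # downsample
                    + cfg.depths[1] * block(2 * w)    # bottleneck
                    + conv(2 * w, w, 3)               # upsample conv
                    + conv(2 * w, w, 1)               # skip merge
                    + cfg.depths[0] * block(w)        # decoder level
                    + conv(w, 6, 3))                  # output projection
        assert gen.n_parameters() == expected
        assert dn.count_parameters(cfg) == expected

    def test_preset_parameter_budgets(self):
        assert dn.count_parameters(dn.GENERATOR_PRESETS["tiny"]) <= 2e5
        ref = dn.count_parameters(dn.GENERATOR_PRESETS["reference"])
        assert 3.5e7 < ref < 4.5e7

    def test_indivisible_window_rejected(self):
        gen = dn.build_generator(dn.GENERATOR_PRESETS["tiny"], seed=0)
        with pytest.raises(ValueError, match="divisible"):
            gen(Tensor(np.zeros((1, 6, 30, 30))))

    def test_seeded_initialization_reproducible(self):
        a = dn.build_generator(dn.GENERATOR_PRESETS["tiny"], seed=5)
        b = dn.build_generator(dn.GENERATOR_PRESETS["tiny"], seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestDiscriminator:
    def test_score_grid_shape_from_three_stride2_stages(self):
        critic = dn.build_discriminator(dn.DiscriminatorConfig(), seed=0)
        score = critic(Tensor(np.zeros((2, 6, 128, 128))))
        assert score.shape == (2, 1, 16, 16)

    def test_scores_unbounded_and_finite(self, rng):
        critic = dn.build_discriminator(dn.DiscriminatorConfig(), seed=0)
        x = Tensor(rng.normal(size=(1, 6, 32, 32)))
        s1 = critic(x).data
        s2 = critic(Tensor(x.data + 100.0)).data
        assert np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))
        assert not np.allclose(s1, s2)   # no saturating nonlinearity

    def test_input_below_receptive_field_rejected(self):
        critic = dn.build_discriminator(dn.DiscriminatorConfig(), seed=0)
        with pytest.raises(ValueError, match="receptive"):
            critic(Tensor(np.zeros((1, 6, 4, 4))))


class _LinearCritic:
    """Per-sample score w . x — analytic gradient norm ||w||."""

    def __init__(self, w):
        self.w = Tensor(w, requires_grad=True)

    def __call__(self, x):
        return ag.tsum(x * self.w, axis=(1, 2, 3))

    def parameters(self):
        return [self.w]


class TestWGANGP:
    shape = (4, 6, 8, 8)

    def _unit_w(self):
        w = np.zeros(self.shape[1:])
        w[0, 0, 0] = 1.0
        return w

    def test_unit_gradient_norm_gives_zero_penalty(self, rng):
        real = Tensor(rng.normal(size=self.shape))
        fake = Tensor(rng.normal(size=self.shape))
        _, _, pen = dn.wgan_gp_losses(_LinearCritic(self._unit_w()), real,
                                      fake, 10.0, seed=0)
        assert pen.item() == pytest.approx(0.0, abs=1e-10)

    def test_gradient_norm_two_gives_lambda(self, rng):
        real = Tensor(rng.normal(size=self.shape))
        fake = Tensor(rng.normal(size=self.shape))
        _, _, pen = dn.wgan_gp_losses(_LinearCritic(2 * self._unit_w()), real,
                                      fake, 10.0, seed=0)
        assert pen.item() == pytest.approx(10.0, rel=1e-6)

    def test_penalty_nonnegative_for_conv_critic(self, rng):
        critic = dn.build_discriminator(dn.DiscriminatorConfig(), seed=1)
        real = Tensor(rng.normal(size=(2, 6, 16, 16)))
        fake = Tensor(rng.normal(size=(2, 6, 16, 16)))
        closs, gloss, pen = dn.wgan_gp_losses(critic, real, fake, 10.0, seed=3)
        assert pen.item() >= 0
        assert np.isfinite(closs.item()) and np.isfinite(gloss.item())

    def test_penalty_differentiable_wrt_critic_weights(self, rng):
        # double backprop: the penalty must propagate to the critic weights
        critic = _LinearCritic(2 * self._unit_w())
        real = Tensor(rng.normal(size=self.shape))
        fake = Tensor(rng.normal(size=self.shape))
        closs, _, _ = dn.wgan_gp_losses(critic, real, fake, 10.0, seed=0)
        (gw,) = ag.grad(closs, critic.parameters())
        # analytic: d/dw [10 (||w|| - 1)^2] = 20 (||w|| - 1) w / ||w||,
        # plus the Wasserstein term's gradient sum(fake) - sum(real)
        wd = critic.w.data
        norm = np.linalg.norm(wd)
        expected = (20 * (norm - 1) * wd / norm
                    + (fake.data.mean(0) - real.data.mean(0)))
        np.testing.assert_allclose(gw.data, expected, atol=1e-4)

    def test_negative_lambda_rejected(self, rng):
        real = Tensor(rng.normal(size=self.shape))
        with pytest.raises(ValueError, match="non-negative"):
            dn.wgan_gp_losses(_LinearCritic(self._unit_w()), real, real, -1.0)


class TestAugmentation:
    @pytest.fixture()
    def fields(self, tensor_field):
        return tensor_field, tensor_field, tensor_field.mask

    def test_zero_angle_identity(self, fields):
        noisy, target, mask = fields
        a, b, m = dn.augment_sample(noisy, target, mask, 0.0, None)
        np.testing.assert_array_equal(a.d, noisy.d)
        np.testing.assert_array_equal(m, mask)

    def test_90_degree_rotation_swaps_in_plane_channels(self, fields):
        # D' = R D R^T at 90 degrees: Dxx <-> Dyy, Dxy flips sign
        noisy, _, mask = fields
        a, _, m = dn.augment_sample(noisy, noisy, mask, 90.0, None)
        rot = lambda ch: np.rot90(noisy.d[..., ch])
        np.testing.assert_allclose(a.d[..., 0], rot(1), atol=1e-12)
        np.testing.assert_allclose(a.d[..., 1], rot(0), atol=1e-12)
        np.testing.assert_allclose(a.d[..., 3], -rot(3), atol=1e-12)

    def test_rotation_preserves_eigenvalues(self, fields, small_geometry):
        noisy, _, mask = fields
        a, _, m = dn.augment_sample(noisy, noisy, mask, 90.0, None)
        lam_in = np.sort(np.linalg.eigvalsh(noisy.as_matrices()[mask]))
        lam_out = np.sort(np.linalg.eigvalsh(a.as_matrices()[m]))
        np.testing.assert_allclose(np.sort(lam_in.ravel()),
                                   np.sort(lam_out.ravel()), atol=1e-12)

    def test_crop_contains_full_myocardium(self, fields):
        noisy, target, mask = fields
        _, _, m = dn.augment_sample(noisy, target, mask, 0.0, (48, 48))
        assert m.sum() == mask.sum()
        assert m.shape == (48, 48)

    def test_crop_too_small_rejected(self, fields):
        noisy, target, mask = fields
        with pytest.raises(ValueError, match="exceeds crop"):
            dn.augment_sample(noisy, target, mask, 0.0, (16, 16))


class TestSplit:
    def test_ten_subjects_split_8_1_1(self):
        train, val, test = dn.split_patients(list(range(10)), seed=0)
        assert (len(train), len(val), len(test)) == (8, 1, 1)

    def test_partition_disjoint_and_complete(self):
        ids = [f"subj{i}" for i in range(23)]
        train, val, test = dn.split_patients(ids, seed=3)
        assert not set(train) & set(val)
        assert not set(val) & set(test)
        assert not set(train) & set(test)
        assert set(train) | set(val) | set(test) == set(ids)

    def test_deterministic_per_seed(self):
        ids = list(range(20))
        assert dn.split_patients(ids, seed=7) == dn.split_patients(ids, seed=7)
        assert dn.split_patients(ids, seed=7) != dn.split_patients(ids, seed=8)

    def test_fewer_than_ten_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            dn.split_patients(list(range(9)), seed=0)


def _toy_pair(rng, size=32):
    yy, xx = np.mgrid[0:size, 0:size] / size
    target = np.stack([np.sin(2 * np.pi * yy * (i + 1) / 3)
                       * np.cos(2 * np.pi * xx) for i in range(6)])
    noisy = target + rng.normal(0, 0.4, target.shape)
    return dn.TrainingSample(noisy=noisy.astype(np.float32),
                             target=target.astype(np.float32))


class TestTraining:
    def test_single_pair_overfit(self, rng):
        # optimization sanity: 300 steps shrink the MAE below 10% of start
        pair = _toy_pair(rng)
        cfg = dn.TrainConfig(learning_rate=5e-3, epochs=300, batch_size=1,
                             lambda_adv=0.0, seed=0)
        ckpt = dn.train([pair], [pair], dn.GENERATOR_PRESETS["tiny"], cfg)
        initial = np.abs(pair.noisy - pair.target).mean()
        assert ckpt.history[-1]["train_loss"] < 0.1 * initial

    def test_identical_seeds_identical_loss_curves(self, rng):
        pairs = [_toy_pair(rng) for _ in range(3)]
        cfg = dn.TrainConfig(learning_rate=1e-3, epochs=3, batch_size=2,
                             lambda_adv=0.0, seed=42)
        a = dn.train(pairs[:2], pairs[2:], dn.GENERATOR_PRESETS["tiny"], cfg)
        b = dn.train(pairs[:2], pairs[2:], dn.GENERATOR_PRESETS["tiny"], cfg)
        assert a.history == b.history

    def test_checkpoint_is_validation_minimum(self, rng):
        pairs = [_toy_pair(rng) for _ in range(4)]
        cfg = dn.TrainConfig(learning_rate=2e-3, epochs=5, batch_size=2,
                             lambda_adv=0.0, seed=1)
        ckpt = dn.train(pairs[:3], pairs[3:], dn.GENERATOR_PRESETS["tiny"], cfg)
        vals = [h["val_loss"] for h in ckpt.history]
        assert vals[ckpt.best_epoch] == min(vals)

    def test_supervised_limit_first_batch_loss_is_identity_mae(self, rng):
        # identity-at-init + lambda_adv = 0: the first logged training loss
        # equals the plain MAE of the (single) untouched batch
        pairs = [_toy_pair(rng) for _ in range(2)]
        cfg = dn.TrainConfig(learning_rate=1e-3, epochs=1, batch_size=2,
                             lambda_adv=0.0, seed=0)
        ckpt = dn.train(pairs, pairs, dn.GENERATOR_PRESETS["tiny"], cfg)
        expected = np.mean([np.abs(p.noisy - p.target).mean().astype(np.float32)
                            for p in pairs])
        assert ckpt.history[0]["train_loss"] == pytest.approx(expected,
                                                              rel=1e-5)

    def test_adversarial_training_runs_and_stays_finite(self, rng):
        pairs = [_toy_pair(rng, size=16) for _ in range(2)]
        cfg = dn.TrainConfig(learning_rate=1e-3, epochs=2, batch_size=2,
                             lambda_adv=0.01, lambda_gp=10.0, critic_steps=1,
                             seed=0)
        ckpt = dn.train(pairs, pairs, dn.GENERATOR_PRESETS["tiny"], cfg)
        assert all(np.isfinite(h["train_loss"]) for h in ckpt.history)

    def test_empty_sets_rejected(self, rng):
        with pytest.raises(ValueError, match="nonempty"):
            dn.train([], [_toy_pair(rng)], dn.GENERATOR_PRESETS["tiny"],
                     dn.TrainConfig(epochs=1))


class TestEnsemble:
    def _checkpoint_with_bias(self, offset, spec):
        gen = dn.build_generator(dn.GENERATOR_PRESETS["tiny"], seed=0)
        state = gen.state()
        state[-1] = state[-1] + offset      # output-projection bias
        return dn.Checkpoint(
            generator_config=dn.GENERATOR_PRESETS["tiny"], params=state,
            norm_spec=spec, seed=0, best_epoch=0)

    def test_identical_members_match_single_member(self, tensor_field):
        spec = tensor_fit.NormalizationSpec()
        ck = self._checkpoint_with_bias(0.0, spec)
        single = dn.ensemble_predict([ck], tensor_field)
        triple = dn.ensemble_predict([ck, ck, ck], tensor_field)
        np.testing.assert_allclose(triple.d, single.d, atol=1e-12)

    def test_symmetric_errors_cancel(self, tensor_field):
        # members predicting truth + e and truth - e average to the truth
        spec = tensor_fit.NormalizationSpec()
        plus = self._checkpoint_with_bias(+0.25, spec)
        minus = self._checkpoint_with_bias(-0.25, spec)
        identity = self._checkpoint_with_bias(0.0, spec)
        both = dn.ensemble_predict([plus, minus], tensor_field)
        ref = dn.ensemble_predict([identity], tensor_field)
        np.testing.assert_allclose(both.d, ref.d, atol=1e-10)

    def test_ensemble_mae_bounded_by_mean_member_mae(self, tensor_field, rng):
        spec = tensor_fit.NormalizationSpec()
        members = [self._checkpoint_with_bias(rng.normal(0, 0.3), spec)
                   for _ in range(4)]
        target = tensor_field.d
        preds = [dn.ensemble_predict([m], tensor_field).d for m in members]
        ens = dn.ensemble_predict(members, tensor_field).d
        mae_members = np.mean([np.abs(p - target).mean() for p in preds])
        mae_ens = np.abs(ens - target).mean()
        assert mae_ens <= mae_members + 1e-15

    def test_inconsistent_members_rejected(self, tensor_field):
        spec = tensor_fit.NormalizationSpec()
        a = self._checkpoint_with_bias(0.0, spec)
        other_cfg = dataclasses.replace(dn.GENERATOR_PRESETS["tiny"],
                                        base_width=8)
        gen_b = dn.build_generator(other_cfg, seed=0)
        b = dn.Checkpoint(generator_config=other_cfg, params=gen_b.state(),
                          norm_spec=spec, seed=0, best_epoch=0)
        with pytest.raises(ValueError, match="inconsistent"):
            dn.ensemble_predict([a, b], tensor_field)

    def test_empty_ensemble_rejected(self, tensor_field):
        with pytest.raises(ValueError, match="at least one"):
            dn.ensemble_predict([], tensor_field)

    def test_ensemble_spec_requires_distinct_member_seeds(self):
        with pytest.raises(ValueError, match="distinct"):
            dn.EnsembleSpec(n_members=3, member_seeds=(1, 1, 2))
        spec = dn.EnsembleSpec()
        assert spec.n_members == 5 and len(set(spec.member_seeds)) == 5
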