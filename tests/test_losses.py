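"""Closed-form and property checks of the loss suite."""

import numpy as np
import pytest

from petcycle import autodiff as ad
from petcycle import losses as L
from petcycle.losses import (LossWeights, RandomConvFeatures,
                             WeightsUnavailableError, adv_loss_mse,
                             build_feature_extractor, critic_loss_wgan_gp,
                             cycle_loss, generator_adv_loss,
                             gradient_penalty, identity_loss,
                             perceptual_loss, total_loss)


def batch(*arrays):
    return ad.Tensor(np.stack(arrays)[:, None].astype(np.float64))


IDENTITY = lambda x: x


class TestPerceptual:
    def test_identical_batches_give_zero(self):
        x = batch(np.ones((4, 4)))
        assert perceptual_loss(IDENTITY, x, x).item() == 0.0

    def test_constant_offset_with_identity_features(self):
        """phi = id, generated = target + 0.5, 16 pixels -> 0.5 * 16."""
        t = np.zeros((4, 4))
        val = perceptual_loss(IDENTITY, batch(t + 0.5), batch(t)).item()
        assert val == pytest.approx(0.5 * 16)

    def test_duplicating_batch_items_leaves_mean_unchanged(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        single = perceptual_loss(IDENTITY, batch(a), batch(b)).item()
        double = perceptual_loss(IDENTITY, batch(a, a), batch(b, b)).item()
        assert double == pytest.approx(single)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(L.ShapeError):
            perceptual_loss(IDENTITY, batch(np.ones((4, 4))),
                            batch(np.ones((5, 5))))


class TestCycleIdentity:
    def test_identity_generators_give_zero_cycle(self):
        x = batch(np.random.default_rng(1).normal(size=(4, 4)))
        assert cycle_loss(IDENTITY, IDENTITY, x, x).item() == 0.0

    def test_forward_offset_counts_pixels(self):
        """GB(GA(x)) = x + 1 on 16 pixels and perfect backward -> 16."""
        ga = lambda x: x + 1.0
        gb = IDENTITY                        # gb(ga(x)) = x + 1
        xa = batch(np.zeros((4, 4)))
        xb = batch(np.full((4, 4), 0.5))     # ga(gb(xb)) = xb + 1 too
        # isolate the forward term with a backward-perfect pair:
        ga2 = lambda x: x + 1.0
        gb2 = lambda x: x - 1.0              # gb2(ga2(x)) = x exactly
        val = cycle_loss(ga2, gb2, xa, xb).item()
        # forward term 0; backward term |ga2(gb2(xb)) - xb| = 0 as well
        assert val == pytest.approx(0.0)
        val2 = cycle_loss(ga, gb, xa, xb).item()
        assert val2 == pytest.approx(16.0 + 16.0)  # both cycles off by 1

    def test_cycle_symmetric_under_domain_swap(self):
        rng = np.random.default_rng(2)
        xa, xb = batch(rng.normal(size=(4, 4))), batch(rng.normal(size=(4, 4)))
        ga = lambda x: x * 0.9
        gb = lambda x: x + 0.2
        assert cycle_loss(ga, gb, xa, xb).item() == pytest.approx(
            cycle_loss(gb, ga, xb, xa).item())

    def test_identity_loss_zero_for_identity_maps(self):
        x = batch(np.random.default_rng(3).normal(size=(4, 4)))
        assert identity_loss(IDENTITY, IDENTITY, x, x).item() == 0.0

    def test_identity_loss_offset_counts_pixels(self):
        """GA adds 0.1 on 16 pixels, GB = id -> 0.1 * 16."""
        ga = lambda x: x + 0.1
        xa = batch(np.zeros((4, 4)))
        xb = batch(np.ones((4, 4)))
        val = identity_loss(ga, IDENTITY, xa, xb).item()
        assert val == pytest.approx(0.1 * 16)

    def test_first_term_independent_of_xa_when_gb_identity(self):
        ga = lambda x: x + 0.1
        xb = batch(np.ones((4, 4)))
        v1 = identity_loss(ga, IDENTITY, batch(np.zeros((4, 4))), xb).item()
        v2 = identity_loss(ga, IDENTITY, batch(np.full((4, 4), 9.0)),
                           xb).item()
        assert v1 == pytest.approx(v2)


class TestWassersteinCritic:
    def test_constant_critic_leaves_only_the_penalty(self):
        """Gap vanishes and grad is 0, so loss = lambda * (0 - 1)^2."""
        critic = lambda x: ad.Tensor(np.full(x.shape[0], 3.0))
        rng = np.random.default_rng(4)
        real = ad.Tensor(rng.normal(size=(3, 1, 4, 4)))
        fake = ad.Tensor(rng.normal(size=(3, 1, 4, 4)))
        val = critic_loss_wgan_gp(critic, real, fake, lambda_gp=10.0,
                                  seed=0).item()
        assert val == pytest.approx(10.0, rel=1e-3)

    def test_unit_gradient_linear_critic_has_zero_penalty(self):
        """D(x) = sum(x)/sqrt(P) has gradient norm exactly 1."""
        p = 16

        def critic(x):
            return ad.sum_(x, axis=(1, 2, 3)) / np.sqrt(p)

        rng = np.random.default_rng(5)
        real = ad.Tensor(rng.normal(size=(2, 1, 4, 4)))
        fake = ad.Tensor(rng.normal(size=(2, 1, 4, 4)))
        pen = gradient_penalty(critic, real, fake,
                               np.random.default_rng(0)).item()
        assert pen == pytest.approx(0.0, abs=1e-8)

    def test_penalty_weight_scales_linearly(self):
        critic = lambda x: ad.Tensor(np.zeros(x.shape[0]))
        rng = np.random.default_rng(6)
        real = ad.Tensor(rng.normal(size=(2, 1, 4, 4)))
        fake = ad.Tensor(rng.normal(size=(2, 1, 4, 4)))
        v10 = critic_loss_wgan_gp(critic, real, fake, 10.0, seed=1).item()
        v5 = critic_loss_wgan_gp(critic, real, fake, 5.0, seed=1).item()
        assert v10 == pytest.approx(2 * v5, rel=1e-6)

    def test_penalty_symmetric_for_linear_critic(self):
        """A linear critic has constant gradient, so swapping real/fake
        leaves the penalty unchanged."""
        w = np.random.default_rng(7).normal(size=(1, 1, 4, 4))

        def critic(x):
            return ad.sum_(x * ad.Tensor(w), axis=(1, 2, 3))

        rng = np.random.default_rng(8)
        a = ad.Tensor(rng.normal(size=(2, 1, 4, 4)))
        b = ad.Tensor(rng.normal(size=(2, 1, 4, 4)))
        p1 = gradient_penalty(critic, a, b, np.random.default_rng(2)).item()
        p2 = gradient_penalty(critic, b, a, np.random.default_rng(2)).item()
        assert p1 == pytest.approx(p2, rel=1e-6)


class TestGeneratorAdversarial:
    def test_zero_critic_gives_zero(self):
        critic = lambda x: ad.Tensor(np.zeros(x.shape[0]))
        fake = ad.Tensor(np.ones((3, 1, 4, 4)))
        assert generator_adv_loss(critic, fake).item() == 0.0

    def test_constant_critic_gives_minus_constant(self):
        critic = lambda x: ad.Tensor(np.full(x.shape[0], 2.5))
        fake = ad.Tensor(np.ones((3, 1, 4, 4)))
        assert generator_adv_loss(critic, fake).item() == pytest.approx(-2.5)

    def test_scaling_critic_scales_loss(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=4)
        c1 = lambda x: ad.Tensor(scores)
        c2 = lambda x: ad.Tensor(2 * scores)
        fake = ad.Tensor(np.ones((4, 1, 2, 2)))
        assert generator_adv_loss(c2, fake).item() == pytest.approx(
            2 * generator_adv_loss(c1, fake).item())


class TestMSEAdversarial:
    @pytest.mark.parametrize("score,label,expected", [
        (1.0, 1.0, 0.0), (0.0, 1.0, 1.0), (0.5, 0.0, 0.25),
        (0.5, 1.0, 0.25),
    ])
    def test_constant_score_cases(self, score, label, expected):
        critic = lambda x: ad.Tensor(np.full((2, 1, 3, 3), score))
        val = adv_loss_mse(critic, ad.Tensor(np.ones((2, 1, 8, 8))),
                           label).item()
        assert val == pytest.approx(expected)


class TestTotal:
    def test_all_zero_terms_give_zero(self):
        w = LossWeights(lambda_idt=1, lambda_cycle=1, lambda_pept=1)
        assert total_loss(0.0, 0.0, 0.0, 0.0, w).item() == 0.0

    def test_unit_weights_sum_terms(self):
        w = LossWeights(lambda_idt=1, lambda_cycle=1, lambda_pept=1)
        val = total_loss(adv_g=4.0, cycle=3.0, identity=2.0, perceptual=5.0,
                         weights=w).item()
        assert val == pytest.approx(2 + 3 + 4 + 5)

    def test_zero_weights_leave_adversarial_alone(self):
        w = LossWeights(lambda_idt=0, lambda_cycle=0, lambda_pept=0)
        assert total_loss(7.0, 99.0, 99.0, 99.0, w).item() == 7.0

    def test_affine_in_each_weight(self):
        terms = dict(adv_g=1.5, cycle=2.0, identity=3.0, perceptual=4.0)
        for key in ("lambda_idt", "lambda_cycle", "lambda_pept"):
            vals = []
            for lam in (0.0, 1.0, 2.0):
                w = LossWeights(**{key: lam})
                vals.append(total_loss(weights=w, **terms).item())
            assert vals[2] - vals[1] == pytest.approx(vals[1] - vals[0])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_cycle=-1.0)


class TestFeatureExtractors:
    def test_seeded_random_conv_is_deterministic(self):
        a = build_feature_extractor("seeded_random_conv", seed=5)
        b = build_feature_extractor("seeded_random_conv", seed=5)
        x = ad.Tensor(np.random.default_rng(10)
                      .normal(size=(1, 1, 16, 16)).astype(np.float32))
        fa, fb = a(x).data, b(x).data
        assert np.array_equal(fa, fb)
        assert np.array_equal(a(x).data, fa)   # repeated call identical

    def test_random_conv_parameters_frozen(self):
        phi = RandomConvFeatures(seed=0)
        assert all(not p.requires_grad for p in phi.parameters())

    def test_pretrained_without_weights_is_actionable_error(self):
        with pytest.raises(WeightsUnavailableError,
                           match="seeded_random_conv"):
            build_feature_extractor("pretrained_vgg19_conv16")

    def test_pretrained_with_missing_file_is_actionable_error(self, tmp_path):
        with pytest.raises(WeightsUnavailableError, match="not found"):
            build_feature_extractor("pretrained_vgg19_conv16",
                                    weights_path=tmp_path / "none.npz")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_feature_extractor("resnet")
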