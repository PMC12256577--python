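"""Scheduler arithmetic, step mechanics, determinism and checkpointing.

Training-mechanics tests run on deliberately tiny networks (16x16
images, 4 base channels) so the whole module stays fast.
"""

import numpy as np
import pytest

from petcycle import autodiff as ad, nn
from petcycle.losses import LossWeights
from petcycle.networks import CriticConfig, GeneratorConfig
from petcycle.pet_io import NormalizationWindow, PETVolume
from petcycle.phantom import PhantomSpec, generate_dataset
from petcycle.training import (CycleTrainer, DataError, TrainConfig, cawr_lr,
                               denoise, derive_seed, fit, load_checkpoint,
                               load_trainer)


def tiny_config(**kw):
    defaults = dict(
        epochs=1, batch_size=2, lr=1e-3, n_critic=2, seed=5,
        image_side=16, sched_T0=10, sched_Tmult=2,
        generator=GeneratorConfig(n_down=2, base_channels=4,
                                  n_residual_blocks=1),
        critic=CriticConfig(base_channels=4, n_layers_per_scale=2,
                            n_scales=2),
        loss_weights=LossWeights(lambda_idt=1, lambda_cycle=1,
                                 lambda_pept=1),
        window=NormalizationWindow(-1.5, 15.0),
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


def tiny_batch(seed, n=2, side=16):
    rng = np.random.default_rng(seed)
    return (rng.uniform(-1, 1, (n, 1, side, side)),
            rng.uniform(-1, 1, (n, 1, side, side)))


class TestScheduler:
    def test_starts_at_base_rate(self):
        assert cawr_lr(0.0, 10, 2, 1e-4) == pytest.approx(1e-4)

    def test_restarts_at_epochs_10_and_30(self):
        """Cycle lengths 10 then 20: warm restarts land at 10 and 30."""
        for restart in (10.0, 30.0):
            assert cawr_lr(restart, 10, 2, 1e-4) == pytest.approx(1e-4)
        # just before each restart the rate has decayed to ~min_lr
        assert cawr_lr(9.999, 10, 2, 1e-4) < 1e-8
        assert cawr_lr(29.999, 10, 2, 1e-4) < 1e-8

    def test_midpoint_is_half_base_rate(self):
        assert cawr_lr(5.0, 10, 2, 1e-4, min_lr=0.0) == \
            pytest.approx(0.5e-4)
        assert cawr_lr(20.0, 10, 2, 1e-4) == pytest.approx(0.5e-4)

    def test_nonincreasing_within_a_cycle(self):
        lrs = [cawr_lr(t, 10, 2, 1e-4) for t in np.linspace(0, 9.99, 100)]
        assert all(b <= a + 1e-15 for a, b in zip(lrs, lrs[1:]))

    def test_negative_progress_rejected(self):
        with pytest.raises(ValueError):
            cawr_lr(-1.0, 10, 2, 1e-4)

    def test_min_lr_floor(self):
        assert cawr_lr(4.9999, 5, 1, 1e-3, min_lr=1e-5) >= 1e-5


class TestDeriveSeed:
    def test_stable_and_stream_separated(self):
        a1 = derive_seed(42, "gen_a")
        a2 = derive_seed(42, "gen_a")
        b = derive_seed(42, "gen_b")
        assert a1 == a2 != b
        assert 0 <= a1 < 2 ** 31

    def test_index_separates(self):
        assert derive_seed(1, "order", 0) != derive_seed(1, "order", 1)


class TestTrainStep:
    def test_critic_updates_n_critic_times_per_generator_update(self):
        trainer = CycleTrainer(tiny_config(n_critic=3))
        xa, xb = tiny_batch(0)
        for _ in range(4):
            trainer.train_step(xa, xb)
        assert trainer.opt_d.t == 3 * trainer.opt_g.t
        assert trainer.opt_g.t == 4

    def test_two_trainers_same_seed_identical_losses(self):
        bundles = []
        for _ in range(2):
            trainer = CycleTrainer(tiny_config())
            xa, xb = tiny_batch(1)
            bundles.append([trainer.train_step(xa, xb).total
                            for _ in range(3)])
        assert bundles[0] == bundles[1]

    def test_identity_objective_decreases_under_training(self):
        """With only the identity term active, gradient steps shrink it
        (from-scratch output head, so the term starts large)."""
        cfg = tiny_config(loss_weights=LossWeights(
            lambda_idt=1, lambda_cycle=0, lambda_pept=0, lambda_gp=10),
            n_critic=1, lr=5e-3,
            generator=GeneratorConfig(n_down=2, base_channels=4,
                                      n_residual_blocks=1,
                                      identity_init=False))
        trainer = CycleTrainer(cfg)
        xa = np.full((2, 1, 16, 16), 0.3)
        xb = np.full((2, 1, 16, 16), -0.2)
        history = [trainer.train_step(xa, xb).identity for _ in range(50)]
        assert history[-1] < 0.3 * history[0]

    def test_mse_adversarial_variant_steps(self):
        trainer = CycleTrainer(tiny_config(adv_kind="mse"))
        xa, xb = tiny_batch(2)
        bundle = trainer.train_step(xa, xb)
        assert np.isfinite(bundle.total)
        assert bundle.adv_d >= 0.0     # least-squares loss is nonnegative


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("data")
    spec = PhantomSpec(image_size=16, psf_fwhm_mm=4.0)
    manifest = generate_dataset(spec, n_phantoms=4, slices_per_phantom=3,
                                out_dir=out, seed=3,
                                split=(0.5, 0.25, 0.25))
    return manifest


class TestFit:
    def test_writes_checkpoints_and_history(self, tiny_dataset, tmp_path):
        cfg = tiny_config(epochs=2, batch_size=2)
        summary = fit(cfg, tiny_dataset, tmp_path / "run")
        assert (tmp_path / "run" / "epoch_000.npz").exists()
        assert (tmp_path / "run" / "epoch_001.npz").exists()
        assert (tmp_path / "run" / "best.npz").exists()
        history = (tmp_path / "run" / "history.tsv").read_text()
        assert "adv_g" in history.splitlines()[0]
        assert summary["epochs"] == 2

    def test_resumed_run_matches_uninterrupted_run(self, tiny_dataset,
                                                   tmp_path):
        cfg = tiny_config(epochs=2, batch_size=2)
        fit(cfg, tiny_dataset, tmp_path / "full")
        fit(tiny_config(epochs=1, batch_size=2), tiny_dataset,
            tmp_path / "part")
        fit(cfg, tiny_dataset, tmp_path / "resumed",
            resume_from=tmp_path / "part" / "epoch_000.npz")
        full = load_trainer(tmp_path / "full" / "epoch_001.npz")
        resumed = load_trainer(tmp_path / "resumed" / "epoch_001.npz")
        for (ka, pa), (kb, pb) in zip(
                full.gen_a.named_parameters().items(),
                resumed.gen_a.named_parameters().items()):
            assert ka == kb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_best_checkpoint_at_least_first_epoch(self, tiny_dataset,
                                                  tmp_path):
        cfg = tiny_config(epochs=2, batch_size=2)
        summary = fit(cfg, tiny_dataset, tmp_path / "run")
        assert summary["best_val_psnr"] >= -np.inf
        assert summary["best_epoch"] in (0, 1)

    def test_empty_manifest_raises_data_error(self, tmp_path):
        bad = tmp_path / "manifest.tsv"
        bad.write_text("pair_id\tsplit\tld_path\tsd_path\n")
        with pytest.raises(DataError):
            fit(tiny_config(), bad, tmp_path / "run")


class TestDenoise:
    def test_output_geometry_matches_input(self, tiny_dataset, tmp_path):
        cfg = tiny_config(epochs=1, batch_size=2)
        fit(cfg, tiny_dataset, tmp_path / "run")
        model = load_checkpoint(tmp_path / "run" / "best.npz")
        vol = PETVolume(voxels=np.random.default_rng(0)
                        .uniform(0, 10, (3, 16, 16)),
                        spacing=(2, 2, 2), intensity_kind="suv")
        out = denoise(model, vol)
        assert out.voxels.shape == vol.voxels.shape
        assert out.spacing == vol.spacing
        assert out.intensity_kind == "suv"
        assert np.all(out.voxels >= 0)

    def test_checkpoint_round_trip_bitwise_inference(self, tiny_dataset,
                                                     tmp_path):
        cfg = tiny_config(epochs=1, batch_size=2)
        fit(cfg, tiny_dataset, tmp_path / "run")
        m1 = load_checkpoint(tmp_path / "run" / "best.npz")
        m2 = load_checkpoint(tmp_path / "run" / "best.npz")
        x = ad.Tensor(np.random.default_rng(1)
                      .uniform(-1, 1, (1, 1, 16, 16)).astype(nn.DTYPE))
        np.testing.assert_array_equal(m1.gen_a(x).data, m2.gen_a(x).data)


class TestRandomCrop:
    def test_same_window_both_members(self):
        from petcycle.training import random_crop_pair
        rng = np.random.default_rng(0)
        xa = np.arange(2 * 1 * 8 * 8, dtype=float).reshape(2, 1, 8, 8)
        ca, cb = random_crop_pair(xa, xa.copy(), 4, rng)
        assert ca.shape == (2, 1, 4, 4)
        np.testing.assert_array_equal(ca, cb)

    def test_crop_must_respect_downsampling_divisibility(self):
        with pytest.raises(ValueError):
            tiny_config(crop_size=6)   # n_down=2 needs multiples of 4

    def test_cropped_training_runs(self, tiny_dataset, tmp_path):
        cfg = tiny_config(epochs=1, batch_size=2, crop_size=8)
        summary = fit(cfg, tiny_dataset, tmp_path / "run")
        assert summary["epochs"] == 1
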