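"""Training strategies: dataset construction, optimization, determinism."""

import numpy as np
import pytest

from dwisure import (DenoiserConfig, DenoisingModel, GuidedSample,
                     PhantomConfig, SigmaProfile, TrainConfig,
                     generate_phantom)
from dwisure.train import denoise, make_split_dataset, make_sure_dataset

TINY_NET = dict(depth=3, width=8)


@pytest.fixture(scope="module")
def stacks():
    out = []
    for i in range(4):
        cfg = PhantomConfig(grid_size=(32, 32), seed=200 + i,
                            sigma_profile=SigmaProfile(sigma_min=0.02,
                                                       sigma_max=0.06))
        out.append(generate_phantom(cfg))
    return out


class TestSureDataset:
    def test_sample_count_is_subjects_times_directions(self, stacks):
        samples = make_sure_dataset([s for _, s in stacks], TrainConfig())
        assert len(samples) == 4 * 3

    def test_half_fraction_scales_sigma_by_sqrt2(self, stacks):
        """Using 6 of 12 repetitions must yield a sigma-map ~sqrt(2) larger
        than the full 12-average map (the sigma/sqrt(N) law)."""
        raw = [s for _, s in stacks]
        full = make_sure_dataset(raw, TrainConfig(repetition_fraction=1.0),
                                 blur_sigma=0)
        half = make_sure_dataset(raw, TrainConfig(repetition_fraction=0.5),
                                 blur_sigma=0)
        ratios = []
        for f, h in zip(full, half):
            ratios.append(np.mean(h.noise_map * h.norm_scale)
                          / np.mean(f.noise_map * f.norm_scale))
        assert abs(np.mean(ratios) / np.sqrt(2) - 1.0) < 0.1

    def test_guidance_is_b50_average_passthrough(self, stacks):
        from dwisure.preprocess import phase_correct
        raw = [s for _, s in stacks]
        samples = make_sure_dataset(raw, TrainConfig())
        s = samples[0]
        reps = raw[0].repetitions(50.0, 0)
        expected = np.stack([phase_correct(r)[0] for r in reps]).mean(axis=0)
        np.testing.assert_allclose(s.guidance * s.norm_scale, expected,
                                   rtol=1e-10)

    def test_sure_strategy_requires_noise_maps(self):
        s = GuidedSample(target=np.zeros((8, 8)), guidance=None,
                         noise_map=None)
        with pytest.raises(ValueError, match="noise map"):
            DenoisingModel([s], TrainConfig(strategy="sure"))


class TestSplitDataset:
    def test_half2full_partition_sizes(self, stacks):
        raw = [s for _, s in stacks]
        samples = make_split_dataset(raw, TrainConfig(), "half2full")
        # N=12 at b1000: input from 6, reference from all 12
        s = samples[0]
        assert s.reference is not None
        assert s.target.shape == s.reference.shape

    def test_noise2noise_halves_are_disjoint_averages(self, stacks):
        from dwisure.preprocess import phase_correct
        raw = [s for _, s in stacks]
        samples = make_split_dataset(raw, TrainConfig(), "noise2noise")
        s = samples[0]
        reps = np.stack([phase_correct(r)[0]
                         for r in raw[0].repetitions(1000.0, 0)])
        np.testing.assert_allclose(s.target * s.norm_scale,
                                   reps[0::2].mean(axis=0), rtol=1e-10)
        np.testing.assert_allclose(s.reference * s.norm_scale,
                                   reps[1::2].mean(axis=0), rtol=1e-10)

    def test_single_repetition_cannot_split(self):
        cfg = PhantomConfig(grid_size=(16, 16), b_values=(1000.0,),
                            n_repetitions={1000.0: 2}, seed=9)
        _, stack = generate_phantom(cfg)
        stack.data[1000.0] = stack.data[1000.0][:, :1]
        with pytest.raises(ValueError, match="split"):
            make_split_dataset([stack], TrainConfig(), "noise2noise")


class TestFitting:
    def test_same_seed_gives_identical_history(self, stacks):
        raw = [s for _, s in stacks]
        cfg = TrainConfig(strategy="sure", learning_rate=1e-3, batch_size=4,
                          max_epochs=3, seed=11)
        samples = make_sure_dataset(raw, cfg)
        dcfg = DenoiserConfig(**TINY_NET)
        h1 = DenoisingModel(samples, cfg, dcfg).fit().history
        h2 = DenoisingModel(samples, cfg, dcfg).fit().history
        assert h1 == h2

    def test_zero_noise_training_stays_near_identity(self):
        """With sigma -> 0 the SURE objective is fidelity-dominated and the
        residual net should keep outputs close to its inputs."""
        cfg = PhantomConfig(grid_size=(32, 32), rep_phase_scale=0.0,
                            sigma_profile=SigmaProfile(sigma_min=1e-6,
                                                       sigma_max=1e-6),
                            seed=5)
        _, stack = generate_phantom(cfg)
        tcfg = TrainConfig(strategy="sure", learning_rate=1e-4, batch_size=4,
                           max_epochs=3, seed=0)
        samples = make_sure_dataset([stack], tcfg, blur_sigma=0)
        res = DenoisingModel(samples, tcfg,
                             DenoiserConfig(**TINY_NET)).fit()
        for s, img in zip(samples, res.denoise(samples)):
            noisy = s.target * s.norm_scale
            assert np.max(np.abs(img.values - noisy)) < 0.05 * max(
                np.max(np.abs(noisy)), 1e-9)

    def test_mse_strategies_reduce_training_loss(self, stacks):
        raw = [s for _, s in stacks]
        for strategy in ("noise2noise", "half2full"):
            cfg = TrainConfig(strategy=strategy, learning_rate=1e-3,
                              batch_size=4, max_epochs=5, seed=3)
            samples = make_split_dataset(raw, cfg, strategy)
            res = DenoisingModel(samples, cfg,
                                 DenoiserConfig(**TINY_NET)).fit()
            assert res.history["train"][-1] < res.history["train"][0]

    def test_summary_mentions_strategy_and_params(self, stacks):
        raw = [s for _, s in stacks]
        cfg = TrainConfig(strategy="sure", learning_rate=1e-3, batch_size=4,
                          max_epochs=2, seed=1)
        samples = make_sure_dataset(raw, cfg)
        res = DenoisingModel(samples, cfg, DenoiserConfig(**TINY_NET)).fit()
        text = res.summary()
        assert "sure" in text
        assert "residual variance" in text


class TestDenoise:
    def test_identity_network_returns_input(self, stacks):
        raw = [s for _, s in stacks]
        samples = make_sure_dataset(raw, TrainConfig())
        from dwisure.models import build_denoiser
        net = build_denoiser(DenoiserConfig(depth=3, width=4, in_channels=2,
                                            residual=True))
        net.convs[-1].W.fill(0.0)  # exact identity denoiser
        images, traces = denoise(net, samples)
        for s, img in zip(samples, images):
            np.testing.assert_allclose(img.values, s.target * s.norm_scale,
                                       atol=1e-5)
        assert set(traces) == {0, 1, 2, 3}

    def test_direction_permutation_equivariance(self, stacks):
        raw = [s for _, s in stacks]
        samples = make_sure_dataset(raw, TrainConfig())[:3]
        from dwisure.models import build_denoiser
        net = build_denoiser(DenoiserConfig(depth=3, width=4, in_channels=2,
                                            seed=8))
        out_fwd, _ = denoise(net, samples)
        out_rev, _ = denoise(net, samples[::-1])
        for a, b in zip(out_fwd, out_rev[::-1]):
            np.testing.assert_array_equal(a.values, b.values)
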