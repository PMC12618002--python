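"""Schedule identities, forward/backward consistency, conditioning."""

import numpy as np
import pytest

from vqfold.diffusion import (ConditioningContext, DenoiserModel,
                              DiffusionConfig, SamplerConfig,
                              ToySequenceEmbedder, ddpm_sample,
                              diffusion_training_loss, fine_tune_conditional,
                              forward_noise, linear_schedule, sample_latents,
                              sequence_condition, train_diffusion)

TINY = DiffusionConfig(T=20, hidden=32, n_layers=2, steps=30, batch_size=2,
                       seed=0)


# -- schedule ----------------------------------------------------------------

def test_default_schedule_matches_printed_configuration():
    sched = linear_schedule()
    assert sched.T == 400
    assert sched.betas[0] == pytest.approx(1e-4)
    assert sched.betas[-1] == pytest.approx(0.02)


def test_alpha_bars_monotone_and_equal_to_iterative_product():
    sched = linear_schedule(T=100)
    assert (np.diff(sched.alpha_bars) < 0).all()
    running = 1.0
    for t in range(100):
        running *= sched.alphas[t]
        assert abs(sched.alpha_bars[t] - running) < 1e-12


def test_posterior_variance_closed_form():
    sched = linear_schedule(T=50, beta_1=1e-3, beta_T=0.1)
    for t in (2, 17, 50):
        expected = (1 - sched.alpha_bars[t - 2]) / \
            (1 - sched.alpha_bars[t - 1]) * sched.betas[t - 1]
        assert sched.posterior_variance(t) == pytest.approx(expected, rel=1e-12)
    assert sched.posterior_variance(1) == 0.0


def test_schedule_validation():
    with pytest.raises(ValueError):
        linear_schedule(T=10, beta_1=0.02, beta_T=1e-4)
    with pytest.raises(ValueError):
        linear_schedule(T=10, beta_1=0.0, beta_T=0.1)


# -- forward process ---------------------------------------------------------

def test_forward_noise_at_t1_with_zero_eps_scales_by_sqrt_alpha():
    sched = linear_schedule()
    z0 = np.ones((4, 3))
    z1 = forward_noise(z0, 1, np.zeros_like(z0), sched)
    assert np.allclose(z1, np.sqrt(1 - 1e-4) * z0)


def test_forward_noise_terminal_marginal_is_standard_normal():
    sched = linear_schedule(T=400)
    rng = np.random.default_rng(0)
    z0 = rng.standard_normal((10000, 1))    # standardized input
    zT = forward_noise(z0, 400, rng.standard_normal(z0.shape), sched)
    assert np.var(zT) == pytest.approx(1.0, rel=0.05)
    assert np.abs(np.mean(zT)) < 0.05


def test_one_shot_noising_matches_composed_single_steps_in_distribution():
    sched = linear_schedule(T=30, beta_1=1e-3, beta_T=0.08)
    rng = np.random.default_rng(1)
    z0 = np.full((20000, 1), 1.7)
    t = 30
    one_shot = forward_noise(z0, t, rng.standard_normal(z0.shape), sched)
    z = z0.copy()
    for s in range(t):
        beta = sched.betas[s]
        z = np.sqrt(1 - beta) * z + np.sqrt(beta) * rng.standard_normal(z.shape)
    assert np.mean(one_shot) == pytest.approx(np.mean(z), abs=0.02)
    assert np.var(one_shot) == pytest.approx(np.var(z), rel=0.03)


def test_forward_noise_rejects_bad_t_and_shape():
    sched = linear_schedule(T=10, beta_1=1e-4, beta_T=0.02)
    z0 = np.zeros((3, 2))
    with pytest.raises(ValueError):
        forward_noise(z0, 0, np.zeros_like(z0), sched)
    with pytest.raises(ValueError):
        forward_noise(z0, 11, np.zeros_like(z0), sched)
    with pytest.raises(ValueError):
        forward_noise(z0, 3, np.zeros((2, 2)), sched)


# -- training loss -----------------------------------------------------------

def test_loss_zero_for_perfect_model():
    sched = linear_schedule(T=10, beta_1=1e-4, beta_T=0.02)
    z0 = np.random.default_rng(0).normal(size=(6, 4))

    class Perfect:
        def __call__(self, z_t, t, cond):
            from vqfold.nn import Tensor
            return Tensor(z0)

    loss = diffusion_training_loss(Perfect(), z0, 5, None, sched,
                                   np.zeros_like(z0))
    assert float(loss.data) == 0.0


def test_loss_of_zero_model_equals_mean_square():
    sched = linear_schedule(T=10, beta_1=1e-4, beta_T=0.02)
    z0 = np.random.default_rng(1).normal(size=(5, 3))

    class Zeros:
        def __call__(self, z_t, t, cond):
            from vqfold.nn import Tensor
            return Tensor(np.zeros_like(z0))

    loss = diffusion_training_loss(Zeros(), z0, 5, None, sched,
                                   np.zeros_like(z0))
    assert float(loss.data) == pytest.approx((z0 ** 2).mean())


def test_masked_positions_do_not_contribute():
    sched = linear_schedule(T=10, beta_1=1e-4, beta_T=0.02)
    rng = np.random.default_rng(2)
    z0 = rng.normal(size=(6, 4))
    mask = np.array([1, 1, 1, 0, 0, 0], bool)

    class Zeros:
        def __call__(self, z_t, t, cond):
            from vqfold.nn import Tensor
            return Tensor(np.zeros_like(z0))

    base = diffusion_training_loss(Zeros(), z0, 4, None, sched,
                                   np.zeros_like(z0), mask=mask)
    z0b = z0.copy()
    z0b[~mask] += 100.0
    perturbed = diffusion_training_loss(Zeros(), z0b, 4, None, sched,
                                        np.zeros_like(z0), mask=mask)
    assert float(base.data) == pytest.approx(float(perturbed.data))


# -- sampling ----------------------------------------------------------------

def test_oracle_denoiser_roundtrip_recovers_z0_exactly():
    sched = linear_schedule(T=40, beta_1=1e-3, beta_T=0.05)
    z0 = np.random.default_rng(3).normal(size=(7, 5))

    class Oracle:
        def __call__(self, z_t, t, cond):
            return z0

    zT = forward_noise(z0, sched.T, np.zeros_like(z0), sched)
    out = ddpm_sample(Oracle(), sched, z0.shape, np.random.default_rng(0),
                      zero_noise=True, z_init=zT)
    assert np.abs(out - z0).max() < 1e-10


def test_sampling_is_seed_deterministic():
    model, _ = train_diffusion(
        [np.random.default_rng(0).normal(size=(8, 4)) for _ in range(5)], TINY)
    sched = TINY.schedule()
    a = ddpm_sample(model, sched, (2, 8, 4), np.random.default_rng(11))
    b = ddpm_sample(model, sched, (2, 8, 4), np.random.default_rng(11))
    assert np.array_equal(a, b)


def test_snap_to_codebook_returns_exact_codebook_rows():
    rng = np.random.default_rng(4)
    data = [rng.normal(size=(8, 4)) for _ in range(5)]
    model, _ = train_diffusion(data, TINY)
    codebook = rng.normal(size=(16, 4))
    latents = sample_latents(model, SamplerConfig(n_samples=3, length=8,
                                                  seed=0),
                             codebook=codebook)
    for z in latents:
        for row in z.values:
            assert any(np.array_equal(row, cb) for cb in codebook)


def test_snap_requires_codebook():
    model, _ = train_diffusion(
        [np.random.default_rng(0).normal(size=(8, 4)) for _ in range(3)], TINY)
    with pytest.raises(ValueError):
        sample_latents(model, SamplerConfig(n_samples=1, length=8, seed=0))


# -- conditioning ------------------------------------------------------------

def test_sequence_condition_deterministic_and_length_checked():
    emb = ToySequenceEmbedder(dim=16, seed=0)
    a = sequence_condition("AVGAVG", emb)
    b = sequence_condition("AVGAVG", emb)
    assert np.array_equal(a.embeddings, b.embeddings)
    assert a.embeddings.shape == (6, 16)
    with pytest.raises(ValueError):
        sequence_condition("AVG", emb, length=5)


def test_unknown_letter_maps_to_unknown_token(caplog):
    emb = ToySequenceEmbedder(dim=8, seed=0)
    ctx = sequence_condition("AB", emb)   # B is not an amino-acid letter
    assert ctx.embeddings.shape == (2, 8)


def test_embedder_classes_linearly_separable():
    """Mean-pooled embeddings of two sequence classes separate linearly."""
    from sklearn.linear_model import LogisticRegression
    emb = ToySequenceEmbedder(dim=16, seed=0)
    rng = np.random.default_rng(0)
    X, y = [], []
    for _ in range(40):
        n_a = int(rng.integers(15, 25))
        seq_a = "".join(rng.choice(list("AAAG"), size=n_a))
        seq_v = "".join(rng.choice(list("VVVG"), size=n_a))
        X.append(emb.embed(seq_a).data.mean(0)); y.append(0)
        X.append(emb.embed(seq_v).data.mean(0)); y.append(1)
    clf = LogisticRegression(max_iter=1000).fit(X, y)
    assert clf.score(X, y) > 0.9


def test_condition_dropout_one_matches_unconditional_training():
    """With dropout 1.0 the fine-tuning trajectory is the unconditional one."""
    rng = np.random.default_rng(5)
    data = [rng.normal(size=(8, 4)) for _ in range(6)]
    paired = [("AVGAVGAV", z) for z in data]
    m_uncond, _ = train_diffusion(data, TINY)
    m_cond, _ = train_diffusion(data, TINY)
    m_uncond, log_u = train_diffusion(data, TINY, model=m_uncond, seed=77)
    m_cond, _, log_c = fine_tune_conditional(m_cond, paired, TINY,
                                             cond_dropout=1.0, seed=77)
    assert np.allclose([l["loss"] for l in log_u],
                       [l["loss"] for l in log_c])


def test_conditional_sampling_recovers_sequence_class():
    """Conditioning steers samples to the latent pattern of the sequence."""
    rng = np.random.default_rng(6)
    L, d = 10, 4
    mu_a = np.tile([2.0, -2.0, 2.0, -2.0], (L, 1))
    mu_b = -mu_a
    paired = []
    for _ in range(30):
        paired.append(("A" * L, mu_a + 0.1 * rng.standard_normal((L, d))))
        paired.append(("V" * L, mu_b + 0.1 * rng.standard_normal((L, d))))
    cfg = DiffusionConfig(T=25, beta_1=1.6e-3, beta_T=0.32, hidden=48,
                          n_layers=2, steps=500, seed=1)
    model, _ = train_diffusion([z for _, z in paired], cfg)
    model, embedder, _ = fine_tune_conditional(
        model, paired, DiffusionConfig(T=25, beta_1=1.6e-3, beta_T=0.32,
                                       hidden=48, n_layers=2, steps=800,
                                       seed=2))
    ctx = sequence_condition("A" * L, embedder)
    sched = cfg.schedule()
    z = ddpm_sample(model, sched, (40, L, d), np.random.default_rng(3),
                    condition=ctx)
    z = model.destandardize(z)
    d_a = ((z - mu_a) ** 2).sum((1, 2))
    d_b = ((z - mu_b) ** 2).sum((1, 2))
    assert (d_a < d_b).mean() >= 0.9


def test_checkpoint_roundtrip(tmp_path):
    rng = np.random.default_rng(7)
    data = [rng.normal(size=(8, 4)) for _ in range(4)]
    paired = [("AVGAVGAV", z) for z in data]
    model, _ = train_diffusion(data, TINY)
    model, embedder, _ = fine_tune_conditional(model, paired, TINY, seed=1)
    path = tmp_path / "diff.npz"
    model.save(path, embedder=embedder)
    loaded, emb2 = DenoiserModel.load(path)
    ctx = sequence_condition("AVGAVGAV", emb2)
    a = model(data[0], 3, sequence_condition("AVGAVGAV", embedder)).data
    b = loaded(data[0], 3, ctx).data
    assert np.allclose(a, b)
    assert np.array_equal(loaded.latent_mean, model.latent_mean)
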