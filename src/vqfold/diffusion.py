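"""Denoising diffusion over quantized latent arrays.

A DDPM models the joint distribution of per-residue quantized latents: the
forward process adds Gaussian noise along a linear beta schedule (T = 400 by
default); the denoiser is a transformer over residue tokens with timestep
conditioning that predicts the clean latent array (x0 parameterization), so
the training objective is the MSE between the prediction and the native
latents.  Sequence conditioning enters through multi-head cross-attention
inserted after self-attention in each block; the final sampled rows can be
snapped onto the codebook before decoding.

Latents are standardized per dimension (statistics from the training set)
inside the model, so the unit-variance noise assumption of the forward
process holds regardless of the encoder's output scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import nn
from .nn import Tensor
from .vqae import LatentArray, VQAutoencoder, quantize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass
class DiffusionSchedule:
    """Linear beta schedule with cached alpha products.

    betas[t-1] is the noise variance added at step t (t = 1..T); alpha_bars
    are the cumulative products of (1 - beta).
    """

    betas: np.ndarray

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=np.float64)
        if ((self.betas <= 0) | (self.betas >= 1)).any():
            raise ValueError("betas must lie strictly in (0, 1)")
        if (np.diff(self.betas) <= 0).any():
            raise ValueError("betas must be strictly increasing")
        self.alphas = 1.0 - self.betas
        self.alpha_bars = np.cumprod(self.alphas)

    @property
    def T(self) -> int:
        return len(self.betas)

    def posterior_variance(self, t: int) -> float:
        """Var[z_{t-1} | z_t, z_0] = (1 - abar_{t-1}) / (1 - abar_t) * beta_t."""
        ab_prev = 1.0 if t == 1 else self.alpha_bars[t - 2]
        return (1.0 - ab_prev) / (1.0 - self.alpha_bars[t - 1]) * self.betas[t - 1]


def linear_schedule(T: int = 400, beta_1: float = 1e-4,
                    beta_T: float = 0.02) -> DiffusionSchedule:
    if not 0 < beta_1 < beta_T < 1:
        raise ValueError("need 0 < beta_1 < beta_T < 1")
    return DiffusionSchedule(np.linspace(beta_1, beta_T, T))


def forward_noise(z0: np.ndarray, t: int, eps: np.ndarray,
                  sched: DiffusionSchedule) -> np.ndarray:
    """z_t = sqrt(abar_t) z0 + sqrt(1 - abar_t) eps."""
    if not 1 <= t <= sched.T:
        raise ValueError(f"t must be in [1, {sched.T}]")
    z0 = np.asarray(z0)
    eps = np.asarray(eps)
    if eps.shape != z0.shape:
        raise ValueError("eps must match z0 shape")
    ab = sched.alpha_bars[t - 1]
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

@dataclass
class ConditioningContext:
    embeddings: np.ndarray          # (L, c)
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(len(self.embeddings), dtype=bool)


class SequenceEmbedder(nn.Module):
    """Interface for per-residue sequence encoders used as diffusion
    conditions; a full protein language model can be plugged in through the
    same contract."""

    dim: int

    def embed(self, seq: str) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError


_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_UNKNOWN_TOKEN = len(_AA_ALPHABET)


class ToySequenceEmbedder(SequenceEmbedder):
    """Learned per-residue-type table plus sinusoidal position encoding."""

    def __init__(self, dim: int = 32, seed: int = 0):
        self.dim = dim
        self.table = nn.Embedding(_UNKNOWN_TOKEN + 1, dim,
                                  np.random.default_rng(seed))

    def tokens(self, seq: str) -> np.ndarray:
        idx = []
        for ch in seq.upper():
            pos = _AA_ALPHABET.find(ch)
            if pos < 0:
                logger.warning("unknown amino-acid letter %r mapped to UNK", ch)
                pos = _UNKNOWN_TOKEN
            idx.append(pos)
        return np.array(idx, dtype=np.int64)

    def embed(self, seq: str) -> Tensor:
        tok = self.tokens(seq)
        pos = nn.sinusoidal_embedding(np.arange(len(tok)), self.dim)
        return self.table(tok) + Tensor(pos)


def sequence_condition(seq: str, embedder: SequenceEmbedder,
                       length: Optional[int] = None) -> ConditioningContext:
    """Deterministic conditioning context for a sequence."""
    if length is not None and len(seq) != length:
        raise ValueError(f"sequence length {len(seq)} != target length {length}")
    return ConditioningContext(embedder.embed(seq).data)


# ---------------------------------------------------------------------------
# denoiser
# ---------------------------------------------------------------------------

@dataclass
class DiffusionConfig:
    T: int = 400
    beta_1: float = 1e-4
    beta_T: float = 0.02
    hidden: int = 64
    n_layers: int = 4
    n_heads: int = 4
    cond_dim: int = 32
    cond_dropout: float = 0.1
    steps: int = 2000
    batch_size: int = 4
    learning_rate: float = 1e-3
    lr_decay: bool = True           # cosine decay to 5% over training
    max_grad_norm: float = 1.0
    seed: int = 0

    def schedule(self) -> DiffusionSchedule:
        return linear_schedule(self.T, self.beta_1, self.beta_T)


class _DiTBlock(nn.Module):
    def __init__(self, width: int, n_heads: int, rng: np.random.Generator):
        self.attn = nn.MultiHeadAttention(width, n_heads, rng)
        self.norm1 = nn.LayerNorm(width)
        self.cross: Optional[nn.MultiHeadAttention] = None
        self.norm_cross: Optional[nn.LayerNorm] = None
        self.ff = nn.MLP(width, 2 * width, width, rng)
        self.norm2 = nn.LayerNorm(width)

    def add_cross_attention(self, width: int, cond_dim: int,
                            rng: np.random.Generator) -> None:
        # small output init keeps the fine-tuning start close to the
        # unconditional function
        self.cross = nn.MultiHeadAttention(width, self.attn.n_heads, rng,
                                           kv_dim=cond_dim, out_scale=0.02)
        self.norm_cross = nn.LayerNorm(width)

    def __call__(self, x: Tensor, cond: Optional[Tensor]) -> Tensor:
        x = self.norm1(x + self.attn(x))
        if cond is not None and self.cross is not None:
            x = self.norm_cross(x + self.cross(x, kv=cond))
        x = self.norm2(x + self.ff(x))
        return x


class DenoiserModel(nn.Module):
    """Transformer over residue tokens predicting the clean latent array."""

    def __init__(self, d: int, config: DiffusionConfig = DiffusionConfig()):
        self.config = config
        self.d = d
        rng = np.random.default_rng(config.seed)
        w = config.hidden
        self.in_proj = nn.Linear(d, w, rng)
        self.time_mlp = nn.MLP(w, w, w, rng)
        self.blocks = [_DiTBlock(w, config.n_heads, rng)
                       for _ in range(config.n_layers)]
        self.out_norm = nn.LayerNorm(w)
        self.out_proj = nn.Linear(w, d, rng)
        self.latent_mean = np.zeros(d)
        self.latent_std = np.ones(d)
        self.conditional = False
        self._cross_rng_seed = config.seed + 17

    # -- conditioning -------------------------------------------------------
    def add_conditioning(self, cond_dim: Optional[int] = None) -> None:
        """Insert cross-attention after self-attention in every block."""
        if self.conditional:
            return
        cond_dim = cond_dim if cond_dim is not None else self.config.cond_dim
        rng = np.random.default_rng(self._cross_rng_seed)
        for block in self.blocks:
            block.add_cross_attention(self.config.hidden, cond_dim, rng)
        self.conditional = True

    # -- standardization ----------------------------------------------------
    def set_standardization(self, latents: Sequence[np.ndarray]) -> None:
        flat = np.concatenate([np.asarray(z) for z in latents], axis=0)
        self.latent_mean = flat.mean(0)
        self.latent_std = flat.std(0) + 1e-6

    def standardize(self, z: np.ndarray) -> np.ndarray:
        return (np.asarray(z) - self.latent_mean) / self.latent_std

    def destandardize(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z) * self.latent_std + self.latent_mean

    # -- forward ------------------------------------------------------------
    def __call__(self, z_t: Union[np.ndarray, Tensor], t: int,
                 cond: Optional[Union[ConditioningContext, Tensor]] = None
                 ) -> Tensor:
        x_in = z_t if isinstance(z_t, Tensor) else Tensor(np.asarray(z_t))
        L = x_in.shape[-2]
        w = self.config.hidden
        pos = nn.sinusoidal_embedding(np.arange(L), w)
        t_emb = self.time_mlp(Tensor(nn.sinusoidal_embedding(
            np.array([float(t)]), w)))
        cond_t: Optional[Tensor] = None
        if cond is not None:
            cond_t = cond if isinstance(cond, Tensor) else Tensor(cond.embeddings)
        x = self.in_proj(x_in) + Tensor(pos) + t_emb
        for block in self.blocks:
            x = block(x, cond_t)
        return self.out_proj(self.out_norm(x))

    # -- persistence ---------------------------------------------------------
    def save(self, path, embedder: Optional[ToySequenceEmbedder] = None) -> None:
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        if embedder is not None:
            arrays["embedder_table"] = embedder.table.table.data
        meta = {"config": asdict(self.config), "d": self.d,
                "conditional": self.conditional,
                "has_embedder": embedder is not None}
        np.savez(path, meta=json.dumps(meta),
                 latent_mean=self.latent_mean, latent_std=self.latent_std,
                 **arrays)

    @classmethod
    def load(cls, path) -> tuple["DenoiserModel", Optional[ToySequenceEmbedder]]:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            model = cls(int(meta["d"]), DiffusionConfig(**meta["config"]))
            if meta["conditional"]:
                model.add_conditioning()
            n = len(model.parameters())
            model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
            model.latent_mean = data["latent_mean"]
            model.latent_std = data["latent_std"]
            embedder = None
            if meta["has_embedder"]:
                embedder = ToySequenceEmbedder(model.config.cond_dim)
                embedder.table.table.data = data["embedder_table"]
        return model, embedder


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def diffusion_training_loss(model: DenoiserModel, z0: np.ndarray, t: int,
                            condition: Optional[ConditioningContext],
                            sched: DiffusionSchedule, eps: np.ndarray,
                            mask: Optional[np.ndarray] = None) -> Tensor:
    """Masked MSE between the denoiser output and the clean latents.

    z0 is expected in standardized latent space.
    """
    z_t = forward_noise(z0, t, eps, sched)
    pred = model(z_t, t, condition)
    diff = pred - Tensor(np.asarray(z0))
    if mask is not None:
        m = np.asarray(mask, bool)
        sq = nn.where_mask(m[..., None], diff * diff, 0.0)
        return sq.sum() * (1.0 / (m.sum() * z0.shape[-1]))
    return (diff * diff).mean()


def _as_latent_list(latents: Sequence) -> list[np.ndarray]:
    out = []
    for z in latents:
        out.append(z.values if isinstance(z, LatentArray) else np.asarray(z))
    return out


def train_diffusion(latents: Sequence, config: DiffusionConfig,
                    model: Optional[DenoiserModel] = None,
                    conditions: Optional[Sequence[ConditioningContext]] = None,
                    embedder: Optional[ToySequenceEmbedder] = None,
                    cond_dropout: Optional[float] = None,
                    seed: Optional[int] = None) -> tuple[DenoiserModel, list[dict]]:
    """Train (or resume) the denoiser; returns (model, per-step loss log).

    When `conditions` is given the model must carry cross-attention layers;
    with probability `cond_dropout` a step trains unconditionally so the model
    retains its unconditional mode.  Deterministic given the seed.
    """
    data = _as_latent_list(latents)
    if not data:
        raise ValueError("empty latent dataset")
    sched = config.schedule()
    if model is None:
        model = DenoiserModel(data[0].shape[-1], config)
        model.set_standardization(data)
    data_std = [model.standardize(z) for z in data]
    params = model.parameters()
    if embedder is not None:
        params = params + embedder.parameters()
    opt = nn.Adam(params, lr=config.learning_rate,
                  max_grad_norm=config.max_grad_norm)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    drop = config.cond_dropout if cond_dropout is None else cond_dropout
    log: list[dict] = []
    for step in range(config.steps):
        if config.lr_decay:
            f = max(0.5 * (1.0 + np.cos(np.pi * step / config.steps)), 0.05)
            opt.lr = config.learning_rate * f
        total: Optional[Tensor] = None
        any_cond = False
        for _ in range(config.batch_size):
            i = int(rng.integers(len(data_std)))
            z0 = data_std[i]
            t = int(rng.integers(1, sched.T + 1))
            eps = rng.standard_normal(z0.shape)
            cond: Optional[Union[ConditioningContext, Tensor]] = None
            if conditions is not None:
                use_cond = True
                if drop >= 1.0:
                    use_cond = False
                elif drop > 0.0:
                    use_cond = rng.random() >= drop
                if use_cond:
                    c = conditions[i]
                    cond = c.embed_tensor if hasattr(c, "embed_tensor") else c
                    any_cond = True
            loss = diffusion_training_loss(model, z0, t, cond, sched, eps)
            total = loss if total is None else total + loss
        total = total * (1.0 / config.batch_size)
        if not np.isfinite(total.data):
            raise RuntimeError(f"non-finite diffusion loss at step {step}")
        opt.zero_grad()
        total.backward()
        opt.step()
        log.append({"step": step, "loss": float(total.data),
                    "conditional": any_cond})
    return model, log


def fine_tune_conditional(model: DenoiserModel, paired_dataset: Sequence,
                          config: DiffusionConfig,
                          embedder: Optional[ToySequenceEmbedder] = None,
                          cond_dropout: Optional[float] = None,
                          seed: Optional[int] = None
                          ) -> tuple[DenoiserModel, ToySequenceEmbedder, list[dict]]:
    """Resume training with sequence conditions through cross-attention.

    `paired_dataset` holds (sequence, latent array) pairs; cross-attention
    layers (queries: latent tokens; keys/values: sequence embeddings) are
    inserted after each self-attention, and training continues on the
    conditional MSE objective with condition dropout (default from config).
    """
    if embedder is None:
        embedder = ToySequenceEmbedder(config.cond_dim, seed=config.seed + 5)
    model.add_conditioning(embedder.dim)
    seqs = [p[0] for p in paired_dataset]
    latents = _as_latent_list([p[1] for p in paired_dataset])

    class _LiveCondition:
        """Re-embeds each step so gradients reach the embedder table."""

        def __init__(self, seq: str):
            self.seq = seq

        @property
        def embed_tensor(self) -> Tensor:
            return embedder.embed(self.seq)

    conditions = [_LiveCondition(s) for s in seqs]
    model, log = train_diffusion(latents, config, model=model,
                                 conditions=conditions, embedder=embedder,
                                 cond_dropout=cond_dropout, seed=seed)
    return model, embedder, log


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    n_samples: int = 40
    length: int = 64
    seed: int = 0
    snap_to_codebook: bool = True

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


DenoiserLike = Callable[..., object]


def _denoise_to_array(model: DenoiserLike, z_t: np.ndarray, t: int,
                      cond) -> np.ndarray:
    out = model(z_t, t, cond)
    return out.data if isinstance(out, Tensor) else np.asarray(out)


def ddpm_sample(model: DenoiserLike, sched: DiffusionSchedule,
                shape: tuple, rng: np.random.Generator,
                condition: Optional[ConditioningContext] = None,
                zero_noise: bool = False,
                z_init: Optional[np.ndarray] = None) -> np.ndarray:
    """Ancestral sampling in standardized latent space.

    Starts from z_T ~ N(0, I) (or `z_init`); at each step the model predicts
    the clean array and the standard posterior over z_{t-1} is applied, with
    no noise injected at t = 1 (or anywhere when `zero_noise`, used for
    oracle-consistency checks).  Works on a single array (L, d) or a batch
    (B, L, d).
    """
    z = rng.standard_normal(shape) if z_init is None else np.array(z_init)
    for t in range(sched.T, 0, -1):
        ab_t = sched.alpha_bars[t - 1]
        ab_prev = 1.0 if t == 1 else sched.alpha_bars[t - 2]
        beta_t = sched.betas[t - 1]
        alpha_t = sched.alphas[t - 1]
        z0_hat = _denoise_to_array(model, z, t, condition)
        mean = (np.sqrt(ab_prev) * beta_t / (1.0 - ab_t)) * z0_hat \
            + (np.sqrt(alpha_t) * (1.0 - ab_prev) / (1.0 - ab_t)) * z
        if t > 1 and not zero_noise:
            sigma = np.sqrt((1.0 - ab_prev) / (1.0 - ab_t) * beta_t)
            mean = mean + sigma * rng.standard_normal(shape)
        z = mean
    return z


def sample_latents(model: DenoiserModel, cfg: SamplerConfig,
                   sched: Optional[DiffusionSchedule] = None,
                   condition: Optional[ConditioningContext] = None,
                   codebook: Optional[np.ndarray] = None) -> list[LatentArray]:
    """Draw n_samples latent arrays (physical scale, optionally codebook-snapped)."""
    sched = model.config.schedule() if sched is None else sched
    rng = np.random.default_rng(cfg.seed)
    z = ddpm_sample(model, sched, (cfg.n_samples, cfg.length, model.d), rng,
                    condition=condition)
    out = []
    for row in z:
        phys = model.destandardize(row)
        if cfg.snap_to_codebook:
            if codebook is None:
                raise ValueError("snap_to_codebook requires a codebook")
            _, snapped = quantize(phys, codebook)
            phys = snapped.values
        out.append(LatentArray(phys))
    return out


def generate_backbones(model: DenoiserModel, autoencoder: VQAutoencoder,
                       cfg: SamplerConfig,
                       sched: Optional[DiffusionSchedule] = None,
                       sequence: Optional[str] = None,
                       embedder: Optional[ToySequenceEmbedder] = None):
    """Sample -> snap to codebook -> decode; returns a ConformationEnsemble."""
    from .ensemble import ConformationEnsemble
    condition = None
    if sequence is not None:
        if embedder is None:
            raise ValueError("conditional sampling requires an embedder")
        condition = sequence_condition(sequence, embedder, cfg.length)
    latents = sample_latents(model, cfg, sched, condition,
                             codebook=autoencoder.codebook.data)
    members = [autoencoder.decode(z, sequence=sequence) for z in latents]
    provenance = {"seed": cfg.seed, "n_samples": cfg.n_samples,
                  "length": cfg.length, "snap_to_codebook": cfg.snap_to_codebook,
                  "sequence": sequence, "T": (sched.T if sched is not None
                                              else model.config.T)}
    return ConformationEnsemble(members, provenance)
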