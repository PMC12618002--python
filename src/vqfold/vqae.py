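"""Vector-quantized auto-encoder over protein backbones.

The encoder is a message-passing network over the SE(3)-invariant residue
graph producing one continuous latent vector per residue (16-D by default).
Each latent is snapped to the nearest entry of a learned codebook; the decoder
rebuilds 3-D backbone coordinates from the quantized array through
self-attention blocks with iterative coordinate updates.

Training optimizes, for a backbone x,

    L(x) = L_D(x, D(e)) + ||sg(E(x)) - e||^2 + beta * ||sg(e) - E(x)||^2

where sg is the stop-gradient operator: the middle term moves only the
codebook, the last (weighted by beta, default 0.25) only the encoder, and the
reconstruction term L_D is an SE(3)-invariant frame-aligned point error plus a
local CA-CA distance-map term.  Training has two phases: a joint phase on
short contiguous crops, then decoder-only fine-tuning on longer crops.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import nn
from .backbone import BackboneStructure, CA
from .featurize import FeatureConfig, ResidueGraph, featurize
from .geometry import build_ideal_backbone
from .nn import Tensor


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class LatentArray:
    """Per-residue continuous latents, shape (L, d)."""

    values: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(len(self.values), dtype=bool)
        if not np.isfinite(self.values).all():
            raise ValueError("latents must be finite")


@dataclass
class CodeArray:
    """Per-residue discrete codebook indices in [0, K)."""

    codes: np.ndarray
    n_codes: int
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.mask is None:
            self.mask = np.ones(len(self.codes), dtype=bool)
        if ((self.codes < 0) | (self.codes >= self.n_codes)).any():
            raise ValueError("codes out of range")


@dataclass
class VQLossTerms:
    reconstruction: float
    codebook_term: float
    commitment_term: float
    beta: float

    @property
    def total(self) -> float:
        return (self.reconstruction + self.codebook_term
                + self.beta * self.commitment_term)


@dataclass
class AutoencoderConfig:
    d: int = 16                 # latent dimension per residue
    n_codes: int = 8192         # codebook size K
    hidden: int = 48
    encoder_layers: int = 2
    decoder_layers: int = 3
    n_heads: int = 4
    decoder_positions: str = "absolute"   # "absolute" or "relative"
    crop_phase1: int = 256
    crop_phase2: int = 640
    steps_phase1: int = 2000
    steps_phase2: int = 500
    batch_size: int = 3
    learning_rate: float = 2e-3
    encoder_learning_rate: float = 5e-4
    max_grad_norm: float = 1.0
    encoder_grad_norm: float = 0.5
    lr_decay: bool = True           # cosine decay to 5% over each phase
    beta: float = 0.25
    dead_code_steps: int = 1000
    fape_clamp: float = 10.0
    fape_unclamped_fraction: float = 0.1
    distance_cutoff: float = 20.0
    distance_weight: float = 0.25
    relative_frame_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.crop_phase1 <= 0 or self.crop_phase2 <= 0:
            raise ValueError("crop sizes must be positive")
        if self.n_codes < 2:
            raise ValueError("codebook needs at least 2 vectors")


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize(z: Union[LatentArray, np.ndarray],
             codebook: np.ndarray) -> tuple[CodeArray, LatentArray]:
    """Snap each latent row to its nearest codebook row (squared L2).

    Ties resolve to the smallest index (argmin convention); the returned
    quantized array contains exact copies of the selected codebook rows.
    """
    values = z.values if isinstance(z, LatentArray) else np.asarray(z)
    codebook = np.asarray(codebook)
    if values.shape[-1] != codebook.shape[-1]:
        raise ValueError(
            f"latent dim {values.shape[-1]} != codebook dim {codebook.shape[-1]}")
    d2 = ((values[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    codes = d2.argmin(axis=1)
    return (CodeArray(codes, len(codebook)),
            LatentArray(codebook[codes].copy()))


def straight_through(z: Tensor, zq: np.ndarray) -> Tensor:
    """Forward value equals zq exactly; the gradient passes to z unchanged."""
    zq = np.asarray(zq, dtype=np.float64)

    def bw(out: Tensor) -> None:
        z._accum(out.grad)

    return Tensor._make(zq.copy(), (z,), bw)


def codebook_perplexity(codes: Union[CodeArray, np.ndarray],
                        n_codes: Optional[int] = None) -> float:
    """exp(entropy) of the empirical code distribution; in [1, K]."""
    if isinstance(codes, CodeArray):
        arr, n = codes.codes, codes.n_codes
    else:
        arr = np.asarray(codes, dtype=np.int64)
        n = int(n_codes) if n_codes is not None else int(arr.max()) + 1
    if arr.size == 0:
        raise ValueError("empty code array")
    counts = np.bincount(arr, minlength=n).astype(float)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(np.exp(-(nz * np.log(nz)).sum()))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _affine_prefix_scan(r: Tensor, d: Tensor) -> tuple[Tensor, Tensor]:
    """Inclusive prefix composition of rigid transforms.

    Input: per-element (r_i, d_i) with composition
    (A o B)(x) = d_A + R_A (d_B + R_B x).  Output index i holds
    A_0 o A_1 o ... o A_i.  Runs in log2(L) batched rounds (Hillis-Steele).
    """
    L = r.shape[0]
    t = d
    offset = 1
    while offset < L:
        head_r, head_t = r[:offset], t[:offset]
        a_r, a_t = r[:-offset], t[:-offset]
        b_r, b_t = r[offset:], t[offset:]
        new_r = a_r @ b_r
        new_t = a_t + (a_r @ b_t.reshape(-1, 3, 1)).reshape(-1, 3)
        r = nn.concat([head_r, new_r], axis=0)
        t = nn.concat([head_t, new_t], axis=0)
        offset *= 2
    return r, t


_IDEAL_GEOM_CACHE: Optional[tuple] = None


def _ideal_geometry() -> tuple:
    """Reference local geometry from an ideal helix: atom positions in the
    residue frame (4, 3), the helical inter-residue rotation (3, 3) and
    translation (3,).

    These are the biases of the decoder heads, so an untrained decoder emits
    a compact ideal helix rather than a fully extended chain.
    """
    global _IDEAL_GEOM_CACHE
    if _IDEAL_GEOM_CACHE is None:
        from .geometry import frame_arrays
        ref = build_ideal_backbone("HHHH")
        rot, trans = frame_arrays(ref)
        atoms_local = np.einsum("aj,ji->ai", ref.coords[1] - trans[1], rot[1])
        rel_rot = rot[1].T @ rot[2]
        rel_trans = (trans[2] - trans[1]) @ rot[1]
        _IDEAL_GEOM_CACHE = (atoms_local, rel_rot, rel_trans)
    return _IDEAL_GEOM_CACHE


class _MessagePassingLayer(nn.Module):
    def __init__(self, width: int, edge_dim: int, rng: np.random.Generator):
        self.msg = nn.MLP(2 * width + edge_dim, width, width, rng)
        self.norm1 = nn.LayerNorm(width)
        self.ff = nn.MLP(width, 2 * width, width, rng)
        self.norm2 = nn.LayerNorm(width)

    def __call__(self, h: Tensor, rows: np.ndarray, nbr: np.ndarray,
                 edge: Tensor) -> Tensor:
        m = self.msg(nn.concat([h[rows], h[nbr], edge], axis=-1))
        h = self.norm1(h + m.mean(axis=1))
        return self.norm2(h + self.ff(h))


class _DecoderBlock(nn.Module):
    """Self-attention over the code sequence plus a feed-forward update.

    Positions enter either absolutely (sinusoidal input encoding, added by
    the caller) or through a learned relative-position attention bias, which
    keeps the code->geometry mapping translation-equivariant along the
    sequence.
    """

    def __init__(self, width: int, n_heads: int, rng: np.random.Generator,
                 relative_positions: bool = False):
        self.attn = nn.MultiHeadAttention(
            width, n_heads, rng,
            rel_pos_clip=32 if relative_positions else None)
        self.norm1 = nn.LayerNorm(width)
        self.ff = nn.MLP(width, 2 * width, width, rng)
        self.norm2 = nn.LayerNorm(width)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        return self.norm2(x + self.ff(x))


class VQAutoencoder(nn.Module):
    """Encoder, codebook and decoder with their training losses."""

    def __init__(self, config: AutoencoderConfig = AutoencoderConfig(),
                 feature_config: FeatureConfig = FeatureConfig()):
        self.config = config
        self.feature_config = feature_config
        rng = np.random.default_rng(config.seed)
        w = config.hidden
        self.node_in = nn.Linear(feature_config.node_dim, w, rng)
        self.enc_layers = [
            _MessagePassingLayer(w, feature_config.edge_dim, rng)
            for _ in range(config.encoder_layers)]
        self.enc_out = nn.Linear(w, config.d, rng)
        self.codebook = Tensor(rng.normal(0.0, 1.0, size=(config.n_codes, config.d)),
                               requires_grad=True)
        self._codebook_initialized = False
        self.dec_in = nn.Linear(config.d, w, rng)
        rel = config.decoder_positions == "relative"
        self.dec_blocks = [_DecoderBlock(w, config.n_heads, rng,
                                         relative_positions=rel)
                           for _ in range(config.decoder_layers)]
        # per-residue geometry heads: relative frame update (rotation via
        # Gram-Schmidt of two predicted vectors, translation in the previous
        # frame) and small deviations from ideal local atom geometry
        self.rot_head = nn.Linear(w, 6, rng, scale=0.1)
        self.trans_head = nn.Linear(w, 3, rng, scale=0.1)
        self.atom_head = nn.Linear(w, 12, rng, scale=0.1)

    # -- encoder ------------------------------------------------------------
    def encode_graph(self, graph: ResidueGraph) -> Tensor:
        L, k = graph.neighbor_index.shape
        rows = np.repeat(np.arange(L), k).reshape(L, k)
        edge = Tensor(graph.edge_features)
        h = self.node_in(Tensor(graph.node_features))
        for layer in self.enc_layers:
            h = layer(h, rows, graph.neighbor_index, edge)
        return self.enc_out(h)

    def encode(self, s: BackboneStructure) -> LatentArray:
        """Per-residue latents; invariant to rigid motion of the input."""
        graph = featurize(s, self.feature_config)
        return LatentArray(self.encode_graph(graph).data)

    # -- decoder ------------------------------------------------------------
    def decode_latents(self, z: Tensor) -> Tensor:
        """Latents (L, d) -> backbone coordinates (L, 4, 3) in a canonical pose.

        Attention blocks mix the code sequence; per-residue heads then predict
        a relative rigid-frame update (rotation and translation with respect
        to the previous residue's frame) plus small deviations from ideal
        local atom geometry.  The chain of frames is composed cumulatively,
        so the network only ever works with local, near-unit-scale
        quantities.
        """
        L = z.shape[0]
        x = self.dec_in(z)
        if self.config.decoder_positions == "absolute":
            x = x + Tensor(nn.sinusoidal_embedding(np.arange(L),
                                                   self.config.hidden))
        for block in self.dec_blocks:
            x = block(x)

        # relative rotations via Gram-Schmidt around the ideal-helix bias
        ideal_atoms, helix_rot, helix_trans = _ideal_geometry()
        raw = self.rot_head(x)
        a1 = raw[:, 0:3] + Tensor(helix_rot[:, 0])
        a2 = raw[:, 3:6] + Tensor(helix_rot[:, 1])

        def _norm(v: Tensor) -> Tensor:
            return v / ((v * v).sum(axis=-1, keepdims=True) + 1e-9).sqrt()

        bx = _norm(a1)
        by = _norm(a2 - (a2 * bx).sum(axis=-1, keepdims=True) * bx)
        bz = _cross_t(bx, by)
        r_rel = nn.stack([bx, by, bz], axis=-1)          # (L, 3, 3), columns
        d_rel = self.trans_head(x) + Tensor(helix_trans)
        atoms_local = (self.atom_head(x).reshape(L, 4, 3)
                       + Tensor(ideal_atoms))

        # cumulative composition of the per-residue affine updates
        # (R_i, t_i) = (R_0..R_i, t_{i-1} + R_{i-1} d_i) via an inclusive
        # parallel prefix scan over (R, d) pairs
        first_mask = np.ones((L, 1))
        first_mask[0] = 0.0                 # residue 0 anchors the chain
        rot, trans = _affine_prefix_scan(r_rel, d_rel * Tensor(first_mask))
        return atoms_local @ rot.swapaxes(-1, -2) + trans.reshape(L, 1, 3)

    def decode(self, q: Union[LatentArray, np.ndarray],
               chain_id: str = "A",
               sequence: Optional[str] = None) -> BackboneStructure:
        """Backbone from (quantized) latents; a deterministic pure function."""
        values = q.values if isinstance(q, LatentArray) else np.asarray(q)
        coords = self.decode_latents(Tensor(values)).data
        L = len(values)
        return BackboneStructure(
            chain_ids=[chain_id] * L,
            residue_numbers=np.arange(1, L + 1),
            insertion_codes=[""] * L,
            amino_acids=list(sequence) if sequence else ["X"] * L,
            coords=coords,
            atom_mask=np.ones((L, 4), dtype=bool))

    def reconstruct(self, s: BackboneStructure) -> BackboneStructure:
        """encode -> quantize -> decode round trip."""
        z = self.encode(s)
        _, zq = quantize(z, self.codebook.data)
        return self.decode(zq, sequence=s.sequence())

    def codes(self, s: BackboneStructure) -> CodeArray:
        c, _ = quantize(self.encode(s), self.codebook.data)
        return c

    # -- parameters by component --------------------------------------------
    def decoder_parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set = set()
        for mod in [self.dec_in] + self.dec_blocks:
            mod._collect(params, seen)
        return params

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        meta = {"config": asdict(self.config),
                "feature_config": asdict(self.feature_config),
                "codebook_initialized": self._codebook_initialized}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "VQAutoencoder":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            cfg_d = meta["config"]
            fcfg_d = meta["feature_config"]
            for key in ("crop_phase1", "crop_phase2"):
                cfg_d[key] = int(cfg_d[key])
            cfg = AutoencoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in cfg_d.items()})
            fcfg = FeatureConfig(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in fcfg_d.items()})
            model = cls(cfg, fcfg)
            n = len(model.parameters())
            model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
            model._codebook_initialized = bool(meta["codebook_initialized"])
        return model


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _frames_t(coords: Tensor, eps: float = 1e-8) -> tuple[Tensor, Tensor]:
    """Differentiable Gram-Schmidt frames from (L, 4, 3) backbone coords."""
    ca = coords[:, 1, :]
    cvec = coords[:, 2, :] - ca
    nvec = coords[:, 0, :] - ca

    def normalize(v: Tensor) -> Tensor:
        return v / ((v * v).sum(axis=-1, keepdims=True) + eps).sqrt()

    x = normalize(cvec)
    y = normalize(nvec - (nvec * x).sum(axis=-1, keepdims=True) * x)
    z = _cross_t(x, y)
    return nn.stack([x, y, z], axis=-1), ca


def _cross_t(a: Tensor, b: Tensor) -> Tensor:
    ax, ay, az = a[:, 0], a[:, 1], a[:, 2]
    bx, by, bz = b[:, 0], b[:, 1], b[:, 2]
    return nn.stack([ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx],
                    axis=-1)


def _local_coords(rot: Tensor, trans: Tensor, points: Tensor) -> Tensor:
    """Points (M, 3) expressed in every frame: result (L, M, 3)."""
    L = rot.shape[0]
    M = points.shape[0]
    rel = points.reshape(1, M, 3) + (-trans.reshape(L, 1, 3))
    return rel @ rot  # (L, M, 3) @ (L, 3, 3): local = R^T-free since columns are axes

def reconstruction_loss_t(coords: Tensor, target: BackboneStructure,
                          config: AutoencoderConfig) -> Tensor:
    """Differentiable L_D: clamped FAPE (own frames each) + distance-map MSE."""
    _np = np
    mask = target.atom_mask.reshape(-1)
    rot_r, ca_r = _frames_t(coords)
    pts_r = coords.reshape(-1, 3)[np.flatnonzero(mask)]
    local_r = _local_coords(rot_r, ca_r, pts_r)

    from .geometry import frame_arrays
    rot_t, ca_t = frame_arrays(target)
    pts_t = target.coords.reshape(-1, 3)[mask]
    rel_t = pts_t[None, :, :] - ca_t[:, None, :]
    local_t = _np.einsum("lmj,lji->lmi", rel_t, rot_t)

    diff = local_r - Tensor(local_t)
    dist = ((diff * diff).sum(axis=-1) + 1e-12).sqrt()
    # a small unclamped fraction keeps a gradient on grossly misplaced (and
    # mirror-image) geometry that the clamp would otherwise silence
    u = config.fape_unclamped_fraction
    fape = (dist.clamp_max(config.fape_clamp).mean() * (1.0 - u)
            + dist.mean() * u) * (1.0 / config.fape_clamp)

    ca_rec = coords[:, 1, :]
    L = len(target)
    d_rec = _pairwise_dist_t(ca_rec, L)
    ca_tgt = target.coords[:, CA]
    d_tgt = _np.linalg.norm(ca_tgt[:, None, :] - ca_tgt[None, :, :], axis=-1)
    pair_mask = (d_tgt < config.distance_cutoff) & ~_np.eye(L, dtype=bool)
    n_pairs = max(int(pair_mask.sum()), 1)
    # per-pair squared error clamped at (5 A)^2 and normalized to [0, 1]:
    # grossly misplaced pairs must not drown the gradients of the local terms
    d_err = ((d_rec - Tensor(d_tgt)) ** 2.0).clamp_max(25.0) * (1.0 / 25.0)
    dm = (d_err * Tensor(pair_mask.astype(float))).sum() * (1.0 / n_pairs)

    # multiscale relative-frame consistency: rotation and translation of
    # residue i+sep expressed in the frame of residue i, compared at several
    # sequence separations.  SE(3)-invariant and well-conditioned; medium
    # separations suppress slow orientation drift along the chain.
    rel_terms = []
    for sep in (1, 2, 4, 8, 16):
        if sep >= L:
            break
        n = L - sep
        rel_r_rec = rot_r[:n].swapaxes(-1, -2) @ rot_r[sep:]
        step_rec = ((ca_r[sep:] - ca_r[:n]).reshape(n, 1, 3)
                    @ rot_r[:n]).reshape(n, 3)
        rel_r_tgt = _np.einsum("lji,ljk->lik", rot_t[:n], rot_t[sep:])
        step_tgt = _np.einsum("lj,lji->li", ca_t[sep:] - ca_t[:n], rot_t[:n])
        scale = 1.0 / (1.0 + 0.25 * sep)  # larger-sep translations grow in norm
        rel_terms.append((((rel_r_rec - Tensor(rel_r_tgt)) ** 2.0).mean()
                          + ((step_rec - Tensor(step_tgt)) ** 2.0).mean() * scale))
    rel = rel_terms[0]
    for term in rel_terms[1:]:
        rel = rel + term
    rel = rel * (1.0 / len(rel_terms))

    return fape + config.distance_weight * dm + config.relative_frame_weight * rel


def _pairwise_dist_t(points: Tensor, L: int) -> Tensor:
    diff = points.reshape(L, 1, 3) + (-points.reshape(1, L, 3))
    return ((diff * diff).sum(axis=-1) + 1e-12).sqrt()


def reconstruction_loss(recon: Union[BackboneStructure, np.ndarray],
                        target: BackboneStructure,
                        config: AutoencoderConfig = AutoencoderConfig()) -> float:
    """L_D between a reconstruction and its target (SE(3)-invariant)."""
    coords = recon.coords if isinstance(recon, BackboneStructure) else np.asarray(recon)
    if coords.shape[0] != len(target):
        raise ValueError("length mismatch")
    return float(reconstruction_loss_t(Tensor(coords), target, config).data)


def vq_loss(z: Tensor, model: VQAutoencoder, target: BackboneStructure,
            coords: Optional[Tensor] = None) -> tuple[Tensor, VQLossTerms, CodeArray]:
    """Full three-term objective with the stop-gradient routing.

    Returns (total loss tensor, detached term values, code assignment).
    """
    cfg = model.config
    code_arr, zq = quantize(z.data, model.codebook.data)
    zq_rows = model.codebook[code_arr.codes]          # grads flow to codebook
    codebook_term = ((Tensor(z.data) - zq_rows) ** 2.0).mean()
    commitment = ((z - Tensor(zq.values)) ** 2.0).mean()
    if coords is None:
        coords = model.decode_latents(straight_through(z, zq.values))
    recon = reconstruction_loss_t(coords, target, cfg)
    total = recon + codebook_term + cfg.beta * commitment
    terms = VQLossTerms(float(recon.data), float(codebook_term.data),
                        float(commitment.data), cfg.beta)
    return total, terms, code_arr


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _crop_sample(s: BackboneStructure, crop: int,
                 rng: np.random.Generator) -> BackboneStructure:
    if len(s) <= crop:
        return s
    start = int(rng.integers(0, len(s) - crop + 1))
    return s.crop(start, start + crop)


def train_autoencoder(dataset: Sequence, config: AutoencoderConfig,
                      feature_config: FeatureConfig = FeatureConfig()
                      ) -> tuple[VQAutoencoder, list[dict]]:
    """Two-phase training; returns the model and a per-step metric log.

    Phase 1 trains encoder, codebook and decoder on contiguous crops of
    length min(L, crop_phase1); phase 2 freezes encoder and codebook and
    trains the decoder on crops of length min(L, crop_phase2).  Dead codebook
    rows (unused for `dead_code_steps` steps) are re-seeded from a current
    encoder output.  Fully deterministic given config.seed.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    structures = [item[1] if isinstance(item, tuple) else item for item in dataset]
    model = VQAutoencoder(config, feature_config)
    rng = np.random.default_rng(config.seed + 1)
    log: list[dict] = []

    dec_ids = {id(p) for p in model.decoder_parameters()}
    encoder_params = [p for p in model.parameters()
                      if id(p) not in dec_ids and p is not model.codebook]

    def run_phase(steps: int, crop: int, phase: int) -> None:
        # the encoder moves on a shorter leash than decoder and codebook:
        # fast encoder drift makes the decoder chase moving latents
        if phase == 1:
            opts = [nn.Adam(encoder_params, lr=config.encoder_learning_rate,
                            max_grad_norm=config.encoder_grad_norm),
                    nn.Adam([model.codebook], lr=config.learning_rate,
                            max_grad_norm=config.max_grad_norm),
                    nn.Adam(model.decoder_parameters(), lr=config.learning_rate,
                            max_grad_norm=config.max_grad_norm)]
        else:
            opts = [nn.Adam(model.decoder_parameters(), lr=config.learning_rate,
                            max_grad_norm=config.max_grad_norm)]
        base_lrs = [o.lr for o in opts]
        last_used = np.zeros(config.n_codes, dtype=np.int64)
        for step in range(steps):
            if config.lr_decay:
                f = max(0.5 * (1.0 + np.cos(np.pi * step / steps)), 0.05)
                for o, lr0 in zip(opts, base_lrs):
                    o.lr = lr0 * f
            total = None
            terms = None
            codes_seen: list[np.ndarray] = []
            z_last = None
            for i in rng.integers(0, len(structures), size=config.batch_size):
                s = _crop_sample(structures[int(i)], crop, rng)
                graph = featurize(s, feature_config)
                z = model.encode_graph(graph)
                z_last = z
                if not model._codebook_initialized:
                    lat = z.data
                    mu, sd = lat.mean(0), lat.std(0) + 1e-3
                    init_rng = np.random.default_rng(config.seed + 2)
                    model.codebook.data = mu + sd * init_rng.normal(
                        size=model.codebook.data.shape)
                    model._codebook_initialized = True
                one, terms, code_arr = vq_loss(z, model, s)
                codes_seen.append(code_arr.codes)
                total = one if total is None else total + one
            total = total * (1.0 / config.batch_size)
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at phase {phase} step {step}: {terms}")
            for o in opts:
                o.zero_grad()
            total.backward()
            for o in opts:
                o.step()
            all_codes = np.concatenate(codes_seen)
            last_used[np.unique(all_codes)] = step
            if phase == 1 and step and step % 100 == 0:
                dead = np.flatnonzero(step - last_used >= config.dead_code_steps)
                if dead.size:
                    pick = rng.integers(0, len(z_last.data), size=dead.size)
                    model.codebook.data[dead] = z_last.data[pick]
                    last_used[dead] = step
            log.append({
                "phase": phase, "step": step,
                "L_D": terms.reconstruction,
                "codebook_term": terms.codebook_term,
                "commitment_term": terms.commitment_term,
                "total": float(total.data),
                "perplexity": codebook_perplexity(
                    CodeArray(all_codes, config.n_codes)),
            })

    run_phase(config.steps_phase1, config.crop_phase1, 1)
    if config.steps_phase2 > 0:
        run_phase(config.steps_phase2, config.crop_phase2, 2)
    return model, log


def log_to_csv(log: Sequence[dict], path) -> None:
    import pandas as pd
    pd.DataFrame(log).to_csv(path, index=False)
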