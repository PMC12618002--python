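"""SE(3)-invariant residue-graph featurization for the encoder.

Each residue becomes a node connected to its k nearest neighbors by CA-CA
distance.  All features are expressed in per-residue rigid frames, so any
rigid motion of the input leaves the graph numerically unchanged; this is the
property that makes the downstream latent space SE(3)-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .backbone import BackboneStructure, C, CA, N
from .geometry import frame_arrays

# virtual CB direction from ideal tetrahedral geometry (unit-vector recipe)
_CB_A, _CB_B, _CB_C = -0.58273431, 0.56802827, -0.54067466


@dataclass
class FeatureConfig:
    """Featurization hyperparameters.

    k: neighbors per residue; rbf_bins Gaussian bases span rbf_range (Angstrom)
    for CA-CA distance encoding; sequence separation is clipped at
    max_seq_sep before one-hot encoding (a dedicated class marks cross-chain
    edges).
    """

    k: int = 30
    rbf_bins: int = 16
    rbf_range: tuple = (2.0, 22.0)
    max_seq_sep: int = 32

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.rbf_range[0] <= 0 or self.rbf_range[1] <= self.rbf_range[0]:
            raise ValueError("rbf_range must be positive and increasing")

    @property
    def n_seq_sep_classes(self) -> int:
        return 2 * self.max_seq_sep + 2  # +1 for the cross-chain class

    @property
    def edge_dim(self) -> int:
        return self.n_seq_sep_classes + self.rbf_bins + 3 + 4

    @property
    def node_dim(self) -> int:
        return 9


@dataclass
class ResidueGraph:
    neighbor_index: np.ndarray   # (L, k) int
    node_features: np.ndarray    # (L, F_n)
    edge_features: np.ndarray    # (L, k, F_e)
    mask: np.ndarray             # (L,) bool

    def __post_init__(self):
        L = self.neighbor_index.shape[0]
        if ((self.neighbor_index < 0) | (self.neighbor_index >= L)).any():
            raise ValueError("neighbor indices out of range")
        if (self.neighbor_index == np.arange(L)[:, None]).any():
            raise ValueError("self-loops are not allowed")
        for arr in (self.node_features, self.edge_features):
            if not np.isfinite(arr).all():
                raise ValueError("features must be finite")


def knn_graph(s: BackboneStructure, k: int) -> np.ndarray:
    """Indices of the k nearest other residues by CA-CA distance.

    Ties are broken toward the lower residue index; k is truncated to L-1.
    """
    L = len(s)
    k = min(k, L - 1)
    d = cdist(s.ca, s.ca)
    np.fill_diagonal(d, np.inf)
    # lexsort: primary key distance, secondary key index (ascending)
    idx = np.lexsort((np.broadcast_to(np.arange(L), (L, L)), d), axis=1)
    return idx[:, :k].astype(np.int64)


def node_features(s: BackboneStructure,
                  frames: Optional[tuple] = None) -> np.ndarray:
    """Per-residue directional features in the residue's own frame.

    Unit CA->N and CA->C vectors plus the virtual-CB direction (ideal
    tetrahedral geometry), all frame-local; shape (L, 9).
    """
    rot, trans = frame_arrays(s) if frames is None else frames
    ca = s.coords[:, CA]
    to_n = s.coords[:, N] - ca
    to_c = s.coords[:, C] - ca
    a = np.cross(to_n * -1.0, to_c)  # b x c with b = CA - N
    cb_dir = _CB_A * a + _CB_B * (-to_n) + _CB_C * to_c

    def local_unit(v: np.ndarray) -> np.ndarray:
        local = np.einsum("lij,lj->li", rot.transpose(0, 2, 1), v)
        return local / np.linalg.norm(local, axis=-1, keepdims=True)

    return np.concatenate([local_unit(to_n), local_unit(to_c),
                           local_unit(cb_dir)], axis=-1)


def _rotmat_to_quat(r: np.ndarray) -> np.ndarray:
    """Batched rotation matrices -> unit quaternions with w >= 0."""
    m = r
    w = np.sqrt(np.maximum(0.0, 1.0 + m[..., 0, 0] + m[..., 1, 1] + m[..., 2, 2])) / 2
    x = np.sqrt(np.maximum(0.0, 1.0 + m[..., 0, 0] - m[..., 1, 1] - m[..., 2, 2])) / 2
    y = np.sqrt(np.maximum(0.0, 1.0 - m[..., 0, 0] + m[..., 1, 1] - m[..., 2, 2])) / 2
    z = np.sqrt(np.maximum(0.0, 1.0 - m[..., 0, 0] - m[..., 1, 1] + m[..., 2, 2])) / 2
    x = np.copysign(x, m[..., 2, 1] - m[..., 1, 2])
    y = np.copysign(y, m[..., 0, 2] - m[..., 2, 0])
    z = np.copysign(z, m[..., 1, 0] - m[..., 0, 1])
    q = np.stack([w, x, y, z], axis=-1)
    q /= np.linalg.norm(q, axis=-1, keepdims=True)
    neg = q[..., 0] < 0
    q[neg] *= -1.0
    return q


def edge_features(s: BackboneStructure, frames: tuple,
                  neighbor_index: np.ndarray,
                  cfg: FeatureConfig) -> np.ndarray:
    """Per-edge invariant features, shape (L, k, F_e).

    Blocks: one-hot signed sequence separation (clipped, with a cross-chain
    class), Gaussian RBF of the CA-CA distance, the unit CA_i->CA_j vector in
    frame i, and the relative orientation R_i^T R_j as a w>=0 quaternion.
    """
    rot, _ = frames
    L, k = neighbor_index.shape
    ca = s.coords[:, CA]
    nb = neighbor_index
    rows = np.repeat(np.arange(L), k).reshape(L, k)

    # sequence separation with chain awareness
    sep = nb - rows[:, :]
    chains = np.asarray(s.chain_ids)
    same_chain = chains[rows] == chains[nb]
    clipped = np.clip(sep, -cfg.max_seq_sep, cfg.max_seq_sep) + cfg.max_seq_sep
    cls = np.where(same_chain, clipped, cfg.n_seq_sep_classes - 1)
    onehot = np.zeros((L, k, cfg.n_seq_sep_classes))
    np.put_along_axis(onehot, cls[..., None], 1.0, axis=-1)

    # distance RBF
    diff = ca[nb] - ca[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    centers = np.linspace(cfg.rbf_range[0], cfg.rbf_range[1], cfg.rbf_bins)
    width = centers[1] - centers[0]
    rbf = np.exp(-((dist[..., None] - centers) / width) ** 2)

    # direction in frame i
    local = np.einsum("lij,lkj->lki", rot.transpose(0, 2, 1), diff)
    local /= np.maximum(np.linalg.norm(local, axis=-1, keepdims=True), 1e-9)

    # relative orientation quaternion
    rel = np.einsum("lij,lkjm->lkim", rot.transpose(0, 2, 1), rot[nb])
    quat = _rotmat_to_quat(rel)

    return np.concatenate([onehot, rbf, local, quat], axis=-1)


def featurize(s: BackboneStructure,
              cfg: FeatureConfig = FeatureConfig()) -> ResidueGraph:
    """Full invariant residue graph for a backbone."""
    frames = frame_arrays(s)
    nb = knn_graph(s, cfg.k)
    return ResidueGraph(
        neighbor_index=nb,
        node_features=node_features(s, frames),
        edge_features=edge_features(s, frames, nb, cfg),
        mask=np.ones(len(s), dtype=bool),
    )
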