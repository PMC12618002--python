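"""Conformational-ensemble statistics and multi-conformation metrics.

Given a set of same-length backbones for one sequence this module computes
the quantities used to judge conformational sampling: residue-wise RMSF
after iterative superposition, displacement profiles between alternative
structures, their Pearson correlation, ensemble TM-scores against
experimental references, mutual TM-score matrices, secondary-structure /
loop / domain composition, and seeded 2-D embeddings with density-based
cluster populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .backbone import BackboneStructure
from .geometry import (assign_secondary_structure, kabsch_superpose,
                       loop_lengths, partition_domains, tm_superpose)


@dataclass
class ConformationEnsemble:
    """Same-length backbones for one sequence, with sampling provenance."""

    members: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        L = len(self.members[0])
        if any(len(m) != L for m in self.members):
            raise ValueError("all ensemble members must have equal length")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_residues(self) -> int:
        return len(self.members[0])


def rmsf(e: ConformationEnsemble, max_iter: int = 10,
         tol: float = 1e-3) -> np.ndarray:
    """Residue-wise root-mean-square fluctuation of CA positions.

    Members are iteratively superposed onto the running mean structure using
    the TM-score-optimal transform (which anchors the alignment on the
    conformationally consistent core instead of letting a large-displacement
    segment hijack a least-squares fit); iteration stops when the mean
    structure shifts by less than `tol` Angstrom.  RMSF_i is the RMS CA
    deviation from the converged mean at residue i.
    """
    if len(e) < 2:
        raise ValueError("RMSF needs at least 2 ensemble members")
    coords = np.stack([m.ca for m in e.members])        # (n, L, 3)
    mean = coords[0].copy()
    for _ in range(max_iter):
        aligned = np.empty_like(coords)
        for i, xyz in enumerate(coords):
            _, sup = tm_superpose(xyz, mean)
            aligned[i] = sup.apply(xyz)
        new_mean = aligned.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        coords = aligned
        mean = new_mean
        if shift < tol:
            break
    dev = coords - mean
    return np.sqrt((dev ** 2).sum(-1).mean(axis=0))


def residue_displacement(a: BackboneStructure,
                         b: BackboneStructure) -> np.ndarray:
    """Per-residue backbone displacement between two structures.

    b is superposed onto a with the TM-score-optimal CA transform; the value
    at residue i is the mean deviation over its present backbone atoms.
    """
    if len(a) != len(b):
        raise ValueError("structures must have equal length")
    _, sup = tm_superpose(b.ca, a.ca)
    moved = b.coords @ sup.rotation.T + sup.translation
    d = np.linalg.norm(moved - a.coords, axis=-1)       # (L, 4)
    mask = a.atom_mask & b.atom_mask
    out = np.empty(len(a))
    for i in range(len(a)):
        out[i] = d[i][mask[i]].mean()
    return out


def rmsf_displacement_correlation(e: ConformationEnsemble,
                                  a: BackboneStructure,
                                  b: BackboneStructure) -> float:
    """Pearson correlation between ensemble RMSF and the a-vs-b displacement."""
    profile_rmsf = rmsf(e)
    profile_disp = residue_displacement(a, b)
    if np.ptp(profile_rmsf) < 1e-10 or np.ptp(profile_disp) < 1e-10:
        raise ValueError("correlation undefined for zero-variance profile")
    r, _ = stats.pearsonr(profile_rmsf, profile_disp)
    return float(r)


def tm_score_ensemble(predictions: ConformationEnsemble,
                      experimental: Sequence[BackboneStructure]) -> float:
    """Mean over references of the best TM-score achieved by any prediction.

    Each TM-score is normalized by the (experimental) reference length.
    """
    from .geometry import tm_score
    if not experimental:
        raise ValueError("need at least one experimental structure")
    best = []
    for ref in experimental:
        best.append(max(tm_score(p, ref) for p in predictions.members))
    return float(np.mean(best))


def mutual_tm(e: ConformationEnsemble) -> tuple[np.ndarray, float]:
    """All-pairs TM-score matrix (unit diagonal) and its off-diagonal median."""
    from .geometry import tm_score
    n = len(e)
    if n < 2:
        raise ValueError("mutual TM-scores need at least 2 members")
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tm_score(e.members[i], e.members[j])
    off = m[~np.eye(n, dtype=bool)]
    return m, float(np.median(off))


@dataclass
class CompositionReport:
    ss_fractions: dict                 # {"H": ..., "E": ..., "C": ...}
    loop_length_hist: dict             # {length: count}
    domain_sizes: list                 # pooled over members (L >= 40 only)


def composition_report(e: ConformationEnsemble,
                       min_domain_size: int = 40) -> CompositionReport:
    """Secondary-structure fractions, loop-length histogram and domain sizes
    aggregated over all ensemble members."""
    counts = {"H": 0, "E": 0, "C": 0}
    hist: dict = {}
    domains: list = []
    for m in e.members:
        labels = assign_secondary_structure(m)
        for ch in labels:
            counts[ch] += 1
        for ll in loop_lengths(labels):
            hist[ll] = hist.get(ll, 0) + 1
        if len(m) >= min_domain_size:
            _, sizes = partition_domains(m, min_size=min_domain_size)
            domains.extend(sizes)
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()}
    return CompositionReport(fractions, hist, domains)


@dataclass
class EmbeddingReport:
    embedding_2d: np.ndarray           # (n_members_total, 2)
    cluster_labels: np.ndarray         # -1 marks unclustered points
    populations: dict                  # cluster label -> fraction (sums to 1)
    reference_min_rmsd: np.ndarray     # per reference
    reference_nearest_member: np.ndarray
    member_ensemble_index: np.ndarray


def _ca_rmsd(a: BackboneStructure, b: BackboneStructure) -> float:
    return kabsch_superpose(a.ca, b.ca).rmsd


def embed_and_cluster(ensembles: Sequence[ConformationEnsemble],
                      references: Sequence[BackboneStructure] = (),
                      seed: int = 0,
                      cluster_eps_fraction: float = 0.5,
                      min_samples: int = 3) -> EmbeddingReport:
    """2-D stochastic-neighbor embedding of pooled conformations plus
    density-based clustering on the CA-RMSD matrix.

    The DBSCAN radius is `cluster_eps_fraction` times the median pairwise
    RMSD.  References are assigned to their nearest member; the per-reference
    minimum RMSD over all members is reported.  Deterministic given `seed`.
    """
    from sklearn.cluster import DBSCAN
    from sklearn.manifold import TSNE

    members: list = []
    member_idx: list = []
    for ei, e in enumerate(ensembles):
        members.extend(e.members)
        member_idx.extend([ei] * len(e))
    n = len(members)
    if n < 3:
        raise ValueError("need at least 3 pooled conformations")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _ca_rmsd(members[i], members[j])

    perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    emb = TSNE(n_components=2, metric="precomputed", init="random",
               random_state=seed, perplexity=perplexity).fit_transform(dist)

    eps = cluster_eps_fraction * np.median(dist[np.triu_indices(n, 1)])
    labels = DBSCAN(eps=max(eps, 1e-6), min_samples=min_samples,
                    metric="precomputed").fit_predict(dist)
    populations = {int(lab): float((labels == lab).mean())
                   for lab in np.unique(labels)}

    ref_min = np.zeros(len(references))
    ref_nearest = np.zeros(len(references), dtype=np.int64)
    for ri, ref in enumerate(references):
        d = np.array([_ca_rmsd(ref, m) for m in members])
        ref_min[ri] = d.min()
        ref_nearest[ri] = int(d.argmin())
    return EmbeddingReport(emb, labels, populations, ref_min, ref_nearest,
                           np.array(member_idx))


@dataclass
class CodebookEmbeddingReport:
    embedding_2d: np.ndarray           # (K, 2)
    mean_feature: np.ndarray           # (K,), NaN for unused codes
    used: np.ndarray                   # (K,) bool


def codebook_embedding_report(codebook: np.ndarray,
                              code_assignments: Sequence[np.ndarray],
                              feature_values: Sequence[np.ndarray],
                              seed: int = 0) -> CodebookEmbeddingReport:
    """Seeded 2-D embedding of codebook rows colored by a structural feature.

    `code_assignments` and `feature_values` are parallel per-structure arrays
    (e.g. codes and neighbor counts); each used code is annotated with the
    mean feature over the residues assigned to it.
    """
    from sklearn.manifold import TSNE
    codebook = np.asarray(codebook)
    K = len(codebook)
    codes = np.concatenate([np.asarray(c, dtype=np.int64)
                            for c in code_assignments])
    if codes.size == 0:
        raise ValueError("no code assignments given")
    feats = np.concatenate([np.asarray(f, dtype=np.float64)
                            for f in feature_values])
    if codes.shape != feats.shape:
        raise ValueError("assignments and features must be parallel")
    sums = np.bincount(codes, weights=feats, minlength=K)
    counts = np.bincount(codes, minlength=K)
    used = counts > 0
    mean_feature = np.full(K, np.nan)
    mean_feature[used] = sums[used] / counts[used]
    perplexity = min(30.0, max(2.0, (K - 1) / 3.0))
    emb = TSNE(n_components=2, init="random", random_state=seed,
               perplexity=perplexity).fit_transform(codebook)
    return CodebookEmbeddingReport(emb, mean_feature, used)


@dataclass
class EnsembleReport:
    """Aggregate report for one sampled ensemble."""

    rmsf: Optional[np.ndarray]
    mutual_tm: np.ndarray
    mutual_tm_median: float
    composition: CompositionReport

    def to_dict(self) -> dict:
        return {
            "rmsf": None if self.rmsf is None else self.rmsf.tolist(),
            "mutual_tm_median": self.mutual_tm_median,
            "ss_fractions": self.composition.ss_fractions,
            "loop_length_hist": {str(k): v for k, v
                                 in self.composition.loop_length_hist.items()},
            "domain_sizes": self.composition.domain_sizes,
        }


def ensemble_report(e: ConformationEnsemble) -> EnsembleReport:
    mt, med = mutual_tm(e)
    return EnsembleReport(rmsf(e) if len(e) >= 2 else None, mt, med,
                          composition_report(e))
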