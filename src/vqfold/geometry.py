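"""Rigid-body geometry and structural metrics for protein backbones.

Contains the deterministic geometry stack used throughout the package:
per-residue rigid frames (the local coordinate systems behind all
SE(3)-invariant features), least-squares superposition, TM-score with an
iterative fragment-seeded search, reconstruction RMSD (recRMSD),
CA-geometry secondary-structure assignment, loop and domain statistics,
contact/clash counting, and an ideal-geometry backbone builder used by the
synthetic-data generators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .backbone import ATOM_NAMES, BackboneStructure, C, CA, N, O


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rigid frames
# ---------------------------------------------------------------------------

@dataclass
class RigidFrame:
    """Orthonormal rotation (det +1) and translation; maps local -> global."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6 or abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise GeometryError("rotation must be orthonormal with det +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.translation) @ self.rotation

    def compose(self, other: "RigidFrame") -> "RigidFrame":
        return RigidFrame(self.rotation @ other.rotation,
                          self.rotation @ other.translation + self.translation)


def frame_arrays(s: BackboneStructure) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue frames by Gram-Schmidt on (N, CA, C).

    Origin at CA, x-axis along CA->C, y-axis the component of CA->N orthogonal
    to x, z = x cross y.  Returns rotations (L, 3, 3) whose columns are the
    axes, and translations (L, 3).
    """
    if not (s.atom_mask[:, N].all() and s.atom_mask[:, C].all()):
        raise GeometryError("frames require N, CA and C for every residue")
    ca = s.coords[:, CA]
    v1 = s.coords[:, C] - ca
    v2 = s.coords[:, N] - ca
    n1 = np.linalg.norm(v1, axis=-1, keepdims=True)
    if (n1 < 1e-8).any():
        raise GeometryError("zero-length CA->C vector")
    x = v1 / n1
    y = v2 - (v2 * x).sum(-1, keepdims=True) * x
    n2 = np.linalg.norm(y, axis=-1, keepdims=True)
    if (n2 < 1e-6).any():
        raise GeometryError("collinear N/CA/C: degenerate residue geometry")
    y = y / n2
    z = np.cross(x, y)
    rot = np.stack([x, y, z], axis=-1)
    return rot, ca.copy()


def build_frames(s: BackboneStructure) -> list[RigidFrame]:
    rot, trans = frame_arrays(s)
    return [RigidFrame(r, t) for r, t in zip(rot, trans)]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via normalized quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Rigid transform (applied to the mobile set) minimizing weighted RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    correspondence: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                     weights: Optional[np.ndarray] = None) -> SuperpositionResult:
    """Least-squares rigid superposition of `mobile` onto `target`.

    Reflections are disallowed (the rotation determinant is forced to +1).
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if mobile.shape != target.shape:
        raise ValueError(f"point sets differ: {mobile.shape} vs {target.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if weights is None:
        w = np.full(len(mobile), 1.0 / len(mobile))
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    mu_m = w @ mobile
    mu_t = w @ target
    a = (mobile - mu_m) * w[:, None]
    b = target - mu_t
    h = a.T @ b
    u, sv, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_t - rot @ mu_m
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(-1).mean()))
    return SuperpositionResult(rot, trans, rmsd, np.arange(len(mobile)))


def _tm_d0(length: int) -> float:
    if length > 21:
        return 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8
    return 0.5  # floor for short chains where the cubic-root formula degenerates


def _tm_from_transform(mobile: np.ndarray, target: np.ndarray, rot, trans,
                       d0: float) -> float:
    d = np.linalg.norm(mobile @ rot.T + trans - target, axis=-1)
    return float((1.0 / (1.0 + (d / d0) ** 2)).mean())


def tm_superpose(mobile_ca: np.ndarray, target_ca: np.ndarray
                 ) -> tuple[float, SuperpositionResult]:
    """TM-score-optimizing superposition under sequential correspondence.

    Seeds come from sliding fragments of lengths L, L/2 and L/4; each seed is
    refined by iterative reweighted superposition keeping residue pairs with
    d_i < d0 (threshold relaxed when too few pairs survive), at most 20
    iterations.  Returns (TM-score normalized by the target length, transform).
    """
    mobile_ca = np.asarray(mobile_ca, dtype=np.float64)
    target_ca = np.asarray(target_ca, dtype=np.float64)
    if mobile_ca.shape != target_ca.shape:
        raise ValueError("TM-score requires equal-length CA traces")
    L = len(mobile_ca)
    d0 = _tm_d0(L)
    best_score = -1.0
    best: Optional[SuperpositionResult] = None
    frag_lengths = sorted({L, max(L // 2, 4), max(L // 4, 4)}, reverse=True)
    for fl in frag_lengths:
        step = max(fl // 2, 1)
        for start in range(0, L - fl + 1, step):
            sel = np.zeros(L, dtype=bool)
            sel[start:start + fl] = True
            for _ in range(20):
                sup = kabsch_superpose(mobile_ca[sel], target_ca[sel])
                d = np.linalg.norm(mobile_ca @ sup.rotation.T + sup.translation
                                   - target_ca, axis=-1)
                cut = d0
                new_sel = d < cut
                while new_sel.sum() < 3:
                    cut *= 1.5
                    new_sel = d < cut
                score = float((1.0 / (1.0 + (d / d0) ** 2)).mean())
                if score > best_score:
                    best_score = score
                    best = SuperpositionResult(sup.rotation, sup.translation,
                                               float(np.sqrt((d ** 2).mean())),
                                               np.flatnonzero(new_sel))
                if new_sel.sum() == sel.sum() and (new_sel == sel).all():
                    break
                sel = new_sel
    assert best is not None
    return best_score, best


def tm_score(a: BackboneStructure, b: BackboneStructure) -> float:
    """TM-score between same-length backbones, normalized by the target (b).

    Uses sequential residue correspondence; values in (0, 1], > 0.5 indicates
    the same fold.
    """
    if len(a) != len(b):
        raise ValueError("tm_score requires equal-length structures")
    score, _ = tm_superpose(a.ca, b.ca)
    return score


def rec_rmsd(original: BackboneStructure,
             reconstruction: BackboneStructure) -> float:
    """RMSD of backbone atoms after TM-score-optimal CA superposition.

    The reconstruction is superposed onto the original using the transform
    that maximizes the CA TM-score; the RMSD is then taken over all backbone
    atoms present in both structures.
    """
    if len(original) != len(reconstruction):
        raise ValueError("rec_rmsd requires equal-length structures")
    _, sup = tm_superpose(reconstruction.ca, original.ca)
    mask = original.atom_mask & reconstruction.atom_mask
    moved = reconstruction.coords @ sup.rotation.T + sup.translation
    diff = moved[mask] - original.coords[mask]
    return float(np.sqrt((diff ** 2).sum(-1).mean()))


# ---------------------------------------------------------------------------
# secondary structure (CA-geometry rules) and derived statistics
# ---------------------------------------------------------------------------

@dataclass
class SecondaryStructureConfig:
    """Threshold ranges for the CA-only assignment rules (Angstrom, degrees)."""

    helix_d13: tuple = (4.5, 5.9)      # CA(i)-CA(i+3) distance
    helix_tau: tuple = (25.0, 80.0)    # CA pseudo-dihedral i..i+3
    strand_d02: tuple = (5.7, 7.3)     # CA(i)-CA(i+2) distance
    strand_tau_abs: tuple = (150.0, 180.0)


def _pseudo_dihedral(p0, p1, p2, p3) -> np.ndarray:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = (n1 * n2).sum(-1)
    y = (m1 * n2).sum(-1)
    return np.degrees(np.arctan2(-y, x))


def assign_secondary_structure(
        s: BackboneStructure,
        config: SecondaryStructureConfig = SecondaryStructureConfig()) -> str:
    """Per-residue H/E/C labels from CA geometry alone (P-SEA style).

    A window of four consecutive CA atoms votes helix when its i..i+3 distance
    and pseudo-dihedral fall in helical ranges (two consecutive windows, i.e. a
    5-residue stretch, are required); extended windows vote strand; everything
    else is coil.  Chains shorter than 5 residues are all coil.
    """
    L = len(s)
    labels = np.full(L, "C", dtype="U1")
    if L < 5:
        return "".join(labels)
    ca = s.ca
    d13 = np.linalg.norm(ca[3:] - ca[:-3], axis=-1)          # window i..i+3
    d02 = np.linalg.norm(ca[2:] - ca[:-2], axis=-1)          # i..i+2
    tau = _pseudo_dihedral(ca[:-3], ca[1:-2], ca[2:-1], ca[3:])
    hel = ((config.helix_d13[0] <= d13) & (d13 <= config.helix_d13[1]) &
           (config.helix_tau[0] <= tau) & (tau <= config.helix_tau[1]))
    ext = ((config.strand_d02[0] <= d02[:-1]) & (d02[:-1] <= config.strand_d02[1]) &
           (config.strand_d02[0] <= d02[1:]) & (d02[1:] <= config.strand_d02[1]) &
           (np.abs(tau) >= config.strand_tau_abs[0]) &
           (np.abs(tau) <= config.strand_tau_abs[1]))
    # two consecutive agreeing windows cover a 5-residue stretch
    for i in np.flatnonzero(ext[:-1] & ext[1:]):
        labels[i:i + 5] = "E"
    for i in np.flatnonzero(hel[:-1] & hel[1:]):
        labels[i:i + 5] = "H"
    return "".join(labels)


def loop_lengths(labels: str) -> list[int]:
    """Lengths of maximal coil (C) runs, terminal runs included."""
    out: list[int] = []
    run = 0
    for ch in labels:
        if ch == "C":
            run += 1
        else:
            if run:
                out.append(run)
            run = 0
    if run:
        out.append(run)
    return out


def neighbor_count(s: BackboneStructure, cutoff: float = 15.0) -> np.ndarray:
    """Number of other residues with CA-CA distance below `cutoff` Angstrom."""
    d = cdist(s.ca, s.ca)
    counts = (d < cutoff).sum(axis=1) - 1  # remove self
    return counts.astype(np.int64)


def count_clashes(s: BackboneStructure, cutoff: float = 2.5) -> float:
    """Steric clashes per residue among non-bonded backbone atoms.

    Counts pairs of present backbone atoms from residues at sequence
    separation >= 2 that lie closer than `cutoff` Angstrom, divided by L.
    """
    idx_res, idx_atom = np.nonzero(s.atom_mask)
    pts = s.coords[idx_res, idx_atom]
    d = cdist(pts, pts)
    sep = np.abs(idx_res[:, None] - idx_res[None, :])
    close = (d < cutoff) & (sep >= 2)
    return float(np.triu(close, k=1).sum()) / len(s)


def partition_domains(s: BackboneStructure, contact_cutoff: float = 8.0,
                      min_size: int = 40) -> tuple[np.ndarray, list[int]]:
    """Structural domains by recursive spectral bipartition of the CA contact
    graph.

    The CA contact graph (distance < `contact_cutoff`) is split along the
    Fiedler vector; a split is accepted while it improves Newman contact-graph
    modularity and leaves every part with at least `min_size` residues.
    Returns (per-residue integer labels, domain sizes ordered by label).
    """
    L = len(s)
    if L < min_size:
        raise ValueError(f"domain partition requires at least {min_size} residues")
    adj = (cdist(s.ca, s.ca) < contact_cutoff).astype(float)
    np.fill_diagonal(adj, 0.0)
    deg = adj.sum(1)
    two_m = deg.sum()

    def modularity(labels: np.ndarray) -> float:
        q = 0.0
        for lab in np.unique(labels):
            m = labels == lab
            q += adj[np.ix_(m, m)].sum() / two_m - (deg[m].sum() / two_m) ** 2
        return q

    labels = np.zeros(L, dtype=np.int64)
    improved = True
    while improved:
        improved = False
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            if len(members) < 2 * min_size:
                continue
            sub = adj[np.ix_(members, members)]
            lap = np.diag(sub.sum(1)) - sub
            vals, vecs = np.linalg.eigh(lap)
            fiedler = vecs[:, 1]
            part = fiedler >= np.median(fiedler)
            if part.sum() < min_size or (~part).sum() < min_size:
                continue
            trial = labels.copy()
            trial[members[part]] = labels.max() + 1
            if modularity(trial) > modularity(labels) + 1e-9:
                labels = trial
                improved = True
    # relabel compactly in order of first occurrence
    _, labels = np.unique(labels, return_inverse=True)
    order = {}
    remap = np.empty_like(labels)
    nxt = 0
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = nxt
            nxt += 1
        remap[i] = order[lab]
    sizes = [int((remap == k).sum()) for k in range(remap.max() + 1)]
    return remap, sizes


# ---------------------------------------------------------------------------
# ideal-geometry backbone construction
# ---------------------------------------------------------------------------

# ideal peptide geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

DEFAULT_TORSIONS: Mapping[str, tuple] = {
    "H": (-57.0, -47.0),
    "E": (-120.0, 120.0),
}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d given chain a-b-c and internal coordinates."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_backbone(ss: str,
                         torsion_table: Optional[Mapping[str, tuple]] = None,
                         rng: Optional[np.random.Generator] = None,
                         chain_id: str = "A") -> BackboneStructure:
    """Build a backbone with ideal bond geometry from an H/E/C string.

    Helical and strand residues use fixed (phi, psi) pairs from
    `torsion_table`; coil residues draw both torsions uniformly from
    (-180, 180] using `rng` (seeded default).  Carbonyl oxygens are placed in
    the peptide plane from psi.
    """
    if not ss:
        raise ValueError("secondary-structure string must be non-empty")
    table = dict(DEFAULT_TORSIONS)
    if torsion_table:
        table.update(torsion_table)
    if rng is None:
        rng = np.random.default_rng(0)
    L = len(ss)
    phi = np.zeros(L)
    psi = np.zeros(L)
    for i, lab in enumerate(ss):
        if lab == "C":
            phi[i] = rng.uniform(-180.0, 180.0)
            psi[i] = rng.uniform(-180.0, 180.0)
        elif lab in table:
            phi[i], psi[i] = table[lab]
        else:
            raise ValueError(f"unknown secondary-structure label {lab!r}")

    coords = np.zeros((L, 4, 3))
    # first residue in a canonical pose
    coords[0, N] = (0.0, 0.0, 0.0)
    coords[0, CA] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(ANGLE_N_CA_C)
    coords[0, C] = coords[0, CA] + BOND_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0])
    for i in range(L - 1):
        coords[i + 1, N] = _place_atom(coords[i, N], coords[i, CA], coords[i, C],
                                       BOND_C_N, ANGLE_CA_C_N, psi[i])
        coords[i + 1, CA] = _place_atom(coords[i, CA], coords[i, C],
                                        coords[i + 1, N],
                                        BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        coords[i + 1, C] = _place_atom(coords[i, C], coords[i + 1, N],
                                       coords[i + 1, CA],
                                       BOND_CA_C, ANGLE_N_CA_C, phi[i + 1])
    for i in range(L):
        coords[i, O] = _place_atom(coords[i, N], coords[i, CA], coords[i, C],
                                   BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)

    if L == 1:
        raise ValueError("backbone must have at least 2 residues")
    return BackboneStructure(
        chain_ids=[chain_id] * L,
        residue_numbers=np.arange(1, L + 1),
        insertion_codes=[""] * L,
        amino_acids=["X"] * L,
        coords=coords,
        atom_mask=np.ones((L, 4), dtype=bool),
    )
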