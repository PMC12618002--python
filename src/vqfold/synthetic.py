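"""Synthetic toy backbones with known ground truth.

These generators stand in for curated structure databases at desk scale:
secondary-structure strings drawn from a run-length grammar are realized as
ideal-geometry backbones with Gaussian coordinate jitter, and a two-state
hinge construction provides conformational ensembles whose residue-wise
displacement profile is known exactly.  Every generator is a pure function of
its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .backbone import BackboneStructure
from .geometry import build_ideal_backbone

# fixed secondary-structure -> amino-acid code giving the conditional model a
# learnable sequence->structure signal
SS_TO_AA = {"H": "A", "E": "V", "C": "G"}
AA_LETTERS = tuple(SS_TO_AA.values())


@dataclass
class ToyDatasetConfig:
    n_structures: int = 50
    length_range: tuple = (40, 64)
    run_mean_h: float = 8.0
    run_mean_e: float = 5.0
    run_mean_c: float = 4.0
    jitter_sigma: float = 0.2
    sequence_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.length_range[0] < 20:
            raise ValueError("toy backbones must be at least 20 residues")
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be non-negative")
        if not 0.0 <= self.sequence_noise_rate <= 1.0:
            raise ValueError("sequence noise rate must be in [0, 1]")

    @property
    def run_means(self) -> dict:
        return {"H": self.run_mean_h, "E": self.run_mean_e, "C": self.run_mean_c}


def sample_ss_string(cfg: ToyDatasetConfig, length: int,
                     rng: np.random.Generator) -> str:
    """H/E/C string of `length` with geometric run lengths of configured means."""
    states = "HEC"
    means = cfg.run_means
    out: list[str] = []
    state = states[rng.integers(3)]
    while len(out) < length:
        run = rng.geometric(1.0 / means[state])
        out.extend(state * run)
        state = states[(states.index(state) + 1 + rng.integers(2)) % 3]
    return "".join(out[:length])


def build_toy_backbone(ss: str, sigma: float,
                       rng: np.random.Generator) -> BackboneStructure:
    """Ideal-geometry build of `ss` plus i.i.d. Gaussian jitter on all atoms."""
    s = build_ideal_backbone(ss, rng=rng)
    if sigma > 0:
        s = s.with_coords(s.coords + rng.normal(0.0, sigma, size=s.coords.shape))
    return s


def sequence_from_ss(ss: str, noise_rate: float,
                     rng: np.random.Generator) -> str:
    """A/V/G sequence read off the secondary structure, with mislabeling."""
    seq = []
    for lab in ss:
        aa = SS_TO_AA[lab]
        if noise_rate > 0 and rng.random() < noise_rate:
            aa = rng.choice([a for a in AA_LETTERS if a != aa])
        seq.append(aa)
    return "".join(seq)


def make_toy_dataset(cfg: ToyDatasetConfig) -> list:
    """List of (sequence, BackboneStructure) pairs drawn from the grammar."""
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(cfg.n_structures):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        ss = sample_ss_string(cfg, length, rng)
        s = build_toy_backbone(ss, cfg.jitter_sigma, rng)
        seq = sequence_from_ss(ss, cfg.sequence_noise_rate, rng)
        s = BackboneStructure(s.chain_ids, s.residue_numbers, s.insertion_codes,
                              list(seq), s.coords, s.atom_mask)
        out.append((seq, s))
    return out


@dataclass
class TwoStateDataset:
    """Hinge-motion ensemble with exactly known displacement ground truth."""

    sequence: str
    state_a: BackboneStructure      # noise-free template, base conformation
    state_b: BackboneStructure      # template with rotated C-terminal segment
    members: list                   # jittered copies: list of BackboneStructure
    state_labels: np.ndarray        # 0 = state A, 1 = state B, per member
    displacement: np.ndarray        # per-residue CA displacement A vs B (Angstrom)
    hinge_position: int
    hinge_angle: float

    def pairs(self) -> list:
        return [(self.sequence, m) for m in self.members]


def make_two_state_dataset(base_ss: str, hinge_position: int,
                           hinge_angle: float, n_per_state: int,
                           rng: np.random.Generator,
                           jitter_sigma: float = 0.2) -> TwoStateDataset:
    """Two rigid conformations related by a hinge rotation, plus jittered copies.

    State A is the ideal build of `base_ss`; state B rotates every atom of the
    residues at and beyond `hinge_position` by `hinge_angle` degrees about an
    axis through the hinge CA.  Both states share one sequence.  The returned
    displacement profile is the per-residue CA distance between the two
    templates (zero before the hinge by construction).
    """
    L = len(base_ss)
    if not 0 < hinge_position < L - 1:
        raise ValueError("hinge position must be interior")
    if not 0.0 <= hinge_angle < 180.0:
        raise ValueError("hinge angle must be in [0, 180) degrees")
    state_a = build_ideal_backbone(base_ss, rng=np.random.default_rng(
        int(rng.integers(2 ** 31))))
    # rotation axis: local z-axis of the hinge residue, through its CA
    from .geometry import frame_arrays  # local import avoids cycle at module load
    rot_frames, trans = frame_arrays(state_a)
    axis = rot_frames[hinge_position][:, 2]
    pivot = trans[hinge_position]
    theta = np.radians(hinge_angle)
    kx, ky, kz = axis
    k_cross = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    rot = (np.eye(3) + np.sin(theta) * k_cross
           + (1 - np.cos(theta)) * (k_cross @ k_cross))
    coords_b = state_a.coords.copy()
    seg = slice(hinge_position, L)
    coords_b[seg] = (coords_b[seg] - pivot) @ rot.T + pivot
    state_b = state_a.with_coords(coords_b)

    displacement = np.linalg.norm(state_b.ca - state_a.ca, axis=-1)
    sequence = "".join(SS_TO_AA[lab] for lab in base_ss)

    members: list = []
    labels: list = []
    for template, lab in ((state_a, 0), (state_b, 1)):
        for _ in range(n_per_state):
            jittered = template.with_coords(
                template.coords + rng.normal(0.0, jitter_sigma,
                                             size=template.coords.shape))
            members.append(jittered)
            labels.append(lab)
    return TwoStateDataset(sequence, state_a, state_b, members,
                           np.array(labels), displacement,
                           hinge_position, hinge_angle)
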