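"""Frames, superposition, TM-score, recRMSD, secondary structure, domains."""

import numpy as np
import pytest

from vqfold.backbone import BackboneStructure
from vqfold.geometry import (GeometryError, assign_secondary_structure,
                             build_frames, build_ideal_backbone, count_clashes,
                             frame_arrays, kabsch_superpose, loop_lengths,
                             neighbor_count, partition_domains, random_rotation,
                             rec_rmsd, tm_score, tm_superpose)
from conftest import rigid_copy


def _structure_from_ca(ca, rng=None):
    """Wrap CA positions into a backbone with plausible N/C placement."""
    L = len(ca)
    coords = np.zeros((L, 4, 3))
    coords[:, 1] = ca
    coords[:, 0] = ca + [-1.0, 0.5, 0.0]
    coords[:, 2] = ca + [1.0, 0.5, 0.0]
    coords[:, 3] = ca + [1.2, 1.5, 0.0]
    return BackboneStructure(["A"] * L, np.arange(1, L + 1), [""] * L,
                             ["X"] * L, coords, np.ones((L, 4), bool))


# -- frames -----------------------------------------------------------------

def test_frame_of_canonical_residue_is_identity():
    coords = np.zeros((2, 4, 3))
    coords[0, 1] = (0, 0, 0)            # CA at origin
    coords[0, 2] = (1.5, 0, 0)          # C on +x
    coords[0, 0] = (-0.5, 1.3, 0)       # N in the xy-plane, +y side
    coords[0, 3] = (2, 1, 0)
    coords[1] = coords[0] + 5.0
    s = BackboneStructure(["A", "A"], [1, 2], ["", ""], ["X", "X"],
                          coords, np.ones((2, 4), bool))
    frames = build_frames(s)
    assert np.allclose(frames[0].rotation, np.eye(3), atol=1e-12)
    assert np.allclose(frames[0].translation, 0.0)


def test_frames_are_equivariant_under_global_rotation(helix20, rng):
    rot_before, _ = frame_arrays(helix20)
    moved, rot, trans = rigid_copy(helix20, rng)
    rot_after, _ = frame_arrays(moved)
    assert np.allclose(rot_after, rot @ rot_before, atol=1e-9)


def test_frame_inverse_maps_own_atoms_to_canonical_pose(toy_fold):
    frames = build_frames(toy_fold)
    for i in (0, 5, len(toy_fold) - 1):
        f = frames[i]
        local = f.inverse_apply(toy_fold.coords[i, :3])
        assert np.allclose(local[1], 0.0, atol=1e-9)          # CA at origin
        assert np.allclose(local[2][1:], 0.0, atol=1e-9)      # C on +x
        assert local[2][0] > 0


def test_degenerate_collinear_residue_raises():
    coords = np.zeros((2, 4, 3))
    coords[0, 0] = (-1, 0, 0)
    coords[0, 2] = (1, 0, 0)            # N, CA, C collinear
    coords[1] = coords[0] + 4.0
    s = BackboneStructure(["A", "A"], [1, 2], ["", ""], ["X", "X"],
                          coords, np.ones((2, 4), bool))
    with pytest.raises(GeometryError):
        build_frames(s)


# -- superposition ----------------------------------------------------------

def test_kabsch_identity_and_rigid_recovery(rng):
    pts = rng.normal(size=(8, 3)) * 5
    res = kabsch_superpose(pts, pts)
    assert res.rmsd < 1e-10
    assert np.allclose(res.rotation, np.eye(3), atol=1e-8)
    rot = random_rotation(rng)
    moved = pts @ rot.T + [3.0, -2.0, 7.0]
    res = kabsch_superpose(pts, moved)
    assert res.rmsd < 1e-10
    assert np.allclose(res.apply(pts), moved, atol=1e-8)


def _small_rotation(axis_sample, angle):
    axis = axis_sample / np.linalg.norm(axis_sample)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _brute_force_min_rmsd(mobile, target, seed=5):
    """Rotation-search oracle: coarse random sampling followed by shrinking
    local perturbations; independent of the SVD route."""
    rng = np.random.default_rng(seed)
    mc = mobile - mobile.mean(0)
    tc = target - target.mean(0)

    def rmsd_of(rot):
        return np.sqrt((((mc @ rot.T) - tc) ** 2).sum(-1).mean())

    best_rot = np.eye(3)
    best = rmsd_of(best_rot)
    for _ in range(4000):
        rot = random_rotation(rng)
        r = rmsd_of(rot)
        if r < best:
            best, best_rot = r, rot
    angle = 0.2
    while angle > 1e-6:
        improved = False
        for _ in range(200):
            rot = _small_rotation(rng.normal(size=3), angle) @ best_rot
            r = rmsd_of(rot)
            if r < best:
                best, best_rot = r, rot
                improved = True
        if not improved:
            angle *= 0.5
    return best


def test_kabsch_matches_random_rotation_search(rng):
    pts = rng.normal(size=(4, 3)) * 3
    noisy = pts + rng.normal(scale=0.5, size=pts.shape)
    exact = kabsch_superpose(pts, noisy).rmsd
    brute = _brute_force_min_rmsd(pts, noisy)
    assert exact <= brute + 1e-9          # Kabsch is the true minimum
    assert brute - exact < 1e-4           # oracle converges onto it


def test_kabsch_rejects_mismatched_sets(rng):
    with pytest.raises(ValueError):
        kabsch_superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


def test_kabsch_never_reflects(rng):
    pts = rng.normal(size=(6, 3))
    mirrored = pts * [-1.0, 1.0, 1.0]
    res = kabsch_superpose(pts, mirrored)
    assert np.linalg.det(res.rotation) > 0.99
    assert res.rmsd > 0.1


# -- TM-score and recRMSD ---------------------------------------------------

def test_tm_score_identical_structures_is_one(toy_fold):
    assert tm_score(toy_fold, toy_fold) == pytest.approx(1.0, abs=1e-9)


def test_tm_score_invariant_and_symmetric(toy_fold, rng):
    moved, _, _ = rigid_copy(toy_fold, rng)
    other = toy_fold.with_coords(
        toy_fold.coords + rng.normal(scale=1.0, size=toy_fold.coords.shape))
    assert tm_score(moved, other) == pytest.approx(
        tm_score(toy_fold, other), abs=1e-5)
    assert tm_score(toy_fold, other) == pytest.approx(
        tm_score(other, toy_fold), abs=0.02)


def test_tm_score_decreases_with_noise(rng):
    base = build_ideal_backbone("H" * 30)
    scores = []
    for sigma in (0.0, 1.0, 2.0, 4.0):
        noisy = base.with_coords(
            base.coords + rng.normal(scale=sigma, size=base.coords.shape))
        scores.append(tm_score(noisy, base))
    assert scores[0] == pytest.approx(1.0, abs=1e-9)
    assert all(a >= b - 0.02 for a, b in zip(scores, scores[1:]))
    assert scores[-1] < scores[0] - 0.2


def test_tm_score_requires_equal_length(helix20):
    with pytest.raises(ValueError):
        tm_score(helix20, build_ideal_backbone("H" * 19))


def test_rec_rmsd_zero_for_identity_and_rigid_motion(toy_fold, rng):
    assert rec_rmsd(toy_fold, toy_fold) < 1e-10
    moved, _, _ = rigid_copy(toy_fold, rng)
    assert rec_rmsd(toy_fold, moved) < 1e-6


def test_rec_rmsd_matches_isotropic_noise_level():
    """recRMSD of structure vs noisy copy approaches sigma*sqrt(3)."""
    rng = np.random.default_rng(42)
    base = build_ideal_backbone("H" * 40 + "E" * 30 + "H" * 30,
                                rng=np.random.default_rng(0))
    sigma = 1.0
    vals = []
    for _ in range(5):
        noisy = base.with_coords(
            base.coords + rng.normal(scale=sigma, size=base.coords.shape))
        vals.append(rec_rmsd(base, noisy))
    expected = sigma * np.sqrt(3.0)
    assert np.mean(vals) == pytest.approx(expected, rel=0.06)


# -- secondary structure ----------------------------------------------------

def test_ideal_helix_mostly_helix(helix20):
    labels = assign_secondary_structure(helix20)
    assert labels.count("H") >= 16


def test_ideal_strand_mostly_strand(strand20):
    labels = assign_secondary_structure(strand20)
    assert labels.count("E") >= 14


def test_random_coil_mostly_coil():
    n_c = n_tot = 0
    for seed in range(5):
        s = build_ideal_backbone("C" * 40, rng=np.random.default_rng(seed))
        labels = assign_secondary_structure(s)
        n_c += labels.count("C")
        n_tot += 40
    assert n_c / n_tot > 0.6


def test_short_chain_is_all_coil():
    s = build_ideal_backbone("HHHH")
    assert assign_secondary_structure(s) == "CCCC"


def test_ss_assignment_agrees_with_independent_psea(toy_fold):
    """Cross-check against biotite's P-SEA implementation (majority vote)."""
    biotite_struct = pytest.importorskip("biotite.structure")
    import biotite.structure as struc
    atoms = struc.AtomArray(len(toy_fold))
    atoms.coord = toy_fold.ca.astype(np.float32)
    atoms.atom_name = np.array(["CA"] * len(toy_fold))
    atoms.res_name = np.array(["ALA"] * len(toy_fold))
    atoms.res_id = np.arange(1, len(toy_fold) + 1)
    atoms.chain_id = np.array(["A"] * len(toy_fold))
    atoms.element = np.array(["C"] * len(toy_fold))
    ref = struc.annotate_sse(atoms)
    ref = "".join({"a": "H", "b": "E", "c": "C"}[x] for x in ref)
    mine = assign_secondary_structure(toy_fold)
    agreement = np.mean([a == b for a, b in zip(mine, ref)])
    # run-boundary conventions differ between CA-only methods; the bulk of
    # the assignment must agree
    assert agreement > 0.65


@pytest.mark.parametrize("labels,expected", [
    ("HHHHCCCHHH", [3]),
    ("CCCCCCC", [7]),
    ("CCHHHECC", [2, 2]),
    ("HHHH", []),
    ("CHC", [1, 1]),
])
def test_loop_lengths(labels, expected):
    assert loop_lengths(labels) == expected


# -- neighbors, clashes, domains --------------------------------------------

def test_neighbor_count_examples():
    ca = np.array([[0, 0, 0], [20, 0, 0]], float)
    s = _structure_from_ca(ca)
    assert neighbor_count(s, 15.0).tolist() == [0, 0]
    ca = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0]], float)
    s = _structure_from_ca(ca)
    assert neighbor_count(s, 15.0).tolist() == [1, 2, 1]


def test_neighbor_count_matches_brute_force(toy_fold):
    counts = neighbor_count(toy_fold, 15.0)
    ca = toy_fold.ca
    for i in range(len(toy_fold)):
        ref = sum(1 for j in range(len(toy_fold))
                  if j != i and np.linalg.norm(ca[i] - ca[j]) < 15.0)
        assert counts[i] == ref


def test_clashes_zero_on_ideal_helix(helix20):
    assert count_clashes(helix20) == 0.0


def test_clashes_detect_overlapping_atoms(helix20):
    doubled = BackboneStructure(
        ["A"] * 40, np.arange(1, 41), [""] * 40, ["X"] * 40,
        np.concatenate([helix20.coords, helix20.coords]),
        np.ones((40, 4), bool))
    assert count_clashes(doubled) > 0


def test_clashes_match_brute_force(toy_fold):
    cutoff = 3.0
    fast = count_clashes(toy_fold, cutoff)
    n = 0
    flat = [(i, toy_fold.coords[i, a]) for i in range(len(toy_fold))
            for a in range(4)]
    for x in range(len(flat)):
        for y in range(x + 1, len(flat)):
            if abs(flat[x][0] - flat[y][0]) >= 2 and \
                    np.linalg.norm(flat[x][1] - flat[y][1]) < cutoff:
                n += 1
    assert fast == pytest.approx(n / len(toy_fold))


def _globule(rng, n, center):
    from scipy.spatial.distance import pdist
    pts = center + rng.normal(scale=6.0, size=(n, 3))
    return pts


def test_domains_single_globule_is_one_domain(rng):
    s = _structure_from_ca(_globule(rng, 60, np.zeros(3)))
    labels, sizes = partition_domains(s)
    assert sizes == [60]
    assert sum(sizes) == len(s)


def test_domains_two_globules_with_linker(rng):
    a = _globule(rng, 55, np.zeros(3))
    linker = np.linspace([8, 0, 0], [42, 0, 0], 10)
    b = _globule(rng, 55, np.array([50.0, 0, 0]))
    s = _structure_from_ca(np.concatenate([a, linker, b]))
    labels, sizes = partition_domains(s)
    assert len(sizes) == 2
    assert sum(sizes) == len(s)
    assert abs(sizes[0] - 60) <= 5 and abs(sizes[1] - 60) <= 5


# -- ideal builder ----------------------------------------------------------

def test_ideal_helix_rise():
    s = build_ideal_backbone("H" * 20)
    ca = s.ca - s.ca.mean(0)
    axis = np.linalg.svd(ca, full_matrices=False)[2][0]
    rise = np.abs(np.diff(ca @ axis)).mean()
    assert rise == pytest.approx(1.5, abs=0.1)


def test_ideal_builder_bond_lengths_and_length():
    s = build_ideal_backbone("HHEECCHH", rng=np.random.default_rng(0))
    assert len(s) == 8
    c_n = np.linalg.norm(s.coords[1:, 0] - s.coords[:-1, 2], axis=-1)
    assert np.abs(c_n - 1.329).max() < 0.001
    n_ca = np.linalg.norm(s.coords[:, 1] - s.coords[:, 0], axis=-1)
    assert np.abs(n_ca - 1.458).max() < 0.001


def test_ideal_builder_rejects_unknown_label():
    with pytest.raises(ValueError):
        build_ideal_backbone("HXZ")


# -- metric invariance suite -------------------------------------------------

def test_metrics_invariant_under_rigid_motion(toy_fold, rng):
    moved, _, _ = rigid_copy(toy_fold, rng)
    assert assign_secondary_structure(moved) == \
        assign_secondary_structure(toy_fold)
    assert np.array_equal(neighbor_count(moved), neighbor_count(toy_fold))
    assert count_clashes(moved) == pytest.approx(count_clashes(toy_fold))
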