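"""Ensemble statistics: RMSF, displacements, TM metrics, clustering."""

import numpy as np
import pytest

from vqfold.backbone import BackboneStructure
from vqfold.ensemble import (CompositionReport, ConformationEnsemble,
                             codebook_embedding_report, composition_report,
                             embed_and_cluster, ensemble_report, mutual_tm,
                             residue_displacement, rmsf,
                             rmsf_displacement_correlation, tm_score_ensemble)
from vqfold.geometry import build_ideal_backbone, tm_score
from vqfold.synthetic import build_toy_backbone
from conftest import rigid_copy


@pytest.fixture
def fold():
    return build_toy_backbone("HHHHHHHHCCCEEEEECCHHHHHHHH", 0.15,
                              np.random.default_rng(0))


def _jittered(s, sigma, seed):
    rng = np.random.default_rng(seed)
    return s.with_coords(s.coords + rng.normal(scale=sigma, size=s.coords.shape))


# -- RMSF --------------------------------------------------------------------

def test_rmsf_zero_for_identical_copies(fold):
    e = ConformationEnsemble([fold, fold, fold])
    assert np.allclose(rmsf(e), 0.0, atol=1e-12)


def test_rmsf_zero_for_rigid_motions(fold, rng):
    members = [fold] + [rigid_copy(fold, rng)[0] for _ in range(3)]
    assert np.abs(rmsf(ConformationEnsemble(members))).max() < 1e-3


def test_rmsf_localizes_single_residue_displacement(fold):
    delta = 2.0
    j = 12
    moved = fold.coords.copy()
    moved[j] += [0.0, 0.0, 2 * delta]
    e = ConformationEnsemble([fold, fold.with_coords(moved)])
    prof = rmsf(e)
    assert prof[j] == pytest.approx(delta, rel=0.1)
    others = np.delete(prof, j)
    assert others.max() < 0.4


def test_rmsf_requires_two_members(fold):
    with pytest.raises(ValueError):
        rmsf(ConformationEnsemble([fold]))


# -- displacements -----------------------------------------------------------

def test_displacement_zero_for_identity_and_invariant(fold, rng):
    assert np.allclose(residue_displacement(fold, fold), 0.0, atol=1e-9)
    moved, _, _ = rigid_copy(fold, rng)
    assert np.abs(residue_displacement(fold, moved)).max() < 1e-6


def test_displacement_peak_at_translated_residue(fold):
    j = 10
    moved = fold.coords.copy()
    moved[j] += [3.0, 0.0, 0.0]
    prof = residue_displacement(fold, fold.with_coords(moved))
    assert prof[j] == pytest.approx(3.0, rel=0.15)
    assert prof[j] == prof.max()


def test_correlation_examples(fold):
    e = ConformationEnsemble([fold, _jittered(fold, 0.3, 1),
                              _jittered(fold, 0.3, 2)])
    prof = rmsf(e)
    # proportional / anti-proportional displacement profiles
    from scipy import stats
    assert stats.pearsonr(prof, 2.5 * prof)[0] == pytest.approx(1.0)
    assert stats.pearsonr(prof, -prof)[0] == pytest.approx(-1.0)
    r, _ = stats.pearsonr([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
    assert r == pytest.approx(0.98198, abs=1e-5)


def test_correlation_zero_variance_raises(fold):
    e = ConformationEnsemble([fold, fold, fold])
    with pytest.raises(ValueError):
        rmsf_displacement_correlation(e, fold, fold)


# -- TM-score metrics --------------------------------------------------------

def test_tm_score_ensemble_with_exact_copies_is_one(fold):
    refs = [fold, _jittered(fold, 1.0, 3)]
    preds = ConformationEnsemble([refs[0], refs[1], _jittered(fold, 2.0, 4)])
    assert tm_score_ensemble(preds, refs) == pytest.approx(1.0, abs=1e-6)


def test_tm_score_ensemble_single_reference_is_best_score(fold):
    preds = ConformationEnsemble([_jittered(fold, s, i)
                                  for i, s in enumerate((0.5, 1.5, 3.0))])
    ref = fold
    expected = max(tm_score(p, ref) for p in preds.members)
    assert tm_score_ensemble(preds, [ref]) == pytest.approx(expected)


def test_tm_score_ensemble_matches_brute_force_and_is_monotone(fold):
    refs = [_jittered(fold, 1.0, 10), _jittered(fold, 2.0, 11)]
    members = [_jittered(fold, s, 20 + i) for i, s in enumerate((0.3, 1.0, 2.5))]
    preds = ConformationEnsemble(members)
    brute = np.mean([max(tm_score(p, r) for p in members) for r in refs])
    assert tm_score_ensemble(preds, refs) == pytest.approx(brute)
    bigger = ConformationEnsemble(members + [fold])
    assert tm_score_ensemble(bigger, refs) >= tm_score_ensemble(preds, refs)


def test_mutual_tm_matrix_properties(fold):
    members = [_jittered(fold, s, i) for i, s in enumerate((0.2, 0.5, 1.0, 2.0))]
    e = ConformationEnsemble(members)
    m, med = mutual_tm(e)
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 1.0)
    off = m[~np.eye(4, dtype=bool)]
    assert med == pytest.approx(np.median(off))


def test_mutual_tm_identical_members(fold):
    m, med = mutual_tm(ConformationEnsemble([fold, fold, fold]))
    assert np.allclose(m, 1.0, atol=1e-6)
    assert med == pytest.approx(1.0, abs=1e-6)


# -- composition -------------------------------------------------------------

def test_composition_all_helix_ensemble():
    members = [build_toy_backbone("H" * 30, 0.1, np.random.default_rng(i))
               for i in range(3)]
    rep = composition_report(ConformationEnsemble(members))
    assert rep.ss_fractions["H"] > 0.8
    assert sum(rep.ss_fractions.values()) == pytest.approx(1.0)


def test_composition_loop_histogram_conserves_runs(fold):
    e = ConformationEnsemble([fold, fold])
    rep = composition_report(e)
    from vqfold.geometry import assign_secondary_structure, loop_lengths
    runs = loop_lengths(assign_secondary_structure(fold)) * 2
    assert sum(rep.loop_length_hist.values()) == len(runs)


# -- embedding / clustering --------------------------------------------------

def test_embed_and_cluster_separates_two_constructed_states():
    rng = np.random.default_rng(0)
    a = build_toy_backbone("H" * 14 + "C" * 3 + "E" * 13, 0.0, rng)
    coords_b = a.coords.copy()
    coords_b[15:] = coords_b[15:] @ np.array(
        [[0.0, -1.0, 0], [1.0, 0.0, 0], [0, 0, 1.0]]).T + [0, 18.0, 0]
    b = a.with_coords(coords_b)
    members = [_jittered(a, 0.2, i) for i in range(12)] + \
              [_jittered(b, 0.2, 100 + i) for i in range(8)]
    e = ConformationEnsemble(members)
    rep = embed_and_cluster([e], references=[a, b], seed=0)
    real = {k: v for k, v in rep.populations.items() if k != -1}
    assert len(real) == 2
    pops = sorted(real.values())
    assert pops[0] == pytest.approx(0.4, abs=0.05)
    assert pops[1] == pytest.approx(0.6, abs=0.05)
    assert rep.reference_min_rmsd.max() < 1.0


def test_embed_and_cluster_reference_equal_to_member_has_zero_rmsd(fold):
    members = [fold, _jittered(fold, 0.5, 1), _jittered(fold, 0.5, 2),
               _jittered(fold, 0.5, 3)]
    rep = embed_and_cluster([ConformationEnsemble(members)],
                            references=[fold], seed=0)
    assert rep.reference_min_rmsd[0] < 1e-9
    assert rep.reference_nearest_member[0] == 0


def test_embed_and_cluster_deterministic(fold):
    members = [_jittered(fold, 0.5, i) for i in range(6)]
    e = ConformationEnsemble(members)
    a = embed_and_cluster([e], seed=3)
    b = embed_and_cluster([e], seed=3)
    assert np.array_equal(a.cluster_labels, b.cluster_labels)
    assert np.array_equal(a.embedding_2d, b.embedding_2d)


def test_codebook_embedding_report_mean_features():
    rng = np.random.default_rng(0)
    cb = rng.normal(size=(24, 8))
    codes = [np.concatenate([np.repeat(np.arange(10), 3),
                             np.repeat(np.arange(10, 20), 2)])]
    feats = [np.concatenate([np.full(30, 1.0), np.full(20, 5.0)])]
    rep = codebook_embedding_report(cb, codes, feats, seed=0)
    assert np.allclose(rep.mean_feature[:10], 1.0)
    assert np.allclose(rep.mean_feature[10:20], 5.0)
    assert not rep.used[20:].any()
    assert np.isnan(rep.mean_feature[20:]).all()
    assert rep.embedding_2d.shape == (24, 2)


def test_codebook_embedding_constant_feature():
    rng = np.random.default_rng(1)
    cb = rng.normal(size=(12, 4))
    rep = codebook_embedding_report(cb, [np.arange(12)], [np.full(12, 2.5)],
                                    seed=0)
    assert np.allclose(rep.mean_feature, 2.5)


def test_ensemble_report_aggregates(fold):
    e = ConformationEnsemble([fold, _jittered(fold, 0.4, 1)])
    rep = ensemble_report(e)
    assert rep.rmsf.shape == (len(fold),)
    assert rep.mutual_tm.shape == (2, 2)
    payload = rep.to_dict()
    assert set(payload) >= {"rmsf", "mutual_tm_median", "ss_fractions"}


def test_ensemble_validation(fold):
    with pytest.raises(ValueError):
        ConformationEnsemble([])
    short = build_toy_backbone("H" * 20, 0.1, np.random.default_rng(0))
    with pytest.raises(ValueError):
        ConformationEnsemble([fold, short])
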