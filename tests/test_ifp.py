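import numpy as np
import pytest

from conftest import single_donor_pocket
from fraggrow.chemio import FragGrowError, Pose, parse_molecule
from fraggrow.growth import Candidate
from fraggrow.ifp import (IFPLayout, InteractionFingerprint, cluster_ifps,
                          compute_ifp, select_candidates, tanimoto)
from fraggrow.score import EnergyModel, ScoreRecord


def _fp(bits, n_res=2):
    layout = IFPLayout(tuple(("A", i, "") for i in range(1, n_res + 1)))
    return InteractionFingerprint(tuple(sorted(bits)), layout)


class TestComputeIfp:
    def test_far_ligand_all_zero(self, toy_pocket, model):
        from fraggrow.score import generate_conformers

        mol = parse_molecule("c1ccncc1")
        pose = generate_conformers(mol, 1, 1)[0]
        far = Pose(mol, pose.coords + 50.0)
        fp = compute_ifp(far, toy_pocket, model)
        assert fp.bits == ()
        assert len(fp) == len(toy_pocket.residue_keys) * 5

    def test_crystal_pose_sets_bits(self, toy, toy_pocket, model):
        fp = compute_ifp(toy.crystal_pose, toy_pocket, model)
        assert len(fp.bits) > 0

    def test_single_constructed_hbond_sets_one_bit(self, model):
        pocket = single_donor_pocket()
        donor = [h for h in pocket.hotspots if h.kind == "hb_donor"][0]
        mol = parse_molecule("C=O")
        o_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 8)
        c_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 6)
        coords = np.zeros((mol.GetNumAtoms(), 3)) + 50.0
        ideal = donor.anchor + 3.0 * donor.direction
        coords[o_idx] = ideal
        coords[c_idx] = ideal + 1.23 * donor.direction
        fp = compute_ifp(Pose(mol, coords), pocket, model,
                         hotspots=[donor])
        assert len(fp.bits) == 1
        res_idx = fp.layout.residues.index(donor.residue)
        kind_idx = fp.layout.kinds.index("hb_donor_to_ligand")
        assert fp.bits[0] == res_idx * len(fp.layout.kinds) + kind_idx

    def test_deterministic(self, toy, toy_pocket, model):
        a = compute_ifp(toy.crystal_pose, toy_pocket, model)
        b = compute_ifp(toy.crystal_pose, toy_pocket, model)
        assert a.bits == b.bits


class TestTanimoto:
    def test_identical_nonzero(self):
        assert tanimoto(_fp({1, 2}), _fp({1, 2})) == 1.0

    def test_disjoint(self):
        assert tanimoto(_fp({0, 1}), _fp({2, 3})) == 0.0

    def test_partial_overlap(self):
        assert tanimoto(_fp({1, 2, 3}), _fp({2, 3, 4})) == 0.5

    def test_both_empty_is_one(self):
        assert tanimoto(_fp(set()), _fp(set())) == 1.0

    def test_layout_mismatch_raises(self):
        with pytest.raises(FragGrowError):
            tanimoto(_fp({1}), _fp({1}, n_res=3))


class TestClusterIfps:
    def test_identical_fingerprints_one_cluster(self):
        fps = [_fp({1, 2})] * 4
        assert cluster_ifps(fps, 0.6) == [[0, 1, 2, 3]]

    def test_unreachable_threshold_all_singletons(self):
        fps = [_fp({1}), _fp({1}), _fp({1})]
        assert cluster_ifps(fps, 1.1) == [[0], [1], [2]]

    def test_hand_traced_leader_assignment(self):
        fp1 = _fp({0, 1, 2, 3, 4})
        fp2 = _fp({0, 1, 2, 3})           # sim to fp1 = 4/5 = 0.8
        fp3 = _fp({0, 5, 6, 7, 8})        # sim to fp1 = 1/9 ~ 0.11
        assert tanimoto(fp1, fp2) == pytest.approx(0.8)
        assert tanimoto(fp1, fp3) < 0.6 and tanimoto(fp2, fp3) < 0.6
        assert cluster_ifps([fp1, fp2, fp3], 0.6) == [[0, 1], [2]]

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        fps = [_fp(set(rng.choice(10, size=rng.integers(0, 6),
                                  replace=False).tolist()))
               for _ in range(25)]
        clusters = cluster_ifps(fps, 0.5)
        flat = sorted(i for cl in clusters for i in cl)
        assert flat == list(range(25))


def _scored(smiles, energy, pli=0.5):
    cand = Candidate(mol=parse_molecule(smiles), iteration=1)
    cand.scores = ScoreRecord(energy, pli, 0.0)
    return cand


class TestSelectCandidates:
    def test_plain_topk_by_energy(self):
        cands = [_scored("CC", -5.0), _scored("CCC", -7.0),
                 _scored("CCCC", -3.0)]
        out = select_candidates(cands, "binding_energy", "plain", k=2)
        assert [c.scores.binding_energy for c in out] == [-7.0, -5.0]

    def test_pli_objective_descending(self):
        cands = [_scored("CC", -1.0, pli=0.2), _scored("CCC", -1.0, pli=0.9)]
        out = select_candidates(cands, "pli_score", "plain", k=1)
        assert out[0].scores.pli_score == 0.9

    def test_equal_objective_tie_broken_by_canonical_string(self):
        a = _scored("CCO", -5.0)
        b = _scored("CCN", -5.0)
        out = select_candidates([a, b], "binding_energy", "plain", k=2)
        assert [c.smiles for c in out] == sorted([a.smiles, b.smiles])

    def test_clustered_returns_per_cluster_best(self):
        cands = [_scored("CC", -7.0), _scored("CCC", -6.0),
                 _scored("CCCC", -5.0)]
        fps = [_fp({0, 1, 2, 3, 4}), _fp({0, 1, 2, 3}), _fp({7, 8, 9})]
        out = select_candidates(cands, "binding_energy", "ifp_clustered",
                                k=5, threshold=0.6, fingerprints=fps)
        assert len(out) == 2
        assert out[0].scores.binding_energy == -7.0
        assert out[1].scores.binding_energy == -5.0
        # representative optimality: no cluster member beats its rep
        assert -6.0 not in [c.scores.binding_energy for c in out]

    def test_unscored_candidate_raises(self):
        with pytest.raises(FragGrowError):
            select_candidates([Candidate(mol=parse_molecule("C"),
                                         iteration=0)],
                              "binding_energy", "plain", k=1)

    def test_unknown_objective_raises(self):
        with pytest.raises(ValueError):
            select_candidates([_scored("C", -1.0)], "docking_score",
                              "plain", k=1)
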