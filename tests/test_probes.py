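import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import single_donor_pocket
from fraggrow.chemio import FragGrowError, Pose, parse_molecule
from fraggrow.pocket import detect_hotspots, extract_pocket
from fraggrow.config import PlacementParams
from fraggrow.probes import (DefaultRefiner, ExternalRefiner, ProbePose,
                             enumerate_probe_placements, select_probes)
from fraggrow.score import EnergyModel, make_context

#: a one-residue pocket has a degenerate bounding box; widen the margin
WIDE = PlacementParams(pocket_margin=8.0)


class TestEnumeratePlacements:
    def test_pyridine_reaches_donor_window(self, model):
        pocket = single_donor_pocket()
        donor = [h for h in pocket.hotspots if h.kind == "hb_donor"][0]
        probe = parse_molecule("c1ccncc1")
        poses = enumerate_probe_placements(probe, pocket, pocket.hotspots,
                                           n_conformers=2, seed=1,
                                           model=model, params=WIDE)
        assert poses
        n_idx = next(a.GetIdx() for a in probe.GetAtoms()
                     if a.GetAtomicNum() == 7)
        d = np.linalg.norm(poses[0].pose.coords[n_idx] - donor.anchor)
        assert 2.6 <= d <= 3.4

    def test_featureless_probe_raises(self, model):
        pocket = single_donor_pocket()
        with pytest.raises(FragGrowError):
            enumerate_probe_placements(parse_molecule("CCC"), pocket,
                                       pocket.hotspots, seed=1, model=model)

    def test_no_complementary_pair_gives_empty(self, model):
        pocket = single_donor_pocket()
        donors_only = [h for h in pocket.hotspots if h.kind == "hb_donor"]
        # benzene offers only a ring; a donor hotspot cannot pair with it
        out = enumerate_probe_placements(parse_molecule("c1ccccc1"), pocket,
                                         donors_only, seed=1, model=model,
                                         params=WIDE)
        assert out == []

    def test_same_seed_identical(self, toy_pocket, model):
        probe = parse_molecule("c1ccncc1")
        a = enumerate_probe_placements(probe, toy_pocket,
                                       toy_pocket.hotspots, n_conformers=2,
                                       seed=9, model=model)
        b = enumerate_probe_placements(probe, toy_pocket,
                                       toy_pocket.hotspots, n_conformers=2,
                                       seed=9, model=model)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.pose.coords, pb.pose.coords)
            assert pa.pharmacophore_score == pb.pharmacophore_score

    def test_sorted_by_score_then_energy(self, toy_pocket, model):
        probe = parse_molecule("c1ccncc1")
        poses = enumerate_probe_placements(probe, toy_pocket,
                                           toy_pocket.hotspots,
                                           n_conformers=2, seed=9,
                                           model=model)
        keys = [(-p.pharmacophore_score, p.binding_energy) for p in poses]
        assert keys == sorted(keys)

    def test_placement_equivariance(self, toy, model):
        pocket = extract_pocket(toy.protein, toy.crystal_pose, 5.0)
        pocket.hotspots = detect_hotspots(pocket)
        probe = parse_molecule("c1ccncc1")
        base = enumerate_probe_placements(probe, pocket, pocket.hotspots,
                                          n_conformers=1, seed=4,
                                          model=model, params=WIDE)
        R = Rotation.from_rotvec([0.2, 0.7, -0.4]).as_matrix()
        t = np.array([3.0, -1.0, 6.0])
        prot = pocket.protein.transformed(R, t)
        ref = Pose(pocket.reference.mol, pocket.reference.coords @ R.T + t)
        pocket2 = extract_pocket(prot, ref, 5.0)
        pocket2.hotspots = detect_hotspots(pocket2)
        moved = enumerate_probe_placements(probe, pocket2, pocket2.hotspots,
                                           n_conformers=1, seed=4,
                                           model=model, params=WIDE)
        assert len(base) == len(moved)
        for pa, pb in zip(base, moved):
            assert pb.pharmacophore_score == \
                pytest.approx(pa.pharmacophore_score, abs=1e-6)
            assert pb.binding_energy == \
                pytest.approx(pa.binding_energy, abs=1e-6)
            assert np.allclose(pb.pose.coords, pa.pose.coords @ R.T + t,
                               atol=1e-6)


class TestRefinement:
    def test_energy_nonincreasing_sweep(self, toy_pocket, model):
        from fraggrow.score import generate_conformers

        probe = parse_molecule("c1ccncc1")
        base = generate_conformers(probe, 1, 2)[0]
        ctx = make_context(probe, toy_pocket, model, toy_pocket.hotspots)
        refiner = DefaultRefiner(model=model)
        rng = np.random.default_rng(3)
        for _ in range(25):
            pose = Pose(probe, base.coords + rng.uniform(-2, 2, 3))
            e0, _ = ctx.energy(pose.coords)
            refined = refiner.refine(pose, toy_pocket)
            e1, _ = ctx.energy(refined.coords)
            assert e1 <= e0 + 1e-9

    def test_trust_region_respected(self, toy_pocket, model):
        from fraggrow.chemio import heavy_indices
        from fraggrow.score import generate_conformers

        probe = parse_molecule("c1ccncc1")
        pose = generate_conformers(probe, 1, 2)[0]
        refined = DefaultRefiner(model=model).refine(pose, toy_pocket)
        hv = heavy_indices(probe)
        disp = np.linalg.norm(refined.coords[hv].mean(axis=0)
                              - pose.coords[hv].mean(axis=0))
        assert disp <= 2.0 + 1e-6

    def test_external_refiner_contract_with_mock(self, tmp_path, toy_pocket,
                                                 model):
        """A mock executable that echoes the probe back verbatim satisfies
        the refiner contract and is interchangeable with the default."""
        from fraggrow.score import generate_conformers

        script = tmp_path / "mockrefine.py"
        script.write_text(
            "#!/usr/bin/env python\n"
            "import sys\n"
            "print(open(sys.argv[1]).read())\n")
        script.chmod(0o755)
        probe = parse_molecule("c1ccncc1")
        pose = generate_conformers(probe, 1, 2)[0]
        refiner = ExternalRefiner(executable=str(script), model=model)
        refined = refiner.refine(pose, toy_pocket)
        assert refined.coords.shape == pose.coords.shape
        ctx = make_context(probe, toy_pocket, model, toy_pocket.hotspots)
        assert ctx.energy(refined.coords)[0] <= \
            ctx.energy(pose.coords)[0] + 1e-6


def _probe_pose(smiles, coords_shift, score, energy):
    mol = parse_molecule(smiles)
    from fraggrow.score import generate_conformers

    pose = generate_conformers(mol, 1, 1)[0]
    shifted = Pose(mol, pose.coords + coords_shift)
    return ProbePose(mol, shifted, score, energy, ())


class TestSelectProbes:
    def test_near_identical_poses_deduplicated(self):
        a = _probe_pose("c1ccccc1", 0.0, 1.0, -3.0)
        b = ProbePose(a.mol, Pose(a.mol, a.pose.coords + 0.1), 0.9, -2.9, ())
        assert len(select_probes([a, b], k=5)) == 1

    def test_k_larger_than_pool_returns_pool(self):
        a = _probe_pose("c1ccccc1", 0.0, 1.0, -3.0)
        b = _probe_pose("c1ccncc1", 5.0, 0.5, -1.0)
        assert len(select_probes([a, b], k=10)) == 2

    def test_zero_energy_weight_is_pure_pharmacophore_order(self):
        a = _probe_pose("c1ccccc1", 0.0, 0.5, -10.0)
        b = _probe_pose("c1ccncc1", 5.0, 0.9, 0.0)
        out = select_probes([a, b], k=2, energy_weight=0.0)
        assert out[0] is b

    def test_empty_pool_raises(self):
        with pytest.raises(FragGrowError):
            select_probes([], k=1)
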