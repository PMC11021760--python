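import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import single_donor_pocket
from fraggrow.chemio import (FragGrowError, Pose, heavy_indices, mol_coords,
                             parse_molecule)
from fraggrow.config import EnergyParams
from fraggrow.geom import axis_rotation, plane_fit
from fraggrow.score import (EnergyModel, align_to_parent, binding_energy,
                            energy_and_clash, generate_conformers,
                            make_context, pli_score, rigid_dock,
                            shape_similarity, symmetry_rmsd)


class TestConformers:
    def test_rigid_benzene_collapses_to_one(self):
        assert len(generate_conformers(parse_molecule("c1ccccc1"), 10, 3)) == 1

    def test_flexible_chain_gives_several(self):
        confs = generate_conformers(parse_molecule("CCCCCC"), 20, 3)
        assert len(confs) > 1

    def test_pairwise_distinct(self):
        from rdkit import Chem
        from rdkit.Chem import rdMolAlign

        mol = parse_molecule("CCCCCC")
        confs = generate_conformers(mol, 10, 3)
        noh = Chem.RemoveHs(Chem.Mol(mol))
        hv = heavy_indices(mol)
        for i in range(len(confs)):
            for j in range(i + 1, len(confs)):
                work = Chem.Mol(noh)
                work.RemoveAllConformers()
                for pose in (confs[i], confs[j]):
                    conf = Chem.Conformer(noh.GetNumAtoms())
                    for k, idx in enumerate(hv):
                        conf.SetAtomPosition(k, tuple(pose.coords[idx]))
                    work.AddConformer(conf, assignId=True)
                assert rdMolAlign.GetBestRMS(work, work, 0, 1) >= 0.5

    def test_same_seed_bitwise_identical(self):
        mol = parse_molecule("CCOCC")
        a = generate_conformers(mol, 5, 42)
        b = generate_conformers(mol, 5, 42)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.coords, pb.coords)

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            generate_conformers(parse_molecule("C"), 0, 1)


class TestAlign:
    def test_identity(self, benzene_pose):
        idmap = {i: i for i in range(benzene_pose.mol.GetNumAtoms())}
        _, rmsd = align_to_parent(benzene_pose, benzene_pose, idmap)
        assert rmsd < 1e-12

    def test_rigid_motion_removed(self, benzene_pose):
        R = Rotation.from_rotvec([0.4, 0.2, -0.9]).as_matrix()
        moved = Pose(benzene_pose.mol,
                     benzene_pose.coords @ R.T + np.array([3.0, -1.0, 2.0]))
        idmap = {i: i for i in range(benzene_pose.mol.GetNumAtoms())}
        aligned, rmsd = align_to_parent(moved, benzene_pose, idmap)
        assert rmsd < 1e-6
        assert np.allclose(aligned.coords, benzene_pose.coords, atol=1e-6)

    def test_underdetermined_raises(self, benzene_pose):
        with pytest.raises(FragGrowError):
            align_to_parent(benzene_pose, benzene_pose, {0: 0, 1: 1})

    def test_collinear_map_handled(self):
        # three collinear heavy atoms: the spin about the axis is
        # unresolved; the fit must still succeed and match the axis
        mol = parse_molecule("C#CC")
        hv = heavy_indices(mol)
        coords = np.zeros((mol.GetNumAtoms(), 3))
        for k, idx in enumerate(hv):
            coords[k if False else idx] = [1.3 * k, 0.0, 0.0]
        pose = Pose(mol, coords)
        R = Rotation.from_rotvec([0.0, 0.9, 0.0]).as_matrix()
        moved = Pose(mol, coords @ R.T + 1.0)
        aligned, rmsd = align_to_parent(moved, pose, {i: i for i in hv})
        assert rmsd < 1e-6


class TestBindingEnergy:
    def test_noninteracting_limit_is_zero(self, toy_pocket, model):
        mol = parse_molecule("c1ccccc1")
        confs = generate_conformers(mol, 1, 1)
        far = Pose(mol, confs[0].coords + 50.0)
        assert binding_energy(far, toy_pocket, model) == 0.0

    def test_single_ideal_hbond_is_minus_whb(self):
        # formaldehyde O at the ideal acceptor site of a lone Ser donor
        pocket = single_donor_pocket()
        donor = [h for h in pocket.hotspots if h.kind == "hb_donor"][0]
        mol = parse_molecule("C=O")
        o_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 8)
        c_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 6)
        coords = np.zeros((mol.GetNumAtoms(), 3))
        ideal = donor.anchor + 3.0 * donor.direction
        coords[o_idx] = ideal
        coords[c_idx] = ideal + 1.23 * donor.direction
        h_idxs = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 1]
        for k, hi in enumerate(h_idxs):
            coords[hi] = coords[c_idx] + [0.6 * (-1) ** k, 0.9, 0.0]
        model = EnergyModel(params=EnergyParams(steric_eps=0.0))
        e = binding_energy(Pose(mol, coords), pocket, model,
                           hotspots=pocket.hotspots)
        assert e == pytest.approx(-model.params.w_hb, abs=1e-9)

    def test_hard_clash_sets_flag_and_penalty(self, model):
        pocket = single_donor_pocket()
        og = pocket.protein.coords[0]
        mol = parse_molecule("C")
        coords = np.zeros((mol.GetNumAtoms(), 3))
        coords[0] = og + np.array([0.5 * 0.5 * (1.52 + 1.70), 0, 0])
        e, clash = energy_and_clash(Pose(mol, coords), pocket, model)
        assert clash
        assert e > model.params.clash_energy_threshold

    def test_joint_rigid_transform_invariance(self, toy, toy_pocket, model):
        from fraggrow.pocket import detect_hotspots, extract_pocket

        e0 = binding_energy(toy.crystal_pose, toy_pocket, model)
        R = Rotation.from_rotvec([1.0, -0.3, 0.4]).as_matrix()
        t = np.array([-4.0, 2.0, 7.0])
        prot = toy.protein.transformed(R, t)
        ref = Pose(toy.crystal_pose.mol, toy.crystal_pose.coords @ R.T + t)
        pocket = extract_pocket(prot, ref, 5.0)
        pocket.hotspots = detect_hotspots(pocket)
        e1 = binding_energy(ref, pocket, model)
        assert e1 == pytest.approx(e0, abs=1e-6)


class TestRigidDock:
    def test_energy_never_increases(self, toy_pocket, model):
        mol = parse_molecule("c1ccncc1")
        base = generate_conformers(mol, 1, 5)[0]
        rng = np.random.default_rng(0)
        ctx = make_context(mol, toy_pocket, model, toy_pocket.hotspots)
        for trial in range(20):
            coords = base.coords + rng.uniform(-3, 3, 3)
            pose = Pose(mol, coords)
            e0, _ = ctx.energy(pose.coords)
            _, e1, _ = rigid_dock(pose, toy_pocket, model, seed=trial,
                                  context=ctx)
            assert e1 <= e0 + 1e-9

    def test_optimum_is_fixed_point(self, toy_pocket, model):
        mol = parse_molecule("c1ccncc1")
        pose = generate_conformers(mol, 1, 5)[0]
        ctx = make_context(mol, toy_pocket, model, toy_pocket.hotspots)
        opt, e_opt, _ = rigid_dock(pose, toy_pocket, model, seed=1,
                                   context=ctx)
        again, e2, _ = rigid_dock(opt, toy_pocket, model, seed=2, context=ctx)
        assert e2 <= e_opt + 1e-9
        # unless a restart found a strictly better basin, the pose stays put
        if e2 > e_opt - 1e-3:
            assert symmetry_rmsd(mol, again, opt) < 0.35


class TestPliScore:
    def test_null_when_far(self, toy_pocket, model):
        mol = parse_molecule("c1ccccc1")
        pose = generate_conformers(mol, 1, 1)[0]
        far = Pose(mol, pose.coords + 50.0)
        assert pli_score(far, toy_pocket, toy_pocket.hotspots, model) == 0.0

    def test_single_hotspot_ideally_satisfied_is_one(self):
        pocket = single_donor_pocket()
        donor = [h for h in pocket.hotspots if h.kind == "hb_donor"][0]
        # keep only the donor hotspot for the saturation limit
        mol = parse_molecule("C=O")
        o_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 8)
        c_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 6)
        coords = np.zeros((mol.GetNumAtoms(), 3))
        ideal = donor.anchor + 3.0 * donor.direction
        coords[o_idx] = ideal
        coords[c_idx] = ideal + 1.23 * donor.direction
        model = EnergyModel()
        score = pli_score(Pose(mol, coords), pocket, [donor], model)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_half_of_two_equal_weight_hotspots(self):
        from fraggrow.pocket import Hotspot

        pocket = single_donor_pocket()
        donor = [h for h in pocket.hotspots if h.kind == "hb_donor"][0]
        other = Hotspot("hb_donor", donor.anchor + np.array([0, 40.0, 0]),
                        donor.direction, ("A", 99, ""))
        mol = parse_molecule("C=O")
        o_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 8)
        c_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 6)
        coords = np.zeros((mol.GetNumAtoms(), 3))
        ideal = donor.anchor + 3.0 * donor.direction
        coords[o_idx] = ideal
        coords[c_idx] = ideal + 1.23 * donor.direction
        score = pli_score(Pose(mol, coords), pocket, [donor, other],
                          EnergyModel())
        assert score == pytest.approx(0.5, abs=1e-9)


class TestShapeSimilarity:
    def test_self_similarity_is_one(self, benzene_pose):
        assert shape_similarity(benzene_pose, benzene_pose) == 1.0

    def test_disjoint_is_zero(self, benzene_pose):
        far = Pose(benzene_pose.mol, benzene_pose.coords + 30.0)
        assert shape_similarity(benzene_pose, far) == 0.0

    def test_symmetry(self, benzene_pose):
        other = Pose(benzene_pose.mol, benzene_pose.coords + 1.0)
        ab = shape_similarity(benzene_pose, other)
        ba = shape_similarity(other, benzene_pose)
        assert ab == pytest.approx(ba, abs=1e-12)
        assert 0.0 < ab < 1.0

    def test_two_sphere_voxel_oracle(self):
        """Single-atom poses: Tanimoto must equal a brute-force voxel count
        on the same grid convention."""
        mol = parse_molecule("C")
        c_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 6)
        coords_a = np.zeros((mol.GetNumAtoms(), 3))
        coords_b = np.zeros((mol.GetNumAtoms(), 3))
        coords_b[c_idx, 0] = 1.7
        pa, pb = Pose(mol, coords_a), Pose(mol, coords_b)
        model = EnergyModel()
        got = shape_similarity(pa, pb, grid_spacing=0.5, model=model)
        # independent full-grid rasterization
        r = model.radius("C")
        spacing = 0.5
        lo = np.minimum(coords_a[c_idx], coords_b[c_idx]) - r - spacing
        hi = np.maximum(coords_a[c_idx], coords_b[c_idx]) + r + spacing
        shape = np.ceil((hi - lo) / spacing).astype(int) + 1
        axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        occ_a = (gx - coords_a[c_idx, 0]) ** 2 + gy ** 2 + gz ** 2 <= r * r
        occ_b = (gx - coords_b[c_idx, 0]) ** 2 + gy ** 2 + gz ** 2 <= r * r
        expected = occ_a[occ_a & occ_b].size and \
            np.sum(occ_a & occ_b) / np.sum(occ_a | occ_b)
        assert got == pytest.approx(float(expected), abs=1e-12)


class TestSymmetryRmsd:
    def test_identity(self, benzene_pose):
        assert symmetry_rmsd(benzene_pose.mol, benzene_pose,
                             benzene_pose) == 0.0

    def test_uniform_translation_is_exact(self, benzene_pose):
        moved = Pose(benzene_pose.mol,
                     benzene_pose.coords + np.array([1.0, 0.0, 0.0]))
        assert symmetry_rmsd(benzene_pose.mol, benzene_pose, moved) == \
            pytest.approx(1.0, abs=1e-12)

    def test_benzene_sixty_degree_rotation_is_zero(self):
        mol = parse_molecule("c1ccccc1")
        hv = heavy_indices(mol)
        coords = np.zeros((mol.GetNumAtoms(), 3))
        for k, idx in enumerate(hv):  # ideal hexagon, ring order = SMILES
            ang = np.radians(60.0 * k)
            coords[idx] = [1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0]
            h = mol.GetAtomWithIdx(idx).GetNeighbors()
            h_idx = next(a.GetIdx() for a in h if a.GetAtomicNum() == 1)
            coords[h_idx] = [2.48 * np.cos(ang), 2.48 * np.sin(ang), 0.0]
        pose = Pose(mol, coords)
        R = axis_rotation(np.array([0.0, 0.0, 1.0]), np.pi / 3)
        rotated = Pose(mol, coords @ R.T)
        assert symmetry_rmsd(mol, pose, rotated) < 1e-6
        # the naive per-index comparison would be far from zero
        d = rotated.coords[hv] - pose.coords[hv]
        assert np.sqrt(np.mean(np.sum(d * d, axis=1))) > 0.5
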