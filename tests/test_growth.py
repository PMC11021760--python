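import numpy as np
import pytest
from rdkit import Chem

from fraggrow.chemio import ChemistryError, FragGrowError, canonical_smiles, \
    parse_molecule
from fraggrow.config import GrowthRules
from fraggrow.growth import (Candidate, Fragment, enumerate_attachment_points,
                             fragment_from_smiles, fuse_rings, grow,
                             link_direct, link_via_linker,
                             load_fragment_library, replay_lineage,
                             spiro_join)
from oracles import (direct_products, fuse_products, linker_products,
                     spiro_products)


def canon(smiles: str) -> str:
    return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))


class TestAttachmentPoints:
    def test_benzene_symmetry_reduced_to_one(self):
        assert len(enumerate_attachment_points(parse_molecule("c1ccccc1"))) == 1

    def test_benzene_unreduced_has_six(self):
        sites = enumerate_attachment_points(parse_molecule("c1ccccc1"),
                                            symmetry_reduction=False)
        assert len(sites) == 6

    def test_neopentane_central_carbon_excluded(self):
        mol = parse_molecule("CC(C)(C)C")
        central = next(a.GetIdx() for a in mol.GetAtoms()
                       if a.GetAtomicNum() == 6 and
                       sum(1 for n in a.GetNeighbors()
                           if n.GetAtomicNum() > 1) == 4)
        assert central not in enumerate_attachment_points(
            mol, symmetry_reduction=False)

    def test_amide_nitrogen_forbidden_by_default(self):
        mol = parse_molecule("CC(=O)NC")
        n_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 7)
        assert n_idx not in enumerate_attachment_points(
            mol, symmetry_reduction=False)
        assert n_idx in enumerate_attachment_points(
            mol, forbidden_smarts=(), symmetry_reduction=False)


class TestLinkDirect:
    @pytest.mark.parametrize("a,b,expected", [
        ("c1ccccc1", "C", "Cc1ccccc1"),
        ("c1ccccc1", "c1ccccc1", "c1ccc(-c2ccccc2)cc1"),
        ("C1CCCCC1", "O", "OC1CCCCC1"),
    ])
    def test_textbook_joins(self, a, b, expected):
        mol_a = parse_molecule(a)
        frag = fragment_from_smiles(b)
        res = link_direct(mol_a, 0, frag.mol, frag.attachment_points[0])
        assert canonical_smiles(res[0]) == canon(expected)

    def test_fluorine_site_raises(self):
        mol = parse_molecule("Fc1ccccc1")
        f_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 9)
        frag = fragment_from_smiles("C")
        with pytest.raises(ChemistryError):
            link_direct(mol, f_idx, frag.mol, 0)

    def test_index_maps_cover_all_heavy_atoms(self):
        a = parse_molecule("c1ccncc1")
        frag = fragment_from_smiles("C")
        mol, a_map, b_map = link_direct(a, 0, frag.mol, 0)
        heavy_a = [i for i in a_map
                   if a.GetAtomWithIdx(i).GetAtomicNum() > 1]
        assert len(heavy_a) == 6
        for old, new in a_map.items():
            assert a.GetAtomWithIdx(old).GetAtomicNum() == \
                mol.GetAtomWithIdx(new).GetAtomicNum()


class TestLinker:
    def test_diphenylmethane(self):
        ch2 = fragment_from_smiles("C", role="linker")
        res = link_via_linker(parse_molecule("c1ccccc1"), 0, ch2,
                              parse_molecule("c1ccccc1"), 0)
        assert canonical_smiles(res[0]) == canon("c1ccccc1Cc1ccccc1")

    def test_asymmetric_linker_both_orientations(self):
        amide = fragment_from_smiles("[*]C(=O)N[*]", role="linker")
        a = parse_molecule("c1ccccc1")
        b = parse_molecule("Cc1ccccc1")
        p1, p2 = amide.attachment_points
        r1 = link_via_linker(a, 0, amide, b, 0, orientation=(p1, p2))
        r2 = link_via_linker(a, 0, amide, b, 0, orientation=(p2, p1))
        # toluene methyl vs phenyl ends differ: two distinct amide products
        assert canonical_smiles(r1[0]) != canonical_smiles(r2[0])

    def test_three_point_linker_rejected_at_load(self):
        with pytest.raises(FragGrowError):
            fragment_from_smiles("[*]C([*])C[*]", role="linker")


class TestFuseRings:
    def test_benzene_benzene_gives_naphthalene(self):
        a = parse_molecule("c1ccccc1")
        frag = fragment_from_smiles("c1ccccc1")
        res = fuse_rings(a, (0, 1), frag.mol, (0, 1))
        assert canonical_smiles(res[0]) == canon("c1ccc2ccccc2c1")

    def test_benzene_cyclopentane_gives_indane_skeleton(self):
        a = parse_molecule("c1ccccc1")
        frag = fragment_from_smiles("C1CCCC1")
        res = fuse_rings(a, (0, 1), frag.mol, (0, 1))
        assert canonical_smiles(res[0]) == canon("C1Cc2ccccc2C1")

    def test_non_ring_bond_raises(self):
        a = parse_molecule("Cc1ccccc1")
        methyl_bond = next(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
            for b in a.GetBonds() if not b.IsInRing()
            and b.GetBeginAtom().GetAtomicNum() > 1
            and b.GetEndAtom().GetAtomicNum() > 1)
        frag = fragment_from_smiles("c1ccccc1")
        with pytest.raises(ChemistryError):
            fuse_rings(a, methyl_bond, frag.mol, (0, 1))

    def test_element_mismatch_rejected(self):
        a = parse_molecule("c1ccncc1")
        n_bond = next((b.GetBeginAtomIdx(), b.GetEndAtomIdx())
                      for b in a.GetBonds() if b.IsInRing()
                      and 7 in (b.GetBeginAtom().GetAtomicNum(),
                                b.GetEndAtom().GetAtomicNum()))
        frag = fragment_from_smiles("c1ccccc1")
        assert fuse_rings(a, n_bond, frag.mol, (0, 1)) is None or \
            fuse_rings(a, n_bond, frag.mol, (0, 1), mapping_order=1) is None


class TestSpiro:
    def test_spiro_decane(self):
        a = parse_molecule("C1CCCCC1")
        frag = fragment_from_smiles("C1CCCC1")
        res = spiro_join(a, 0, frag.mol, 0)
        assert canonical_smiles(res[0]) == canon("C1CCC2(CC1)CCCC2")

    def test_oxetane_spiro_accepted(self):
        a = parse_molecule("C1CCCCC1")
        frag = fragment_from_smiles("C1COC1")
        res = spiro_join(a, 0, frag.mol, 0)
        assert res is not None
        assert "O" in canonical_smiles(res[0])

    def test_aromatic_atom_raises(self):
        a = parse_molecule("c1ccccc1")
        frag = fragment_from_smiles("C1CCCC1")
        with pytest.raises(ChemistryError):
            spiro_join(a, 0, frag.mol, 0)


def _cand(smiles, cid=0):
    return Candidate(mol=parse_molecule(smiles), iteration=0, cand_id=cid)


class TestGrow:
    def test_direct_count_matches_nested_loop(self):
        # 2 asymmetric parent sites x 3 one-site fragments = 6 products
        parent = _cand("CO")
        lib = [fragment_from_smiles(s) for s in ("C", "N", "OC" )]
        rules = GrowthRules(direct=True, linker=False, fuse=False,
                            spiro=False, forbidden_substitution_smarts=(),
                            symmetry_reduction=False)
        out = grow([parent], lib, rules)
        oracle = set()
        for frag_smi in ("C", "N", "CO"):
            oracle |= direct_products("CO", frag_smi)
        assert {c.smiles for c in out} == oracle

    def test_all_rules_disabled_gives_empty(self):
        rules = GrowthRules(direct=False, linker=False, fuse=False,
                            spiro=False)
        assert grow([_cand("c1ccccc1")],
                    [fragment_from_smiles("C")], rules) == []

    def test_duplicate_fragment_no_duplicate_products(self):
        lib = [fragment_from_smiles("C"), fragment_from_smiles("C")]
        out = grow([_cand("c1ccccc1")], lib)
        smiles = [c.smiles for c in out]
        assert len(smiles) == len(set(smiles))

    def test_empty_parents_raise(self):
        with pytest.raises(FragGrowError):
            grow([], [fragment_from_smiles("C")])

    def test_lineage_replay_reproduces_molecule(self):
        parent = _cand("c1ccncc1")
        lib = [fragment_from_smiles("C"), fragment_from_smiles("c1ccccc1"),
               fragment_from_smiles("C1CCCC1")]
        out = grow([parent], lib)
        assert out
        for cand in out:
            assert replay_lineage(cand) == cand.smiles

    def test_linker_rule_only_in_pair_context(self):
        probes = [_cand("c1ccccc1", 0), _cand("c1ccccc1", 1)]
        linker = fragment_from_smiles("C", role="linker")
        rules = GrowthRules(direct=False, fuse=False, spiro=False)
        assert grow(probes, [linker], rules) == []
        out = grow(probes, [linker], rules,
                   pair_context=[(probes[0], probes[1])])
        assert {c.smiles for c in out} == {canon("c1ccccc1Cc1ccccc1")}

    def test_products_all_sanitizable(self):
        out = grow([_cand("c1ccncc1")],
                   [fragment_from_smiles("c1ccccc1"),
                    fragment_from_smiles("C1CCCC1")])
        for cand in out:
            remol = Chem.MolFromSmiles(cand.smiles)
            assert remol is not None


PARENT_POOL = ("CCO", "C1CC1", "c1ccccc1", "C1CCOC1", "CC(C)=O", "c1ccncc1")
FRAG_POOL = ("C", "N", "O", "C1CCCC1", "c1ccccc1", "C1CC1", "CCO")


def oracle_grow(parent_smi, frag_smis, rules: GrowthRules) -> set[str]:
    out = set()
    for f in frag_smis:
        if rules.direct:
            out |= direct_products(parent_smi, f)
        if rules.fuse:
            out |= fuse_products(parent_smi, f)
        if rules.spiro:
            out |= spiro_products(parent_smi, f)
    return out


@pytest.mark.parametrize("trial", range(12))
def test_enumeration_oracle_equivalence_sample(trial):
    """grow() equals an independent implicit-H brute-force enumerator."""
    rng = np.random.default_rng(trial)
    parent_smi = PARENT_POOL[rng.integers(len(PARENT_POOL))]
    frags = [FRAG_POOL[i] for i in
             rng.choice(len(FRAG_POOL), size=rng.integers(1, 4),
                        replace=False)]
    toggles = rng.integers(0, 2, size=3).astype(bool)
    if not toggles.any():
        toggles[0] = True
    rules = GrowthRules(direct=bool(toggles[0]), fuse=bool(toggles[1]),
                        spiro=bool(toggles[2]), linker=False,
                        forbidden_substitution_smarts=(),
                        symmetry_reduction=bool(rng.integers(0, 2)))
    out = grow([_cand(parent_smi)],
               [fragment_from_smiles(f) for f in frags], rules)
    assert {c.smiles for c in out} == \
        oracle_grow(parent_smi, frags, rules)


def test_library_file_round_trip(tmp_path):
    path = tmp_path / "lib.smi"
    path.write_text(
        "# a comment\n"
        "c1ccccc1 benzene\n"
        "C ch2 linker\n"
        "[*]CC[*] ethylene linker\n"
        "c1ccncc1 probe\n")
    lib = load_fragment_library(str(path))
    assert [f.role for f in lib] == \
        ["building_block", "linker", "linker", "probe"]
    assert len(lib[2].attachment_points) == 2
    for idx in lib[2].attachment_points:
        assert lib[2].mol.GetAtomWithIdx(idx).GetAtomicNum() == 6
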