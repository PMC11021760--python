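import logging

import numpy as np
import pytest
from rdkit import RDLogger

from fraggrow.chemio import Pose, parse_molecule
from fraggrow.pocket import detect_hotspots, extract_pocket
from fraggrow.score import EnergyModel
from fraggrow.testkit import make_toy_complex

RDLogger.DisableLog("rdApp.*")
logging.getLogger("fraggrow").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy():
    """Small two-fragment toy complex (4-phenylpyridine ligand)."""
    return make_toy_complex("c1ccc(-c2ccncc2)cc1", seed=7)


@pytest.fixture(scope="session")
def toy_pocket(toy):
    pocket = extract_pocket(toy.protein, toy.crystal_pose, 5.0)
    pocket.hotspots = detect_hotspots(pocket)
    return pocket


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture()
def benzene_pose():
    from rdkit.Chem import AllChem

    mol = parse_molecule("c1ccccc1")
    params = AllChem.ETKDGv3()
    params.randomSeed = 11
    AllChem.EmbedMolecule(mol, params)
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    from fraggrow.chemio import mol_coords

    return Pose(mol, mol_coords(mol))


def single_donor_pocket():
    """A pocket holding exactly one Ser hydroxyl pointing along +x from the
    origin region, with the H-bond target site at the origin."""
    from fraggrow.chemio import ProteinStructure
    from fraggrow.testkit import _ser_donor

    resname, atoms = _ser_donor(np.zeros(3), np.array([1.0, 0.0, 0.0]))
    protein = ProteinStructure(
        elements=[el for _, el, _ in atoms],
        names=[nm for nm, _, _ in atoms],
        resnames=[resname] * len(atoms),
        resseqs=[1] * len(atoms),
        chains=["A"] * len(atoms),
        icodes=[""] * len(atoms),
        coords=np.array([p for _, _, p in atoms]),
    )
    ref = parse_molecule("C")
    ref_pose = Pose(ref, np.zeros((ref.GetNumAtoms(), 3)))
    pocket = extract_pocket(protein, ref_pose, 6.0)
    pocket.hotspots = detect_hotspots(pocket)
    return pocket
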