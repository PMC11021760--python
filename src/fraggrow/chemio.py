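"""Molecule and protein structure I/O plus the shared pose data model.

Molecules are RDKit ``Mol`` objects kept hydrogen-complete throughout the
pipeline; the canonical (H-suppressed) SMILES string is the identity and
dedup key for every generated structure.  Atom provenance (which growth step
an atom came from) is stored in the ``prov`` atom property.

Proteins are parsed from PDB with Biopython and flattened into plain numpy
arrays, which is all the pocket/hotspot machinery needs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from rdkit import Chem
from rdkit.Chem import AllChem

log = logging.getLogger(__name__)

WATER_RESNAMES = {"HOH", "WAT", "DOD", "TIP", "TIP3"}

PROV_TAG = "prov"
NEW_PROV = "new"


class FragGrowError(Exception):
    """Base class for all package errors."""


class ParseError(FragGrowError):
    """Unparsable molecular input."""


class ChemistryError(FragGrowError):
    """Chemically illegal structure (valence, aromaticity...)."""


class FormatError(FragGrowError):
    """Structurally invalid file (e.g. a PDB without ATOM records)."""


# ---------------------------------------------------------------------------
# molecules


def parse_molecule(text: str, format_tag: str = "smiles") -> Chem.Mol:
    """Parse a SMILES string or an SDF/MOL block into a sanitized,
    hydrogen-complete molecule with aromaticity and ring flags perceived.
    """
    if not text or not text.strip():
        raise ParseError("empty molecular input")
    if format_tag == "smiles":
        mol = Chem.MolFromSmiles(text, sanitize=False)
        if mol is None:
            raise ParseError(f"could not parse SMILES {text!r}")
        _sanitize(mol, text)
        mol = Chem.AddHs(mol)
    elif format_tag == "sdf":
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
        if mol is None:
            raise ParseError("could not parse SDF/MOL block")
        _sanitize(mol, text.splitlines()[0] if text.splitlines() else "?")
        mol = Chem.AddHs(mol, addCoords=mol.GetNumConformers() > 0)
    else:
        raise ValueError(f"unknown format_tag {format_tag!r}")
    Chem.GetSSSR(mol)
    for atom in mol.GetAtoms():
        if not atom.HasProp(PROV_TAG):
            atom.SetProp(PROV_TAG, NEW_PROV)
    return mol


def _sanitize(mol: Chem.Mol, context: str) -> None:
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException as exc:
        raise ChemistryError(f"valence violation in {context!r}: {exc}") from exc
    except (Chem.KekulizeException, ValueError) as exc:
        raise ParseError(f"cannot sanitize {context!r}: {exc}") from exc


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical H-suppressed SMILES — the identity key used everywhere."""
    return Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(mol)))


def heavy_indices(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]


def mol_coords(mol: Chem.Mol, conf_id: int = -1) -> np.ndarray:
    conf = mol.GetConformer(conf_id)
    return np.array(conf.GetPositions(), dtype=float)


def set_mol_coords(mol: Chem.Mol, coords: np.ndarray, conf_id: int = -1) -> None:
    conf = mol.GetConformer(conf_id)
    for i, xyz in enumerate(np.asarray(coords, float)):
        conf.SetAtomPosition(i, tuple(xyz))


# ---------------------------------------------------------------------------
# poses


@dataclass
class Pose:
    """One coordinate set for a molecule, plus the rigid frame that produced
    it (identity if the coordinates are original)."""

    mol: Chem.Mol
    coords: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.mol.GetNumAtoms(), 3):
            raise ValueError(
                f"coordinate count {self.coords.shape} does not match "
                f"atom count {self.mol.GetNumAtoms()}"
            )
        R = np.asarray(self.rotation, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")

    def heavy_coords(self) -> np.ndarray:
        return self.coords[heavy_indices(self.mol)]

    def transformed(self, R: np.ndarray, t: np.ndarray,
                    center: np.ndarray | None = None) -> "Pose":
        from .geom import apply_rigid

        new = apply_rigid(self.coords, R, t, center)
        return Pose(self.mol, new, R @ self.rotation, t + self.translation)

    def copy(self) -> "Pose":
        return Pose(self.mol, self.coords.copy(), self.rotation.copy(),
                    self.translation.copy())


def pose_from_conformer(mol: Chem.Mol, conf_id: int = -1) -> Pose:
    return Pose(mol, mol_coords(mol, conf_id))


# ---------------------------------------------------------------------------
# proteins


@dataclass
class HeteroGroup:
    """A HETATM residue, returned as a candidate reference ligand."""

    resname: str
    names: list[str]
    elements: list[str]
    coords: np.ndarray


@dataclass
class ProteinStructure:
    """Flat arrays of the protein's atoms plus a residue lookup index."""

    elements: list[str]
    names: list[str]
    resnames: list[str]
    resseqs: list[int]
    chains: list[str]
    icodes: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite protein coordinates")
        self._residues: dict[tuple, list[int]] = {}
        for i in range(len(self.elements)):
            self._residues.setdefault(self.residue_key(i), []).append(i)

    def __len__(self) -> int:
        return len(self.elements)

    def residue_key(self, i: int) -> tuple[str, int, str]:
        return (self.chains[i], self.resseqs[i], self.icodes[i])

    @property
    def residues(self) -> dict[tuple, list[int]]:
        return self._residues

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "ProteinStructure":
        return ProteinStructure(
            list(self.elements), list(self.names), list(self.resnames),
            list(self.resseqs), list(self.chains), list(self.icodes),
            self.coords @ np.asarray(R, float).T + np.asarray(t, float),
        )


def _pick_altloc(atom):
    """Highest occupancy wins; ties go to altloc 'A'."""
    if atom.is_disordered() != 2:  # 2 marks the DisorderedAtom wrapper
        return atom
    best = None
    for child in atom.disordered_get_list():
        if best is None:
            best = child
            continue
        occ_b = best.get_occupancy() or 0.0
        occ_c = child.get_occupancy() or 0.0
        if occ_c > occ_b or (occ_c == occ_b and child.get_altloc() == "A"):
            best = child
    return best


def read_protein(path: str, include_waters: bool = False,
                 with_hetero: bool = False):
    """Read a PDB file into a :class:`ProteinStructure`.

    HETATM groups (excluding waters) are returned as candidate reference
    ligands when ``with_hetero`` is true.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("prot", path)
    elements, names, resnames, resseqs, chains, icodes, coords = \
        [], [], [], [], [], [], []
    hetero: list[HeteroGroup] = []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            resname = residue.get_resname().strip()
            if resname in WATER_RESNAMES and not include_waters:
                continue
            atoms = [_pick_altloc(a) for a in residue.get_list()]
            # disordered positions collapse to one atom per name
            seen = set()
            kept = []
            for a in atoms:
                if a.get_name() in seen:
                    continue
                seen.add(a.get_name())
                kept.append(a)
            if hetflag.strip():
                hetero.append(HeteroGroup(
                    resname=resname,
                    names=[a.get_name() for a in kept],
                    elements=[(a.element or "C").strip().capitalize() for a in kept],
                    coords=np.array([a.get_coord() for a in kept], dtype=float),
                ))
                continue
            for a in kept:
                elements.append((a.element or "C").strip().capitalize())
                names.append(a.get_name())
                resnames.append(resname)
                resseqs.append(int(resseq))
                chains.append(chain.get_id())
                icodes.append(icode.strip())
                coords.append(a.get_coord())
    if not elements:
        raise FormatError(f"no ATOM records in {path}")
    protein = ProteinStructure(elements, names, resnames, resseqs, chains,
                               icodes, np.array(coords, dtype=float))
    if with_hetero:
        return protein, hetero
    return protein


_PDB_LINE = ("{rec:<6}{serial:>5} {name:<4}{alt:1}{resname:<3} {chain:1}"
             "{resseq:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}"
             "{occ:>6.2f}{b:>6.2f}          {elem:>2}")


def write_protein(protein: ProteinStructure, path: str) -> None:
    """Write a ProteinStructure as a minimal PDB file (ATOM records only)."""
    with open(path, "w") as fh:
        for i in range(len(protein)):
            name = protein.names[i]
            pad = name if len(name) >= 4 else f" {name:<3}"
            fh.write(_PDB_LINE.format(
                rec="ATOM", serial=i + 1, name=pad, alt=" ",
                resname=protein.resnames[i], chain=protein.chains[i],
                resseq=protein.resseqs[i], icode=protein.icodes[i] or " ",
                x=protein.coords[i, 0], y=protein.coords[i, 1],
                z=protein.coords[i, 2], occ=1.0, b=0.0,
                elem=protein.elements[i].upper()) + "\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# candidate SDF output


def write_sdf(candidates, path: str) -> None:
    """Write scored candidates as a V2000 SDF with score data tags.

    Each record carries the docked pose coordinates plus binding_energy,
    pli_score, shape_similarity, iteration and lineage tags.
    """
    if not candidates:
        log.warning("writing empty SDF %s", path)
        with open(path, "w"):
            pass
        return
    writer = Chem.SDWriter(path)
    writer.SetKekulize(True)
    try:
        for cand in candidates:
            if cand.pose is None:
                raise FragGrowError(
                    f"candidate {canonical_smiles(cand.mol)} has no pose")
            mol = Chem.Mol(cand.mol)
            if mol.GetNumConformers() == 0:
                conf = Chem.Conformer(mol.GetNumAtoms())
                mol.AddConformer(conf, assignId=True)
            set_mol_coords(mol, cand.pose.coords)
            mol.SetProp("_Name", canonical_smiles(cand.mol))
            scores = cand.scores
            if scores is not None:
                mol.SetProp("binding_energy", f"{scores.binding_energy:.6f}")
                mol.SetProp("pli_score", f"{scores.pli_score:.6f}")
                mol.SetProp("shape_similarity", f"{scores.shape_similarity:.6f}")
            mol.SetProp("iteration", str(cand.iteration))
            mol.SetProp("lineage", cand.lineage_string())
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str) -> list[Chem.Mol]:
    """Read an SDF into hydrogen-complete molecules with coordinates."""
    import os

    if os.path.getsize(path) == 0:
        return []
    supplier = Chem.SDMolSupplier(path, sanitize=False, removeHs=False)
    out = []
    for mol in supplier:
        if mol is None:
            raise ParseError(f"unreadable record in {path}")
        _sanitize(mol, path)
        mol = Chem.AddHs(mol, addCoords=mol.GetNumConformers() > 0)
        out.append(mol)
    return out
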