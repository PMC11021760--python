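"""Independent brute-force oracles used by the growth tests.

These enumerators are deliberately written against RDKit's *implicit*
hydrogen model (the package's own surgery works on hydrogen-complete
molecules and removes explicit H atoms), so the two paths share no
bookkeeping: sanitization recomputes implicit hydrogen counts after every
graph edit here.
"""

from __future__ import annotations

from rdkit import Chem


def _sites(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def _san_smiles(rw: Chem.RWMol) -> str | None:
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def _rings_ok(smiles: str, lo: int = 3, hi: int = 8) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return all(lo <= len(r) <= hi for r in mol.GetRingInfo().AtomRings())


def direct_products(a_smi: str, b_smi: str) -> set[str]:
    """All single-bond joins of two molecules, by canonical SMILES."""
    a = Chem.MolFromSmiles(a_smi)
    b = Chem.MolFromSmiles(b_smi)
    out = set()
    for ai in _sites(a):
        for bi in _sites(b):
            rw = Chem.RWMol(Chem.CombineMols(a, b))
            rw.AddBond(ai, bi + a.GetNumAtoms(), Chem.BondType.SINGLE)
            for idx in (ai, bi + a.GetNumAtoms()):
                atom = rw.GetAtomWithIdx(idx)
                atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() - 1))
                atom.SetNoImplicit(True)
            smi = _san_smiles(rw)
            if smi is not None:
                out.add(smi)
    return out


def linker_products(a_smi: str, linker_smi: str, b_smi: str,
                    points: tuple[int, int]) -> set[str]:
    """a-linker-b bridges through the linker's two declared attachment
    points, both orientations."""
    out = set()
    p1, p2 = points
    orients = [(p1, p2)] if p1 == p2 else [(p1, p2), (p2, p1)]
    for l1, l2 in orients:
        for half in direct_products_at(a_smi, linker_smi, l1):
            out |= direct_products_at_second(half, b_smi, l2, linker_smi, l1)
    return out


def direct_products_at(a_smi, b_smi, bi) -> set[tuple[str, int]]:
    """Joins of every a-site to the fixed b site; returns (smiles, marker)
    pairs where the marker atom is tagged with an atom map number."""
    a = Chem.MolFromSmiles(a_smi)
    b = Chem.MolFromSmiles(b_smi)
    out = set()
    for ai in _sites(a):
        rw = Chem.RWMol(Chem.CombineMols(a, b))
        for i, atom in enumerate(rw.GetAtoms()):
            atom.SetAtomMapNum(i + 1 if i >= a.GetNumAtoms() else 0)
        rw.AddBond(ai, bi + a.GetNumAtoms(), Chem.BondType.SINGLE)
        for idx in (ai, bi + a.GetNumAtoms()):
            atom = rw.GetAtomWithIdx(idx)
            atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() - 1))
            atom.SetNoImplicit(True)
        smi = _san_smiles(rw)
        if smi is not None:
            out.add(smi)
    return out


def direct_products_at_second(half_smi: str, b_smi: str, l2: int,
                              linker_smi: str, l1: int) -> set[str]:
    """Attach b to the linker's second site inside the half-product (the
    linker atoms carry atom map numbers l+1)."""
    half = Chem.MolFromSmiles(half_smi)
    if half is None:
        return set()
    target = None
    for atom in half.GetAtoms():
        if atom.GetAtomMapNum() == l2 + 1:
            target = atom.GetIdx()
    if target is None:
        return set()
    if half.GetAtomWithIdx(target).GetTotalNumHs() < 1:
        return set()
    b = Chem.MolFromSmiles(b_smi)
    out = set()
    for bi in _sites(b):
        rw = Chem.RWMol(Chem.CombineMols(half, b))
        rw.AddBond(target, bi + half.GetNumAtoms(), Chem.BondType.SINGLE)
        for idx in (target, bi + half.GetNumAtoms()):
            atom = rw.GetAtomWithIdx(idx)
            atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() - 1))
            atom.SetNoImplicit(True)
        for atom in rw.GetAtoms():
            atom.SetAtomMapNum(0)
        smi = _san_smiles(rw)
        if smi is not None:
            out.add(smi)
    return out


def fuse_products(a_smi: str, b_smi: str) -> set[str]:
    """All bond-on-bond ring fusions (identical elements, both mappings)."""
    a = Chem.MolFromSmiles(a_smi)
    b = Chem.MolFromSmiles(b_smi)
    out = set()
    a_bonds = [bd for bd in a.GetBonds() if bd.IsInRing()]
    b_bonds = [bd for bd in b.GetBonds() if bd.IsInRing()]
    for ba in a_bonds:
        for bb in b_bonds:
            pairs = [((ba.GetBeginAtomIdx(), ba.GetEndAtomIdx()),
                      (bb.GetBeginAtomIdx(), bb.GetEndAtomIdx())),
                     ((ba.GetBeginAtomIdx(), ba.GetEndAtomIdx()),
                      (bb.GetEndAtomIdx(), bb.GetBeginAtomIdx()))]
            for (a1, a2), (b1, b2) in pairs:
                smi = _fuse_once(a, b, a1, a2, b1, b2)
                if smi is not None and _rings_ok(smi):
                    out.add(smi)
    return out


def _fuse_once(a, b, a1, a2, b1, b2):
    for bsrc, atgt in ((b1, a1), (b2, a2)):
        if b.GetAtomWithIdx(bsrc).GetAtomicNum() != \
                a.GetAtomWithIdx(atgt).GetAtomicNum():
            return None
    n_a = a.GetNumAtoms()
    rw = Chem.RWMol(Chem.CombineMols(a, b))
    for bsrc, atgt in ((b1, a1), (b2, a2)):
        grafted = 0
        for nbr in b.GetAtomWithIdx(bsrc).GetNeighbors():
            ni = nbr.GetIdx()
            if ni in (b1, b2):
                continue
            if rw.GetBondBetweenAtoms(atgt, ni + n_a) is not None:
                return None
            bond = b.GetBondBetweenAtoms(bsrc, ni)
            rw.AddBond(atgt, ni + n_a, bond.GetBondType())
            grafted += 1
        # each grafted bond consumes one hydrogen of the target atom
        atom = rw.GetAtomWithIdx(atgt)
        budget = a.GetAtomWithIdx(atgt).GetTotalNumHs() - grafted
        if budget < 0:
            return None
        atom.SetNumExplicitHs(budget)
        atom.SetNoImplicit(True)
    for idx in sorted((b1 + n_a, b2 + n_a), reverse=True):
        rw.RemoveAtom(idx)
    return _san_smiles(rw)


def spiro_products(a_smi: str, b_smi: str) -> set[str]:
    """All aliphatic spiro junctions with enough hydrogen budget."""
    a = Chem.MolFromSmiles(a_smi)
    b = Chem.MolFromSmiles(b_smi)
    out = set()
    a_atoms = [at.GetIdx() for at in a.GetAtoms()
               if at.IsInRing() and not at.GetIsAromatic()
               and at.GetTotalNumHs() >= 2]
    b_atoms = [at.GetIdx() for at in b.GetAtoms()
               if at.IsInRing() and not at.GetIsAromatic()
               and at.GetTotalNumHs() >= 2]
    for aa in a_atoms:
        for bb in b_atoms:
            n_a = a.GetNumAtoms()
            rw = Chem.RWMol(Chem.CombineMols(a, b))
            failed = False
            grafted = 0
            for nbr in b.GetAtomWithIdx(bb).GetNeighbors():
                bond = b.GetBondBetweenAtoms(bb, nbr.GetIdx())
                if rw.GetBondBetweenAtoms(aa, nbr.GetIdx() + n_a) is not None:
                    failed = True
                    break
                rw.AddBond(aa, nbr.GetIdx() + n_a, bond.GetBondType())
                grafted += 1
            budget = a.GetAtomWithIdx(aa).GetTotalNumHs() - grafted
            if failed or budget < 0:
                continue
            atom = rw.GetAtomWithIdx(aa)
            atom.SetNumExplicitHs(budget)
            atom.SetNoImplicit(True)
            rw.RemoveAtom(bb + n_a)
            smi = _san_smiles(rw)
            if smi is not None and _rings_ok(smi):
                out.add(smi)
    return out
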