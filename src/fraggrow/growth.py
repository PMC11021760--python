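"""Fragment linking rules: direct bond, linker bridge, ring fusion, spiro.

All molecules are hydrogen-complete; a linking operation removes explicit
hydrogens to free valence, performs the graph surgery, and sanitizes the
product.  Products that fail valence/aromaticity perception are *rejected*
(``None`` is returned), not raised — illegal inputs (no free valence,
non-ring bond where a ring bond is required) raise instead.

Every operation also returns index maps from the product's atoms back to
its inputs so that poses and provenance can be inherited downstream.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from rdkit import Chem

from .chemio import (ChemistryError, FragGrowError, ParseError, Pose,
                     canonical_smiles, parse_molecule)
from .config import GrowthRules

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fragments


@dataclass
class Fragment:
    """A library fragment with marked or implicit attachment points."""

    mol: Chem.Mol
    attachment_points: tuple[int, ...]
    role: str = "building_block"  # probe | building_block | linker
    frag_id: str = ""
    #: original-ligand atom indices (set by ligand fragmentation)
    source_atoms: tuple[int, ...] = ()
    #: crystal-frame coordinates per atom (set by ligand fragmentation)
    crystal_pose: Pose | None = None

    def __post_init__(self):
        if self.role == "linker" and len(self.attachment_points) != 2:
            raise FragGrowError(
                f"linker fragment {self.frag_id!r} must have exactly 2 "
                f"attachment points, got {len(self.attachment_points)}")
        for i in self.attachment_points:
            if _free_valence(self.mol.GetAtomWithIdx(i)) < 1:
                raise FragGrowError(
                    f"attachment atom {i} of {self.frag_id!r} has no free "
                    "valence")

    @property
    def smiles(self) -> str:
        return canonical_smiles(self.mol)


def _free_valence(atom: Chem.Atom) -> int:
    return atom.GetTotalNumHs(includeNeighbors=True)


def _h_neighbor(mol: Chem.Mol, idx: int) -> int:
    for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
        if nbr.GetAtomicNum() == 1:
            return nbr.GetIdx()
    raise ChemistryError(f"atom {idx} has no hydrogen / free valence")


def fragment_from_smiles(smiles: str, role: str = "building_block",
                         frag_id: str = "") -> Fragment:
    """Build a Fragment from a SMILES string.

    ``[*]`` dummy atoms mark explicit attachment points and win over the
    implicit any-H-bearing-atom convention; dummies are replaced by H.
    """
    raw = Chem.MolFromSmiles(smiles, sanitize=False)
    if raw is None:
        raise ParseError(f"could not parse fragment SMILES {smiles!r}")
    dummies = [a.GetIdx() for a in raw.GetAtoms() if a.GetAtomicNum() == 0]
    explicit: list[int] = []
    if dummies:
        rw = Chem.RWMol(raw)
        for d in dummies:
            nbrs = [n.GetIdx() for n in rw.GetAtomWithIdx(d).GetNeighbors()]
            if len(nbrs) != 1:
                raise ParseError(f"dummy atom with {len(nbrs)} neighbors in "
                                 f"{smiles!r}")
            explicit.append(nbrs[0])
            rw.GetAtomWithIdx(d).SetAtomicNum(1)
        raw = rw.GetMol()
    try:
        Chem.SanitizeMol(raw)
    except Exception as exc:
        raise ChemistryError(f"cannot sanitize fragment {smiles!r}: {exc}")
    mol = Chem.AddHs(raw)
    if explicit:
        # one dummy per attachment: duplicates (two markers on one atom) kept
        points = tuple(sorted(explicit))
    else:
        points = tuple(a.GetIdx() for a in mol.GetAtoms()
                       if a.GetAtomicNum() > 1 and _free_valence(a) >= 1)
        if not points:
            raise FragGrowError(f"fragment {smiles!r} has no attachment point")
        if role == "linker" and len(points) == 1 \
                and _free_valence(mol.GetAtomWithIdx(points[0])) >= 2:
            points = (points[0], points[0])
    return Fragment(mol, points, role=role, frag_id=frag_id or smiles)


def load_fragment_library(path: str) -> list[Fragment]:
    """Read a fragment library: one SMILES per line, optional name, optional
    ``linker`` role token; ``#`` starts a comment."""
    out: list[Fragment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            smiles = tokens[0]
            role = "building_block"
            name = ""
            for tok in tokens[1:]:
                if tok.lower() == "linker":
                    role = "linker"
                elif tok.lower() == "probe":
                    role = "probe"
                else:
                    name = tok
            try:
                out.append(fragment_from_smiles(
                    smiles, role=role, frag_id=name or f"{path}:{ln}"))
            except FragGrowError as exc:
                raise type(exc)(f"{path}:{ln}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# attachment-point enumeration


_DEFAULT_FORBIDDEN = ("[NX3;$(N[CX3]=[OX1])]",)


def enumerate_attachment_points(mol: Chem.Mol,
                                forbidden_smarts=_DEFAULT_FORBIDDEN,
                                symmetry_reduction: bool = True) -> list[int]:
    """Heavy atoms with at least one hydrogen to give up, minus atoms whose
    substitution is forbidden by config (amide N by default).  With symmetry
    reduction, one representative per automorphism-equivalence class."""
    forbidden: set[int] = set()
    for smarts in forbidden_smarts:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"bad forbidden-substitution SMARTS {smarts!r}")
        for match in mol.GetSubstructMatches(patt):
            forbidden.add(match[0])
    sites = [a.GetIdx() for a in mol.GetAtoms()
             if a.GetAtomicNum() > 1 and _free_valence(a) >= 1
             and a.GetIdx() not in forbidden]
    if not symmetry_reduction:
        return sites
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    seen: set[int] = set()
    out = []
    for i in sites:
        if ranks[i] not in seen:
            seen.add(ranks[i])
            out.append(i)
    return out


# ---------------------------------------------------------------------------
# surgery helpers


def _finish(rw: Chem.RWMol, removed: list[int], n_a: int, n_total: int):
    """Remove marked atoms (descending) and compute old->new index maps."""
    for idx in sorted(set(removed), reverse=True):
        rw.RemoveAtom(idx)
    removed_set = set(removed)
    mapping: dict[int, int] = {}
    new = 0
    for old in range(n_total):
        if old in removed_set:
            continue
        mapping[old] = new
        new += 1
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None, None
    Chem.GetSSSR(mol)
    a_map = {old: mapping[old] for old in range(n_a) if old in mapping}
    b_map = {old - n_a: mapping[old] for old in range(n_a, n_total)
             if old in mapping}
    return mol, (a_map, b_map)


def _ring_sizes_ok(mol: Chem.Mol, lo: int, hi: int) -> bool:
    return all(lo <= len(r) <= hi for r in mol.GetRingInfo().AtomRings())


def link_direct(a: Chem.Mol, ai: int, b: Chem.Mol, bi: int):
    """Join two hydrogen-complete molecules with a single bond ai-bi.

    Returns (product, a_map, b_map) or None if sanitization rejects the
    product.  Raises ChemistryError when either site has no free valence.
    """
    if _free_valence(a.GetAtomWithIdx(ai)) < 1:
        raise ChemistryError(f"no free valence at atom {ai}")
    if _free_valence(b.GetAtomWithIdx(bi)) < 1:
        raise ChemistryError(f"no free valence at fragment atom {bi}")
    n_a = a.GetNumAtoms()
    combo = Chem.CombineMols(a, b)
    rw = Chem.RWMol(combo)
    ha = _h_neighbor(a, ai)
    hb = _h_neighbor(b, bi) + n_a
    rw.AddBond(ai, bi + n_a, Chem.BondType.SINGLE)
    mol, maps = _finish(rw, [ha, hb], n_a, combo.GetNumAtoms())
    if mol is None:
        return None
    return mol, maps[0], maps[1]


def link_via_linker(a: Chem.Mol, ai: int, linker: Fragment,
                    b: Chem.Mol, bi: int,
                    orientation: tuple[int, int] | None = None):
    """Bridge two molecules through a two-point linker fragment.

    ``orientation`` selects which linker attachment point bonds to ``a``;
    the caller enumerates both orders for asymmetric linkers.  Returns
    (product, a_map, linker_map, b_map) or None on rejection.
    """
    if len(linker.attachment_points) != 2:
        raise FragGrowError("linker must have exactly 2 attachment points")
    lp1, lp2 = orientation or linker.attachment_points
    step1 = link_direct(a, ai, linker.mol, lp1)
    if step1 is None:
        return None
    m1, a_map, l_map = step1
    step2 = link_direct(m1, l_map[lp2], b, bi)
    if step2 is None:
        return None
    product, m1_map, b_map = step2
    a_map2 = {k: m1_map[v] for k, v in a_map.items() if v in m1_map}
    l_map2 = {k: m1_map[v] for k, v in l_map.items() if v in m1_map}
    return product, a_map2, l_map2, b_map


def fuse_rings(a: Chem.Mol, bond_a: tuple[int, int], b: Chem.Mol,
               bond_b: tuple[int, int], mapping_order: int = 0,
               identical_elements_only: bool = True,
               ring_size_bounds: tuple[int, int] = (3, 8)):
    """Fuse a ring bond of ``b`` onto a ring bond of ``a`` (condensed system).

    The two atoms of ``bond_b`` are identified with the atoms of ``bond_a``;
    ``mapping_order`` selects which of the two possible identifications is
    used.  Returns (product, a_map, b_map) or None if the merge fails
    valence/aromaticity perception or the ring-size guard.
    """
    _require_ring_bond(a, bond_a, "bond_a")
    _require_ring_bond(b, bond_b, "bond_b")
    a1, a2 = bond_a
    b1, b2 = bond_b if mapping_order == 0 else (bond_b[1], bond_b[0])
    for bsrc, atgt in ((b1, a1), (b2, a2)):
        ba, aa = b.GetAtomWithIdx(bsrc), a.GetAtomWithIdx(atgt)
        if identical_elements_only and ba.GetAtomicNum() != aa.GetAtomicNum():
            return None
    n_a = a.GetNumAtoms()
    combo = Chem.CombineMols(a, b)
    rw = Chem.RWMol(combo)
    removed: list[int] = []
    for bsrc, atgt in ((b1, a1), (b2, a2)):
        removed.append(bsrc + n_a)
        a_h_pool = [n.GetIdx() for n in a.GetAtomWithIdx(atgt).GetNeighbors()
                    if n.GetAtomicNum() == 1]
        for nbr in b.GetAtomWithIdx(bsrc).GetNeighbors():
            ni = nbr.GetIdx()
            if ni in (b1, b2):
                continue
            if nbr.GetAtomicNum() == 1:
                removed.append(ni + n_a)
                continue
            bond = b.GetBondBetweenAtoms(bsrc, ni)
            if rw.GetBondBetweenAtoms(atgt, ni + n_a) is not None:
                return None
            if not a_h_pool:
                return None  # no hydrogen left to give up at the target
            removed.append(a_h_pool.pop())
            rw.AddBond(atgt, ni + n_a, bond.GetBondType())
    mol, maps = _finish(rw, removed, n_a, combo.GetNumAtoms())
    if mol is None or not _ring_sizes_ok(mol, *ring_size_bounds):
        return None
    return mol, maps[0], maps[1]


def spiro_join(a: Chem.Mol, atom_a: int, b: Chem.Mol, atom_b: int,
               ring_size_bounds: tuple[int, int] = (3, 8)):
    """Identify a saturated ring atom of ``b`` with one of ``a``, producing a
    spiro junction.  Aromatic atoms are illegal (the rule is restricted to
    aliphatic rings); returns None when the merged valence is impossible.
    """
    for mol, idx, label in ((a, atom_a, "atom_a"), (b, atom_b, "atom_b")):
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetIsAromatic():
            raise ChemistryError(f"{label} is aromatic; spiro junctions are "
                                 "aliphatic only")
        if not atom.IsInRing():
            raise ChemistryError(f"{label} is not a ring atom")
    n_a = a.GetNumAtoms()
    combo = Chem.CombineMols(a, b)
    rw = Chem.RWMol(combo)
    removed = [atom_b + n_a]
    a_h_pool = [n.GetIdx() for n in a.GetAtomWithIdx(atom_a).GetNeighbors()
                if n.GetAtomicNum() == 1]
    for nbr in b.GetAtomWithIdx(atom_b).GetNeighbors():
        ni = nbr.GetIdx()
        if nbr.GetAtomicNum() == 1:
            removed.append(ni + n_a)
            continue
        bond = b.GetBondBetweenAtoms(atom_b, ni)
        if not a_h_pool:
            return None
        removed.append(a_h_pool.pop())
        rw.AddBond(atom_a, ni + n_a, bond.GetBondType())
    mol, maps = _finish(rw, removed, n_a, combo.GetNumAtoms())
    if mol is None or not _ring_sizes_ok(mol, *ring_size_bounds):
        return None
    return mol, maps[0], maps[1]


def _require_ring_bond(mol: Chem.Mol, bond: tuple[int, int], label: str):
    bd = mol.GetBondBetweenAtoms(*bond)
    if bd is None or not bd.IsInRing():
        raise ChemistryError(f"{label} {bond} is not a ring bond")


# ---------------------------------------------------------------------------
# candidates and the grow step


@dataclass
class GrowthStep:
    rule: str
    parent_ids: tuple[int, ...]
    fragment_id: str
    sites: tuple


@dataclass(eq=False)
class Candidate:
    """A grown molecule with its lineage, and (once scored) pose + scores."""

    mol: Chem.Mol
    iteration: int
    step: GrowthStep | None = None
    parents: tuple = ()
    #: per parent: {product atom index -> parent atom index}
    inherited_maps: tuple = ()
    fragment: Fragment | None = None
    fragment_map: dict = field(default_factory=dict)
    pose: Pose | None = None
    scores: object = None
    cand_id: int = -1
    #: (parents, inherited_maps) of duplicate growth routes to the same
    #: canonical structure; explored as extra pose-inheritance origins
    alt_origins: list = field(default_factory=list)

    @property
    def smiles(self) -> str:
        return canonical_smiles(self.mol)

    def lineage_string(self) -> str:
        if self.step is None:
            return f"probe:{self.smiles}"
        parents = ",".join(p.lineage_string() for p in self.parents)
        return (f"{self.step.rule}[{self.step.fragment_id}@"
                f"{self.step.sites}]({parents})")

    def heavy_atom_count(self) -> int:
        return sum(1 for at in self.mol.GetAtoms() if at.GetAtomicNum() > 1)


def replay_lineage(cand: Candidate) -> str:
    """Re-apply the recorded rule to the recorded parents and return the
    canonical string of the rebuilt product (lineage integrity check)."""
    if cand.step is None:
        return cand.smiles
    rule, sites = cand.step.rule, cand.step.sites
    frag = cand.fragment
    a = cand.parents[0].mol
    if rule == "direct":
        res = link_direct(a, sites[0], frag.mol, sites[1])
    elif rule == "linker":
        b = cand.parents[1].mol
        res = link_via_linker(a, sites[0], frag, b, sites[1],
                              orientation=sites[2])
    elif rule == "fuse":
        res = fuse_rings(a, sites[0], frag.mol, sites[1], mapping_order=sites[2])
    elif rule == "spiro":
        res = spiro_join(a, sites[0], frag.mol, sites[1])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if res is None:
        raise FragGrowError("lineage replay produced a rejected product")
    return canonical_smiles(res[0])


def _ring_bonds(mol: Chem.Mol, symmetry_reduction: bool) -> list[tuple[int, int]]:
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
             for b in mol.GetBonds() if b.IsInRing()]
    if not symmetry_reduction:
        return bonds
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    seen, out = set(), []
    for i, j in bonds:
        key = tuple(sorted((ranks[i], ranks[j])))
        if key not in seen:
            seen.add(key)
            out.append((i, j))
    return out


def _spiro_atoms(mol: Chem.Mol, symmetry_reduction: bool) -> list[int]:
    atoms = [a.GetIdx() for a in mol.GetAtoms()
             if a.IsInRing() and not a.GetIsAromatic()
             and a.GetAtomicNum() > 1
             and a.GetTotalNumHs(includeNeighbors=True) >= 2]
    if not symmetry_reduction:
        return atoms
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    seen, out = set(), []
    for i in atoms:
        if ranks[i] not in seen:
            seen.add(ranks[i])
            out.append(i)
    return out


def grow(parents: list[Candidate], library: list[Fragment],
         rules: GrowthRules | None = None,
         pair_context: list[tuple[Candidate, Candidate]] | None = None,
         iteration: int = 1) -> list[Candidate]:
    """Apply every enabled linking rule at every legal site combination.

    The linker rule runs only in probe-probe context (``pair_context``
    supplies co-placed probe pairs).  Products are deduplicated by canonical
    string; each Candidate carries full lineage and pose-inheritance maps.
    """
    if not parents:
        raise FragGrowError("grow() needs at least one parent")
    rules = rules or GrowthRules()
    sym = rules.symmetry_reduction
    building = [f for f in library if f.role != "linker"]
    linkers = [f for f in library if f.role == "linker"]
    seen: dict[str, Candidate] = {}
    tally = {"direct": 0, "linker": 0, "fuse": 0, "spiro": 0, "rejected": 0,
             "duplicate": 0}

    def emit(mol, rule, parent_list, frag, sites, maps, frag_map):
        if mol is None:
            tally["rejected"] += 1
            return
        smi = canonical_smiles(mol)
        if smi in seen:
            tally["duplicate"] += 1
            prev = seen[smi]
            if maps and len(prev.alt_origins) < 8:
                # translate this route's maps into the kept product's atom
                # numbering (same canonical graph, different construction)
                iso = mol.GetSubstructMatch(prev.mol)
                if iso:
                    trans = tuple({kept_i: m_inv[iso[kept_i]]
                                   for kept_i in range(len(iso))
                                   if iso[kept_i] in m_inv}
                                  for m_inv in
                                  ({v: k for k, v in m.items()} for m in maps))
                    origin = (tuple(parent_list), trans)
                    if origin[0] != prev.parents or \
                            origin[1] != prev.inherited_maps:
                        prev.alt_origins.append(origin)
            return
        step = GrowthStep(rule, tuple(p.cand_id for p in parent_list),
                          frag.frag_id, sites)
        # surgery returns {input atom -> product atom}; candidates store the
        # product -> parent orientation for pose inheritance
        inv = tuple({v: k for k, v in m.items()} for m in maps)
        seen[smi] = Candidate(
            mol=mol, iteration=iteration, step=step,
            parents=tuple(parent_list), inherited_maps=inv,
            fragment=frag, fragment_map=frag_map)
        tally[rule] += 1

    for parent in parents:
        if rules.direct:
            sites_a = enumerate_attachment_points(
                parent.mol, rules.forbidden_substitution_smarts, sym)
            for ai in sites_a:
                for frag in building:
                    frag_sites = _reduced_points(frag, sym)
                    for bi in frag_sites:
                        res = _try(link_direct, parent.mol, ai, frag.mol, bi)
                        if res is None:
                            emit(None, "direct", [parent], frag,
                                 (ai, bi), (), {})
                            continue
                        mol, a_map, b_map = res
                        emit(mol, "direct", [parent], frag, (ai, bi),
                             (a_map,), b_map)
        if rules.fuse:
            for bond_a in _ring_bonds(parent.mol, sym):
                for frag in building:
                    for bond_b in _ring_bonds(frag.mol, sym):
                        for order in (0, 1):
                            res = fuse_rings(
                                parent.mol, bond_a, frag.mol, bond_b,
                                mapping_order=order,
                                identical_elements_only=rules.fuse_identical_elements_only,
                                ring_size_bounds=(rules.ring_size_min,
                                                  rules.ring_size_max))
                            if res is None:
                                emit(None, "fuse", [parent], frag,
                                     (bond_a, bond_b, order), (), {})
                                continue
                            mol, a_map, b_map = res
                            emit(mol, "fuse", [parent], frag,
                                 (bond_a, bond_b, order), (a_map,), b_map)
        if rules.spiro:
            for aa in _spiro_atoms(parent.mol, sym):
                for frag in building:
                    for bb in _spiro_atoms(frag.mol, sym):
                        res = spiro_join(parent.mol, aa, frag.mol, bb,
                                         ring_size_bounds=(rules.ring_size_min,
                                                           rules.ring_size_max))
                        if res is None:
                            emit(None, "spiro", [parent], frag, (aa, bb),
                                 (), {})
                            continue
                        mol, a_map, b_map = res
                        emit(mol, "spiro", [parent], frag, (aa, bb),
                             (a_map,), b_map)
    if rules.linker and pair_context:
        for pa, pb in pair_context:
            sites_a = enumerate_attachment_points(
                pa.mol, rules.forbidden_substitution_smarts, sym)
            sites_b = enumerate_attachment_points(
                pb.mol, rules.forbidden_substitution_smarts, sym)
            for frag in linkers:
                p1, p2 = frag.attachment_points
                orients = [(p1, p2)] if p1 == p2 else [(p1, p2), (p2, p1)]
                for orient in orients:
                    for ai in sites_a:
                        for bi in sites_b:
                            res = link_via_linker(pa.mol, ai, frag, pb.mol,
                                                  bi, orientation=orient)
                            if res is None:
                                emit(None, "linker", [pa, pb], frag,
                                     (ai, bi, orient), (), {})
                                continue
                            mol, a_map, l_map, b_map = res
                            emit(mol, "linker", [pa, pb], frag,
                                 (ai, bi, orient), (a_map, b_map), l_map)
    log.info("grow: %s", tally)
    out = list(seen.values())
    for c in out:
        c.grow_tally = tally
    return out


def _reduced_points(frag: Fragment, symmetry_reduction: bool) -> list[int]:
    if not symmetry_reduction:
        return list(frag.attachment_points)
    ranks = list(Chem.CanonicalRankAtoms(frag.mol, breakTies=False))
    seen, out = set(), []
    for i in frag.attachment_points:
        if ranks[i] not in seen:
            seen.add(ranks[i])
            out.append(i)
    return out


def _try(fn, *args):
    try:
        return fn(*args)
    except ChemistryError:
        return None
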