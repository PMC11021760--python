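"""Medicinal-chemistry filtering.

Two passes exist in the pipeline: the per-iteration *core* pass (structural
alerts, allowed elements, ring-size bounds) and the *enhanced* final pass,
which additionally evaluates terminal-group alerts against the acyclic
substituents hanging off ring systems, plus user property bounds (molecular
weight, heavy atoms, rotatable bonds, ring count).

The default rule set lives in ``data/default_alerts.yaml`` and is an
explicit, documented list; users can replace it wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemio import FragGrowError


class FilterConfigError(FragGrowError):
    """Uncompilable user pattern — raised at load time, never mid-run."""


@dataclass(frozen=True)
class AlertPattern:
    name: str
    smarts: str
    severity: str
    pattern: Chem.Mol = field(repr=False, compare=False, default=None)


@dataclass
class FilterRuleSet:
    structural_alerts: list[AlertPattern]
    terminal_alerts: list[AlertPattern]
    allowed_elements: frozenset[str]
    ring_size_min: int
    ring_size_max: int
    mw_max: float
    heavy_atoms_max: int
    rotatable_bonds_max: int
    ring_count_max: int

    def __post_init__(self):
        if self.ring_size_min > self.ring_size_max:
            raise FilterConfigError("ring size bounds out of order")


@dataclass
class FilterResult:
    passed: bool
    violations: list[tuple[str, tuple[int, ...]]]

    def __post_init__(self):
        assert self.passed == (not self.violations)


def _compile(name: str, spec: dict) -> AlertPattern:
    patt = Chem.MolFromSmarts(spec["smarts"])
    if patt is None:
        raise FilterConfigError(f"alert {name!r}: bad SMARTS {spec['smarts']!r}")
    return AlertPattern(name, spec["smarts"], spec.get("severity", "reject"),
                        patt)


def load_rules(path: str | Path | None = None) -> FilterRuleSet:
    path = path or Path(__file__).parent / "data" / "default_alerts.yaml"
    with open(path) as fh:
        data = yaml.safe_load(fh)
    bounds = data.get("property_bounds", {})
    return FilterRuleSet(
        structural_alerts=[_compile(k, v)
                           for k, v in data.get("structural_alerts", {}).items()],
        terminal_alerts=[_compile(k, v)
                         for k, v in data.get("terminal_alerts", {}).items()],
        allowed_elements=frozenset(data.get("allowed_elements",
                                            ["C", "H", "N", "O", "S", "F",
                                             "Cl", "Br"])),
        ring_size_min=int(data.get("ring_size_min", 3)),
        ring_size_max=int(data.get("ring_size_max", 8)),
        mw_max=float(bounds.get("mw_max", 550.0)),
        heavy_atoms_max=int(bounds.get("heavy_atoms_max", 40)),
        rotatable_bonds_max=int(bounds.get("rotatable_bonds_max", 10)),
        ring_count_max=int(bounds.get("ring_count_max", 6)),
    )


def count_rotatable_bonds(mol: Chem.Mol) -> int:
    """Rotatable bond: any single non-ring bond between two non-terminal
    heavy atoms, excluding amide C-N bonds."""
    amide = Chem.MolFromSmarts("[CX3](=[OX1])-[NX3]")
    amide_bonds = set()
    for match in mol.GetSubstructMatches(amide):
        c, _, n = match
        amide_bonds.add(frozenset((c, n)))
    count = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        if _heavy_degree(a) < 2 or _heavy_degree(b) < 2:
            continue  # terminal atom
        if frozenset((a.GetIdx(), b.GetIdx())) in amide_bonds:
            continue
        count += 1
    return count


def _heavy_degree(atom: Chem.Atom) -> int:
    return sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1)


def terminal_atoms(mol: Chem.Mol) -> set[int]:
    """Atoms of the terminal acyclic substituents: non-ring atoms that are
    not on a path between two ring systems (i.e. each acyclic connected
    piece touching at most one ring attachment)."""
    ring_atoms = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
    if not ring_atoms:
        return {a.GetIdx() for a in mol.GetAtoms()}
    acyclic = [a.GetIdx() for a in mol.GetAtoms()
               if a.GetIdx() not in ring_atoms]
    # connected components of the acyclic subgraph
    comp: dict[int, int] = {}
    for i in acyclic:
        if i in comp:
            continue
        stack, cid = [i], i
        while stack:
            j = stack.pop()
            if j in comp:
                continue
            comp[j] = cid
            for n in mol.GetAtomWithIdx(j).GetNeighbors():
                if n.GetIdx() not in ring_atoms:
                    stack.append(n.GetIdx())
    anchors: dict[int, set[int]] = {}
    for j, cid in comp.items():
        for n in mol.GetAtomWithIdx(j).GetNeighbors():
            if n.GetIdx() in ring_atoms:
                anchors.setdefault(cid, set()).add(n.GetIdx())
    return {j for j, cid in comp.items() if len(anchors.get(cid, set())) <= 1}


def apply_mcf(mol: Chem.Mol, rules: FilterRuleSet,
              mode: str = "core") -> FilterResult:
    """Evaluate all alerts; ``enhanced`` mode adds terminal-group alerts and
    property bounds.  Every violation is listed, not just the first."""
    if mode not in ("core", "enhanced"):
        raise ValueError(f"unknown filter mode {mode!r}")
    violations: list[tuple[str, tuple[int, ...]]] = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in rules.allowed_elements:
            violations.append((f"element:{atom.GetSymbol()}", (atom.GetIdx(),)))
    for ring in mol.GetRingInfo().AtomRings():
        if not rules.ring_size_min <= len(ring) <= rules.ring_size_max:
            violations.append((f"ring_size:{len(ring)}", tuple(ring)))
    for alert in rules.structural_alerts:
        for match in mol.GetSubstructMatches(alert.pattern):
            violations.append((alert.name, tuple(match)))
    if mode == "enhanced":
        term = terminal_atoms(mol)
        for alert in rules.terminal_alerts:
            for match in mol.GetSubstructMatches(alert.pattern):
                heavy = tuple(i for i in match
                              if mol.GetAtomWithIdx(i).GetAtomicNum() > 1)
                if heavy and all(i in term for i in heavy):
                    violations.append((f"terminal:{alert.name}", tuple(match)))
        mw = Descriptors.MolWt(mol)
        if mw > rules.mw_max:
            violations.append((f"mw:{mw:.1f}>{rules.mw_max}", ()))
        n_heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
        if n_heavy > rules.heavy_atoms_max:
            violations.append((f"heavy_atoms:{n_heavy}", ()))
        nrot = count_rotatable_bonds(mol)
        if nrot > rules.rotatable_bonds_max:
            violations.append((f"rotatable_bonds:{nrot}", ()))
        nring = mol.GetRingInfo().NumRings()
        if nring > rules.ring_count_max:
            violations.append((f"ring_count:{nring}", ()))
    return FilterResult(passed=not violations, violations=violations)
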