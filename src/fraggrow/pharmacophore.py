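"""Ligand pharmacophore features and the geometric satisfaction switches.

The same typing rules and distance/angle windows are used by probe
placement, the empirical energy, the PLI score and the interaction
fingerprints, so there is a single source of truth for what counts as an
interaction.

Feature kinds on the ligand side: ``donor`` (polar X-H, one feature per
hydrogen), ``acceptor`` (O/N with an available lone pair), ``aromatic_ring``
and ``hydrophobic`` (apolar carbon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .config import GeometricWindows
from .geom import angle_deg, plane_fit, unit

# Acceptor typing: carbonyl / hydroxyl / ether / anionic O, pyridine-type and
# imine N, nitrile N.  Amide N, pyrrole-type N and charged N are excluded.
ACCEPTOR_SMARTS = (
    "[OX1]",
    "[OX2;!$([OX2][Si])]",
    "[O-]",
    "[nX2+0]",
    "[NX2+0;$([NX2]=[C,N])]",
    "[NX1+0]",
)

_HYDROPHOBIC_PATTERN = "[#6;!$([#6]~[#7,#8,#16,#15,F,Cl,Br,I])]"


@dataclass(frozen=True)
class LigandFeature:
    """A pharmacophore feature defined on molecule atom indices.

    ``atoms`` is the heavy atom (donor/acceptor/hydrophobic) or the ring
    atoms (aromatic_ring); ``h_atom`` is the donor hydrogen where relevant.
    """

    kind: str
    atoms: tuple[int, ...]
    h_atom: int | None = None

    def anchor(self, coords: np.ndarray) -> np.ndarray:
        if self.kind == "aromatic_ring":
            return coords[list(self.atoms)].mean(axis=0)
        return coords[self.atoms[0]]

    def direction(self, coords: np.ndarray,
                  neighbor_idx: tuple[int, ...] = ()) -> np.ndarray | None:
        """Unit direction of the feature in the given coordinate frame."""
        if self.kind == "donor":
            return unit(coords[self.h_atom] - coords[self.atoms[0]])
        if self.kind == "aromatic_ring":
            _, normal = plane_fit(coords[list(self.atoms)])
            return normal
        if self.kind == "acceptor":
            if not neighbor_idx:
                return None
            v = np.zeros(3)
            a = coords[self.atoms[0]]
            for n in neighbor_idx:
                v -= unit(coords[n] - a)
            norm = np.linalg.norm(v)
            return v / norm if norm > 1e-8 else None
        return None


def ligand_features(mol: Chem.Mol) -> list[LigandFeature]:
    """Detect donors, acceptors, aromatic rings and hydrophobic carbons.

    Deterministic ordering by (kind, atom indices).
    """
    feats: list[LigandFeature] = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in (7, 8, 16):
            for nbr in atom.GetNeighbors():
                if nbr.GetAtomicNum() == 1:
                    feats.append(LigandFeature("donor", (atom.GetIdx(),),
                                               h_atom=nbr.GetIdx()))
    seen_acc: set[int] = set()
    for smarts in ACCEPTOR_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        for (idx,) in mol.GetSubstructMatches(patt):
            if idx not in seen_acc:
                seen_acc.add(idx)
                feats.append(LigandFeature("acceptor", (idx,)))
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            feats.append(LigandFeature("aromatic_ring", tuple(sorted(ring))))
    patt = Chem.MolFromSmarts(_HYDROPHOBIC_PATTERN)
    for (idx,) in mol.GetSubstructMatches(patt):
        feats.append(LigandFeature("hydrophobic", (idx,)))
    feats.sort(key=lambda f: (f.kind, f.atoms))
    return feats


def acceptor_neighbors(mol: Chem.Mol, idx: int) -> tuple[int, ...]:
    """Heavy neighbors of an acceptor atom (for the lone-pair direction)."""
    return tuple(n.GetIdx() for n in mol.GetAtomWithIdx(idx).GetNeighbors()
                 if n.GetAtomicNum() > 1)


#: ligand feature kind matching each hotspot kind
COMPLEMENT = {
    "hb_donor": "acceptor",
    "hb_acceptor": "donor",
    "aromatic_ring": "aromatic_ring",
    "hydrophobic_patch": "hydrophobic",
}


def _tri(x: float, window) -> float:
    lo, ideal, hi = window
    if x <= lo or x >= hi:
        return 0.0
    return (x - lo) / (ideal - lo) if x < ideal else (hi - x) / (hi - ideal)


def _angle_taper(dev: float, max_dev: float) -> float:
    return max(0.0, 1.0 - dev / max_dev)


def hb_switch(donor_anchor: np.ndarray, donor_dir: np.ndarray,
              acceptor_pos: np.ndarray, windows: GeometricWindows) -> float:
    """Geometric H-bond satisfaction in [0, 1].

    Distance is donor-heavy to acceptor-heavy; the angular term measures the
    deviation of the donor H direction from the donor->acceptor axis (a
    deviation of ``hb_angle_max`` corresponds to the 120 deg D-H...A limit).
    """
    d = float(np.linalg.norm(acceptor_pos - donor_anchor))
    gd = _tri(d, windows.hb_dist)
    if gd == 0.0:
        return 0.0
    dev = angle_deg(donor_dir, acceptor_pos - donor_anchor)
    return gd * _angle_taper(dev, windows.hb_angle_max)


def aromatic_switch(c1: np.ndarray, n1: np.ndarray, c2: np.ndarray,
                    n2: np.ndarray, windows: GeometricWindows) -> float:
    """Ring-ring satisfaction: stacked (parallel) or T-shaped geometry."""
    d = float(np.linalg.norm(c2 - c1))
    gd = _tri(d, windows.aromatic_dist)
    if gd == 0.0:
        return 0.0
    alpha = angle_deg(n1, n2)
    alpha = min(alpha, 180.0 - alpha)
    stack = _angle_taper(alpha, windows.aromatic_stack_max)
    t_lo, t_hi = windows.aromatic_t_range
    tshape = 0.0
    if alpha >= t_lo:
        tshape = min(1.0, (alpha - t_lo) / (t_hi - t_lo))
    return gd * max(stack, tshape)


def hydrophobic_switch(patch: np.ndarray, carbon: np.ndarray,
                       windows: GeometricWindows) -> float:
    return _tri(float(np.linalg.norm(carbon - patch)), windows.hydrophobic_dist)


def satisfaction(hotspot, feature: LigandFeature, mol: Chem.Mol,
                 coords: np.ndarray, windows: GeometricWindows) -> float:
    """Degree in [0, 1] to which a ligand feature satisfies a hotspot."""
    kind = hotspot.kind
    if COMPLEMENT[kind] != feature.kind:
        return 0.0
    if kind == "hb_donor":
        return hb_switch(hotspot.anchor, hotspot.direction,
                         feature.anchor(coords), windows)
    if kind == "hb_acceptor":
        d_anchor = feature.anchor(coords)
        d_dir = feature.direction(coords)
        d = float(np.linalg.norm(hotspot.anchor - d_anchor))
        gd = _tri(d, windows.hb_dist)
        if gd == 0.0:
            return 0.0
        dev = angle_deg(d_dir, hotspot.anchor - d_anchor)
        return gd * _angle_taper(dev, windows.hb_angle_max)
    if kind == "aromatic_ring":
        c2 = feature.anchor(coords)
        n2 = feature.direction(coords)
        return aromatic_switch(hotspot.anchor, hotspot.direction, c2, n2,
                               windows)
    if kind == "hydrophobic_patch":
        return hydrophobic_switch(hotspot.anchor, feature.anchor(coords),
                                  windows)
    raise ValueError(f"unknown hotspot kind {kind!r}")
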