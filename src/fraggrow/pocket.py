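"""Binding-site definition and typed hotspot detection.

The pocket is defined from the position of a reference ligand: every residue
with a heavy atom within a cutoff (default 5 Å) of a reference heavy atom is
a member.  Hotspots are the protein's interaction anchors inside that shell:
hydrogen-bond donors (polar X-H), acceptors (O/N with an available lone
pair), aromatic side-chain rings (His/Phe/Tyr/Trp) and hydrophobic patches
(clusters of apolar carbons).

The typing rules are this package's own convention (documented in the
methods note); they are driven by the tables in :mod:`fraggrow.config`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .chemio import FragGrowError, Pose, ProteinStructure
from .config import AROMATIC_RING_ATOMS, HotspotParams
from .geom import plane_fit, unit

log = logging.getLogger(__name__)

HOTSPOT_KINDS = ("hb_donor", "hb_acceptor", "aromatic_ring", "hydrophobic_patch")

#: element written for each hotspot kind in the pseudo-atom PDB dump
_DUMP_ELEMENT = {"hb_donor": "N", "hb_acceptor": "O",
                 "aromatic_ring": "C", "hydrophobic_patch": "S"}


@dataclass(frozen=True)
class Hotspot:
    kind: str
    anchor: np.ndarray
    direction: np.ndarray
    residue: tuple[str, int, str]

    def __post_init__(self):
        object.__setattr__(self, "anchor", np.asarray(self.anchor, float))
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("hotspot direction must be unit-norm")
        object.__setattr__(self, "direction", d)


@dataclass
class Pocket:
    protein: ProteinStructure
    residue_keys: list[tuple]
    atom_indices: list[int]
    bbox_min: np.ndarray
    bbox_max: np.ndarray
    reference: Pose | None = None
    hotspots: list[Hotspot] | None = field(default=None, repr=False)

    @property
    def member_coords(self) -> np.ndarray:
        return self.protein.coords[self.atom_indices]

    @property
    def centroid(self) -> np.ndarray:
        return self.member_coords.mean(axis=0)

    def interior_point(self) -> np.ndarray:
        """Reference-ligand centroid if known, else the member centroid."""
        if self.reference is not None:
            return self.reference.heavy_coords().mean(axis=0)
        return self.centroid

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        p = np.atleast_2d(points)
        lo, hi = self.bbox_min - margin, self.bbox_max + margin
        return np.all((p >= lo) & (p <= hi), axis=1)


def extract_pocket(protein: ProteinStructure, reference: Pose,
                   cutoff: float = 5.0) -> Pocket:
    """Select every residue with a heavy atom within `cutoff` Å of any
    reference-ligand heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ref_xyz = reference.heavy_coords()
    if len(ref_xyz) == 0:
        raise FragGrowError("reference ligand has no heavy atoms")
    heavy = protein.heavy_mask()
    dmat = cdist(protein.coords, ref_xyz)
    near = (dmat.min(axis=1) <= cutoff) & heavy
    member_keys: list[tuple] = []
    seen = set()
    for i in np.flatnonzero(near):
        key = protein.residue_key(int(i))
        if key not in seen:
            seen.add(key)
            member_keys.append(key)
    if not member_keys:
        raise FragGrowError("reference outside protein: empty pocket selection")
    member_keys.sort()
    atom_indices = [i for key in member_keys for i in protein.residues[key]]
    xyz = protein.coords[atom_indices]
    return Pocket(protein, member_keys, atom_indices,
                  xyz.min(axis=0), xyz.max(axis=0), reference=reference)


# ---------------------------------------------------------------------------
# hotspot detection


def _residue_bonds(protein: ProteinStructure, idx: list[int],
                   params: HotspotParams) -> dict[int, list[int]]:
    """Distance-based intra-residue bond inference."""
    xyz = protein.coords[idx]
    d = cdist(xyz, xyz)
    nbrs: dict[int, list[int]] = {i: [] for i in idx}
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            ea = protein.elements[idx[a]]
            eb = protein.elements[idx[b]]
            limit = params.xh_bond_max if "H" in (ea, eb) else 1.95
            if "H" == ea and "H" == eb:
                continue
            if d[a, b] <= limit:
                nbrs[idx[a]].append(idx[b])
                nbrs[idx[b]].append(idx[a])
    return nbrs


def detect_hotspots(pocket: Pocket,
                    params: HotspotParams | None = None) -> list[Hotspot]:
    """Type the pocket's interaction anchors.

    Donors: N/O/S with a bound hydrogen, direction along the X-H bond.
    Acceptors: O always (carbonyl, hydroxyl, ether, carboxylate); N without
    hydrogens and with two heavy neighbors (pyridine-type); direction is the
    lone-pair bisector (away from the bonded heavy atoms).  Aromatic rings:
    centroid + normal of His/Phe/Tyr/Trp side-chain rings, normal signed
    toward the pocket interior.  Hydrophobic patches: centroids of clusters
    of >= 3 mutually near apolar carbons.

    Output is deterministically ordered by (residue key, kind, anchor).
    """
    params = params or HotspotParams()
    protein = pocket.protein
    interior = pocket.interior_point()
    spots: list[Hotspot] = []
    for key in pocket.residue_keys:
        idx = protein.residues[key]
        nbrs = _residue_bonds(protein, idx, params)
        resname = protein.resnames[idx[0]]
        spots.extend(_polar_spots(protein, idx, nbrs, key, interior))
        ring = _aromatic_spot(protein, idx, resname, key, interior)
        if ring is not None:
            spots.append(ring)
    if params.include_hydrophobic:
        spots.extend(_hydrophobic_spots(pocket, params, interior))
    if not spots:
        log.warning("no hotspots detected in pocket")
    spots.sort(key=lambda h: (h.residue, h.kind, tuple(np.round(h.anchor, 6))))
    return spots


def _polar_spots(protein, idx, nbrs, key, interior):
    out = []
    for i in idx:
        el = protein.elements[i]
        if el not in ("N", "O", "S"):
            continue
        h_nbrs = [j for j in nbrs[i] if protein.elements[j] == "H"]
        heavy_nbrs = [j for j in nbrs[i] if protein.elements[j] != "H"]
        for h in h_nbrs:
            out.append(Hotspot(
                "hb_donor", protein.coords[i],
                unit(protein.coords[h] - protein.coords[i]), key))
        is_acceptor = False
        if el == "O":
            is_acceptor = True
        elif el == "N" and not h_nbrs and len(heavy_nbrs) >= 2:
            is_acceptor = True  # pyridine-type N (e.g. His without H)
        if is_acceptor:
            v = np.zeros(3)
            for j in heavy_nbrs:
                v -= unit(protein.coords[j] - protein.coords[i])
            if np.linalg.norm(v) < 1e-8:
                v = interior - protein.coords[i]
            if np.linalg.norm(v) < 1e-8:
                continue
            out.append(Hotspot("hb_acceptor", protein.coords[i], unit(v), key))
    return out


def _aromatic_spot(protein, idx, resname, key, interior):
    wanted = AROMATIC_RING_ATOMS.get(resname)
    if not wanted:
        return None
    positions = []
    for name in wanted:
        found = [i for i in idx if protein.names[i] == name]
        if not found:
            return None
        positions.append(protein.coords[found[0]])
    centroid, normal = plane_fit(np.array(positions))
    if np.dot(normal, interior - centroid) < 0:
        normal = -normal
    return Hotspot("aromatic_ring", centroid, normal, key)


def _hydrophobic_spots(pocket, params, interior):
    protein = pocket.protein
    apolar = []
    for i in pocket.atom_indices:
        if protein.elements[i] != "C":
            continue
        xyz = protein.coords[i]
        near_polar = False
        for j in pocket.atom_indices:
            if protein.elements[j] in ("N", "O", "S") and \
                    np.linalg.norm(protein.coords[j] - xyz) < 1.95:
                near_polar = True
                break
        if not near_polar:
            apolar.append(i)
    # leader clustering on mutual distance
    clusters: list[list[int]] = []
    for i in apolar:
        for cl in clusters:
            if all(np.linalg.norm(protein.coords[i] - protein.coords[j])
                   <= params.hydrophobic_cluster_dist for j in cl):
                cl.append(i)
                break
        else:
            clusters.append([i])
    out = []
    for cl in clusters:
        if len(cl) < params.hydrophobic_min_carbons:
            continue
        centroid = protein.coords[cl].mean(axis=0)
        v = interior - centroid
        direction = unit(v) if np.linalg.norm(v) > 1e-8 else np.array([0.0, 0.0, 1.0])
        out.append(Hotspot("hydrophobic_patch", centroid, direction,
                           protein.residue_key(cl[0])))
    return out


def write_hotspot_pdb(hotspots: list[Hotspot], path: str) -> None:
    """Dump hotspots as pseudo-atoms for visual inspection."""
    with open(path, "w") as fh:
        for i, h in enumerate(hotspots, start=1):
            el = _DUMP_ELEMENT[h.kind]
            fh.write(
                f"HETATM{i:>5}  {el:<3}HSP A{i:>4}    "
                f"{h.anchor[0]:>8.3f}{h.anchor[1]:>8.3f}{h.anchor[2]:>8.3f}"
                f"  1.00  0.00          {el:>2}\n")
        fh.write("END\n")
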