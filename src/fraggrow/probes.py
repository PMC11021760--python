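"""Probe placement at pocket hotspots, pose refinement, probe selection.

For every probe conformer and every geometrically feasible pairing of a
probe pharmacophore feature with a complementary hotspot (donor-acceptor,
acceptor-donor, ring-ring), a pose is constructed that realizes the ideal
interaction geometry, then rotations about the interaction axis are
sampled.  Clashing poses are discarded; the survivors are scored by the
pharmacophore score (sum of per-kind-weighted geometric switches over all
matched hotspots) and the empirical binding energy.

Pose refinement is a pluggable contract: the default refiner is a rigid-body
local optimizer of the empirical energy inside a trust region; an external
command-line refiner (e.g. a tight-binding quantum code) can be swapped in
through the same interface.
"""

from __future__ import annotations

import logging
import subprocess
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .chemio import FragGrowError, Pose, heavy_indices
from .config import DockingParams, EnergyParams, PlacementParams
from .geom import apply_rigid, axis_rotation, rotation_between, unit
from .pharmacophore import (COMPLEMENT, acceptor_neighbors, ligand_features,
                            satisfaction)
from .pocket import Hotspot, Pocket
from .score import EnergyModel, make_context, rigid_dock

log = logging.getLogger(__name__)

#: pairings realized during placement (hydrophobic patches contribute to
#: scoring but do not anchor a placement)
_PLACEABLE = ("hb_donor", "hb_acceptor", "aromatic_ring")


@dataclass
class ProbePose:
    mol: object
    pose: Pose
    pharmacophore_score: float
    binding_energy: float
    matched_hotspots: tuple[int, ...]
    clash: bool = False


class PoseRefiner(Protocol):
    """Contract: refine(pose, pocket) -> pose with identical topology and
    energy not above the starting energy (within tolerance)."""

    name: str

    def refine(self, pose: Pose, pocket: Pocket) -> Pose: ...


def _pharmacophore_score(mol, coords, hotspots, model: EnergyModel,
                         features=None) -> tuple[float, tuple[int, ...]]:
    feats = features if features is not None else ligand_features(mol)
    p = model.params
    weight = {"hb_donor": p.w_hb, "hb_acceptor": p.w_hb,
              "aromatic_ring": p.w_aromatic,
              "hydrophobic_patch": p.w_hydrophobic}
    total, matched = 0.0, []
    for i, h in enumerate(hotspots):
        best = 0.0
        for f in feats:
            if COMPLEMENT[h.kind] != f.kind:
                continue
            g = satisfaction(h, f, mol, coords, model.windows)
            if g > best:
                best = g
        if best > 0.0:
            matched.append(i)
            total += weight[h.kind] * best
    return total, tuple(matched)


def _placement_targets(hotspot: Hotspot, windows) -> list[tuple[np.ndarray, np.ndarray]]:
    """(ideal feature anchor point, required feature direction) pairs."""
    if hotspot.kind == "hb_donor":
        d = windows.hb_dist[1]
        return [(hotspot.anchor + d * hotspot.direction, -hotspot.direction)]
    if hotspot.kind == "hb_acceptor":
        d = windows.hb_dist[1]
        return [(hotspot.anchor + d * hotspot.direction, -hotspot.direction)]
    if hotspot.kind == "aromatic_ring":
        d = windows.aromatic_dist[1]
        # stacked on either face; the ring normal sign is arbitrary
        return [(hotspot.anchor + d * hotspot.direction, hotspot.direction),
                (hotspot.anchor + d * hotspot.direction, -hotspot.direction)]
    return []


def enumerate_probe_placements(probe, pocket: Pocket, hotspots: list[Hotspot],
                               n_conformers: int = 5, seed: int = 0,
                               model: EnergyModel | None = None,
                               params: PlacementParams | None = None) -> list[ProbePose]:
    """All feasible feature-hotspot pairings realized as clash-free poses,
    sorted by pharmacophore score (descending), ties by energy (ascending).
    Deterministic under a fixed seed."""
    from .score import generate_conformers

    model = model or EnergyModel()
    params = params or PlacementParams()
    feats_all = ligand_features(probe)
    placeable = [f for f in feats_all
                 if f.kind in ("donor", "acceptor", "aromatic_ring")]
    if not placeable:
        raise FragGrowError("unplaceable probe: no donor/acceptor/aromatic "
                            "feature")
    pairable = {COMPLEMENT[h.kind] for h in hotspots if h.kind in _PLACEABLE}
    if not any(f.kind in pairable for f in placeable):
        log.warning("no complementary hotspot for any probe feature")
        return []
    conformers = generate_conformers(probe, n_conformers, seed)
    ctx = make_context(probe, pocket, model, hotspots)
    heavy = heavy_indices(probe)
    out: list[ProbePose] = []
    angles = np.linspace(0.0, 2 * np.pi, params.n_axis_rotations,
                         endpoint=False)
    for conf in conformers:
        for f in placeable:
            for hi, h in enumerate(hotspots):
                if h.kind not in _PLACEABLE or COMPLEMENT[h.kind] != f.kind:
                    continue
                for point, fdir in _placement_targets(h, model.windows):
                    secondary = pocket.interior_point() - h.anchor
                    coords0 = _orient_feature(conf.coords, heavy, f, probe,
                                              point, fdir, secondary)
                    if coords0 is None:
                        continue
                    axis = fdir
                    anchor = point
                    for ang in angles:
                        R = axis_rotation(axis, float(ang))
                        coords = apply_rigid(coords0, R, np.zeros(3),
                                             center=anchor)
                        if not np.all(pocket.contains(coords[heavy],
                                                      margin=params.pocket_margin)):
                            continue
                        e, clash = ctx.energy(coords)
                        if clash:
                            continue
                        score, matched = _pharmacophore_score(
                            probe, coords, hotspots, model, feats_all)
                        if hi not in matched:
                            continue
                        out.append(ProbePose(probe, Pose(probe, coords),
                                             score, e, matched))
    out.sort(key=lambda p: (-p.pharmacophore_score, p.binding_energy))
    return out


def _orient_feature(coords, heavy, feature, mol, target_point, target_dir,
                    secondary_target):
    """Rigidly move conformer coords so the feature sits at the target with
    the required direction.

    The spin about the interaction axis is fixed by mapping a covariant
    secondary direction of the probe (anchor -> farthest heavy atom) onto a
    covariant secondary direction of the pocket, which makes the placement
    equivariant under rigid transforms of the complex; the axis is then
    swept explicitly by the caller.
    """
    anchor = feature.anchor(coords)
    if feature.kind == "acceptor":
        d = feature.direction(coords,
                              acceptor_neighbors(mol, feature.atoms[0]))
    else:
        d = feature.direction(coords)
    if d is None:
        return None
    rel = coords[heavy] - anchor
    far = rel[np.argmax(np.linalg.norm(rel, axis=1))]
    R = _frame_rotation(d, far, target_dir, secondary_target)
    moved = (coords - anchor) @ R.T
    return moved + target_point


def _frame_rotation(d, p, d2, p2):
    """Rotation mapping the orthonormal frame built on (d, p) onto the one
    built on (d2, p2); falls back to the minimal rotation when a secondary
    direction is degenerate."""
    def frame(a, b):
        a = unit(a)
        b_orth = b - np.dot(b, a) * a
        n = np.linalg.norm(b_orth)
        if n < 1e-8:
            return None
        b_orth /= n
        return np.column_stack([a, b_orth, np.cross(a, b_orth)])

    f1 = frame(d, p)
    f2 = frame(d2, p2)
    if f1 is None or f2 is None:
        return rotation_between(d, d2)
    return f2 @ f1.T


# ---------------------------------------------------------------------------
# refinement


@dataclass
class DefaultRefiner:
    """Rigid-body local optimization of the empirical energy (6 DOF) inside
    a centroid trust region."""

    model: EnergyModel = field(default_factory=EnergyModel)
    params: DockingParams = field(default_factory=DockingParams)
    seed: int = 0
    name: str = "empirical-rigid"

    def refine(self, pose: Pose, pocket: Pocket) -> Pose:
        refined, _, _ = rigid_dock(
            pose, pocket, self.model, seed=self.seed, params=self.params,
            trust_radius=self.params.refine_trust_radius)
        return refined


def default_refine(pose: Pose, pocket: Pocket,
                   model: EnergyModel | None = None, seed: int = 0) -> Pose:
    return DefaultRefiner(model=model or EnergyModel(), seed=seed).refine(
        pose, pocket)


@dataclass
class ExternalRefiner:
    """Adapter that shells out to an external pose refiner executable.

    The executable receives an XYZ file of the probe and one of the pocket
    residues within ``pocket_radius`` of it, and must write refined probe
    coordinates (same atom order, XYZ) plus an energy line to stdout.  Off
    by default; interchangeable with :class:`DefaultRefiner`.
    """

    executable: str
    pocket_radius: float = 8.0
    name: str = "external"
    model: EnergyModel = field(default_factory=EnergyModel)

    def refine(self, pose: Pose, pocket: Pocket) -> Pose:
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as tmp:
            probe_xyz = Path(tmp) / "probe.xyz"
            _write_xyz(probe_xyz, pose.mol, pose.coords)
            pocket_xyz = Path(tmp) / "pocket.xyz"
            _write_pocket_xyz(pocket_xyz, pocket, pose, self.pocket_radius)
            res = subprocess.run(
                [self.executable, str(probe_xyz), str(pocket_xyz)],
                capture_output=True, text=True, check=True)
            coords = _parse_xyz_coords(res.stdout, pose.mol.GetNumAtoms())
        refined = Pose(pose.mol, coords)
        # the contract requires non-increasing energy; fall back otherwise
        ctx = make_context(pose.mol, pocket, self.model, None)
        e_new, _ = ctx.energy(coords)
        e_old, _ = ctx.energy(pose.coords)
        if e_new > e_old + 1e-6:
            return pose
        return refined


def _write_xyz(path, mol, coords):
    with open(path, "w") as fh:
        fh.write(f"{mol.GetNumAtoms()}\n\n")
        for atom, xyz in zip(mol.GetAtoms(), coords):
            fh.write(f"{atom.GetSymbol()} {xyz[0]:.6f} {xyz[1]:.6f} "
                     f"{xyz[2]:.6f}\n")


def _write_pocket_xyz(path, pocket, pose, radius):
    from scipy.spatial.distance import cdist

    protein = pocket.protein
    idx = pocket.atom_indices
    d = cdist(protein.coords[idx], pose.coords).min(axis=1)
    keep = [i for i, di in zip(idx, d) if di <= radius]
    with open(path, "w") as fh:
        fh.write(f"{len(keep)}\n\n")
        for i in keep:
            x, y, z = protein.coords[i]
            fh.write(f"{protein.elements[i]} {x:.6f} {y:.6f} {z:.6f}\n")


def _parse_xyz_coords(text: str, n_atoms: int) -> np.ndarray:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    rows = []
    for ln in lines:
        parts = ln.split()
        if len(parts) == 4:
            try:
                rows.append([float(p) for p in parts[1:]])
            except ValueError:
                continue
    if len(rows) < n_atoms:
        raise FragGrowError("external refiner returned too few coordinates")
    return np.array(rows[:n_atoms], dtype=float)


# ---------------------------------------------------------------------------
# selection


def select_probes(poses: list[ProbePose], k: int,
                  energy_weight: float = 0.2,
                  dedup_rmsd: float = 1.0) -> list[ProbePose]:
    """Rank by pharmacophore_score - energy_weight * binding_energy, dedup
    near-identical poses of the same molecule, return the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not poses:
        raise FragGrowError("no probe poses to select from")

    def combined(p: ProbePose) -> float:
        return p.pharmacophore_score - energy_weight * p.binding_energy

    ranked = sorted(poses, key=lambda p: (-combined(p), p.binding_energy))
    kept: list[ProbePose] = []
    from .chemio import canonical_smiles
    from .score import symmetry_rmsd

    for p in ranked:
        dup = False
        for q in kept:
            if canonical_smiles(p.mol) != canonical_smiles(q.mol):
                continue
            if p.pose.coords.shape == q.pose.coords.shape:
                # symmetry-aware: a rotated copy of a symmetric probe is the
                # same placement
                if symmetry_rmsd(p.mol, p.pose, q.pose) < dedup_rmsd:
                    dup = True
                    break
        if not dup:
            kept.append(p)
        if len(kept) == k:
            return kept
    if len(kept) < k:
        log.warning("probe pool smaller than k (%d < %d)", len(kept), k)
    return kept
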