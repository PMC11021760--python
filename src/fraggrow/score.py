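"""Geometry engine: conformers, alignment, rigid docking and descriptors.

The empirical interaction energy is an explicit surrogate scoring function
(kcal/mol scale, lower is better):

    E = sum_pairs steric(r)  -  sum_hotspots w_kind * g_best  +  clash terms

where ``steric`` is a soft 8-4 Lennard-Jones-like well on ligand-protein
heavy-atom pairs within a cutoff, ``g_best`` is the best geometric-switch
satisfaction of each pocket hotspot by any complementary ligand feature
(shared windows with probe placement and the fingerprints), and hard
overlaps (pair distance below ``clash_factor`` times the vdW contact sum)
add a flat-plus-ramp penalty that pushes the energy above the rejection
threshold.

Rigid docking optimizes the six rigid-body degrees of freedom of a pose by
derivative-free local search (Nelder-Mead) with a few seeded restarts; the
conformation itself is never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .chemio import (FragGrowError, Pose, heavy_indices, mol_coords,
                     set_mol_coords)
from .config import DEFAULT_VDW, VDW_RADII, DockingParams, EnergyParams, \
    GeometricWindows
from .geom import kabsch
from .pharmacophore import acceptor_neighbors, ligand_features
from .pocket import Hotspot, Pocket, detect_hotspots


@dataclass
class ScoreRecord:
    binding_energy: float
    pli_score: float
    shape_similarity: float
    clash_flag: bool = False


@dataclass
class EnergyModel:
    """Parameters + windows of the empirical interaction score."""

    params: EnergyParams = field(default_factory=EnergyParams)
    windows: GeometricWindows = field(default_factory=GeometricWindows)
    vdw: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def radius(self, element: str) -> float:
        return self.vdw.get(element, DEFAULT_VDW)


class _EnergyContext:
    """Precomputed pairing data for one (molecule, pocket) combination.

    Everything index-based is resolved once; the per-call work in
    :meth:`energy` is pure vectorized numpy so the docking optimizer can
    afford hundreds of evaluations per pose.
    """

    def __init__(self, mol: Chem.Mol, pocket: Pocket, model: EnergyModel,
                 hotspots: list[Hotspot] | None):
        self.mol = mol
        self.model = model
        self.heavy = heavy_indices(mol)
        self.lig_radii = np.array([model.radius(mol.GetAtomWithIdx(i).GetSymbol())
                                   for i in self.heavy])
        protein = pocket.protein
        pk_idx = [i for i in pocket.atom_indices if protein.elements[i] != "H"]
        self.pk_xyz = protein.coords[pk_idx]
        self.pk_radii = np.array([model.radius(protein.elements[i])
                                  for i in pk_idx])
        self.r0 = self.lig_radii[:, None] + self.pk_radii[None, :]
        if hotspots is None:
            if pocket.hotspots is None:
                pocket.hotspots = detect_hotspots(pocket)
            hotspots = pocket.hotspots
        self.hotspots = hotspots
        self.features = ligand_features(mol)
        self.acc_nbrs = {f: acceptor_neighbors(mol, f.atoms[0])
                         for f in self.features if f.kind == "acceptor"}
        # ligand feature index arrays
        self.acc_idx = np.array([f.atoms[0] for f in self.features
                                 if f.kind == "acceptor"], dtype=int)
        don = [(f.atoms[0], f.h_atom) for f in self.features
               if f.kind == "donor"]
        self.don_idx = np.array([d[0] for d in don], dtype=int)
        self.don_h = np.array([d[1] for d in don], dtype=int)
        self.rings = [list(f.atoms) for f in self.features
                      if f.kind == "aromatic_ring"]
        self.hyd_idx = np.array([f.atoms[0] for f in self.features
                                 if f.kind == "hydrophobic"], dtype=int)
        # hotspot arrays by kind, remembering original positions
        self._hs_groups: dict[str, tuple[list[int], np.ndarray, np.ndarray]] = {}
        for kind in ("hb_donor", "hb_acceptor", "aromatic_ring",
                     "hydrophobic_patch"):
            idx = [i for i, h in enumerate(hotspots) if h.kind == kind]
            if idx:
                self._hs_groups[kind] = (
                    idx,
                    np.array([hotspots[i].anchor for i in idx]),
                    np.array([hotspots[i].direction for i in idx]))
        p = model.params
        self._weights = np.array([{"hb_donor": p.w_hb, "hb_acceptor": p.w_hb,
                                   "aromatic_ring": p.w_aromatic,
                                   "hydrophobic_patch": p.w_hydrophobic}[h.kind]
                                  for h in hotspots])

    def energy(self, coords: np.ndarray) -> tuple[float, bool]:
        p = self.model.params
        xyz = coords[self.heavy]
        d = cdist(xyz, self.pk_xyz)
        mask = d < p.steric_cutoff
        e = 0.0
        clash = False
        if np.any(mask):
            r = d[mask]
            r0 = self.r0[mask]
            rc = np.maximum(r, 0.6 * r0)  # keep the well finite under overlap
            q = (r0 / rc) ** 4
            e += float(np.sum(p.steric_eps * (q * q - 2.0 * q)))
            over = r < p.clash_factor * r0
            if np.any(over):
                clash = True
                depth = p.clash_factor * r0[over] - r[over]
                e += float(np.sum(p.clash_penalty + p.clash_ramp * depth))
        best = self._hotspot_best_array(coords)
        e -= float(np.dot(self._weights, best)) if len(best) else 0.0
        return e, clash

    def _hotspot_best_array(self, coords: np.ndarray) -> np.ndarray:
        """Best satisfaction per hotspot (vectorized)."""
        w = self.model.windows
        best = np.zeros(len(self.hotspots))
        grp = self._hs_groups.get("hb_donor")
        if grp is not None and len(self.acc_idx):
            idx, anchors, dirs = grp
            acc = coords[self.acc_idx]
            diff = acc[None, :, :] - anchors[:, None, :]
            dist = np.linalg.norm(diff, axis=2)
            gd = _tri_vec(dist, w.hb_dist)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = np.einsum("hd,had->ha", dirs, diff) / \
                    np.maximum(dist, 1e-12)
            dev = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ga = np.maximum(0.0, 1.0 - dev / w.hb_angle_max)
            best[idx] = np.max(gd * ga, axis=1)
        grp = self._hs_groups.get("hb_acceptor")
        if grp is not None and len(self.don_idx):
            idx, anchors, _ = grp
            dh = coords[self.don_idx]
            hh = coords[self.don_h]
            wdir = hh - dh
            wdir /= np.maximum(np.linalg.norm(wdir, axis=1, keepdims=True),
                               1e-12)
            diff = anchors[:, None, :] - dh[None, :, :]
            dist = np.linalg.norm(diff, axis=2)
            gd = _tri_vec(dist, w.hb_dist)
            cosang = np.einsum("ld,hld->hl", wdir, diff) / \
                np.maximum(dist, 1e-12)
            dev = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ga = np.maximum(0.0, 1.0 - dev / w.hb_angle_max)
            best[idx] = np.max(gd * ga, axis=1)
        grp = self._hs_groups.get("aromatic_ring")
        if grp is not None and self.rings:
            idx, anchors, dirs = grp
            cents = np.array([coords[r].mean(axis=0) for r in self.rings])
            normals = np.array([_ring_normal(coords[r]) for r in self.rings])
            diff = cents[None, :, :] - anchors[:, None, :]
            dist = np.linalg.norm(diff, axis=2)
            gd = _tri_vec(dist, w.aromatic_dist)
            cosang = np.abs(np.einsum("hd,rd->hr", dirs, normals))
            alpha = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            stack = np.maximum(0.0, 1.0 - alpha / w.aromatic_stack_max)
            t_lo, t_hi = w.aromatic_t_range
            tshape = np.clip((alpha - t_lo) / (t_hi - t_lo), 0.0, 1.0)
            tshape[alpha < t_lo] = 0.0
            best[idx] = np.max(gd * np.maximum(stack, tshape), axis=1)
        grp = self._hs_groups.get("hydrophobic_patch")
        if grp is not None and len(self.hyd_idx):
            idx, anchors, _ = grp
            dist = cdist(anchors, coords[self.hyd_idx])
            best[idx] = np.max(_tri_vec(dist, w.hydrophobic_dist), axis=1)
        return best

    def hotspot_best(self, coords: np.ndarray) -> dict[int, float]:
        """Best satisfaction per hotspot index (for PLI and fingerprints)."""
        arr = self._hotspot_best_array(coords)
        return {i: float(v) for i, v in enumerate(arr)}


def _tri_vec(x: np.ndarray, window) -> np.ndarray:
    lo, ideal, hi = window
    up = (x - lo) / (ideal - lo)
    down = (hi - x) / (hi - ideal)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def _ring_normal(pts: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    return vt[2]


def make_context(mol: Chem.Mol, pocket: Pocket, model: EnergyModel,
                 hotspots: list[Hotspot] | None = None) -> _EnergyContext:
    return _EnergyContext(mol, pocket, model, hotspots)


def binding_energy(pose: Pose, pocket: Pocket, model: EnergyModel,
                   hotspots: list[Hotspot] | None = None,
                   context: _EnergyContext | None = None) -> float:
    ctx = context or make_context(pose.mol, pocket, model, hotspots)
    e, _ = ctx.energy(pose.coords)
    return e


def energy_and_clash(pose: Pose, pocket: Pocket, model: EnergyModel,
                     context: _EnergyContext | None = None) -> tuple[float, bool]:
    ctx = context or make_context(pose.mol, pocket, model, None)
    return ctx.energy(pose.coords)


# ---------------------------------------------------------------------------
# conformers


def generate_conformers(mol: Chem.Mol, n: int, seed: int) -> list[Pose]:
    """Up to n distinct conformers (pairwise heavy-atom best-RMS >= 0.5 Å),
    deterministic under a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    work = Chem.Mol(mol)
    work.RemoveAllConformers()
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    params.numThreads = 1
    ids = AllChem.EmbedMultipleConfs(work, numConfs=max(n * 2, 4), params=params)
    if len(ids) == 0:
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(work, numConfs=max(n * 2, 4),
                                         params=params)
    if len(ids) == 0:
        raise FragGrowError(
            f"conformer embedding failed for {Chem.MolToSmiles(mol)}")
    try:
        AllChem.MMFFOptimizeMoleculeConfs(work, maxIters=200)
    except Exception:  # pragma: no cover - MMFF missing params
        pass
    noh = Chem.RemoveHs(Chem.Mol(work))
    kept: list[int] = []
    for cid in ids:
        distinct = True
        for prev in kept:
            rms = rdMolAlign.GetBestRMS(Chem.Mol(noh), Chem.Mol(noh),
                                        prbId=cid, refId=prev)
            if rms < 0.5:
                distinct = False
                break
        if distinct:
            kept.append(int(cid))
        if len(kept) >= n:
            break
    return [Pose(mol, mol_coords(work, cid)) for cid in kept]


# ---------------------------------------------------------------------------
# alignment


def align_to_parent(conformer: Pose, parent: Pose,
                    inherited_map: dict[int, int]) -> tuple[Pose, float]:
    """Least-squares rigid superposition of the conformer's inherited heavy
    atoms onto the parent pose.  Returns the transformed pose and residual
    RMSD over the mapped atoms."""
    pairs = [(i, j) for i, j in sorted(inherited_map.items())
             if conformer.mol.GetAtomWithIdx(i).GetAtomicNum() > 1]
    if len(pairs) < 3:
        raise FragGrowError("underdetermined alignment: fewer than 3 mapped "
                            "heavy atoms")
    mobile = conformer.coords[[i for i, _ in pairs]]
    target = parent.coords[[j for _, j in pairs]]
    R, t, rmsd = kabsch(mobile, target)
    moved = conformer.coords @ R.T + t
    return Pose(conformer.mol, moved, R @ conformer.rotation,
                t + conformer.translation), rmsd


# ---------------------------------------------------------------------------
# rigid docking


def _transform_from_x(x: np.ndarray, center: np.ndarray,
                      coords: np.ndarray) -> np.ndarray:
    R = Rotation.from_rotvec(x[3:]).as_matrix()
    return (coords - center) @ R.T + center + x[:3]


def rigid_dock(pose: Pose, pocket: Pocket, model: EnergyModel, seed: int = 0,
               params: DockingParams | None = None,
               context: _EnergyContext | None = None,
               trust_radius: float | None = None) -> tuple[Pose, float, bool]:
    """Local rigid-body (6-DOF) energy optimization with seeded restarts.

    Returns (best pose, energy, clash flag).  The docked energy never
    exceeds the starting energy.  A hard-clash start is not an error: the
    penalty-laden energy is simply the starting point.
    """
    dp = params or DockingParams()
    ctx = context or make_context(pose.mol, pocket, model, None)
    start = pose.coords.copy()
    center = start[heavy_indices(pose.mol)].mean(axis=0)
    e0, clash0 = ctx.energy(start)
    if not np.isfinite(e0):
        raise FragGrowError("non-finite starting energy")

    def objective(x: np.ndarray) -> float:
        coords = _transform_from_x(x, center, start)
        e, _ = ctx.energy(coords)
        if trust_radius is not None:
            disp = float(np.linalg.norm(x[:3]))
            if disp > trust_radius:
                e += 100.0 * (disp - trust_radius) ** 2
        return e

    rng = np.random.default_rng(seed)
    starts = [np.zeros(6)]
    for _ in range(dp.n_restarts):
        t = rng.uniform(-dp.perturb_translation, dp.perturb_translation, 3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(-np.radians(dp.perturb_rotation_deg),
                          np.radians(dp.perturb_rotation_deg))
        starts.append(np.concatenate([t, axis * ang]))
    # explicit initial simplex: 0.3 Å translation / ~6 deg rotation steps
    # (the scipy default shrinks to nothing around a zero start)
    steps = np.array([0.3, 0.3, 0.3, 0.1, 0.1, 0.1])
    best_x, best_e = np.zeros(6), e0
    for x0 in starts:
        simplex = np.vstack([x0] + [x0 + steps[i] * np.eye(6)[i]
                                    for i in range(6)])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": dp.max_iter, "xatol": dp.xatol,
                                "fatol": dp.fatol,
                                "initial_simplex": simplex})
        if res.fun < best_e:
            best_e, best_x = float(res.fun), res.x
    coords = _transform_from_x(best_x, center, start)
    if trust_radius is not None:
        disp = np.linalg.norm(best_x[:3])
        if disp > trust_radius:  # project back onto the trust region
            best_x = best_x.copy()
            best_x[:3] *= trust_radius / disp
            coords = _transform_from_x(best_x, center, start)
    e, clash = ctx.energy(coords)
    if e > e0:  # restarts may only improve
        coords, e, clash = start, e0, clash0
        best_x = np.zeros(6)
    R = Rotation.from_rotvec(best_x[3:]).as_matrix()
    out = Pose(pose.mol, coords, R @ pose.rotation,
               best_x[:3] + pose.translation)
    return out, e, clash


# ---------------------------------------------------------------------------
# descriptors


def pli_score(pose: Pose, pocket: Pocket, hotspots: list[Hotspot] | None,
              model: EnergyModel,
              context: _EnergyContext | None = None) -> float:
    """Weighted fraction of pocket hotspots satisfied by the pose, in [0,1]."""
    ctx = context or make_context(pose.mol, pocket, model, hotspots)
    if not ctx.hotspots:
        return 0.0
    p = model.params
    weight = {"hb_donor": p.w_hb, "hb_acceptor": p.w_hb,
              "aromatic_ring": p.w_aromatic,
              "hydrophobic_patch": p.w_hydrophobic}
    best = ctx.hotspot_best(pose.coords)
    num = sum(weight[h.kind] * best[i] for i, h in enumerate(ctx.hotspots))
    den = sum(weight[h.kind] for h in ctx.hotspots)
    return num / den


def shape_similarity(pose: Pose, reference: Pose,
                     grid_spacing: float = 0.5,
                     model: EnergyModel | None = None) -> float:
    """Tanimoto of occupied-voxel sets of the two poses' vdW volumes."""
    model = model or EnergyModel()
    a_xyz, a_r = _heavy_spheres(pose, model)
    b_xyz, b_r = _heavy_spheres(reference, model)
    rmax = max(a_r.max(), b_r.max())
    lo = np.minimum(a_xyz.min(axis=0), b_xyz.min(axis=0)) - rmax - grid_spacing
    hi = np.maximum(a_xyz.max(axis=0), b_xyz.max(axis=0)) + rmax + grid_spacing
    shape = np.ceil((hi - lo) / grid_spacing).astype(int) + 1
    occ_a = _rasterize(a_xyz, a_r, lo, grid_spacing, shape)
    occ_b = _rasterize(b_xyz, b_r, lo, grid_spacing, shape)
    union = int(np.sum(occ_a | occ_b))
    if union == 0:
        return 1.0
    return float(np.sum(occ_a & occ_b)) / union


def _heavy_spheres(pose: Pose, model: EnergyModel):
    idx = heavy_indices(pose.mol)
    radii = np.array([model.radius(pose.mol.GetAtomWithIdx(i).GetSymbol())
                      for i in idx])
    return pose.coords[idx], radii


def _rasterize(xyz, radii, origin, spacing, shape) -> np.ndarray:
    occ = np.zeros(shape, dtype=bool)
    for p, r in zip(xyz, radii):
        lo_i = np.maximum(((p - r - origin) / spacing).astype(int), 0)
        hi_i = np.minimum(((p + r - origin) / spacing).astype(int) + 2, shape)
        ax = [origin[k] + spacing * np.arange(lo_i[k], hi_i[k])
              for k in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        d2 = (gx - p[0]) ** 2 + (gy - p[1]) ** 2 + (gz - p[2]) ** 2
        occ[lo_i[0]:hi_i[0], lo_i[1]:hi_i[1], lo_i[2]:hi_i[2]] |= d2 <= r * r
    return occ


def symmetry_rmsd(mol: Chem.Mol, a: Pose, b: Pose,
                  max_matches: int = 10000) -> float:
    """Minimum heavy-atom RMSD over graph automorphisms, WITHOUT
    re-superposition: poses are compared in their common (pocket) frame.
    """
    noh = Chem.RemoveHs(Chem.Mol(mol))
    hmap = heavy_indices(mol)
    xa = a.coords[hmap]
    xb = b.coords[hmap]
    matches = noh.GetSubstructMatches(noh, uniquify=False,
                                      maxMatches=max_matches)
    if not matches:
        matches = (tuple(range(noh.GetNumAtoms())),)
    best = np.inf
    for perm in matches:
        d = xa[list(perm)] - xb
        rmsd = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
        if rmsd < best:
            best = rmsd
    return best
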