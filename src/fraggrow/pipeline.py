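"""End-to-end orchestration: placement, iterative growth, benchmark mode.

The generation loop implements the standard fragment-growing cycle: place
and select probes (non-iterative part), then repeat grow -> filter ->
conformers -> align -> rigid dock -> select until the molecular-weight
ceiling or the iteration limit stops growth.  The final output pass applies
the enhanced medicinal-chemistry filters and annotates every record with
binding energy, PLI score and shape similarity.

Benchmark mode fragments a reference ligand by breaking ring-connected
bonds, elects the fragments that hydrogen-bond to the protein in the
crystal geometry as probes, regrows, and reports the pocket-frame
symmetry-aware RMSD of the regrown ligand to its crystal pose:
below 2 Å counts as reproduced, 2-4.5 Å as almost, above 4.5 Å as failed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemio import (FragGrowError, Pose, canonical_smiles, heavy_indices,
                     mol_coords, write_sdf)
from .config import GenerationConfig
from .filters import apply_mcf, count_rotatable_bonds, load_rules
from .growth import Candidate, Fragment, grow
from .ifp import compute_ifp, select_candidates
from .pharmacophore import ligand_features
from .pocket import Pocket, detect_hotspots, extract_pocket
from .probes import (DefaultRefiner, ProbePose, enumerate_probe_placements,
                     select_probes)
from .score import (EnergyModel, ScoreRecord, align_to_parent,
                    generate_conformers, make_context, pli_score, rigid_dock,
                    shape_similarity)

log = logging.getLogger(__name__)


def classify_reproduction(rmsd: float) -> str:
    """<2 Å reproduced; 2-4.5 Å almost; >4.5 Å failed."""
    if rmsd < 2.0:
        return "reproduced"
    if rmsd <= 4.5:
        return "almost"
    return "failed"


# ---------------------------------------------------------------------------
# ligand fragmentation


_AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])-[NX3]")


def _cut_bonds(mol: Chem.Mol) -> list[int]:
    """Acyclic single bonds with >= 1 ring-atom endpoint, exempting amide
    C-N bonds and terminal single-heavy-atom cuts."""
    amide_bonds = set()
    for match in mol.GetSubstructMatches(_AMIDE):
        amide_bonds.add(frozenset((match[0], match[2])))
    cuts = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        if not (a.IsInRing() or b.IsInRing()):
            continue
        if frozenset((a.GetIdx(), b.GetIdx())) in amide_bonds:
            continue
        if min(_side_heavy_count(mol, a.GetIdx(), b.GetIdx()),
               _side_heavy_count(mol, b.GetIdx(), a.GetIdx())) < 2:
            continue  # terminal decoration (methyl, halogen, hydroxyl...)
        cuts.append(bond.GetIdx())
    return cuts


def _side_heavy_count(mol: Chem.Mol, start: int, blocked: int) -> int:
    """Heavy atoms reachable from `start` without crossing `blocked`."""
    seen = {blocked}
    stack = [start]
    count = 0
    while stack:
        i = stack.pop()
        if i in seen:
            continue
        seen.add(i)
        if mol.GetAtomWithIdx(i).GetAtomicNum() > 1:
            count += 1
        for n in mol.GetAtomWithIdx(i).GetNeighbors():
            stack.append(n.GetIdx())
    return count


def fragment_ligand(mol: Chem.Mol) -> list[Fragment]:
    """Fragment by breaking ring-connected bonds; open valences H-capped.

    Each fragment records its source atoms (original-ligand indices) and,
    when the ligand carries coordinates, its crystal-frame pose.  Acyclic
    pieces isolated between two cuts become linker-role fragments.
    """
    n_orig = mol.GetNumAtoms()
    cuts = _cut_bonds(mol)
    if not cuts:
        frag = _make_fragment(mol, list(range(n_orig)), [], mol, 0)
        return [frag]
    fragged = Chem.FragmentOnBonds(mol, cuts, addDummies=True)
    groups = Chem.GetMolFrags(fragged)
    out = []
    for gi, group in enumerate(groups):
        out.append(_extract_fragment(fragged, list(group), n_orig, mol, gi))
    return out


def _extract_fragment(fragged, group, n_orig, source_mol, gi) -> Fragment:
    has_conf = source_mol.GetNumConformers() > 0
    emap = {old: new for new, old in enumerate(group)}
    rw = Chem.RWMol()
    for old in group:
        atom = fragged.GetAtomWithIdx(old)
        a = Chem.Atom(atom.GetAtomicNum() if atom.GetAtomicNum() else 1)
        a.SetFormalCharge(atom.GetFormalCharge())
        rw.AddAtom(a)
    for old in group:
        for nbr in fragged.GetAtomWithIdx(old).GetNeighbors():
            if nbr.GetIdx() in emap and nbr.GetIdx() > old:
                bt = fragged.GetBondBetweenAtoms(old, nbr.GetIdx()).GetBondType()
                if fragged.GetAtomWithIdx(old).GetAtomicNum() == 0 or \
                        nbr.GetAtomicNum() == 0:
                    bt = Chem.BondType.SINGLE
                rw.AddBond(emap[old], emap[nbr.GetIdx()], bt)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    attachment = tuple(sorted(
        emap[n.GetIdx()]
        for old in group if fragged.GetAtomWithIdx(old).GetAtomicNum() == 0
        for n in fragged.GetAtomWithIdx(old).GetNeighbors()))
    source_atoms = tuple(old for old in group if old < n_orig)
    crystal = None
    if has_conf:
        src_xyz = mol_coords(source_mol)
        coords = np.zeros((mol.GetNumAtoms(), 3))
        for old in group:
            if old < n_orig:
                coords[emap[old]] = src_xyz[old]
            else:
                # cap H: place along the broken bond at ~1.09 Å
                nbr = fragged.GetAtomWithIdx(old).GetNeighbors()[0].GetIdx()
                far = mol_coords(fragged)[old]
                near = src_xyz[nbr]
                v = far - near
                norm = np.linalg.norm(v)
                coords[emap[old]] = near + (v / norm * 1.09 if norm > 1e-6
                                            else np.array([1.09, 0, 0]))
        crystal = coords
    role = "building_block"
    if attachment and len(attachment) == 2 and \
            not any(mol.GetAtomWithIdx(i).IsInRing() for i in range(mol.GetNumAtoms())):
        role = "linker"
    points = attachment or tuple(
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetAtomicNum() > 1 and a.GetTotalNumHs(includeNeighbors=True) >= 1)
    frag = Fragment(mol, points, role=role, frag_id=f"frag{gi}",
                    source_atoms=source_atoms)
    if crystal is not None:
        frag.crystal_pose = Pose(mol, crystal)
    return frag


def _make_fragment(mol, group, attachment, source_mol, gi) -> Fragment:
    points = tuple(
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetAtomicNum() > 1 and a.GetTotalNumHs(includeNeighbors=True) >= 1)
    frag = Fragment(Chem.Mol(mol), points, frag_id=f"frag{gi}",
                    source_atoms=tuple(group))
    if mol.GetNumConformers() > 0:
        frag.crystal_pose = Pose(frag.mol, mol_coords(mol))
    return frag


# ---------------------------------------------------------------------------
# run report


@dataclass
class IterationTally:
    iteration: int
    emitted: int = 0
    rule_rejected: int = 0
    rule_duplicates: int = 0
    cross_duplicates: int = 0
    filter_rejected: int = 0
    mw_rejected: int = 0
    embed_failed: int = 0
    scored: int = 0
    selected: int = 0

    def balanced(self) -> bool:
        return self.emitted == (self.cross_duplicates + self.filter_rejected
                                + self.mw_rejected + self.embed_failed
                                + self.scored)


@dataclass
class RunReport:
    seed: int
    iterations: list[IterationTally] = field(default_factory=list)
    n_probes_placed: int = 0
    n_final: int = 0
    final_smiles: list[str] = field(default_factory=list)
    stopped_early: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "n_probes_placed": self.n_probes_placed,
            "n_final": self.n_final,
            "stopped_early": self.stopped_early,
            "iterations": [vars(t) for t in self.iterations],
            "final_smiles": self.final_smiles,
        }, indent=2)


# ---------------------------------------------------------------------------
# generation


def _sub_seed(seed: int, *tags: int) -> int:
    s = seed & 0x7FFFFFFF
    for t in tags:
        s = (s * 1000003 + t + 1) & 0x7FFFFFFF
    return s


class GenerationRun:
    """Stateful driver for one generation run (kept as a class so the
    benchmark and CLI can share the plumbing)."""

    def __init__(self, config: GenerationConfig, *, protein=None,
                 reference: Pose | None = None, probe_library=None,
                 fragment_library=None):
        self.config = config
        self.model = EnergyModel(config.energy, config.windows)
        self.rules = load_rules(config.filter_rule_file)
        if protein is None:
            from .chemio import read_protein
            protein = read_protein(config.protein_path)
        if reference is None:
            from .chemio import read_sdf
            ref_mol = read_sdf(config.reference_ligand_path)[0]
            reference = Pose(ref_mol, mol_coords(ref_mol))
        if probe_library is None:
            from .growth import load_fragment_library
            probe_library = load_fragment_library(config.probe_library_path)
        if fragment_library is None:
            from .growth import load_fragment_library
            fragment_library = load_fragment_library(
                config.fragment_library_path)
        self.protein = protein
        self.reference = reference
        self.probe_library = probe_library
        self.fragment_library = fragment_library
        self.pocket: Pocket = extract_pocket(protein, reference,
                                             config.pocket_cutoff)
        self.pocket.hotspots = detect_hotspots(self.pocket, config.hotspots)
        self._next_id = 0

    # -- probes ------------------------------------------------------------

    def place_probes(self) -> list[Candidate]:
        cfg = self.config
        refiner = DefaultRefiner(model=self.model, params=cfg.docking,
                                 seed=_sub_seed(cfg.seed, 7))
        pool: list[ProbePose] = []
        for pi, probe in enumerate(self.probe_library):
            try:
                placements = enumerate_probe_placements(
                    probe.mol, self.pocket, self.pocket.hotspots,
                    n_conformers=cfg.placement.n_conformers,
                    seed=_sub_seed(cfg.seed, 11, pi), model=self.model,
                    params=cfg.placement)
            except FragGrowError as exc:
                log.warning("probe %s skipped: %s", probe.frag_id, exc)
                continue
            if not placements:
                continue
            # dedup placements (symmetry-aware) before spending refinement
            # effort, so one heavily-sampled site cannot crowd out others
            distinct = select_probes(placements,
                                     k=cfg.placement.refine_top,
                                     energy_weight=cfg.placement.energy_weight,
                                     dedup_rmsd=cfg.placement.dedup_rmsd)
            for pp in distinct:
                refined = refiner.refine(pp.pose, self.pocket)
                ctx = make_context(probe.mol, self.pocket, self.model,
                                   self.pocket.hotspots)
                e, _ = ctx.energy(refined.coords)
                from .probes import _pharmacophore_score
                score, matched = _pharmacophore_score(
                    probe.mol, refined.coords, self.pocket.hotspots,
                    self.model)
                pool.append(ProbePose(probe.mol, refined, score, e, matched))
        if not pool:
            raise FragGrowError("zero placed probes: no complementary "
                                "feature/hotspot pairing succeeded")
        best = select_probes(pool, cfg.k_probes,
                             energy_weight=cfg.placement.energy_weight,
                             dedup_rmsd=cfg.placement.dedup_rmsd)
        out = []
        for pp in best:
            cand = Candidate(mol=pp.mol, iteration=0, pose=pp.pose)
            cand.scores = self._score_record(cand, pp.binding_energy)
            cand.cand_id = self._next_id
            self._next_id += 1
            out.append(cand)
        return out

    # -- scoring -----------------------------------------------------------

    def _score_record(self, cand: Candidate, energy: float,
                      clash: bool = False) -> ScoreRecord:
        pli = pli_score(cand.pose, self.pocket, self.pocket.hotspots,
                        self.model)
        shape = 0.0
        if self.reference is not None:
            shape = shape_similarity(cand.pose, self.reference,
                                     model=self.model)
        return ScoreRecord(binding_energy=energy, pli_score=pli,
                           shape_similarity=shape, clash_flag=clash)

    def _alignment_variants(self, cand: Candidate, cap: int = 24):
        """Target coordinate sets for aligning a child onto its parent
        pose(s), enumerated over parent-graph automorphisms so that a grown
        substituent may occupy any symmetry-equivalent direction."""
        import itertools

        variants = []
        origins = [(cand.parents, cand.inherited_maps)] + list(cand.alt_origins)
        per_origin = max(4, cap // len(origins))
        for origin_idx, (parents, maps) in enumerate(origins):
            per_parent = [_heavy_automorphisms(p.mol, cap=12)
                          for p in parents]
            room = per_origin
            for combo in itertools.islice(itertools.product(*per_parent),
                                          room):
                idxs, targets = [], []
                ok = True
                for parent, pmap, sigma in zip(parents, maps, combo):
                    for prod_i, par_j in sorted(pmap.items()):
                        if cand.mol.GetAtomWithIdx(prod_i).GetAtomicNum() == 1:
                            continue
                        mapped = sigma.get(par_j)
                        if mapped is None:
                            ok = False
                            break
                        idxs.append(prod_i)
                        targets.append(parent.pose.coords[mapped])
                    if not ok:
                        break
                if ok and len(idxs) >= 3:
                    variants.append((idxs, np.array(targets), origin_idx))
        return variants

    def score_candidate(self, cand: Candidate, seed: int) -> bool:
        """Conformers -> align to parent pose -> rigid dock -> descriptors.
        Returns False when embedding fails."""
        cfg = self.config
        try:
            conformers = generate_conformers(cand.mol, cfg.n_conformers, seed)
        except FragGrowError:
            return False
        variants = self._alignment_variants(cand)
        if not variants:
            return False
        ctx = make_context(cand.mol, self.pocket, self.model,
                           self.pocket.hotspots)
        aligned = []
        for conf in conformers:
            for idxs, targets, origin in variants:
                pose, rmsd = _align_to_targets(conf, idxs, targets)
                e, _ = ctx.energy(pose.coords)
                aligned.append((e, rmsd, origin, pose, idxs))
        aligned.sort(key=lambda t: (t[0], t[1], t[2]))
        thresh = self.model.params.clash_energy_threshold
        if aligned[0][0] > thresh:
            # every alignment clashes: try to relieve it by spinning about
            # the anchor axis before giving up on docking
            rescued = []
            seen_origins = set()
            for e0, rmsd, origin, pose, idxs in aligned:
                if origin in seen_origins:
                    continue
                seen_origins.add(origin)
                swept = _anchor_axis_sweep(pose, idxs, ctx)
                e_swept, _ = ctx.energy(swept.coords)
                rescued.append((e_swept, rmsd, origin, swept, idxs))
            rescued.sort(key=lambda t: (t[0], t[1], t[2]))
            if rescued[0][0] > thresh:
                cand.pose = aligned[0][3]
                cand.scores = self._score_record(cand, aligned[0][0],
                                                 clash=True)
                return True
            aligned = rescued
        # dock the best-aligned starts, at most one per growth origin so a
        # single greedy placement cannot monopolize the dock budget
        max_starts = 4
        starts, used_origins, picked = [], set(), set()
        for pos, (e0, _, origin, pose, idxs) in enumerate(aligned):
            if e0 > thresh or len(starts) >= max_starts:
                break
            if origin in used_origins:
                continue
            used_origins.add(origin)
            picked.add(pos)
            starts.append((pose, idxs))
        for pos, (e0, _, origin, pose, idxs) in enumerate(aligned):
            if e0 > thresh or len(starts) >= max_starts:
                break
            if pos not in picked:
                starts.append((pose, idxs))
        if not starts:
            starts = [(aligned[0][3], aligned[0][4])]
        best_pose, best_e, best_clash = None, np.inf, False
        for pose, idxs in starts:
            # a symmetric anchor leaves the spin about its own axis
            # undetermined; scan that spin continuously before docking
            pose = _anchor_axis_sweep(pose, idxs, ctx)
            docked, e, clash = rigid_dock(pose, self.pocket, self.model,
                                          seed=seed, params=cfg.docking,
                                          context=ctx)
            if e < best_e:
                best_pose, best_e, best_clash = docked, e, clash
        if best_pose is None:
            return False
        # coordinate-descent polish: spin about each ring axis, re-dock
        polish = _no_restart_params(cfg.docking)
        for ring in ctx.rings:
            swept = _anchor_axis_sweep(best_pose, ring, ctx)
            if not np.allclose(swept.coords, best_pose.coords):
                docked, e, clash = rigid_dock(swept, self.pocket, self.model,
                                              seed=seed, params=polish,
                                              context=ctx)
                if e < best_e - 1e-9:
                    best_pose, best_e, best_clash = docked, e, clash
        cand.pose = best_pose
        cand.scores = self._score_record(cand, best_e, best_clash)
        return True

    # -- the loop ----------------------------------------------------------

    def run(self) -> tuple[list[Candidate], RunReport]:
        cfg = self.config
        report = RunReport(seed=cfg.seed)
        probes = self.place_probes()
        report.n_probes_placed = len(probes)
        all_scored: list[Candidate] = list(probes)
        seen = {c.smiles for c in probes}
        parents = probes
        for it in range(1, cfg.max_iterations + 1):
            pair_context = None
            if it == 1 and len(probes) > 1:
                pair_context = [(a, b) for i, a in enumerate(probes)
                                for b in probes[i + 1:]
                                if _centroids_close(a, b, 10.0)]
            children = grow(parents, self.fragment_library, cfg.rules,
                            pair_context=pair_context, iteration=it)
            tally = IterationTally(iteration=it)
            if children:
                gt = children[0].grow_tally
                tally.rule_rejected = gt["rejected"]
                tally.rule_duplicates = gt["duplicate"]
            tally.emitted = len(children)
            scored_children: list[Candidate] = []
            for ci, child in enumerate(children):
                smi = child.smiles
                if smi in seen:
                    tally.cross_duplicates += 1
                    continue
                seen.add(smi)
                if Descriptors.MolWt(child.mol) > cfg.mw_ceiling:
                    tally.mw_rejected += 1
                    continue
                if not apply_mcf(child.mol, self.rules, "core").passed:
                    tally.filter_rejected += 1
                    continue
                if not self.score_candidate(child,
                                            _sub_seed(cfg.seed, 13, it, ci)):
                    tally.embed_failed += 1
                    continue
                child.cand_id = self._next_id
                self._next_id += 1
                tally.scored += 1
                scored_children.append(child)
            if not scored_children:
                report.iterations.append(tally)
                report.stopped_early = f"no survivors at iteration {it}"
                break
            fps = [compute_ifp(c.pose, self.pocket, self.model,
                               self.pocket.hotspots)
                   for c in scored_children]
            selected = select_candidates(
                scored_children, objective=cfg.selection.objective,
                mode=cfg.selection.mode, k=cfg.selection.k,
                threshold=cfg.selection.ifp_similarity_threshold,
                fingerprints=fps)
            tally.selected = len(selected)
            report.iterations.append(tally)
            all_scored.extend(scored_children)
            parents = selected
        final = [c for c in all_scored
                 if apply_mcf(c.mol, self.rules, "enhanced").passed]
        sign = 1.0 if cfg.selection.objective == "binding_energy" else -1.0
        final.sort(key=lambda c: (sign * getattr(c.scores,
                                                 cfg.selection.objective),
                                  c.smiles))
        report.n_final = len(final)
        report.final_smiles = [c.smiles for c in final]
        return final, report


def _centroids_close(a: Candidate, b: Candidate, cutoff: float) -> bool:
    ca = a.pose.coords[heavy_indices(a.mol)].mean(axis=0)
    cb = b.pose.coords[heavy_indices(b.mol)].mean(axis=0)
    return float(np.linalg.norm(ca - cb)) <= cutoff


def _heavy_automorphisms(mol: Chem.Mol, cap: int = 12) -> list[dict]:
    """Graph automorphisms of the heavy-atom skeleton as dicts over
    full-molecule atom indices."""
    noh = Chem.RemoveHs(Chem.Mol(mol))
    hv = heavy_indices(mol)
    matches = noh.GetSubstructMatches(noh, uniquify=False, maxMatches=cap)
    if not matches:
        matches = (tuple(range(noh.GetNumAtoms())),)
    return [{hv[q]: hv[t] for q, t in enumerate(perm)} for perm in matches]


def _no_restart_params(base):
    """A restart-free copy of docking params for cheap local polish."""
    import dataclasses

    return dataclasses.replace(base, n_restarts=0)


def _anchor_axis_sweep(pose: Pose, anchor_idxs, ctx, n: int = 24) -> Pose:
    """Rotate the whole pose about the anchor atoms' best-fit plane normal
    (through their centroid) and keep the lowest-energy angle.

    The anchor atoms stay essentially fixed (exactly so for a planar ring),
    while grown substituents sweep their circle — resolving the spin left
    undetermined when the anchor fragment is symmetric.
    """
    from scipy.spatial.transform import Rotation

    pts = pose.coords[list(anchor_idxs)]
    if len(pts) < 3:
        return pose
    center = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - center)
    if s[1] < 1e-6:  # collinear anchor: no well-defined plane
        return pose
    axis = vt[2]
    best_coords, best_e = pose.coords, ctx.energy(pose.coords)[0]
    for ang in np.linspace(0.0, 2 * np.pi, n, endpoint=False)[1:]:
        R = Rotation.from_rotvec(axis * ang).as_matrix()
        coords = (pose.coords - center) @ R.T + center
        e, _ = ctx.energy(coords)
        if e < best_e:
            best_coords, best_e = coords, e
    return Pose(pose.mol, best_coords)


def _align_to_targets(conformer: Pose, idxs, targets) -> tuple[Pose, float]:
    from .geom import kabsch

    heavy = [k for k, i in enumerate(idxs)
             if conformer.mol.GetAtomWithIdx(i).GetAtomicNum() > 1]
    if len(heavy) < 3:
        raise FragGrowError("underdetermined alignment")
    mobile = conformer.coords[[idxs[k] for k in heavy]]
    target = targets[heavy]
    R, t, rmsd = kabsch(mobile, target)
    return Pose(conformer.mol, conformer.coords @ R.T + t), rmsd


def run_generation(config: GenerationConfig, *, protein=None, reference=None,
                   probe_library=None, fragment_library=None,
                   write_outputs: bool = True):
    """Execute placement plus the iterative growth loop.

    Returns (final candidates, RunReport); when ``write_outputs`` is set the
    scored SDF and the JSON report land in ``config.output_dir``.
    """
    config.validate()
    run = GenerationRun(config, protein=protein, reference=reference,
                        probe_library=probe_library,
                        fragment_library=fragment_library)
    final, report = run.run()
    if write_outputs:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sdf(final, str(outdir / "generated.sdf"))
        (outdir / "report.json").write_text(report.to_json())
    return final, report


# ---------------------------------------------------------------------------
# benchmark


def _forms_hbond(frag: Fragment, hotspots, windows) -> bool:
    if frag.crystal_pose is None:
        return False
    from .pharmacophore import satisfaction

    feats = ligand_features(frag.mol)
    coords = frag.crystal_pose.coords
    for h in hotspots:
        if h.kind not in ("hb_donor", "hb_acceptor"):
            continue
        for f in feats:
            if satisfaction(h, f, frag.mol, coords, windows) > 0.0:
                return True
    return False


def cross_symmetry_rmsd(cand_mol: Chem.Mol, cand_pose: Pose,
                        ref_mol: Chem.Mol, ref_pose: Pose) -> float:
    """Pocket-frame heavy-atom RMSD between poses of two graph-identical
    molecules, minimized over all graph isomorphisms (no re-fitting)."""
    noh_c = Chem.RemoveHs(Chem.Mol(cand_mol))
    noh_r = Chem.RemoveHs(Chem.Mol(ref_mol))
    hv_c = heavy_indices(cand_mol)
    hv_r = heavy_indices(ref_mol)
    matches = noh_r.GetSubstructMatches(noh_c, uniquify=False,
                                        maxMatches=10000)
    if not matches or noh_c.GetNumAtoms() != noh_r.GetNumAtoms():
        return float("inf")
    xc = cand_pose.coords[hv_c]
    xr = ref_pose.coords[hv_r]
    best = float("inf")
    for perm in matches:
        d = xc - xr[list(perm)]
        rmsd = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
        best = min(best, rmsd)
    return best


def run_benchmark(complexes, config: GenerationConfig) -> pd.DataFrame:
    """Regrow-and-reproduce benchmark over (protein, reference pose) pairs.

    For each complex the reference ligand is fragmented, H-bonding fragments
    become probes, all fragments become building blocks, generation runs,
    and the minimum pocket-frame symmetry RMSD between a regrown copy of the
    ligand and its crystal pose is reported with its classification.
    """
    rows = []
    for idx, (protein, ref_pose) in enumerate(complexes):
        ligand = ref_pose.mol
        frags = fragment_ligand(ligand)
        pocket = extract_pocket(protein, ref_pose, config.pocket_cutoff)
        pocket.hotspots = detect_hotspots(pocket, config.hotspots)
        probes = [f for f in frags
                  if _forms_hbond(f, pocket.hotspots, config.windows)]
        nrot = count_rotatable_bonds(ligand)
        n_heavy = len(heavy_indices(ligand))
        if not probes:
            log.warning("complex %d skipped: no fragment forms a crystal "
                        "H-bond", idx)
            rows.append({"complex": idx, "rmsd": float("nan"),
                         "classification": "skipped",
                         "heavy_atoms": n_heavy, "rotatable_bonds": nrot,
                         "n_generated": 0, "target_recovered": False})
            continue
        final, report = run_generation(
            config, protein=protein, reference=ref_pose,
            probe_library=probes, fragment_library=frags,
            write_outputs=False)
        target = canonical_smiles(ligand)
        hits = [c for c in final if c.smiles == target]
        if hits:
            rmsd = min(cross_symmetry_rmsd(c.mol, c.pose, ligand, ref_pose)
                       for c in hits)
        else:
            rmsd = float("inf")
        rows.append({"complex": idx, "rmsd": rmsd,
                     "classification": classify_reproduction(rmsd),
                     "heavy_atoms": n_heavy, "rotatable_bonds": nrot,
                     "n_generated": len(final),
                     "target_recovered": bool(hits)})
    return pd.DataFrame(rows)
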