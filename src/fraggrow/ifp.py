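"""Interaction fingerprints, binding-mode clustering, candidate selection.

A fingerprint is an ordered bitvector laid out as (pocket residue key x
interaction kind); a bit is set when the pose makes a contact of that kind
with that residue under the same geometric windows the energy model uses.
Clustering is deterministic leader clustering: candidates are processed in
descending-objective order and join the first cluster whose leader is at
least `threshold` similar, so cluster leaders are strong poses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemio import FragGrowError, Pose, canonical_smiles
from .config import CHARGED_PROTEIN_ATOMS
from .pocket import Pocket
from .score import EnergyModel, make_context

KINDS = ("hb_donor_to_ligand", "hb_acceptor_from_ligand", "hydrophobic",
         "aromatic", "ionic")

_HOTSPOT_TO_KIND = {
    "hb_donor": "hb_donor_to_ligand",
    "hb_acceptor": "hb_acceptor_from_ligand",
    "hydrophobic_patch": "hydrophobic",
    "aromatic_ring": "aromatic",
}


@dataclass(frozen=True)
class IFPLayout:
    residues: tuple[tuple, ...]
    kinds: tuple[str, ...] = KINDS

    def index(self, residue, kind) -> int:
        return self.residues.index(residue) * len(self.kinds) + \
            self.kinds.index(kind)

    @property
    def length(self) -> int:
        return len(self.residues) * len(self.kinds)


@dataclass(frozen=True)
class InteractionFingerprint:
    bits: tuple[int, ...]  # sorted set-bit positions
    layout: IFPLayout

    def __len__(self) -> int:
        return self.layout.length


def compute_ifp(pose: Pose, pocket: Pocket, model: EnergyModel,
                hotspots=None) -> InteractionFingerprint:
    """Residue-level contact pattern of a pose under the shared windows."""
    ctx = make_context(pose.mol, pocket, model, hotspots)
    layout = IFPLayout(tuple(pocket.residue_keys))
    best = ctx.hotspot_best(pose.coords)
    bits: set[int] = set()
    for i, h in enumerate(ctx.hotspots):
        if best[i] > 0.0:
            bits.add(layout.index(h.residue, _HOTSPOT_TO_KIND[h.kind]))
    bits |= _ionic_bits(pose, pocket, model, layout)
    return InteractionFingerprint(tuple(sorted(bits)), layout)


def _ionic_bits(pose: Pose, pocket: Pocket, model: EnergyModel,
                layout: IFPLayout) -> set[int]:
    """Opposite formal charges within the ionic cutoff."""
    lig_charged = [(a.GetIdx(), a.GetFormalCharge())
                   for a in pose.mol.GetAtoms() if a.GetFormalCharge() != 0]
    if not lig_charged:
        return set()
    bits: set[int] = set()
    protein = pocket.protein
    cutoff = model.windows.ionic_dist
    for i in pocket.atom_indices:
        key = (protein.resnames[i], protein.names[i])
        q_prot = CHARGED_PROTEIN_ATOMS.get(key, 0)
        if q_prot == 0:
            continue
        for li, q_lig in lig_charged:
            if q_prot * q_lig < 0 and \
                    np.linalg.norm(pose.coords[li] - protein.coords[i]) <= cutoff:
                bits.add(layout.index(protein.residue_key(i), "ionic"))
    return bits


def tanimoto(a: InteractionFingerprint, b: InteractionFingerprint) -> float:
    """|a & b| / |a | b|; 1.0 when both are empty."""
    if a.layout != b.layout:
        raise FragGrowError("fingerprints have different layouts")
    sa, sb = set(a.bits), set(b.bits)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def cluster_ifps(fps: list[InteractionFingerprint],
                 similarity_threshold: float) -> list[list[int]]:
    """Leader clustering in input order; returns a partition as lists of
    input indices (every index in exactly one cluster)."""
    clusters: list[list[int]] = []
    leaders: list[InteractionFingerprint] = []
    for i, fp in enumerate(fps):
        for ci, leader in enumerate(leaders):
            if tanimoto(fp, leader) >= similarity_threshold:
                clusters[ci].append(i)
                break
        else:
            clusters.append([i])
            leaders.append(fp)
    return clusters


def select_candidates(cands: list, objective: str = "binding_energy",
                      mode: str = "plain", k: int = 8,
                      threshold: float = 0.6,
                      fingerprints: list[InteractionFingerprint] | None = None):
    """Top-k selection, plain or diversified by IFP clustering.

    plain: top-k by the objective (energy ascending / PLI descending), ties
    broken by canonical string.  ifp_clustered: cluster the candidates'
    fingerprints (input processed in descending objective order), take the
    best of each cluster, then the top-k among those representatives.
    """
    if objective not in ("binding_energy", "pli_score"):
        raise ValueError(f"unknown objective {objective!r}")
    if mode not in ("plain", "ifp_clustered"):
        raise ValueError(f"unknown selection mode {mode!r}")
    for c in cands:
        if c.scores is None:
            raise FragGrowError(
                f"unscored candidate {canonical_smiles(c.mol)}")

    sign = 1.0 if objective == "binding_energy" else -1.0

    def key(c):
        return (sign * getattr(c.scores, objective), canonical_smiles(c.mol))

    ranked = sorted(cands, key=key)
    if mode == "plain":
        return ranked[:k]
    if fingerprints is None:
        raise FragGrowError("ifp_clustered selection needs fingerprints")
    fp_by_id = {id(c): fp for c, fp in zip(cands, fingerprints)}
    fps_ranked = [fp_by_id[id(c)] for c in ranked]
    clusters = cluster_ifps(fps_ranked, threshold)
    reps = [ranked[cluster[0]] for cluster in clusters]  # best of each cluster
    reps.sort(key=key)
    return reps[:k]
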