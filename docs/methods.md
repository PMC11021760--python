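# Methods

This note documents the models, conventions and numerical choices behind
`fraggrow`, in the spirit of an extended methods section.  Nothing here is
an empirical claim beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Data model

Molecules are RDKit graphs kept **hydrogen-complete** throughout: every
linking operation removes explicit hydrogens to free valence, and all
geometry (placement, docking, RMSD) runs on full-atom coordinate arrays.
The canonical H-suppressed SMILES string is the identity of a structure and
the deduplication key everywhere.  Atom provenance (which growth step an
atom entered in) travels in an atom property.  Proteins are flattened from
PDB (Biopython parser; highest-occupancy altloc kept, ties to `A`; waters
dropped) into plain arrays keyed by `(chain, resseq, icode)`.

## Hotspot typing

The typing rules are this package's own convention — published pocket
analysis tools do not agree on one table, so ours is explicit and lives in
`fraggrow.config`, not in code paths:

* **Donor**: N/O/S with a hydrogen within 1.3 Å; direction along the X–H
  bond.  One hotspot per polar hydrogen.
* **Acceptor**: any O (carbonyl, hydroxyl, ether, carboxylate), and N
  without hydrogens having ≥2 heavy neighbours (pyridine-type, e.g.
  unprotonated His).  Amide/pyrrole-type and charged N are not acceptors.
  On the ligand side, aromatic-ether oxygens (furan-type) are likewise
  excluded — their lone pairs are delocalized and they are notoriously poor
  acceptors.  Direction is the lone-pair bisector (away from the bonded
  heavy atoms).
* **Aromatic ring**: centroid and best-fit-plane normal of His/Phe/Tyr/Trp
  side-chain rings; the normal is signed toward the pocket interior
  (reference-ligand centroid).
* **Hydrophobic patch**: centroid of ≥3 mutually near (≤5 Å) apolar
  carbons, found by leader clustering.  Toggleable; included because the
  scoring function needs a reward for nonpolar contact.

## Geometric windows and switches

Each interaction is scored by a switch in [0,1]: a triangular distance term
(1 at the ideal value, 0 at the window edges) times a linear angular taper.
Defaults follow common crystallographic surveys:

| interaction | distance window (lo/ideal/hi, Å) | angular term |
|---|---|---|
| H-bond | 2.6 / 3.0 / 3.4 (heavy–heavy) | donor-H axis within 60° of the D→A axis (≈ D–H…A ≥ 120°) |
| aromatic | 3.5 / 3.8 / 5.0 (centroid) | stacked ≤30° or T-shaped 60–90° between normals |
| hydrophobic | 3.5 / 4.0 / 5.5 | none |
| ionic (fingerprint only) | ≤ 4.5 | none |

The same windows drive probe placement, the energy, the PLI score and the
interaction fingerprints — a single source of truth, so a "contact" means
the same thing everywhere.

## The empirical energy

`E = Σ steric(r) − Σ_hotspots w·g_best + clash terms`, with a soft 8-4
well (`ε[(r0/r)^8 − 2(r0/r)^4]`, ε = 0.05, r0 = sum of Bondi-style vdW
radii, 6 Å cutoff, inner distance clamped at 0.6·r0 so the well stays
finite), per-hotspot best-feature reward (w_hb = 1.0, w_aromatic = 0.7,
w_hydrophobic = 0.3), and a flat-plus-ramp penalty for any pair closer than
0.7·r0 that pushes the energy above the rejection threshold (10.0).  This
is an explicit surrogate scoring function: the architecture (shared
windows, hotspot-level rewards, soft sterics) is the reproducible claim,
not the parameterization.  Only intermolecular terms are scored; ligand
internal strain is handled implicitly by generating force-field-relaxed
conformers and never deforming them during docking.

## Placement, docking, and symmetry

Probe placement constructs poses analytically at ideal interaction
geometry, then sweeps the spin about the interaction axis (default 12
steps; the regrow study uses 24).  The residual orientation is fixed by
mapping covariant frames (probe anchor→farthest-atom direction onto the
hotspot anchor→pocket-interior direction), which makes the placement set
equivariant under rigid transforms of the complex.

Rigid docking optimizes the six rigid-body degrees of freedom by
Nelder–Mead from an explicit initial simplex (0.3 Å / ~6° steps — the
default simplex collapses around a zero start), with seeded random restarts
(≤1 Å, ≤15° by default).  The docked energy never exceeds the starting
energy; a hard-clash start is returned with its penalty energy and clash
flag rather than raising.

Symmetric fragments need special care, and three mechanisms address them:

1. **Alignment variants.** A child conformer is aligned onto its parent
   pose through every heavy-atom graph automorphism of the parent (capped),
   so a substituent grown on, say, a benzene probe can point in any
   symmetry-equivalent direction.
2. **Alternative origins.** Products are deduplicated by canonical string
   with first-parent-wins lineage (parents arrive best-first), but every
   duplicate growth route is recorded and explored as an extra
   pose-inheritance origin; dock starts are spread across distinct origins
   so one greedy placement cannot monopolize the budget.
3. **Axis sweeps.** Before and after docking, the pose is spun continuously
   about the anchor fragment's plane normal (and each ring's normal in a
   final coordinate-descent polish), resolving the spin a symmetric anchor
   leaves undetermined.

Pose-reproduction RMSD is computed in the pocket frame **without
re-superposition**, minimized over graph automorphisms (`symmetry_rmsd`);
the alignment RMSD inside `align_to_parent` is the usual post-superposition
residual.  The two must not be confused.

## Filters

The default medicinal-chemistry rule set (`data/default_alerts.yaml`) is an
explicit list of reactive/unstable motifs (acyl halides, peroxides, geminal
diols, aliphatic aldehydes, azo/triazene chains, extreme Michael acceptors,
anhydrides, isocyanates), an element whitelist (C,H,N,O,S,F,Cl,Br) and ring
sizes 3–8.  Geminal diols are alerted deliberately even though
carbonyl-hydration liabilities slip through some published filter sets.
Enhanced mode additionally evaluates terminal-group alerts against the
acyclic substituents hanging off ring systems (acyclic pieces bridging two
ring systems are not "terminal") and user property bounds (MW ≤ 550 Da
default — a common lead-like ceiling; heavy atoms, rotatable bonds, ring
count).  Rotatable bonds are counted by the explicit definition: single,
non-ring, both atoms heavy and non-terminal, amide C–N excluded.

## Pose refinement contract

Probe refinement is a contract: `refine(pose, pocket) → pose` with equal
topology and non-increasing energy.  The default refiner is the rigid-body
optimizer inside a 2 Å centroid trust region.  An external command-line
refiner (e.g. a semiempirical tight-binding code) can be swapped in through
`ExternalRefiner`, which truncates the pocket to residues within 8 Å of the
probe, exchanges XYZ files with the executable, and falls back to the input
pose if the contract (energy non-increase) is violated.  It is off by
default and covered by a mock-executable contract test.

## Selection

Candidates are selected per iteration by docked binding energy (ascending)
or PLI score (descending), ties broken by canonical string.  With IFP
clustering, fingerprints (residue × {donor-to-ligand, acceptor-from-ligand,
hydrophobic, aromatic, ionic} bits) are leader-clustered in descending
objective order at Tanimoto threshold 0.6 — chosen for determinism and
O(n·k) cost — and the best member of each cluster advances.  Intermediate
selection clusters within an iteration; the final output is a ranked union
over all iterations.

## Synthetic fixtures: what they do and do not show

`testkit` builds toy complexes *backwards* from a planted ligand: the
ligand is embedded (seeded ETKDG + MMFF), fragmented by the same
ring-connected-bond rule the benchmark uses (terminal single-heavy-atom
decorations and amide bonds exempt; acyclic pieces between two cuts become
linkers), and complementary pseudo-residues are placed at ideal interaction
geometry — a Phe-like ring stacked 3.8 Å over each ligand ring, a Ser-like
hydroxyl donating into each ligand acceptor at 3.0 Å, a Gly-like carbonyl
accepting from each ligand donor.  Pseudo-residues are minimal real
residues so hotspot typing runs unmodified.  Everything regenerates
bitwise from (ligand SMILES, seed); no stored fixtures exist.

The regrow study conditions: five ligands of 2–3 fragments each (biphenyl,
4-phenylpyridine, 2-phenylpyrimidine, 3-phenylpyridine, diphenylmethane),
libraries of the true fragments plus ten decoys from a fixed filter-clean
pool, two growth iterations, three conformers per candidate, three probes,
selection width four, one docking restart (the axis sweeps carry the
orientation search), and a molecular-weight ceiling of target + 30 Da —
the weight stop-criterion set to admit one small decoration beyond the
target, which keeps the enumeration at desk scale.

These fixtures exercise the full pipeline — placement, all four linking
rules, docking, filtering, selection, benchmark classification — under
geometry the engine does *not* see ahead of time.  They do not emulate
conformational protein response, water-mediated contacts, realistic pocket
shapes/depths, or library sizes beyond a dozen fragments; passing them
shows the machinery is correct and self-consistent, not that the surrogate
energy ranks real ligands correctly.  Feature-poor symmetric ligands
(biphenyl-like, two equivalent stacking sites and nothing else) are the
hardest case: their energy landscape is nearly degenerate under ring swaps
and offsets, and individual seeds can land in the 2–4.5 Å "almost" band.

## Degenerate inputs and tie-breaks

Collinear atom sets in rigid superposition fall back to a minimal-rotation
principal-axis alignment (the spin about the axis is left at zero).
Hotspot ordering, candidate ordering, and cluster assignment are all
deterministic (lexicographic keys); every stochastic step (embedding,
restarts, library shuffling) takes an explicit seed, and identical seeds
yield byte-identical SDF output.

## Known limitations

* The energy is a surrogate; absolute values are not calibrated to
  experimental affinities and should only be used to rank poses within one
  run.
* Rigid docking cannot repair a bad conformer; recovery depends on the
  seeded conformer ensemble containing a near-native geometry.
* Fusion tries both bond-atom identifications but only one kekulé
  structure per input; exotic aromatic merges that would need H-count
  changes are rejected rather than re-aromatized.
* De novo (reference-free) site detection, flexible receptors, water
  bridges, stereocenter enumeration and synthetic-accessibility scoring are
  out of scope.
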