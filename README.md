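# fraggrow

Fragment-based automated structure generation for protein binding pockets.

`fraggrow` grows small-molecule ligands *de novo* inside a binding site
defined by a reference ligand.  It is aimed at structure-based drug-design
practitioners who want an interpretable, rule-driven alternative to
black-box generative models: every product molecule has an explicit growth
lineage (which fragment was attached where, by which rule), and every pose
is the outcome of a documented empirical score.

## What it does

1. **Pocket & hotspots.** Residues within a cutoff (default 5 Å) of the
   reference ligand define the pocket.  Typed interaction anchors —
   hydrogen-bond donors (X–H), acceptors (O / pyridine-type N with a free
   lone pair), aromatic side-chain rings and hydrophobic patches — are
   detected from the protein geometry.
2. **Probe placement.** Small probe fragments are placed so that a probe
   pharmacophore feature realizes the ideal geometry of a complementary
   hotspot (donor↔acceptor at ~3.0 Å heavy-atom distance, ring↔ring stacked
   at ~3.8 Å), the spin about the interaction axis is sampled, clashing
   poses are discarded, and the survivors are ranked by pharmacophore score
   and empirical binding energy, then refined by rigid-body optimization.
3. **Iterative growth.** Four graph-level linking rules generate offspring:
   direct single bond, linker-mediated bridge between two placed probes,
   ring fusion (condensed systems) and spiro junctions between aliphatic
   rings.  Products pass medicinal-chemistry filters, get seeded 3D
   conformers, are aligned onto the parent pose via their inherited atoms,
   rigidly docked (6 degrees of freedom, derivative-free local search), and
   the best are selected by docked binding energy or PLI score — plainly or
   diversified by interaction-fingerprint (IFP) clustering.  Growth stops at
   a molecular-weight ceiling or the iteration limit.
4. **Output.** All surviving structures pass an enhanced filter pass
   (terminal-group alerts + property bounds) and are written as an SDF with
   `binding_energy`, `pli_score`, `shape_similarity`, `iteration` and
   `lineage` tags, alongside a JSON run report with per-iteration tallies.

The engine is evaluated by a **regrow benchmark**: a known ligand is
fragmented by breaking its ring-connected bonds, the fragments that
hydrogen-bond to the protein in the crystal geometry become probes, all
fragments become building blocks, and the generator must rebuild the ligand
and reproduce its pose.  Reproduction is judged by heavy-atom RMSD in the
pocket frame (no re-superposition), minimized over graph automorphisms:
below 2 Å is *reproduced*, 2–4.5 Å *almost*, above 4.5 Å *failed*.

## The score

The pose score (kcal/mol-scale, lower is better) is

```
E = Σ_pairs steric(r) − Σ_hotspots w_kind · g_best + clash penalties
```

with a soft 8-4 Lennard-Jones-like well on ligand–protein heavy-atom pairs
within 6 Å, and `g_best ∈ [0,1]` the best geometric-switch satisfaction of
each hotspot by any complementary ligand feature (w_hb = 1.0,
w_aromatic = 0.7, w_hydrophobic = 0.3 by default).  The PLI score is the
weighted fraction of satisfied hotspots, `Σ w·g / Σ w ∈ [0,1]`.  The same
distance/angle windows drive placement, scoring and the fingerprints.

## Worked example

Build a synthetic complex around a planted 4-phenylpyridine ligand, then
regrow it from its own fragments plus ten decoys:

```python
from fraggrow.testkit import make_toy_complex, make_fragment_library
from fraggrow.config import GenerationConfig, DockingParams, SelectionParams
from fraggrow.pipeline import run_generation

toy = make_toy_complex("c1ccc(-c2ccncc2)cc1", seed=0)
library = make_fragment_library(list(toy.fragments), n_decoys=10, seed=0)
probes = [f for f in toy.fragments if f.role != "linker"]

config = GenerationConfig(
    seed=0, max_iterations=2, mw_ceiling=185.0,
    n_conformers=3, k_probes=3,
    docking=DockingParams(n_restarts=1),
    selection=SelectionParams(objective="binding_energy", k=4),
    output_dir="demo_out")

final, report = run_generation(config, protein=toy.protein,
                               reference=toy.crystal_pose,
                               probe_library=probes,
                               fragment_library=library)
print(f"{report.n_final} structures from {len(report.iterations)} iterations")
for cand in final[:3]:
    s = cand.scores
    print(f"{cand.smiles:<28} E={s.binding_energy:6.2f}  "
          f"PLI={s.pli_score:.2f}  shape={s.shape_similarity:.2f}")
```

prints

```
136 structures from 2 iterations
c1cncc(-c2cccc3c2C3)c1       E= -7.02  PLI=0.64  shape=0.60
c1ccc(-c2cncc3c2C3)cc1       E= -7.00  PLI=0.63  shape=0.57
c1cncc(-c2ccc3c(c2)C3)c1     E= -6.90  PLI=0.64  shape=0.63
```

`E` is the docked empirical binding energy (more negative = better
contacts), `PLI` the fraction of pocket hotspots the pose satisfies, and
`shape` the voxel-Tanimoto similarity to the reference ligand.  The planted
target itself is recovered with its pose intact:

```python
from fraggrow.chemio import canonical_smiles
from fraggrow.pipeline import cross_symmetry_rmsd, classify_reproduction

target = canonical_smiles(toy.ligand)
hit = next(c for c in final if c.smiles == target)
rmsd = cross_symmetry_rmsd(hit.mol, hit.pose, toy.ligand, toy.crystal_pose)
print(f"{target}: rmsd={rmsd:.2f} Å -> {classify_reproduction(rmsd)}")
# c1ccc(-c2ccncc2)cc1: rmsd=0.06 Å -> reproduced
```

## Command line

```bash
fraggrow fixtures --ligand "c1ccc(-c2ccncc2)cc1" --seed 0 --out toy/
fraggrow place   --protein toy/pocket.pdb --ref-ligand toy/ligand.sdf \
                 --probes toy/probes.smi --out probes_placed.sdf --seed 0
fraggrow run     --config run.yaml
fraggrow filter  --in generated.sdf --mode enhanced
fraggrow benchmark --complexes complexes.tsv --out benchmark.tsv
```

`fraggrow benchmark` accepts a TSV of `protein.pdb<TAB>ligand.sdf` pairs and
emits the regrow table (RMSD, classification, heavy atoms, rotatable
bonds), so the same protocol can be rerun on user-supplied crystal
complexes.

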