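# idpdock

Ensemble docking and bound-ensemble analysis for intrinsically disordered
proteins (IDPs).

An IDP has no single binding pocket: it exists as a heterogeneous,
interconverting conformational ensemble, and a small molecule binds it as a
dynamic cloud of poses rather than one complex. `idpdock` implements the
ensemble-docking protocol for this regime — dock the ligand onto **every**
conformation of an input ensemble, keep one pose per frame, and then treat
the resulting *docked ensemble* as a statistical object: per-residue
interaction populations, dual-residue contact maps, pose-RMSD accuracy
metrics, and normalized-score affinity ranking.

## What it does

**Docking protocols** (`protocol`, `backends`, `boxes`)

- *Per-residue docking*: for each frame, one docking calculation per residue
  inside a cubic search box centred on that residue's centre of mass, with
  edge ∝ the ligand's radius of gyration R_g (default edge = 3.92 · R_g, so
  box volume scales as R_g³); the best-scoring candidate over all residues
  becomes the frame's pose.
- *Whole-conformation docking*: one unrestricted calculation per frame,
  selecting the best of `n_poses` candidates (confidence-style backends rank
  with higher-is-better polarity through the same contract).
- Apo, holo (redocking) and cross docking are the same computation on
  different inputs; holo inputs come from `extract_bound_frames`, which keeps
  frames where any heavy protein atom is within 6 Å of a heavy ligand atom
  and strips the ligand.
- A deterministic, oracle-checkable **mock grid backend** (rigid-ligand
  translation over a regular grid, short-range pair potential) drives tests
  and examples; external grid engines attach through a thin subprocess
  adapter (`GridEngineAdapter`).

**Analysis** (`interactions`, `clustering`, `posermsd`, `scores`)

- Interaction fingerprints per frame and residue: contact (6 Å heavy-atom),
  hydrophobic (5 Å C–C, Cα excluded), charge (5 Å opposite formal charges),
  hydrogen bond (H⋯acceptor ≤ 3.5 Å, donor–H–acceptor angle > 150°), and
  aromatic stacking (ring-centroid separation < 5 Å, both ring normals
  within 45° of the centroid–centroid vector).
- Dual-residue contact matrices: P(residues *i* and *j* simultaneously
  contact the ligand); the diagonal is the single-residue contact
  probability.
- Conformational clustering: pairwise Cα-distance features → 2-D t-SNE →
  k-means (k = 20 by default), perplexity chosen by silhouette grid search;
  ensemble averages are weighted by cluster populations.
- Pose accuracy: *frame-matched* RMSD (docked vs bound pose of the identical
  conformation) and *best-matched* RMSD (minimum over the matching cluster
  after Cα superposition), plus `<3 Å` / `<5 Å` threshold fractions.
- Affinity ranking: min–max score normalization with **one scale per method
  across all ligands** — x_scaled = (x − x_min)/(x_max − x_min), best pooled
  score → 1, worst → 0 — percentile-bootstrap uncertainties, relative
  affinities (tightest binder ≡ 1.0), and the 1/n! random-ranking null.

**Synthetic fixtures** (`synth`) generate self-avoiding Cα-trace peptide
ensembles with templated pseudo side chains, tunable compactness (end-bend
angle), toy ligands with chosen pharmacophores, and ligand-bound ensembles
with *planted* per-residue contact probabilities, so every stage is testable
against known ground truth without external data.

## Worked example

```python
import numpy as np
import idpdock as d

# 1. synthetic disordered 10-mer ensemble, 20 frames
spec = d.FixtureSpec(n_res=10, n_frames=20, seed=1)
ensemble = d.generate_peptide_ensemble(spec)

# 2. three toy ligands docked per-residue with the mock backend
backend = d.MockGridBackend(spacing=1.0)
ligands = {
    "L47": d.generate_ligand(ring=True, amine=True, n_heavy=8),
    "FAS": d.generate_ligand(ring=True, hbond_donor=True, n_heavy=7),
    "L23": d.generate_ligand(amine=True, n_heavy=4),
}
raw = {tag: d.per_residue_ensemble_dock(ensemble, lig, backend, seed=1).scores()
       for tag, lig in ligands.items()}

# 3. one normalization scale across all three ligands
scale = d.fit_normalization(np.concatenate(list(raw.values())), "lower_is_better")
normed = {tag: d.normalize(v, scale) for tag, v in raw.items()}

table = d.affinity_table(normed, n_boot=10_000, seed=1)
print(table.to_string(index=False))
print("random-ranking null:", d.ranking_null_probability(3))
```

prints

```
ligand  mean_normalized_score  bootstrap_error  relative_affinity  rank
   L47               0.854439         0.043711           1.000000     1
   FAS               0.677848         0.034999           0.793325     2
   L23               0.063519         0.016477           0.074339     3
random-ranking null: 0.16666666666666666
```

The larger, ring-bearing ligand collects more favourable mock-backend
contacts on every frame, so it ranks tightest (relative affinity 1.0); the
4-heavy-atom probe binds weakest.  The bootstrap error is the mean half-width
of the 95% percentile CI of each mean normalized score, and a uniformly
random ordering of three ligands would be correct with probability 1/6.

The same pipeline is scriptable from the shell:

```sh
idpdock synth --out-prefix fix --n-res 10 --n-frames 20 --seed 1
idpdock dock  --ensemble fix_ensemble.pdb --ligand fix_ligand.sdf \
              --out-prefix run --spacing 1.0 --seed 1
idpdock scores --scores L47=run_scores.tsv --out affinity.tsv
```

Every command drops a JSON manifest (config, seeds, version, input
checksums) next to its outputs.

## Scope notes

- The mock backend samples rigid translations only (no ligand torsions or
  rotations); it verifies the protocol and statistics, not docking physics.
- Ligand RMSDs use atom-index correspondence without graph-symmetry
  correction.
- mmCIF, protonation-state assignment, and binding free-energy estimation
  are out of scope.  See `docs/methods.md` for modelling decisions and
  limitations.
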