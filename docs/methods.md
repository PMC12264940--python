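# Methods

This note records the models, parameter choices and numerical decisions
behind `idpdock`, and what the synthetic fixtures do and do not establish
about real data.

## Ensemble docking model

The package treats ligand binding to a disordered protein as a
*per-conformation* problem: each frame of a conformational ensemble is an
independent rigid receptor, and the docked ensemble — one selected pose per
frame — is the object analysed statistically. Two protocols produce it:

- **Per-residue protocol.** For a frame with *n* residues, *n* docking
  calculations are run, each restricted to a cubic box centred on one
  residue's mass-weighted centre of mass. The box edge is
  `edge_scale × R_g(ligand)` with `edge_scale = 3.92` by default, so box
  volume is proportional to R_g³. The 3.92 default back-solves two published
  reference volumes (R_g 4.23 Å → 4561 Å³ and 3.53 Å → 2646 Å³, both giving
  edge/R_g ≈ 3.92); a third reference (3.48 Å → 2220 Å³) implies ≈ 3.75, so
  the exact sizing rule used upstream is not recoverable and the factor is
  exposed as configuration rather than guessed. The best-scoring candidate
  under the backend's polarity becomes the frame's pose; ties break to the
  lowest residue index. Failed boxes are excluded rather than scored worst,
  so score distributions are not polluted by sentinel values.
- **Whole-conformation protocol.** One unrestricted calculation per frame
  requesting `n_poses` (default 10) candidates; the best is kept. Backends
  reporting confidence rather than energy declare `higher_is_better`
  polarity and plug into the same selection logic.

Apo, holo and cross docking differ only in their inputs: docking always sees
protein coordinates alone. Holo inputs are produced by the bound-frame
filter (any heavy protein atom within 6 Å of any heavy ligand atom, cutoff
configurable), which also reports the bound fraction.

Seeding: one master seed; per-frame seeds derive deterministically from
(master seed, frame id) via `numpy.random.SeedSequence`, so serial and
parallel execution, and any processing order, give identical results.

## Mock grid backend

The built-in backend translates the rigid ligand conformer (no rotation, no
torsions) so its geometric centroid visits every node of a regular grid of
spacing *g* (default 1 Å) filling the box, and scores each placement as a
sum over ligand-heavy/protein-heavy pairs within 8 Å:

    term(d) = +1000          if d < 2.0 Å   (clash)
            = −exp(−(d−3.5)²/2)  otherwise   (well at 3.5 Å)

Poses are returned sorted by score, ties broken by lexicographic grid order,
which makes the backend bit-reproducible and equal, by construction and by
test, to brute-force enumeration. Its purpose is to make the *protocol* and
all downstream statistics verifiable against independent oracles; it says
nothing about docking physics, which belongs to external engines behind
`GridEngineAdapter`. The adapter's ligand PDBQT writer emits a rigid
single-ROOT block (no torsion tree); torsional preparation is delegated to
engine-side tooling.

## Interaction classification

Per frame, every residue is tested independently for five classes, each
with its own cutoff (all configurable):

| class | criterion | default |
|---|---|---|
| contact | any heavy ligand / heavy residue atom pair | ≤ 6.0 Å |
| hydrophobic | any ligand C / residue C pair, Cα excluded | ≤ 5.0 Å |
| charge | any opposite-formal-charge pair | ≤ 5.0 Å |
| hydrogen bond | donor H (on N/O/S, either side) to heavy N/O/S acceptor on the other side | H⋯A ≤ 3.5 Å and ∠(D,H,A) > 150° |
| aromatic stacking | ring-pair centroid vector R | ‖R‖ < 5 Å and ∠(R, normal) < 45° for both rings |

Decisions taken where the defining text is ambiguous:

- The H-bond distance is hydrogen-to-acceptor, read literally, not
  donor-heavy-to-acceptor; the angle is the standard ∠(D,H,A). Both are
  configurable.
- Acceptors are all heavy N/O/S atoms on either partner, symmetric with the
  donor rule.
- Protein formal charges come from neutral-pH residue templates (Asp/Glu
  carboxylate oxygens −1, Lys Nζ +1, Arg NH1/NH2 +1, His neutral, termini
  uncharged); explicit per-atom charges in the input take precedence.
  Protein rings come from templates (Phe, Tyr, both Trp rings, His —
  His-as-aromatic is a flag, on by default). Ligand charges, rings and
  donors come from the input file via RDKit.
- Ring normals are least-squares plane normals (SVD); the normal's sign is
  meaningless, so each ring-normal angle is folded to [0°, 90°] before the
  45° test.
- Pair searches use a k-d tree and are required by test to agree exactly
  with the all-pairs double loop.

A residue lacking the atoms a class needs simply scores False — classes are
independent, and a specific interaction does not imply the 6 Å contact flag.

Aggregation: populations are fractions of frames per residue and class;
dual-residue contact matrices count simultaneous contacts (symmetric,
diagonal = single-residue probability, off-diagonal bounded by the smaller
diagonal entry). Profile and matrix comparisons report Pearson *r* and RMSE
(matrices over upper triangle + diagonal); zero-variance inputs leave *r*
undefined rather than fabricating a value.

## Clustering and bend angle

Frames are featurized as all pairwise Cα–Cα distances — a rigid-motion
invariant stand-in for the upstream pipeline's unspecified featurization,
and configurable. For each perplexity in a grid the features are embedded in
2-D by t-SNE and partitioned by k-means with fixed k (default 20; the
partitioner on the embedding is this package's decision — the source
protocol names the cluster count but not the partitioner). The silhouette
score, computed in embedding space (also a decision; the alternative,
feature space, is unstated upstream), selects the perplexity. The default
perplexity grid (1100/1200/1800) mirrors published usage at ~20k-frame
scale and is data-dependent; tests use small grids suited to their sizes.

The bend angle of a conformation is the interior angle at the middle of
three anchor Cα atoms (defaults: first, middle, last residue — for the
20-residue C-terminal α-synuclein fragment these correspond to the
published 121/131/140 anchors), clipped into [0°, 180°]. Cluster-level
ensemble averages weight per-cluster means by cluster populations from the
source ensemble; when populations are proportional to cluster sizes this
reduces exactly to the per-frame mean (a test).

## Score statistics

Normalization is min–max with one scale per docking method fitted over the
pooled raw scores of *all* ligands compared with that method; the most
favorable pooled score maps to exactly 1 and the least favorable to exactly
0. Values outside the fitted range clip with a warning. Uncertainty is a
percentile bootstrap of the mean (default 10,000 resamples, 2.5/97.5
percentiles; the reported error is the mean of the upper and lower
deviations). Percentile rather than BCa is deliberate: it is the simplest
method consistent with a bare "bootstrapping with 10,000 samples"
description, and the method is switchable. Relative affinities divide each
ligand's mean normalized score (cluster-weighted when a cluster model is
supplied, else plain) by the best ligand's mean; the random-ranking null
for *n* ligands is 1/n!. Tables built from cross-docked scores carry an
explicit caveat annotation, since scores obtained on a mismatched holo
ensemble need not support affinity comparison. No score-based pose
filtering is applied before averaging.

## Pose-RMSD metrics

Both metrics use heavy ligand atoms with input atom-index correspondence —
no graph-symmetry correction, a documented limitation. Frame-matched RMSD
compares a docked pose with the bound pose of the identical conformation;
since holo docking guarantees identical protein coordinates, no
superposition is applied. Best-matched RMSD superposes each reference
frame's Cα trace onto the docked conformation (Kabsch SVD with a proper
rotation; degenerate/collinear point sets are rejected), carries the
reference ligand along, and takes the minimum — by default over the docked
frame's conformational cluster, with a full-ensemble switch (extending the
search does not change the character of the result, only tightens the
minimum). Threshold fractions use strict `<` at 3 and 5 Å and report
percentages.

## Synthetic fixtures

The generator emulates a short disordered peptide as a self-avoiding Cα
trace: fixed 3.8 Å virtual bonds, 3.0 Å minimum non-bonded Cα separation,
per-frame end-bend angle drawn from a target normal distribution (defaults
148° ± 10°, matching the compactness scale of the most-populated published
cluster) and imposed exactly by rigidly rotating the second chain half
about the middle Cα. Pseudo side chains are templated per residue class:
carboxylate O⁻ pair (Asp-like), ammonium N⁺ (Lys-like), planar 6-ring
(Phe-like, Cα→centroid stalk 3.3 Å by default), aliphatic carbons,
hydroxyl oxygen. Toy ligands assemble a chosen pharmacophore set (aromatic
ring, protonated amine, hydroxyl donor, aliphatic filler) with annotated
bonds, charges and donor/acceptor lists. Planted bound ensembles draw a
target residue per frame from given per-residue probabilities and place the
randomly oriented ligand 4 Å from the target's side-chain centroid (plus
optional isotropic noise); unbound frames park the ligand ~50 Å away.

Fixture scale in the shipped tests (problem sizes chosen to exercise the
statistics at meaningful power while keeping the suite quick): 1000-frame
ensembles for probability recovery, 2000 replicates at 1000 bootstrap
resamples for CI coverage, 100+ random cases for each oracle-equality
check.

The hotspot-recovery fixture deserves a note. With a translation-only
backend, a site is "strongly attractive" only if it is a deep, wide well of
the protein's atom-density field that is *geometrically private* to its own
residue's search box. The fixture therefore places one aromatic ring on an
extended 8 Å stalk (the `aromatic_stalk` parameter) among minimal polar
side chains and probes it with a 2-heavy-atom ligand: the displaced ring is
then reachable essentially only from its own residue's box, and the
protocol attributes ≥95% of selected poses to the planted residue. With the
default 3.3 Å stalk the well sits against the backbone, several residues'
boxes reach it, and the origin attribution is genuinely ambiguous — that is
a property of box-restricted search, not an implementation defect.

What passing fixture tests shows: the protocol's bookkeeping, selection
logic, geometric classifiers, estimators and error bars behave exactly as
specified on data with known ground truth. What it does not show: anything
about force-field realism, real IDP conformational statistics (no excluded
volume beyond Cα radii, no rotamers, no energetics), or the pose accuracy
of any physical docking engine.

## Known limitations

- The mock backend samples neither ligand torsions nor rotations.
- Ligand PDBQT emission for external engines is rigid; pair with
  engine-side preparation for flexible docking.
- No symmetry-corrected RMSD; symmetric ligands can report inflated values.
- Protonation states are taken as given (templates for the protein, input
  file for the ligand); no pKa logic.
- t-SNE embeddings are stochastic across library versions even at fixed
  seed; reproducibility is guaranteed within one environment.
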