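# Methods

This note documents the models, conventions and numerical choices behind
`allofinger`, and what the synthetic study conditions can and cannot show.

## Conformational panel construction

**Superposition and RMSD.** Rigid fits are least-squares (Kabsch): optimal
proper rotation (reflections excluded via the SVD determinant correction)
plus translation, computed on the atom subset of the active framework. RMSD
is the unweighted root-mean-square deviation over that same subset, in nm.
The subset is a parameter of every RMSD call, so the fitting set and the
clustering set are always the same framework selection. Fewer than three
non-collinear subset atoms is an error (the fit is underdetermined). The
all-vs-all matrix uses the closed-form Kabsch objective with batched 3×3
SVDs, so an n-frame matrix costs O(n²) small SVDs and never materialises
fitted coordinates.

**Gromos (Daura) clustering.** Among unassigned frames, the frame with the
most unassigned neighbours within the cutoff (inclusive ≤) becomes the next
cluster representative; it and its neighbours are removed; repeat. Ties in
neighbour count break toward the lowest frame index — deterministic and
stable under re-runs. The default cutoff is 0.225 nm, the midpoint of the
conventional 0.2–0.25 nm band for backbone clustering; it is exposed in
config and on the CLI. RMSD is unweighted (no atomic masses).

**Frameworks.** Clust-N/M/NM/MC select backbone atoms (N, CA, C, O) of the
named sequence domains; Site selects all heavy protein atoms of the
binding-site residues. Secondary-structure-restricted selections can be
supplied as custom predicates; no DSSP dependency is required.

**Binding-site criterion.** A residue belongs to the allosteric site iff in
at least 75 % (inclusive) of all metatrajectory frames its minimum
heavy-atom distance to any ligand heavy atom is at most 1 nm (inclusive).
"All visited structures" is interpreted as all frames, not cluster
representatives. Both thresholds are parameters.

**Panel.** Representatives of the top-3 most populated clusters per domain
framework (population ties keep formation order) plus the first two site
representatives: 4×3 + 2 = 14 entries, in fixed framework order. A warning
is logged if a framework's top-3 clusters cover < 45 % of frames, since the
panel is then a poor summary of that ensemble.

## Dynamic fingerprints

Per (ligand, panel structure): `best_score` (rank-1 docking score,
kcal/mol-like, negative is better), `score_rms`, and `pose_spread`.

Two formulas in the protocol are underspecified and are implemented behind
named options with the chosen default first:

* `score_rms`: root-mean-square of the raw scores of the 10 best poses
  (`mode="rms"`, default) vs standard deviation about their mean
  (`mode="sd"`). The raw-score RMS preserves the magnitude of binding,
  which the sd discards.
* `pose_spread`: mean coordinate RMSD of poses 2–10 to the best pose with
  **no refitting** (`mode="to_best"`, default; all poses share the receptor
  frame, so refitting would delete the positional-adaptation signal) vs the
  all-pairs mean (`mode="all_pairs"`).

Short pose sets use all available poses (logged); a single pose has spread
0. Missing (ligand, structure) docks default to the worst-case penalty:
score 0.0 (no favourable binding), score RMS 0.0, and the maximum observed
spread — failure to bind a conformation is signal under conformational
selection, not missing data. Ligands with no poses anywhere are excluded
with a warning.

## Supervised protocol

* Families: logistic regression (lbfgs, L2, tol 1e-4; iteration cap raised
  to 1000 so the optimiser converges on unscaled features), linear-kernel
  SVM (C = 1), random forest (1000 trees, Gini impurity, seeded). No
  feature scaling by default in the supervised path; the unsupervised
  screen standardises per column because its columns mix kcal/mol and nm.
* Holdout: |train| = ⌊0.7 n⌋, redraw (≤ 100×) until both classes are in
  the training set.
* Cross-validation: k = 10 contiguous, unshuffled blocks of the input row
  order; earlier folds absorb the remainder (n = 133 → three folds of 14,
  seven of 13). Because folds are unshuffled, the synthetic library
  generator emits its records in a seed-deterministic shuffled order — an
  unordered screening library — so folds mix classes. If a test fold still
  lacks one class, that fold's balanced accuracy is NaN (warned) and
  summary means are NaN-aware.
* Positive class: activator (the larger class), configurable.
* Learning curve: for each subset fraction (0.2–1.0, step 0.1), 100 random
  subsets, each holdout-split 70/30; the headline is the median plain
  accuracy (the balanced version is reported alongside).
* Ablation: drop one metric's panel-wide column block, re-run CV, and
  compare fold-level balanced accuracies by
  z = |mean₁ − mean₂| / √(s₁²/k + s₂²/k). z < 1 is read as "no dominant
  feature type". If both fold sets have zero variance, z = 0 with a note.
  Note that when the full model saturates (every fold at 1.0, zero
  variance), even a tiny ablation drop can produce z > 1; the statistic is
  only informative away from the ceiling.

## Chemical baseline

Fingerprints are opaque bit vectors (synthetic templates, or ECFP/MACCS
generated from SMILES through the RDKit adapter). Tanimoto similarity is
|a∧b|/|a∨b|, with two empty vectors defined as identical (logged). k-means
on 0/1 vectors uses Euclidean distance (monotone in Hamming distance) for
parity with the feature-space clustering. In the per-scaffold-group report,
a ligand is "correctly separated" iff it sits in the cluster holding the
majority of its class; a class split exactly evenly counts both clusters as
correct (logged) — the tie is not otherwise decidable.

## Synthetic study conditions

The generators emulate the *statistical* structure the analysis assumes;
they simulate no physics.

* **Library** (defaults): 133 ligands = 84 activators + 49 inhibitors in 8
  scaffold groups (CC 40, CB 17, GT 10, DP 15, BP1 16, BP2 16, Z 18,
  Unk 1 — three inhibitor chemotypes, five activator ones, one singleton;
  the per-group sizes are documented conventions, configurable). Each group
  has a random template bit vector (1024 bits, density 0.1); members flip
  each bit independently at rate 0.03.
* **Metatrajectory** (defaults): 48 residues × 5 heavy atoms along a random
  chain, split into N/M/C sequence thirds, a 10-atom ligand at the M/C
  boundary; 4 conformational basins (weights 0.40/0.27/0.18/0.15), basin
  displacement 0.3 nm per atom, frame noise sd 0.02 nm, 240 frames. The
  basin separation (~0.4 nm RMSD) vs noise floor (~0.05 nm) brackets the
  0.225 nm cutoff, so clustering recovers the basins; centers closer than
  3× the noise sd trigger a warning. True basin labels go to a sidecar
  file, never into pipeline inputs.
* **Docking panel** (defaults): base score −6.0, score sd 0.5, 10 poses,
  pose jitter 0.05 nm; the class-conditional shift improves the mean score
  by 1.0 (i.e. 2 sd) on 6 activator-preferred and 6 disjoint
  inhibitor-preferred structures of the 14. Under these conditions the
  linear SVM reaches ≈ 1.0 CV balanced accuracy; with the shift set to 0
  all families sit at chance (0.35–0.65 over 20 seeds), which is the
  calibration check. These sizes keep the full default pipeline at ~15 s
  and the whole test suite within a few minutes.

Passing tests on these conditions show that the pipeline recovers a planted
conformational-selection signal and stays calibrated under the null. They
do not show that real ensemble-docking features of real ligands separate
activators from inhibitors: real docking scores are not Gaussian, real
basins are not equidistant blobs, and real scaffold groups share bits in
structured ways. Published performance figures on the real chaperone data
are therefore not reproduction targets here.

## Other design decisions

* The metatrajectory is the plain concatenation of input replicas; no
  reweighting or imaging corrections; binary trajectory formats are out of
  scope (multi-model PDB and CSV only; domain labels round-trip through the
  PDB chain id).
* One global seed fans out to per-stage seeds via
  `SeedSequence([seed, stage_key])`, so any stage is independently
  reproducible and all artifacts are byte-identical across re-runs.
* The learning-curve stage is off by default in `run` (it costs ~10× the
  rest of the pipeline combined); `allofinger learncurve` or the config
  toggle enables it.
* Known limitation: `select_panel` iterates frameworks in the mapping
  order given; callers who pass a non-canonical order get that order in the
  panel (the pipeline always passes N, M, NM, MC, Site).
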