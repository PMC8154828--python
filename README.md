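# allofinger

**Dynamic docking fingerprints for classifying allosteric ligands as
activators or inhibitors.**

Allosteric ligands bind away from a protein's active site and can either
inhibit or activate its function — but a docking score alone carries no
information about which. For the Hsp90 chaperone (a homodimer whose
N-terminal ATPase is modulated from an allosteric site at the middle/
C-terminal domain boundary), the functional effect of a ligand is coupled to
which protein conformations it preferentially binds. `allofinger`
implements that idea as a reusable pipeline:

1. **Conformational panel.** A metatrajectory (concatenated MD replicas) is
   clustered with the Gromos (Daura) neighbour-count algorithm under five
   atom *frameworks*: the backbone of the N-terminal domain (Clust-N), the
   middle domain (Clust-M), N+M (Clust-NM), M+C (Clust-MC), and the heavy
   atoms of the allosteric-site residues (those within 1 nm of the bound
   ligand in ≥ 75 % of frames). The representatives of the top-3 clusters
   per domain framework plus the two main site representatives form a
   **14-structure docking panel**.
2. **Dynamic fingerprints.** For each ligand docked against each panel
   structure, three features are extracted: the best docking score s₁, the
   root-mean-square of the 10 best scores √(Σᵢ sᵢ²/10), and the mean
   coordinate RMSD of poses 2–10 to the best pose (pose spread). A
   14-structure panel gives a **42-feature vector per ligand** — its dynamic
   fingerprint.
3. **Classification.** Logistic regression, a linear-kernel SVM and a
   1000-tree random forest predict activator vs inhibitor, evaluated by
   70/30 holdout and 10-fold *unshuffled* cross-validation (balanced
   accuracy = (TPR + TNR)/2), with a learning curve and a per-feature-type
   ablation (z score of the CV change).
4. **Baselines.** Unsupervised k-means/Ward segmentation of the feature
   space scored by cluster purity (k = 2..6), and a dynamics-free chemical
   baseline: Tanimoto/k-means on fingerprint bit vectors with a per-
   scaffold-group fraction-correct comparison against the SVM.

Because ensemble-docking data of this kind is rarely public, the package
ships a first-class synthetic generator that emulates the study design: a
133-ligand library (84 activators, 49 inhibitors, 8 scaffold groups), a
metatrajectory with planted conformational basins, and class-conditional
docking-score panels encoding a conformational-selection signal. Every
stage is tested against these generators and independent oracles.

## Worked example

```bash
allofinger run --seed 0 --outdir demo_out
```

runs the full synthetic pipeline (~15 s) and prints the consolidated
report:

```json
{
  "panel":    {"size": 14, "n_site_residues": 32,
               "clusters_per_framework": {"Clust-N": 4, "Clust-M": 4,
                 "Clust-NM": 4, "Clust-MC": 4, "Site": 4}},
  "features": {"shape": [133, 42], "n_imputed": 0, "n_excluded": 0},
  "train":    {"cv_mean_balanced_accuracy": {"LR": 1.0, "RF": 1.0, "SVM": 1.0}},
  "ablation": {"best_score": 0.0, "score_rms": 0.0, "pose_spread": 0.0},
  "chem":     {"fp_purity_k2": 0.6692, "...": "..."}
}
```

Reading this: the four planted conformational basins were recovered under
every framework (4 clusters each), the panel has the expected 14 structures
and the fingerprint matrix 42 columns. Under the default strong
conformational-selection signal (a 2-standard-deviation best-score shift on
6 preferred structures per class) all three models separate the classes
perfectly in cross-validation, and no single feature type is dominant
(all ablation z scores < 1). The chemical baseline, which sees only
scaffold-template bit vectors, reaches purity ≈ 0.67 at k = 2 — scaffold
similarity alone does not recover function.

The same stages are available individually (`allofinger simulate`,
`cluster`, `screen`, `train`, `ablate`, `learncurve`, `chem`), all driven
by one YAML config and a single seed that fans out deterministically per
stage. Intermediate artifacts are plain CSV. Docking scores follow the
negative-is-better convention; coordinates are in nm.

Using your own data: multi-model PDB or long-format CSV for trajectories
(`Metatrajectory.from_pdb` / `.from_csv`), pose tables as CSV
(`ligand_id,structure_id,rank,score,atom_index,x,y,z`) or SDF with
`LIGAND_ID/STRUCTURE_ID/RANK/SCORE` properties, labels and fingerprint
bitstrings as CSV. `allofinger.chem.fingerprints_from_smiles` generates
ECFP/MACCS bits from SMILES via RDKit.

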