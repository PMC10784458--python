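# gpcrstate

Conformational-state annotation of class A GPCR structures and molecular
dynamics trajectories.

A receptor conformation is represented as an ordered vector of pairwise
distances (Å) between the side-chain geometric centers of residue pairs on
the conserved class A activation pathway, addressed by generic residue
numbering (`5x62`, `6x37`, ...). The shipped default configuration has 38
pairs; it is a plain-text file and fully user-replaceable. On top of this
descriptor the package provides:

- **`generic_numbering`** — parsing of `SxNN` labels (both `x` and `×`
  separators) and resolution to concrete residues via user-supplied
  mapping tables (no network service is ever queried).
- **`descriptor`** — side-chain-center math (heavy atoms only, CA fallback
  for glycine, altloc-aware), per-structure and streaming per-trajectory
  featurization, CSV output.
- **`dataset_builder`** — fixed-interval frame sampling (default plan:
  20 ns at one frame per 100 ps → 200 frames; 38 trajectories → a
  7,600 × 38 matrix), labeled datasets, and leakage-free trajectory-level
  fold assignment with a stratified 28/10 train/test split.
- **`state_model`** — random-forest (default), SVM and gradient-boosted
  classifiers behind one interface; trajectory-grouped 5-fold CV;
  precision/recall/F1/accuracy/MCC computed from first principles;
  single-file model bundles; decision-path extraction and a feature
  importance + cross-correlation report (|r| ≥ 0.9 flagged).
- **`trajectory_annotator`** — per-frame active-state scores, centered
  moving-average smoothing (reporting only), frame classification at the
  θ = 0.375 threshold (strict), trajectory verdicts from the active-frame
  ratio vs δ (strict), binding-site definition by distance cutoff,
  Cα site RMSD after least-squares superposition, and Mann–Whitney group
  comparison.
- **`synthetic_data`** — seeded generator of toy receptor-like ensembles
  (PDB + DCD + mapping + ground-truth CSV) with controllable
  active/inactive separation, interpolation schedules and noise, used by
  the whole test suite and the acceptance script.

## CLI

```sh
# featurize a structure or a trajectory
gpcrstate featurize --structure receptor.pdb --mapping map.txt --out desc.csv
gpcrstate featurize --traj run.dcd --top top.pdb --mapping map.txt --dt 100 --out desc.csv

# build a labeled dataset from a manifest and train a model
gpcrstate build-dataset --manifest manifest.csv --length-ns 20 --interval-ps 100 \
    --out-descriptors desc.csv --out-sidecar side.csv
gpcrstate train --descriptors desc.csv --sidecar side.csv \
    --train-folds 28 --test-folds 10 --seed 0 \
    --out-model model.joblib --out-metrics metrics.json

# annotate a trajectory: per-frame CSV + verdict JSON
gpcrstate annotate --model model.joblib --traj run.dcd --top top.pdb \
    --mapping map.txt --theta 0.375 --delta 0.5 --window 5 \
    --out-csv scores.csv --out-json verdict.json

# decision-path report for one structure
gpcrstate explain --model model.joblib --structure receptor.pdb --mapping map.txt
```

Manifest format (CSV or JSON): columns
`traj_id, state, topology, trajectory, mapping[, dt_ps]`, paths relative
to the manifest file. Mapping files are whitespace-separated
`generic_label resnum [chain] [resname]` tables with `#` comments.

## Reference simulation protocol (documentation only)

Training data for the real receptor use case are short all-atom MD runs;
this package never runs MD itself. The reference protocol used to produce
such trajectories: GROMACS with the CHARMM36 force field and TIP3P water;
receptor embedded in a POPC bilayer; 0.15 mol/L NaCl; steepest-descent
minimization (≤50,000 steps, force tolerance 1000 kJ/mol/nm); 100 ps NVT
(V-rescale, backbone restrained) and 1000 ps NPT (Parrinello–Rahman)
equilibration; 20 ns production with a 2 fs leap-frog integrator, LINCS
constraints, 1.2 nm van der Waals cutoff and PME electrostatics; frames
stored every 100 ps. Short production runs are deliberate: they minimize
the chance of an active↔inactive transition contaminating the per-
trajectory state labels.
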