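# dacs-augment

Data augmentation for drug-synergy classification by DACS-guided compound
substitution, plus the evaluation machinery to measure whether it helps.

The DACS score combines three views of drug similarity:

- **TC** — Tanimoto coefficient between 1024-bit linear-path fingerprints
  (chemical structure);
- **MCC** — Matthews correlation of two drugs' protein-target memberships over
  a fixed interactome universe (mechanism of action);
- **τ_b** — tie-corrected Kendall rank correlation of monotherapy pIC50
  profiles over shared cell lines (pharmacological response), used to
  validate the other two.

`DACS = sqrt(TC² + max(MCC, 0)²)`, in `[0, √2]`. A synergy dataset is
expanded by replacing exactly one drug of a pair with a library compound
whose DACS to the replaced drug clears a cutoff; the cell line, synergy
score and class label are inherited from the parent record. The cutoff is
selected where the fidelity curve (fraction of pairs with positive τ_b
above the threshold) crosses the max-normalized substitute-coverage curve.

## Package layout

| module | contents |
|---|---|
| `dacs_augment.core_io` | domain types (`DrugRecord`, `TargetMap`, `ResponseMatrix`, `SynergyRecord`, `AugmentedRecord`) and CSV/TSV readers & writers |
| `dacs_augment.fingerprints` | named, swappable fingerprint backends (default: RDKit linear-path, 1024 bits) |
| `dacs_augment.similarity` | τ_b, target MCC, Tanimoto, DACS, fraction-positive-τ curves, similarity heatmaps |
| `dacs_augment.augmentation` | threshold curves & selection, candidate retrieval, single-slot substitution engine |
| `dacs_augment.dataset_builder` | ±20 labeling, ambiguity-threshold ladder, chemically-unseen set, stratified & tissue-based folds |
| `dacs_augment.features` | pluggable embedding providers, 900-d instance vectors (2×drug + cell, canonical pair order) |
| `dacs_augment.ml_eval` | LR / SVM / RF / GBT with fixed defaults, cross-validation loops, metric & probability-quartile machinery |
| `dacs_augment.synthetic_data` | planted-cluster generator emulating all inputs, plus retrieval recovery checks |
| `dacs_augment.reporting` | physicochemical summaries (logP, HBD, HBA, QED) and score-distribution tables |

## CLI

```bash
# generate a synthetic input bundle with planted clusters
dacs-augment --seed 7 simulate --config sim.yaml --out-dir sim_data/

# all-against-all similarity table
dacs-augment similarity --library sim_data/library.csv --links sim_data/links.tsv \
    --responses sim_data/responses.csv --out pairs.csv

# fidelity/coverage curves and the selected DACS cutoff
dacs-augment select-threshold --pairs pairs.csv --grid 0:1.41:0.01 --out curves.csv

# expand the synergy table by single-drug substitution
dacs-augment --seed 7 augment --synergy sim_data/synergy.csv \
    --library sim_data/library.csv --links sim_data/links.tsv \
    --cutoff 0.53 --out augmented.csv

# labeled classification dataset with fold assignment
dacs-augment build-dataset --synergy sim_data/synergy.csv --scheme tissue_based \
    --tissue-map sim_data/tissues.yaml --out-dir dataset/

# cross-validated evaluation on a simulated bundle
dacs-augment --seed 7 crossval --sim-dir sim_data/ --model GBT \
    --scheme tissue_based --use-augmented --out report.json
```

Input formats: drug library CSV (`drug_id,smiles` or precomputed
fingerprint columns), chemical-protein links TSV
(`chemical\tprotein\tcombined_score`), monotherapy CSV
(`drug_id,cell_line,pic50,tissue`), synergy CSV
(`drug_a,drug_b,cell_line,tissue,synergy_score`).

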