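# premir

Machine-learning classification of insect pre-microRNA hairpins.

Pre-miRNAs are ~60–250 nt stem-loop precursors from which mature ~22 nt
miRNAs are excised. Distinguishing genuine precursors from the vast
background of genomic "pseudo hairpins" (coding-region fragments that also
fold into stem-loops) is a binary classification problem with severe class
imbalance. `premir` is a library + CLI for the full workflow, aimed at
researchers screening candidate hairpins from PCR products or small-scale
sequence sets:

- read sequences (FASTA) and secondary structures (Vienna dot-bracket with
  MFE), or fold through a pluggable backend (RNAfold bindings when
  available, a deterministic stacking-score folder otherwise);
- compute a fixed, ordered **93-feature descriptor** per hairpin;
- assemble filtered, labelled datasets with a stratified 75/25 split;
- rebalance training data with **SMOTE** (minority oversampling) or
  **NearMiss-1** (majority undersampling);
- train and tune SVM / random forest / logistic regression / KNN
  classifiers with stratified 10-fold cross-validation, and evaluate with a
  full confusion-matrix metric suite;
- excise mature-miRNA arm candidates from predicted precursors.

## The descriptor

For a sequence of length *L* with dot-bracket structure and minimum free
energy *MFE* (kcal/mol):

- **Triplet elements (32)** — every window of 3 adjacent bases contributes
  to a bin keyed by (middle nucleotide, local pairing pattern), where ')'
  is read as '(' so a window pattern is one of 8 strings like `"((."`;
  values are frequencies, count/(L−2).
- **Base composition (45)** — counts and percentages %X = |X|/L·100 of the
  4 nucleotides; counts and percentages %XY = |XY|/(L−1)·100 of the 16
  overlapping dinucleotides; %(G+C) and %(A+U) with their counts; L.
- **Structural (6)** — base pairs `tot_bp`; stems `n_stems` (stacked runs
  of *more than three* contiguous pairs); hairpin loops `n_loops`; total
  hairpin-loop length; pairing propensity dP = tot_bp/L;
  avg_bp = tot_bp/n_stems.
- **Thermodynamic (10)** — MFE; dG = MFE/L; MFE1 = dG/%(G+C);
  MFE2 = dG/n_stems; MFE3 = dG/n_loops; MFE4 = dG/tot_bp; the pairing
  ensemble's Shannon entropy Q = −Σ p_ij log₂ p_ij with dQ = Q/L; the
  ensemble base-pair distance dD = Σ p_ij(1−p_ij)/L; and zD, the z-score of
  dD against dinucleotide-preserving shuffles refolded by the backend.

The manifest (name, group, formula for each of the 93 features) ships as a
versioned JSON data file and is enforced at featurization and prediction
time.

Evaluation reports TP/TN/FP/FN and SN, SP, accuracy, precision, F1, MCC
(standard signed form), trapezoidal ROC-AUC (which collapses to
(SN+SP)/2 for binary scores) and the average-precision AUPRC.

## Worked example

A synthetic study set (hairpin positives, shuffled/random negatives) through
the whole pipeline:

```sh
premir build-dataset --synthetic 60 90 --seed 5 --out data.csv
premir balance --table data.csv --method smote --k 3 --seed 1 --out balanced.csv
premir train --table balanced.csv --preset knn_smote --folds 5 --out model.joblib
premir evaluate --model model.joblib --table data.csv
```

prints

```
wrote 150 rows to data.csv (rejected 0)
wrote balanced dataset (smote) to balanced.csv
trained knn (5-fold CV accuracy 0.9849) -> model.joblib
TP         15
TN         22
FP         1
FN         0
acc        0.973684
SN         1.000000
SP         0.956522
precision  0.937500
F1         0.967742
MCC        0.946963
AUC        1.000000
AUPRC      1.000000
```

The dataset keeps 150 of 150 records (all generated hairpins satisfy the
length < 250 nt, −180 ≤ MFE ≤ −5 kcal/mol and 10–85% GC windows), SMOTE
raises the 45 training positives to parity with the 67 training negatives,
and the evaluation block is the held-out 25% test split: 15 of 15 true
hairpins recovered (SN = 1.0) with one false positive (SP = 0.957,
MCC = 0.947).

Screening a candidate and excising its 5' arm:

```sh
premir predict --model model.joblib --fasta query.fa --backend stacking
# query1	pre-miRNA	1.0000
premir mature --fasta query.fa --backend stacking --arm 5p --length 20
# >query1-5p pos=2-21 loop=1
# GCAGGUAGUUUAGCACGUGA
```

Trained parameter presets for all twelve (algorithm × balancing-strategy)
combinations are available by name (`svm_smote`, `rf_nm`,
`logr_imbalance`, ..., plus the deployment aliases `insect_svm` and
`insect_rf`); see `premir.tuned_presets()`.

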