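# Methods

## Problem and model

`premir` treats pre-miRNA recognition as binary classification of RNA
stem-loops. Each candidate is a sequence over {A,C,G,U} with a secondary
structure in dot-bracket notation and a minimum free energy (MFE, kcal/mol).
The classifier never sees the raw sequence: it sees a fixed, ordered
93-dimensional descriptor combining local sequence/structure context
(triplet elements), global base composition, structural motif counts, and
MFE-derived thermodynamic ratios. Labels are 1 (genuine precursor) and 0
(pseudo hairpin / non-precursor).

## Structure conventions

Positions are 1-based, intervals closed. Pair tables are built by stack
matching; pseudoknot alphabets are rejected. Two motif definitions matter
and both are deliberate readings of loosely standardized terms:

- **Stem**: a maximal run of stacked pairs — (i,j),(i+1,j−1),… — of run
  length ≥ 4, i.e. *more than three* contiguous base pairs read literally.
  `annotate_motifs(min_stem=3)` switches to the ≥ 3 convention used by some
  other tools.
- **Hairpin loop**: an unpaired run immediately enclosed by a single pair —
  the `(\.+)` motif where the flanking brackets pair each other. Internal
  loops, bulges and multibranch interiors are *not* counted in `n_loops`;
  `loop_length` is the **sum** of hairpin-loop sizes across loops (a
  multi-loop precursor contributes all of them).

## Feature formulas and numerical choices

- Triplet elements map ')' to '(' before binning, so both partners of a
  pair read as "paired"; values are frequencies count/(L−2). The 32-bin
  order (middle nucleotide major, pattern minor) is fixed by the manifest.
- Dinucleotide percentages use overlapping windows, denominator L−1, so the
  16 values sum to 100 exactly.
- dG = MFE/L; dP = tot_bp/L; MFE1 = dG/%(G+C); MFE2 = dG/n_stems;
  MFE3 = dG/n_loops; MFE4 = dG/tot_bp; avg_bp = tot_bp/n_stems. The
  "total bases" denominator in MFE4 and avg_bp is taken to be the base-pair
  count: this keeps MFE4 distinct from dG and follows the thermodynamic
  feature lineage these ratios come from.
- **Zero denominators yield 0**, never NaN/∞: an unfolded sequence (no
  stems, no loops, no pairs) must still produce a finite vector so it can
  be classified — as a negative. This convention is part of the descriptor
  definition, not an error path.
- Ensemble features need a base-pair probability matrix p_ij (upper
  triangular, each p_ij ∈ [0,1]). Q = −Σ p_ij log₂ p_ij with 0·log 0 = 0;
  dQ = Q/L; dD = Σ p_ij(1−p_ij)/L, the expected base-pair distance between
  two ensemble draws per nucleotide. Q and dQ are kept as two manifest
  entries. zD is the z-score of dD against M dinucleotide-preserving
  shuffles (Altschul–Erikson Euler-path algorithm) refolded by the same
  backend; M defaults to 100 and the shuffle stream is seeded. zD is 0 when
  M < 2 or the shuffle distribution is degenerate. Bulk pipelines
  (`featurize_many`, dataset building) default to M = 0 because the
  deterministic fixture backend's shuffle distribution is not
  thermodynamically meaningful; single-record `featurize` defaults to
  M = 100 for use with a partition-function backend.

## Folding backends

`FoldingBackend` is a two-method contract: `fold(seq)` →
structure-with-MFE, `pairing_probabilities(seq)` → p_ij matrix.

- `ViennaBackend` wraps the RNAfold thermodynamic model (MFE structure,
  partition function). It is imported lazily; nothing else in the package
  needs it.
- `StackingBackend` is a Nussinov-style base-pair-maximization dynamic
  program (canonical pairs incl. G·U, minimum loop 3 nt, +1 per pair, +1
  stacking bonus) with a surrogate energy of −2 kcal/mol per stacked pair
  and +3 per hairpin loop, and a sharp pseudo-ensemble (p = 0.9 on each
  predicted pair). It is deterministic and dependency-free. It is **not** a
  thermodynamic model: its role is to give fixtures and tests a consistent,
  reproducible structure, MFE scale, and probability matrix.

## Dataset assembly

Filters keep a record iff length < 250 nt (strict: the longest known insect
precursor is 222 nt, so the boundary itself is unobservable in real data),
−180 ≤ MFE ≤ −5 kcal/mol (inclusive; the motivating real extremes −5.4 and
−174.9 lie strictly inside) and 10 ≤ GC% ≤ 85 (inclusive). Rejections carry
the first failing rule in that order. Splitting is stratified 75/25 with a
fixed seed; stratification is used because real positive:negative ratios
are extreme (~1:7).

## Synthetic study set

`generate_fixtures(n_pos, n_neg, seed)` emulates the hairpin-vs-background
contrast without any downloads:

- positives: a stem of 15–40 complementary pairs with G·U wobble at rate
  0.1, a 3–10 nt loop, 2–8 nt tails; the dot-bracket follows from the
  construction and the MFE is the stacking surrogate, which places every
  positive inside the default filter windows;
- negatives: half dinucleotide-preserving shuffles of fresh hairpins
  (composition-matched), half uniform random sequences of 40–110 nt, folded
  by the stacking backend.

What it does *not* emulate: real thermodynamics, genomic base composition,
the taxonomic structure of miRNA families, or negative sets built from
ncRNA that closely mimics precursors. Passing the learning-sanity checks on
this set shows the pipeline is wired correctly and the descriptor separates
structured from unstructured RNA; it says nothing about accuracy on real
insect genomes, for which retraining on curated corpora is required.

## Balancing

SMOTE (k = 5, Euclidean on scaled features) interpolates x + u(x′−x)
between a minority point and one of its k nearest minority neighbours;
NearMiss-1 (k = 3) keeps majority points with the smallest mean distance to
their k nearest minority points, stable ties by row order. Both apply
**after** scaling and after the 75/25 split, to training rows only, so
synthetic points never leak into evaluation. Both are bit-reproducible
under a seed.

## Training, tuning, evaluation

Estimators are scikit-learn: SVC (probabilities via sigmoid/Platt
calibration, `CalibratedClassifierCV(..., ensemble=False)`), random forest
(probability = tree-vote fraction), logistic regression, KNN (minkowski
order p = 3 when that metric is selected). The decision threshold is fixed
at 0.5.

Tuning is a two-stage protocol: uniform random sampling of n configurations
from the per-algorithm grids (SVM C 0.25–100, kernels linear/poly/rbf,
gamma 0.001–10; RF 10–5000 trees, depth 5–100, bootstrap on/off, leaf
1–10, split 2–10; KNN 1–50 neighbours over three metrics; LogR C 10–100
over three solvers), then coordinate-wise grid refinement — hold the best
configuration, sweep one parameter at a time over its full grid, repeat
until stable. Ties resolve toward the simpler model (grids are ordered
simplest-first and only strict improvements move the optimum). All
configuration scores are 10-fold stratified CV mean accuracies under one
run-level seed; every evaluated configuration is logged in the search
trace.

The metric suite computes SN, SP, accuracy, precision, F1 and MCC from the
confusion counts (MCC in the standard signed form, numerator TP·TN −
FP·FN), ROC-AUC by trapezoidal summation over threshold-swept (FPR, TPR)
points — for binary 0/1 scores this collapses to the single-operating-point
identity AUC = (SN+SP)/2 — and AUPRC as the average-precision step sum.
Zero-denominator metrics return 0, so degenerate all-negative classifiers
report precision = F1 = MCC = 0 rather than NaN.

Presets: `tuned_presets()` carries the best-performing parameter sets for
all twelve (algorithm × balancing) combinations from the tuning protocol
run at full scale (e.g. `svm_smote`: C = 10, rbf, γ = 0.01; `rf_smote`:
1600 trees, depth 30, no bootstrap; `knn_nm`: Euclidean, 7 neighbours),
with `insect_svm`/`insect_rf` as deployment aliases.

## Mature-arm extraction

Given a hairpin loop chosen by 5'→3' index, the 5p candidate is the
`length` nucleotides ending immediately before the loop's first unpaired
base and the 3p candidate starts immediately after its last. The cut is
flush with the loop: no Drosha/Dicer offset model is applied, a documented
simplification. Default length 22 nt (configurable 18–26); candidates
shorter than requested (short arms) are truncated with a warning.

## Problem sizes

The test suite and the acceptance script run on synthetic sets of at most
500 + 500 records (descriptor checks use 100 + 100; balancing toys use tens
of points). These sizes were chosen as the smallest at which the learning
checks are stable across seeds.

## Known limitations

- The stacking backend's energies and pseudo-ensemble are surrogates;
  zD computed with it is reproducible but not biophysically meaningful.
- NearMiss versions 2/3 and SMOTE variants (ADASYN, borderline) are not
  implemented.
- No genome-wide scanning, sliding-window hairpin extraction, pseudoknots,
  or miRNA target search.
- Presets encode published tuning outcomes; they are starting points, not
  substitutes for retuning on new corpora.
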