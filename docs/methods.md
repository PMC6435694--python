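# Methods

## Problem and model

`neuropep` classifies short peptides (5–80 aa over the 20 natural amino
acids) as insect neuropeptides or non-neuropeptides from sequence-derived
features, and uses the resulting scorer for single-mutant design and
sliding-window protein scanning.

The features are the classical composition family:

* **AAC** — per-residue percent composition, `Comp(i) = 100·R_i/N`, 20-dim.
* **DPC** — percent frequency of each ordered residue pair over the `N−1`
  overlapping length-2 windows, 400-dim. (Dividing by the number of windows,
  not by the 400 possible dipeptides, is what makes the vector sum to 100
  and is the standard definition.)
* **Split/terminus composition** — AAC or DPC restricted to the first/last
  k ∈ {5,10,15} residues, or to the joined `NkCk` 2k-mer. When
  k ≤ L < 2k the two windows overlap and the joined string still has length
  2k; peptides shorter than k are excluded from that scheme with a warning.
* **Binary profiles** — one-hot encoding of terminus positions, 20 bits per
  position in alphabetical residue order, so `N10C10` is 400-dim with
  exactly 20 ones.

Feature order is strict alphabetical one-letter order everywhere, making
vectors bit-comparable across runs.

Classifiers are standard scikit-learn estimators behind a thin scoring
contract: RBF-kernel SVM (kernel width `g`, regularization `c`,
positive-class cost factor `j` implemented as a class weight), random
forest (`ntree`), pruned decision tree (`m` = minimum leaf size; a
WEKA-style pruning confidence is recorded in the model spec for provenance
but does not drive the sklearn tree), Gaussian naive Bayes, and a
linear-kernel margin classifier standing in for SMO-style linear SVMs.
Scores are signed margins for margin learners and `2·p(positive) − 1` for
probabilistic ones, so threshold 0 is a sensible default for all.

## Benchmarks and validation protocol

A labeled benchmark holds positives and negatives (disjoint by sequence),
an 80/20 stratified train/validation split (`floor(0.8·n)` per class to
train), and a five-fold class-stratified partition of the training split
(fold sizes differ by at most 1 within a class; 700+700 training peptides
give 140+140 folds). Duplicate sequences are removed before splitting —
exact identity only; peptides differing by a single residue are both kept,
since one substitution can change activity.

Hyperparameters are chosen by exhaustive grid search scored by five-fold
cross-validation: in each rotation the model trains on four folds, the
classification threshold is chosen by a full threshold sweep **on the
training folds' scores** (maximizing accuracy, ties broken by the most
balanced |Sen−Spc|) and applied to the held-out fold, so held-out data
never influences the operating point. Headline CV numbers are the
unweighted mean over the five folds; a pooled-score AUROC is also emitted
as a diagnostic. The winning grid point maximizes mean CV accuracy, ties
broken by higher mean MCC, then smaller `c`. The final model is refit on
the whole training split and evaluated externally on the validation split.

The full RBF grid is `g ∈ {1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2, 0.1, 0.5,
1, 5, 10} × c ∈ {1..15} × j ∈ {1..5}` (825 points). The quick grid used by
the CLI default, the preset models and the acceptance script is
`g ∈ {1e-3, 1e-2, 0.1} × c ∈ {1, 5} × j = 1` (6 points), which keeps an
end-to-end run at n = 500 peptides/class on one CPU under half a minute;
the grid is an explicit argument, so the full search is always available.

Metrics are computed from first principles: Sen = 100·TP/(TP+FN),
Spc = 100·TN/(TN+FP), Acc = 100·(TP+TN)/total, and MCC with the usual
product-of-margins denominator (0 by convention when any margin is empty).
AUROC is the Mann–Whitney rank statistic (ties counted half), which equals
the trapezoidal area under the TPR-vs-FPR curve; tests cross-check it
against brute-force pair counting and scikit-learn. Reports print 2
decimals; tests compare at full precision with |Δ| ≤ 0.005 for 2-dp values.

## Hard negatives

The compositionally-similar benchmark selects, for each positive in input
order, the unused candidate-pool peptide minimizing the Euclidean distance
between AAC vectors — greedy nearest-neighbour matching without
replacement, ties broken by smallest candidate id. A globally optimal
assignment is deliberately not attempted: the greedy rule is deterministic,
cheap, and already reduces the mean matched distance to ~60% of a random
matching on synthetic pools.

## Motif mining

Exclusive motifs are contiguous substrings of length 3–6 present in at
least `min_support` positives (support counts peptides, not occurrences)
and in **no** negative. This is a transparent exact-substring enumerator,
a deliberate simplification of pattern-mining tools such as MERCI, whose
degenerate physicochemical alphabets and gapped classes are out of scope.
A maximality filter suppresses any motif wholly contained in a returned
longer motif with identical support. Analyses are meant to run on
deduplicated sets so repeated sequences cannot inflate support.

## Synthetic-data generator

The fixture generator emulates the statistical structure the method
assumes, so the full pipeline is testable without external downloads:

* lengths uniform on 5–80 aa; background residues i.i.d. uniform;
* positives drawn from a composition enriching C, D, E, F, G, N, S, Y
  (the residues over-represented in natural insect neuropeptides) with a
  default weight factor of 2.5;
* per-position terminus preferences for the first five positions (defaults
  follow the reported natural-neuropeptide pattern: A/N at N-position 1,
  then F, D, S, I; L, F, N, G, L from the C-terminus), applied as
  stochastic overrides;
* optional planted motifs (e.g. `ECC`, `GPR`) inserted per peptide with a
  stated probability. When motifs are planted, negatives containing one are
  resampled, making planted motifs exclusive by construction — the property
  the motif-recovery checks rely on;
* a single `effect_size` scalar scales all three bias families.
  `effect_size = 0` makes positives exchangeable with background (the null
  benchmark); the default 1.0 is a moderate regime where the DPC–SVM
  pipeline reaches ~90% CV accuracy, and `STRONG_EFFECT = 2.0` is the
  strongly separable regime (~96–97%), mirroring the qualitative gap
  between a harder natural-peptide benchmark and a cleaner amidated one.

What the generator does **not** emulate: real neuropeptide families and
their homology structure, prepropeptide cleavage signatures, amino-acid
background frequencies of real proteomes (it uses a uniform background),
or any physicochemical coupling between adjacent residues beyond what the
planted biases induce. Passing tests therefore demonstrate that the
pipeline recovers signal it is pointed at and stays calibrated under the
null — not that real-data accuracies are reproduced.

## Numerical and design choices

* MCC returns 0 when any denominator margin is empty (standard convention).
* `sample_random_negatives` draws fragment lengths from the positive length
  multiset so length cannot act as a trivial class leak.
* Splits and folds are stratified by class; all randomness flows through
  explicit integer seeds via `numpy.random.default_rng` (no global state).
* Grid-search tie-breaks (MCC, then smaller `c`) and the threshold
  tie-break (most balanced Sen/Spc) make selection deterministic.
* Model files embed a JSON manifest (algorithm, hyperparameters, feature
  scheme, seed, training-matrix fingerprint, library versions) so a
  train/predict scheme mismatch is detectable rather than silent.
* Degenerate inputs fail loudly: empty sequences, non-natural residues
  (B, J, O, U, Z, X), single-class training data, NaN features, windows
  longer than the protein, and single-class AUROC all raise.

## Problem sizes

The test suite and `scripts/acceptance.py` use n = 500 peptides/class for
the stochastic power/null checks (one CPU, tens of seconds), 875/class for
the split/fold arithmetic, 1000 random peptides for encoder-oracle
equivalence, and 100–150/class for hard-negative and motif checks.

## Known limitations

* WEKA/SVMlight behaviour is represented, not bit-reproduced; published
  real-data accuracies depend on the original curated datasets and are not
  desk-reproducible, so they are not asserted anywhere.
* The motif miner is exact-substring only.
* No homology-aware splitting; redundancy removal is exact-identity.
* C-terminal amidation is carried as metadata and distinguishes fixture
  regimes, but no chemistry-aware feature is derived from it.
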