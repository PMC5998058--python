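# Methods

This note documents the models, formulas, parameter choices and numerical
conventions implemented in `fertpred`, and what the synthetic validation
does and does not establish.

## Descriptor engine

All encodings operate on the 20 canonical residues (alphabetical order
`ACDEFGHIKLMNPQRSTVWY`). Sequences must satisfy 60 < L < 6000 (strict) and
contain no non-canonical letters; both bounds and the lag parameters below
assume validated input, so every lag-based family is defined.

### Families and formulas

* **AAC/DC (420).** Relative residue frequencies (20) and relative
  frequencies of the L−1 adjacent ordered pairs (400). Each block sums
  to 1.
* **Autocorrelation (720).** For each of 8 property scales standardized to
  mean 0, sd 1 over the 20 residues (population sd), and lags d = 1..30:
  * normalized Moreau–Broto: `AC(d) = Σ p_i p_{i+d} / (L−d)`
  * Moran: lag-d centered covariance (denominator L−d) divided by the
    population variance of the sequence series (denominator L)
  * Geary: `Σ (p_i − p_{i+d})² / (2(L−d))` divided by the sample variance
    (denominator L−1)

  Order is type-major (Moreau–Broto, Moran, Geary), then property, then
  lag. A constant series (homopolymer) has zero variance; Moran and Geary
  are defined as 0 there rather than dividing by zero — detected by an
  exact max==min check, since a floating-point mean of identical values
  can leave a ~1e−16 residue that would otherwise make the ratio collapse
  to 1.
* **CTD (147).** Seven properties (hydrophobicity, normalized van der
  Waals volume, polarity, polarizability, charge, secondary structure,
  solvent accessibility), each partitioning the alphabet into 3 groups
  (Dubchak's classic partition). Composition = group fractions (21);
  transition = unordered cross-group adjacent-pair frequencies over L−1
  pairs (21); distribution = positions, as percent of L, of the first,
  25th-, 50th-, 75th-percentile and last member of each group (105). The
  k-th occurrence for percentile q is `ceil(q·n)` with the first
  occurrence at q=0; an empty group contributes five zeros.
* **SOCN/QSO (160).** Sequence-order-coupling numbers
  `τ_d = Σ d(R_i, R_{i+d})²` for d = 1..30 under two 20×20 distance
  matrices, then quasi-sequence-order components
  `f_r / (Σf + w Στ)` (20) and `w τ_d / (Σf + w Στ)` (30) per matrix,
  with w = 0.1 and f the relative frequencies.
* **PseAAC (130).** Type I: correlation factors θ_j = sequence mean of
  `Θ(R_i, R_{i+j})`, where Θ is the mean squared difference of three
  standardized scales (Eisenberg consensus hydrophobicity, Hopp–Woods
  hydrophilicity, side-chain mass); components
  `f_u/(Σf + wΣθ)` and `wθ_j/(Σf + wΣθ)` with λ = 30, w = 0.05. Type II
  (amphiphilic): hydrophobicity- and hydrophilicity-product correlations
  interleaved per lag (20 + 2λ components, same w).
* **Conjoint triad (343).** Residues mapped to Shen's 7 classes
  ({AGV}, {ILFP}, {YMTS}, {HNQW}, {RK}, {DE}, {C}); the L−2 overlapping
  class triads are counted into 7³ bins and normalized as
  `(f − min f)/max f`.

Defaults (nlag = 30 for both autocorrelation and sequence-order lags,
λ = 30, w_qso = 0.1, w_pseaac = 0.05, 8 autocorrelation scales, 7 CTD
properties, 7 triad classes) are the unique standard configuration
producing the group dimensions 420/720/147/160/130/343 — 1920 in total.
Feature names follow the protr conventions (`prop5.G2.residue25`,
`Schneider.Xr.S`, `VS333`, ...) so selected features are addressable by
the names used in the wider literature.

### Data tables

Property scales and groupings ship in `fertpred._tables`; `fertpred
--version` prints their checksums. Two provenance notes:

* The **Grantham** distance matrix is computed from Grantham's published
  formula (coefficients 1.833 / 0.1018 / 0.000399 over his composition,
  polarity and volume scales, scaled to mean off-diagonal distance 100)
  and reproduces published entries (Leu–Ile = 5, Cys–Trp = 215).
* The **Schneider–Wrede-style** matrix is a synthetic stand-in constructed
  from standardized hydrophobicity, hydrophilicity and side-chain-mass
  scales (RMS difference, scaled to [0, 1]); the published table is not
  bundled. It is structurally equivalent (symmetric, nonnegative, zero
  diagonal) and plays the same role in the QSO features, but individual
  `Schneider.*` feature values are not numerically comparable to tools
  using the original table.

Because the descriptor literature contains minor formula variants (e.g.
Moreau–Broto normalization, distribution percentile conventions), each
family is pinned by a brute-force oracle test rather than by prose: an
independently coded direct-formula implementation must agree to 1e−9
relative tolerance on random sequences.

## Benchmark construction

Fixed pipeline order: validate → redundancy-reduce → domain-deplete →
exact-duplicate-remove → sample → split.

* **Redundancy reduction** is greedy incremental clustering (length-sorted,
  join first representative with identity ≥ 0.5). Identity is defined as
  matches / alignment-length under a global alignment (match +1,
  mismatch −1, gap open −2, extend −0.5); dedicated clustering tools
  define identity slightly differently, which is why the definition is
  pinned here and oracle-tested.
* **Negative depletion** removes negatives sharing any domain accession
  with the positive pool (unannotated = kept) and negatives whose residue
  string exactly equals a positive's.
* **Sampling**: per positive class (the three classes plus their union,
  labelled `general`), five pairwise-disjoint negative subsamples of size
  |positives| are drawn without replacement — 20 balanced datasets. Each
  class uses its own RNG stream keyed by (seed, class label), so adding or
  removing a class never reshuffles another's draw. The union keeps the
  first occurrence of duplicated ids and is not re-clustered.
* **Split**: stratified 80/20 with train size `floor(0.8·n)` per label.

## Classifier

RBF-kernel SVMs (scikit-learn's libsvm backend). Grid search evaluates
every (C, γ) pair by stratified five-fold CV accuracy pooled over folds,
ties resolved toward smaller C then smaller γ; default grids
C ∈ {0.1, 1, 10, 100, 1000}, γ ∈ {0.001 … 0.1} bracket the optima
typically reported for this classification task. Within every CV fold the
min–max scaler is refitted on the fold-training part, so no test
information reaches the scaler; the final model stores its training-split
scaling statistics and applies them at prediction time. Probabilities are
Platt-style sigmoid calibration on internal five-fold splits
(`CalibratedClassifierCV(..., ensemble=False)`).

The two-layer cascade evaluates layer 2 only for sequences whose layer-1
probability is strictly above the threshold (default 0.5); the class with
the highest calibrated probability wins, ties broken by fixed alphabetical
class order and flagged. "SVM score" is interpreted as calibrated
probability rather than raw decision value, consistent with reporting
scores on a 0–1 scale; this is a documented interpretation choice. Given
replicate datasets, the member with the highest grid-searched CV accuracy
is selected per class.

Transcript input is translated by a six-frame longest-ORF scan (standard
genetic code; start at any codon by default or at ATG with
`require_atg`; minimum 60 aa; ties by frame index then position). This is
a deliberately simple translator, not a reimplementation of
composition-aware ORF callers; for real transcript data an external caller
can be used upstream and its proteins passed in directly.

## Evaluation

Sn, Sp and Acc are complements of the error rates over N⁺/N⁻. MCC is the
standard confusion-matrix Matthews coefficient, with MCC ≡ 0 when any
denominator factor vanishes. A commonly printed rearrangement of the MCC
with *sum* terms inside both radicand factors is not equivalent for
unbalanced counts (e.g. N⁺=20, N⁻=30, fn=4, fp=6 gives 0.592 standard vs
0.424 under the variant); the standard form is implemented and tested
against an independent label-array oracle. Tables report percentages;
the raw [−1, 1] value is also available.

## Feature-weight fusion

Nine algorithms: chi-squared, information gain, gain ratio, Gini impurity
reduction and symmetric uncertainty (continuous features discretized into
10 equal-width bins); deviation (per-feature sd — label-blind by design);
ReliefF with k = 10 neighbors on min–max scaled features; absolute loading
on the first principal component; and |w| of a linear SVM. Each
algorithm's weights are min–max normalized to [0, 1] so the 0.5 importance
threshold is comparable across algorithms; constant features are pinned
to 0 *after* normalization (a raw scale with negative scores, like relief,
would otherwise place them mid-range). Importance requires a score
strictly above the threshold in at least five algorithms; the optimal set
is the intersection over the five general-benchmark replicates.
Definitions of "deviation" and "uncertainty" vary across toolkits; the
standard deviations and symmetric uncertainty used here are the documented
choices.

## Synthetic validation study

The generator emulates labeled sequence pools with *compositional* class
signal: residues drawn i.i.d. from class-specific frequency vectors,
lengths uniform in (80, 200), optional motif insertion at a uniform
position. The frozen default suite plants a shared fertility signature —
serine and isoleucine frequencies doubled over database-background
frequencies — plus one class-specific extra each (oogenesis S ×1.5 extra,
spermatogenesis I ×1.5 extra, embryogenesis `IAIAIA` insertions with
probability 0.9), with 100 proteins per class and a 1600-protein negative
pool. These effect sizes and sizes were fixed once as the study
conditions; `effect_scale` interpolates them toward a null suite for
permutation-style controls. Compositional signal was chosen because the
descriptor families are composition and order statistics — motif planting
specifically exercises dipeptide/triad features.

Under these conditions the two-layer cascade reaches ≥ 90% held-out
accuracy at both layers, label permutation collapses CV accuracy to
chance, and the fusion selector recovers the planted S/I enrichment
(together with correlated descriptor aliases such as `Xc1.S` and
`Schneider.Xr.I` — the expected behaviour of a redundancy-unaware filter
selector). What this validates: the descriptors carry compositional
signal faithfully, the training machinery has no train/test leakage, and
the selector finds genuinely discriminative features. What it does not
show: performance on real curated proteins, where class signal is weaker,
structured (motifs, domains, phylogenetic correlation) and confounded —
i.i.d. residue draws have none of that structure, so accuracies here are
upper bounds of convenience, not estimates of real-world accuracy.

## Numerical and design notes

* All randomness flows through explicit integer seeds; per-class RNG
  streams derive from (seed, stable class key). Same seed ⇒ identical
  pools, draws, folds, grid choices and predictions.
* Homopolymer conventions: Moran/Geary = 0; all τ_d = 0 (QSO then reduces
  exactly to AAC); PseAAC θ_j = 0; a single nonzero triad bin normalizes
  to 1.
* Descriptor errors name the failing group and sequence id; prediction on
  invalid sequences produces per-sequence error entries without aborting
  the run.
* The boundary filters are strict (a length-60 sequence is rejected), and
  the fertility call is strictly greater than the threshold.
* Problem sizes in the test suite and acceptance script (30–100 proteins
  per class, grids of 3×5 points) are the package's chosen desk-scale
  study conditions; all components accept larger inputs unchanged.

## Known limitations

* The greedy clusterer is O(n²) alignments and meant for desk-scale pools;
  point a real clustering tool at large pools upstream.
* Only canonical, ungapped protein sequences are encoded; no PSSM,
  structural or embedding features.
* Multi-label assignment (one protein in two classes) is out of scope —
  layer 2 returns exactly one class.
* The `Schneider.*` QSO features use the synthetic stand-in distance
  matrix described above.
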