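# fertpred

Sequence-based prediction of fertility-related proteins (oogenesis,
spermatogenesis, embryogenesis) with a two-layer support-vector-machine
cascade over pseudo amino acid composition descriptors.

## Who this is for

Reproductive-biology and protein-function researchers who want to screen
candidate proteins — or unannotated transcripts from RNA-Seq projects — for
involvement in germ-cell development and early embryogenesis, using nothing
but the amino-acid sequence. The package is a library first (Python API +
`examples/`), with a thin `fertpred` command-line interface for FASTA-in /
TSV-out screening.

## The method

**Descriptors.** Each protein sequence is encoded as a 1920-dimensional
vector concatenating six descriptor families in the Chou PseAAC tradition:

| group      | dim | content |
|------------|-----|---------|
| `aac_dc`   | 420 | amino-acid composition $f_r$ + dipeptide composition |
| `autocorr` | 720 | Moreau–Broto, Moran and Geary autocorrelation; 8 standardized property scales × lags $d=1..30$ |
| `ctd`      | 147 | composition–transition–distribution over 7 physicochemical properties × 3 residue groups |
| `order`    | 160 | sequence-order-coupling numbers $\tau_d=\sum_i d(R_i,R_{i+d})^2$ + quasi-sequence-order, for two distance matrices |
| `pseaac`   | 130 | type I PseAAC ($20+\lambda$, $\lambda=30$, $w=0.05$) + type II amphiphilic PseAAC ($20+2\lambda$) |
| `ctriad`   | 343 | conjoint-triad counts over a 7-class reduced alphabet, min–max normalized |

**Classifier.** Two layers of RBF-kernel SVMs. Layer 1 answers *is this
protein fertility-related at all?* (trained on the union of the three
classes vs matched negatives). Sequences with calibrated probability
> 0.5 continue to layer 2, where three binary class models (oogenesis /
spermatogenesis / embryogenesis, each vs its own negatives) vote and the
highest probability wins. Hyperparameters $(C,\gamma)$ come from an
exhaustive grid search under stratified five-fold cross-validation;
features are min–max scaled with training-split statistics only.

**Benchmarks.** Positive pools are paired with equal-size negative
subsamples drawn without replacement — five pairwise-disjoint subsamples
per class, for four classes (three + the general union), giving 20
balanced benchmark datasets, each split 80/20 into train/test.

**Evaluation.** Sensitivity $Sn = 1-N^+_-/N^+$, specificity
$Sp = 1-N^-_+/N^-$, accuracy, and the Matthews correlation coefficient
(standard confusion-matrix form).

**Feature selection.** Nine weighting algorithms (chi-squared, information
gain, gain ratio, Gini, deviation, symmetric uncertainty, ReliefF, PCA
loading, linear-SVM weight) score every feature on a [0, 1] scale; a
feature is important when > 0.5 under at least five algorithms, and the
optimal set is the intersection of the important sets across the five
general-benchmark replicates.

Because curated positive/negative pools require database retrieval, the
package ships a synthetic-data module that generates labeled pools with
planted, documented compositional signal, so the entire pipeline is
testable offline (see `docs/methods.md`).

## Worked example

`python examples/02_train_two_layer.py` generates a small synthetic study
(30 proteins per class), builds the 20 benchmark datasets, trains the
cascade and prints:

```
built 20 benchmark datasets (4 classes x 5 disjoint negative subsamples)
layer 1 (general): C=100.0, gamma=0.005, CV accuracy 91.0%
layer 2 embryogenesis: CV accuracy 91.7%
layer 2 oogenesis: CV accuracy 89.6%
layer 2 spermatogenesis: CV accuracy 83.3%
held-out (general rep 1): Acc 91.7%  Sn 94.4%  Sp 88.9%  MCC 83.5
oogenesis_00000: p(fertility)=0.997 -> fertility, class oogenesis
...
negative_00000: p(fertility)=0.081 -> not fertility-related
```

The CV accuracies are pooled five-fold cross-validation results used both
for grid search and for selecting the best of the five negative-subsample
replicates; the held-out row is the untouched 20% test split. Probabilities
are Platt-calibrated SVM outputs; 0.997 vs 0.081 shows the planted
class signal separating cleanly. The other examples cover descriptor
encoding (`01`), fusion feature selection (`03`, which recovers the planted
serine/isoleucine enrichment), and transcript ORF translation (`04`).

CLI equivalent:

```bash
fertpred simulate --seed 7 --out-dir pools/
fertpred build-dataset --pool-dir pools/ --seed 7 --out-dir bench/
fertpred train --datasets bench/datasets.json --seed 7 --out-dir model/
fertpred predict query.fasta --model model/model.joblib --output calls.tsv
```

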