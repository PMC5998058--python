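"""Benchmark dataset construction with class-imbalance handling.

The construction mirrors the standard recipe for severely imbalanced
positive/negative protein pools: redundancy reduction within pools,
domain-based depletion and exact-duplicate removal of the negative pool,
then five pairwise-disjoint balanced negative subsamples per positive class
(three fertility classes plus their "general" union), yielding 20 benchmark
datasets, each split 80/20 into train and test.

Pipeline order is fixed: validate -> redundancy-reduce -> domain-deplete ->
exact-duplicate-remove -> sample -> split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import numpy as np
from Bio import Align

from .sequence_io import ProteinSequence
from .synthetic_data import LabeledPool

__all__ = [
    "BenchmarkDataset",
    "reduce_redundancy",
    "pairwise_identity",
    "remove_shared_domains",
    "remove_exact_duplicates",
    "build_benchmark_sets",
    "split_train_test",
]


@dataclass
class BenchmarkDataset:
    """One positive set paired with one balanced negative subsample."""

    class_label: str
    replicate_index: int  # 1..5
    positives: list[ProteinSequence]
    negatives: list[ProteinSequence]
    train_ids: set[str] = field(default_factory=set)
    test_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.negatives) != len(self.positives):
            raise ValueError("benchmark dataset must be balanced")
        pos_ids = {s.id for s in self.positives}
        neg_ids = {s.id for s in self.negatives}
        if pos_ids & neg_ids:
            raise ValueError("a sequence appears in both positives and negatives")

    @property
    def label_of(self) -> dict[str, int]:
        out = {s.id: 1 for s in self.positives}
        out.update({s.id: 0 for s in self.negatives})
        return out

    def members(self, ids: set[str]) -> list[ProteinSequence]:
        return [s for s in self.positives + self.negatives if s.id in ids]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in one optimal global alignment.

    Identity = matches / alignment length (columns including gaps).  This is
    the documented in-package definition; dedicated clustering tools define
    identity slightly differently.
    """
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def reduce_redundancy(
    seqs: list[ProteinSequence],
    identity_cutoff: float = 0.5,
) -> list[ProteinSequence]:
    """Greedy incremental clustering; returns cluster representatives.

    Sequences are sorted by length descending (ties by id for determinism);
    each joins the first existing cluster whose representative shares
    identity >= cutoff, else founds a new cluster.
    """
    if not (0.0 < identity_cutoff <= 1.0):
        raise ValueError("identity_cutoff must be in (0, 1]")
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    reps: list[ProteinSequence] = []
    for s in ordered:
        for rep in reps:
            if pairwise_identity(s.residues, rep.residues) >= identity_cutoff:
                break
        else:
            reps.append(s)
    return reps


def remove_shared_domains(
    negatives: LabeledPool,
    neg_domains: dict[str, set[str]],
    pos_domains: set[str],
) -> LabeledPool:
    """Drop negatives annotated with any domain present in the positive set.

    Unannotated negatives are treated as domain-free and kept.
    """
    kept = [
        s for s in negatives.sequences
        if not (neg_domains.get(s.id, set()) & pos_domains)
    ]
    return LabeledPool(class_label=negatives.class_label, sequences=kept)


def remove_exact_duplicates(
    negatives: LabeledPool,
    positives: list[ProteinSequence],
) -> LabeledPool:
    """Drop negatives whose residue string exactly equals some positive's."""
    pos_strings = {s.residues for s in positives}
    kept = [s for s in negatives.sequences if s.residues not in pos_strings]
    return LabeledPool(class_label=negatives.class_label, sequences=kept)


def _class_key(label: str) -> int:
    return int.from_bytes(label.encode(), "little") % (2**31)


GENERAL_LABEL = "general"


def build_benchmark_sets(
    class_pools: dict[str, LabeledPool],
    negative_pool: LabeledPool,
    seed: int,
    n_replicates: int = 5,
) -> list[BenchmarkDataset]:
    """Construct the balanced benchmark datasets (classes + general union).

    For each positive class — the supplied classes plus their ``general``
    union (duplicate ids removed, first occurrence kept) — ``n_replicates``
    pairwise-disjoint negative subsamples of size |positives| are drawn
    without replacement from the negative pool.  Sampling uses one RNG
    stream per (seed, class), so adding a class never changes another
    class's draw.  With three classes and five replicates this yields the
    canonical 20 datasets.
    """
    pools = dict(class_pools)
    seen: set[str] = set()
    union: list[ProteinSequence] = []
    for pool in class_pools.values():
        for s in pool.sequences:
            if s.id not in seen:
                seen.add(s.id)
                union.append(s)
    pools[GENERAL_LABEL] = LabeledPool(GENERAL_LABEL, union)

    datasets: list[BenchmarkDataset] = []
    for label, pool in pools.items():
        n_pos = len(pool)
        needed = n_replicates * n_pos
        if len(negative_pool) < needed:
            raise ValueError(
                f"class {label!r} needs {needed} negatives "
                f"({n_replicates} disjoint subsamples of {n_pos}); "
                f"pool has {len(negative_pool)}"
            )
        rng = np.random.default_rng([seed, _class_key(label)])
        picks = rng.choice(len(negative_pool), size=needed, replace=False)
        for rep in range(n_replicates):
            sub = [negative_pool.sequences[i] for i in picks[rep * n_pos:(rep + 1) * n_pos]]
            datasets.append(BenchmarkDataset(
                class_label=label,
                replicate_index=rep + 1,
                positives=list(pool.sequences),
                negatives=sub,
            ))
    return datasets


def split_train_test(
    ds: BenchmarkDataset,
    train_frac: float = 0.8,
    seed: int = 0,
) -> BenchmarkDataset:
    """Assign a stratified train/test split (train size = floor(frac*n) per label)."""
    rng = np.random.default_rng([seed, _class_key(ds.class_label), ds.replicate_index])
    train_ids: set[str] = set()
    test_ids: set[str] = set()
    for group in (ds.positives, ds.negatives):
        ids = [s.id for s in group]
        perm = rng.permutation(len(ids))
        n_train = floor(train_frac * len(ids))
        train_ids.update(ids[i] for i in perm[:n_train])
        test_ids.update(ids[i] for i in perm[n_train:])
    ds.train_ids = train_ids
    ds.test_ids = test_ids
    return ds
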