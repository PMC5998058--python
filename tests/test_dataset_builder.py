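"""Benchmark construction: redundancy reduction, depletion, sampling, splits."""

import numpy as np
import pytest

from fertpred.dataset_builder import (
    build_benchmark_sets,
    pairwise_identity,
    reduce_redundancy,
    remove_exact_duplicates,
    remove_shared_domains,
    split_train_test,
)
from fertpred.sequence_io import ProteinSequence
from fertpred.synthetic_data import GeneratorSpec, LabeledPool, generate_pool
from conftest import random_protein


def _greedy_oracle(seqs, cutoff):
    """Independent greedy clustering using an exhaustive identity matrix."""
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    ident = {
        (a.id, b.id): pairwise_identity(a.residues, b.residues)
        for a in ordered for b in ordered
    }
    reps = []
    for s in ordered:
        if not any(ident[(s.id, r.id)] >= cutoff for r in reps):
            reps.append(s)
    return reps


class TestReduceRedundancy:
    def test_identical_sequences_collapse(self, rng):
        s = random_protein(rng, 80, "a")
        t = ProteinSequence(id="b", residues=s.residues)
        assert len(reduce_redundancy([s, t])) == 1

    def test_empty_input(self):
        assert reduce_redundancy([]) == []

    def test_invalid_cutoff(self, rng):
        with pytest.raises(ValueError):
            reduce_redundancy([random_protein(rng, 70)], identity_cutoff=1.5)

    def test_matches_bruteforce_oracle(self, rng):
        base = random_protein(rng, 90, "base").residues
        seqs = []
        for i in range(10):
            # mutate a varying fraction of positions to span identities
            n_mut = int(rng.integers(0, 80))
            pos = rng.choice(90, size=n_mut, replace=False)
            res = list(base)
            for p in pos:
                res[p] = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))
            seqs.append(ProteinSequence(id=f"m{i}", residues="".join(res)))
        got = reduce_redundancy(seqs, identity_cutoff=0.5)
        want = _greedy_oracle(seqs, 0.5)
        assert [s.id for s in got] == [s.id for s in want]

    def test_output_has_no_redundant_pair_vs_representatives(self, rng):
        seqs = [random_protein(rng, int(rng.integers(65, 90)), f"s{i}") for i in range(8)]
        reps = reduce_redundancy(seqs, identity_cutoff=0.5)
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                assert pairwise_identity(a.residues, b.residues) < 0.5


class TestDomainDepletion:
    def test_shared_domain_removed_unannotated_kept(self, rng):
        pool = LabeledPool("negative", [random_protein(rng, 70, f"n{i}") for i in range(3)])
        neg_domains = {"n0": {"PF00001"}, "n1": {"PF09999"}}
        out = remove_shared_domains(pool, neg_domains, pos_domains={"PF00001"})
        assert [s.id for s in out.sequences] == ["n1", "n2"]

    def test_matches_set_arithmetic_oracle(self, rng):
        pool = LabeledPool("negative", [random_protein(rng, 70, f"n{i}") for i in range(20)])
        neg_domains = {
            f"n{i}": {f"PF{j:05d}" for j in rng.integers(0, 10, size=2)}
            for i in range(0, 20, 2)
        }
        pos_domains = {"PF00002", "PF00005"}
        out = remove_shared_domains(pool, neg_domains, pos_domains)
        want = [
            s.id for s in pool.sequences
            if not (neg_domains.get(s.id, set()) & pos_domains)
        ]
        assert [s.id for s in out.sequences] == want


class TestExactDuplicates:
    def test_identical_dropped_near_identical_kept(self, rng):
        pos = [random_protein(rng, 70, "p0")]
        near = list(pos[0].residues)
        near[0] = "W" if near[0] != "W" else "Y"
        negs = LabeledPool("negative", [
            ProteinSequence(id="dup", residues=pos[0].residues),
            ProteinSequence(id="near", residues="".join(near)),
        ])
        out = remove_exact_duplicates(negs, pos)
        assert [s.id for s in out.sequences] == ["near"]

    def test_no_overlap_is_identity(self, rng):
        negs = LabeledPool("negative", [random_protein(rng, 70, f"n{i}") for i in range(4)])
        out = remove_exact_duplicates(negs, [random_protein(rng, 80, "p")])
        assert out.sequences == negs.sequences


def _small_pools(rng, sizes=(30, 40, 50), n_neg=1000):
    labels = ("embryogenesis", "oogenesis", "spermatogenesis")
    pools = {}
    for label, n in zip(labels, sizes):
        spec = GeneratorSpec(n_per_class=n, length_range=(61, 90), seed=7)
        pools[label] = generate_pool(spec, label)
    neg = generate_pool(GeneratorSpec(n_per_class=n_neg, length_range=(61, 90), seed=7),
                        "negative")
    return pools, neg


class TestBuildBenchmarkSets:
    def test_twenty_datasets_with_disjoint_negatives(self, rng):
        pools, neg = _small_pools(rng)
        datasets = build_benchmark_sets(pools, neg, seed=3)
        assert len(datasets) == 20
        by_class = {}
        for ds in datasets:
            assert len(ds.negatives) == len(ds.positives)
            by_class.setdefault(ds.class_label, []).append(ds)
        assert set(by_class) == {"embryogenesis", "oogenesis", "spermatogenesis", "general"}
        for reps in by_class.values():
            assert len(reps) == 5
            neg_ids = [frozenset(s.id for s in ds.negatives) for ds in reps]
            for i in range(5):
                assert len(neg_ids[i]) == len(reps[i].negatives)  # no replacement
                for j in range(i + 1, 5):
                    assert not (neg_ids[i] & neg_ids[j])

    def test_general_is_union_of_classes(self, rng):
        pools, neg = _small_pools(rng)
        datasets = build_benchmark_sets(pools, neg, seed=3)
        general = next(ds for ds in datasets if ds.class_label == "general")
        union_ids = set()
        for pool in pools.values():
            union_ids |= {s.id for s in pool.sequences}
        assert {s.id for s in general.positives} == union_ids

    def test_seeded_determinism_and_per_class_streams(self, rng):
        pools, neg = _small_pools(rng)
        a = build_benchmark_sets(pools, neg, seed=3)
        b = build_benchmark_sets(pools, neg, seed=3)
        assert [[s.id for s in ds.negatives] for ds in a] == \
               [[s.id for s in ds.negatives] for ds in b]
        # dropping one class leaves another class's draw untouched
        partial = {k: v for k, v in pools.items() if k != "oogenesis"}
        c = build_benchmark_sets(partial, neg, seed=3)
        emb_a = [[s.id for s in ds.negatives] for ds in a if ds.class_label == "embryogenesis"]
        emb_c = [[s.id for s in ds.negatives] for ds in c if ds.class_label == "embryogenesis"]
        assert emb_a == emb_c

    def test_insufficient_negatives_error_states_requirement(self, rng):
        pools, _ = _small_pools(rng)
        tiny_neg = LabeledPool("negative", [random_protein(rng, 70, f"n{i}")
                                            for i in range(100)])
        with pytest.raises(ValueError, match="negatives"):
            build_benchmark_sets(pools, tiny_neg, seed=3)


class TestSplitTrainTest:
    def test_80_20_counts(self, rng):
        pools, neg = _small_pools(rng, sizes=(100, 30, 40), n_neg=1200)
        ds = next(d for d in build_benchmark_sets(pools, neg, seed=1)
                  if d.class_label == "embryogenesis")
        split_train_test(ds, seed=1)
        train_pos = sum(1 for s in ds.positives if s.id in ds.train_ids)
        test_pos = sum(1 for s in ds.positives if s.id in ds.test_ids)
        assert (train_pos, test_pos) == (80, 20)
        assert not (ds.train_ids & ds.test_ids)
        assert len(ds.train_ids) + len(ds.test_ids) == 200

    def test_floor_rounding_on_tiny_dataset(self, rng):
        pos = [random_protein(rng, 70, f"p{i}") for i in range(5)]
        negs = [random_protein(rng, 70, f"n{i}") for i in range(5)]
        from fertpred.dataset_builder import BenchmarkDataset
        ds = BenchmarkDataset("c", 1, pos, negs)
        split_train_test(ds, seed=0)
        assert sum(1 for s in pos if s.id in ds.train_ids) == 4
        assert sum(1 for s in negs if s.id in ds.train_ids) == 4
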