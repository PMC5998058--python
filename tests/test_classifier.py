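"""SVM training machinery and the two-layer prediction cascade."""

import numpy as np
import pytest

from fertpred.classifier import (
    FeatureCache,
    SvmParams,
    cross_validate,
    evaluate_on_test,
    grid_search,
    predict_two_layer,
    train_binary,
    train_two_layer,
)
from fertpred.dataset_builder import build_benchmark_sets, split_train_test
from fertpred.descriptors import DescriptorConfig
from fertpred.sequence_io import ProteinSequence
from fertpred.synthetic_data import generate_benchmark_suite


def _separable_features(rng, n=50, d=8, margin=3.0):
    X = rng.normal(size=(2 * n, d))
    X[:n, 0] += margin
    y = np.array([1] * n + [0] * n)
    return X, y


class TestCrossValidate:
    def test_each_sample_tested_once(self, rng):
        X, y = _separable_features(rng)
        res = cross_validate(X, y, SvmParams(1, 0.1), k=5, seed=0)
        assert res.pooled_counts.n_pos + res.pooled_counts.n_neg == len(y)
        assert len(res.fold_metrics) == 5

    def test_determinism(self, rng):
        X, y = _separable_features(rng)
        a = cross_validate(X, y, SvmParams(1, 0.1), k=5, seed=3)
        b = cross_validate(X, y, SvmParams(1, 0.1), k=5, seed=3)
        assert a.accuracy == b.accuracy
        assert a.pooled_counts == b.pooled_counts

    def test_separable_data_high_accuracy(self, rng):
        X, y = _separable_features(rng, margin=4.0)
        assert cross_validate(X, y, SvmParams(10, 0.1), k=5, seed=0).accuracy >= 0.95

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array([1, 1, 1, 1, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="fewer than"):
            cross_validate(X, y, SvmParams(1, 0.1), k=5, seed=0)

    def test_permuted_labels_near_chance(self, rng):
        X, y = _separable_features(rng, n=50)
        yp = rng.permutation(y)
        acc = cross_validate(X, yp, SvmParams(100, 0.01), k=5, seed=1).accuracy
        assert 0.3 <= acc <= 0.7


class TestGridSearch:
    def test_returns_grid_member_and_argmax(self, rng):
        X, y = _separable_features(rng)
        C_grid, g_grid = (0.5, 5.0), (0.01, 0.2)
        params, acc, table = grid_search(X, y, C_grid, g_grid, seed=0)
        assert params.C in C_grid and params.gamma in g_grid
        assert all(acc >= a for _, a in table)
        assert len(table) == 4

    def test_single_point_grid(self, rng):
        X, y = _separable_features(rng)
        params, _, _ = grid_search(X, y, (7.0,), (0.03,), seed=0)
        assert (params.C, params.gamma) == (7.0, 0.03)

    def test_tie_prefers_smallest(self, rng):
        X, y = _separable_features(rng, margin=10.0)  # everything ties at 1.0
        params, acc, _ = grid_search(X, y, (1.0, 10.0), (0.01, 0.1), seed=0)
        assert acc == 1.0 and params == SvmParams(1.0, 0.01)

    def test_empty_grid_rejected(self, rng):
        X, y = _separable_features(rng)
        with pytest.raises(ValueError):
            grid_search(X, y, (), (0.1,), seed=0)


@pytest.fixture(scope="module")
def tiny_suite():
    pools, _ = generate_benchmark_suite(31, n_per_class=30, n_negative=640,
                                        length_range=(61, 100))
    classes = {k: pools[k] for k in ("embryogenesis", "oogenesis", "spermatogenesis")}
    datasets = build_benchmark_sets(classes, pools["negative"], seed=31)
    by_class = {}
    for ds in datasets:
        split_train_test(ds, seed=31)
        by_class.setdefault(ds.class_label, []).append(ds)
    return pools, by_class


@pytest.fixture(scope="module")
def tiny_model(tiny_suite):
    _, by_class = tiny_suite
    cfg = DescriptorConfig()
    cache = FeatureCache(cfg)
    model = train_two_layer(
        {label: reps[0] for label, reps in by_class.items()},
        cfg, C_grid=(100.0,), gamma_grid=(0.005, 0.05), seed=31, cache=cache,
    )
    return model, cache, by_class


class TestTrainBinary:
    def test_separable_dataset_generalizes(self, tiny_suite):
        _, by_class = tiny_suite
        cfg = DescriptorConfig()
        cache = FeatureCache(cfg)
        ds = by_class["oogenesis"][0]
        model = train_binary(ds, cfg, (100.0,), (0.005, 0.05), seed=31, cache=cache)
        assert evaluate_on_test(model, ds, cache).acc >= 0.8

    def test_training_determinism(self, tiny_suite):
        _, by_class = tiny_suite
        cfg = DescriptorConfig()
        cache = FeatureCache(cfg)
        ds = by_class["spermatogenesis"][0]
        m1 = train_binary(ds, cfg, (100.0,), (0.05,), seed=31, cache=cache)
        m2 = train_binary(ds, cfg, (100.0,), (0.05,), seed=31, cache=cache)
        X = cache.matrix(ds.members(ds.test_ids))
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
        np.testing.assert_allclose(m1.predict_proba(X), m2.predict_proba(X))

    def test_scaler_fitted_on_train_only(self, tiny_suite):
        _, by_class = tiny_suite
        cfg = DescriptorConfig()
        cache = FeatureCache(cfg)
        ds = by_class["general"][0]
        model = train_binary(ds, cfg, (100.0,), (0.05,), seed=31, cache=cache)
        X_train = cache.matrix(ds.members(ds.train_ids))
        np.testing.assert_allclose(model.scaler.min_, X_train.min(axis=0))

    def test_train_split_accuracy_at_least_cv_accuracy(self, tiny_suite):
        # resubstitution accuracy should not fall far below the CV estimate
        _, by_class = tiny_suite
        cfg = DescriptorConfig()
        cache = FeatureCache(cfg)
        ds = by_class["general"][1]
        model = train_binary(ds, cfg, (100.0,), (0.05,), seed=31, cache=cache)
        seqs = ds.members(ds.train_ids)
        X = cache.matrix(seqs)
        y = np.array([ds.label_of[s.id] for s in seqs])
        train_acc = float((model.predict(X) == y).mean())
        assert train_acc >= model.cv_accuracy - 0.1

    def test_unsplit_dataset_rejected(self, tiny_suite):
        pools, _ = tiny_suite
        from fertpred.dataset_builder import BenchmarkDataset
        ds = BenchmarkDataset("c", 1, pools["oogenesis"].sequences[:5],
                              pools["negative"].sequences[:5])
        with pytest.raises(ValueError, match="split"):
            train_binary(ds)


class TestTwoLayer:
    def test_structure_and_threshold(self, tiny_model):
        model, _, _ = tiny_model
        assert set(model.layer2) == {"embryogenesis", "oogenesis", "spermatogenesis"}
        assert model.threshold == 0.5

    def test_required_keys_enforced(self, tiny_suite):
        _, by_class = tiny_suite
        with pytest.raises(ValueError, match="keys"):
            train_two_layer({"general": by_class["general"][0]})

    def test_prediction_fields_consistent(self, tiny_model, tiny_suite):
        model, _, _ = tiny_model
        pools, _ = tiny_suite
        seqs = pools["oogenesis"].sequences[:5] + pools["negative"].sequences[:5]
        results = predict_two_layer(model, seqs)
        assert [r.sequence_id for r in results] == [s.id for s in seqs]
        for r in results:
            if r.is_fertility:
                assert r.layer1_probability > 0.5
                assert r.assigned_class == max(r.class_scores, key=r.class_scores.get)
            else:
                assert r.class_scores is None and r.assigned_class is None

    def test_threshold_monotonicity(self, tiny_model, tiny_suite):
        model, _, _ = tiny_model
        pools, _ = tiny_suite
        seqs = pools["spermatogenesis"].sequences[:8] + pools["negative"].sequences[:8]
        calls_05 = {r.sequence_id for r in predict_two_layer(model, seqs, threshold=0.5)
                    if r.is_fertility}
        calls_09 = {r.sequence_id for r in predict_two_layer(model, seqs, threshold=0.9)
                    if r.is_fertility}
        assert calls_09 <= calls_05

    def test_invalid_sequence_gets_error_entry(self, tiny_model):
        model, _, _ = tiny_model
        bad = ProteinSequence(id="bad", residues="ACDEF")  # too short
        (res,) = predict_two_layer(model, [bad])
        assert res.error == "too_short" and not res.is_fertility

    def test_replicate_selection_by_cv_accuracy(self, tiny_suite):
        _, by_class = tiny_suite
        cfg = DescriptorConfig()
        cache = FeatureCache(cfg)
        reps = by_class["oogenesis"][:2]
        models = [train_binary(ds, cfg, (100.0,), (0.05,), seed=31, cache=cache)
                  for ds in reps]
        model = train_two_layer(
            {"general": by_class["general"][0],
             "oogenesis": reps,
             "spermatogenesis": by_class["spermatogenesis"][0],
             "embryogenesis": by_class["embryogenesis"][0]},
            cfg, C_grid=(100.0,), gamma_grid=(0.05,), seed=31, cache=cache,
        )
        best_cv = max(m.cv_accuracy for m in models)
        assert model.layer2["oogenesis"].cv_accuracy == best_cv
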