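"""Feature matrix, splits, stacking, and evaluation of the Super Learner."""

import numpy as np
import pytest

from gutperm.descriptors import path_fingerprint
from gutperm.superlearner import (
    N_FEATURES,
    Standardizer,
    build_feature_matrix,
    butina_clusters,
    butina_split,
    evaluate,
    fit_superlearner,
    permanence_targets,
    predict_proba,
    raw_feature_matrix,
    standardized_metrics,
    stratified_folds,
)
from gutperm.synthetic import BenchmarkSpec, generate_benchmark

from conftest import make_record


@pytest.fixture(scope="module")
def benchmark():
    return generate_benchmark(BenchmarkSpec(n_fl=60, n_nofl=60, n_traverser=60, seed=3))


class TestFeatureMatrix:
    def test_31_columns_and_onehot_blocks(self, benchmark):
        records, _ = benchmark
        raw = raw_feature_matrix(records[:50])
        assert raw.shape == (50, N_FEATURES) == (50, 31)
        ion_block = raw[:, 10:14]
        assert np.all(ion_block.sum(axis=1) == 1.0)
        class_block = raw[:, 14:]
        assert np.all(np.isin(class_block.sum(axis=1), (0.0, 1.0)))

    def test_unknown_class_gives_zero_block(self):
        r = make_record("x", chem_class="Other")
        raw = raw_feature_matrix([r])
        assert raw[0, 14:].sum() == 0.0

    def test_training_standardization_zero_mean_unit_sd(self, benchmark):
        records, _ = benchmark
        x, std = build_feature_matrix(records)
        varying = std.scale != 1.0
        assert np.allclose(x.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(x[:, varying].std(axis=0), 1, atol=1e-9)

    def test_standardizer_roundtrip(self, rng):
        x = rng.normal(size=(20, 31))
        std = Standardizer.fit(x)
        assert np.allclose(std.inverse_transform(std.transform(x)), x, atol=1e-12)

    def test_test_rows_reuse_training_statistics(self, benchmark):
        records, _ = benchmark
        x_train, std = build_feature_matrix(records[:100])
        x_test, std2 = build_feature_matrix(records[100:], std)
        assert std2 is std
        # test standardization is an affine map with the training parameters
        raw_test = raw_feature_matrix(records[100:])
        assert np.allclose(x_test, (raw_test - std.mean) / std.scale)


class TestStratifiedFolds:
    def test_uniform_single_class(self):
        records = [make_record(f"m{i}", chem_class="Benzenoids") for i in range(80)]
        folds = stratified_folds(records, k=8, seed=1)
        assert np.bincount(folds).tolist() == [10] * 8

    def test_small_class_pigeonhole(self):
        records = [make_record(f"m{i}", chem_class="Benzenoids") for i in range(40)]
        records += [make_record(f"x{i}", chem_class="Hydrocarbons") for i in range(3)]
        folds = stratified_folds(records, k=8, seed=1)
        small = folds[40:]
        assert len(set(small)) == 3  # three different folds get one each

    def test_class_proportions_balanced(self, benchmark):
        records, _ = benchmark
        folds = stratified_folds(records, k=6, seed=9)
        for cls in {r.chem_class for r in records}:
            idx = [i for i, r in enumerate(records) if r.chem_class == cls]
            counts = np.bincount(folds[idx], minlength=6)
            assert counts.max() - counts.min() <= 1

    def test_deterministic_under_seed(self, benchmark):
        records, _ = benchmark
        a = stratified_folds(records, k=8, seed=5)
        b = stratified_folds(records, k=8, seed=5)
        c = stratified_folds(records, k=8, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds([make_record("a")], k=8, seed=0)


class TestButinaSplit:
    def test_identical_molecules_share_a_side(self):
        fps = [path_fingerprint("CCO")] * 4 + [path_fingerprint("c1ccccc1")] * 4
        train, test = butina_split(fps, threshold=0.8, test_fraction=0.5, seed=0)
        sides = np.zeros(8, dtype=int)
        sides[test] = 1
        assert len(set(sides[:4])) == 1
        assert len(set(sides[4:])) == 1

    def test_dissimilar_singletons_plain_partition(self):
        smiles = ["CCO", "c1ccccc1", "CC(=O)O", "C1CCCCC1", "c1ccncc1", "CCCl", "CS", "C=C"]
        fps = [path_fingerprint(s) for s in smiles]
        clusters = butina_clusters(fps, threshold=0.8)
        assert len(clusters) == len(smiles)
        train, test = butina_split(fps, 0.8, test_fraction=0.25, seed=1)
        assert len(train) + len(test) == len(smiles)
        assert len(test) >= 2

    def test_no_similar_pair_crosses_the_split(self):
        # islands by homologous chain families
        families = [
            [f"{'C' * n}C(=O)O" for n in (10, 11, 12)],
            [f"{'C' * n}CO" for n in (10, 11, 12)],
            [f"c1ccccc1{'C' * n}" for n in (8, 9, 10)],
        ]
        smiles = [s for fam in families for s in fam]
        fps = [path_fingerprint(s) for s in smiles]
        train, test = butina_split(fps, threshold=0.8, test_fraction=0.3, seed=2)
        from gutperm.descriptors import tanimoto

        for i in train:
            for j in test:
                assert tanimoto(fps[i], fps[j]) < 0.8

    def test_giant_cluster_rejected(self):
        fps = [path_fingerprint("CCO")] * 10
        with pytest.raises(ValueError, match="threshold"):
            butina_split(fps, threshold=0.8, test_fraction=0.2, seed=0)


class TestStack:
    @pytest.fixture(scope="class")
    def separable_fit(self, benchmark):
        records, truth = benchmark
        folds = stratified_folds(records, k=4, seed=7)
        train = [r for r, f in zip(records, folds) if f != 0]
        test = [r for r, f in zip(records, folds) if f == 0]
        x_train, std = build_feature_matrix(train)
        x_test, _ = build_feature_matrix(test, std)
        y_train = permanence_targets(train)
        y_test = permanence_targets(test)
        model = fit_superlearner(x_train, y_train, cv_folds=4, seed=1)
        return model, x_train, y_train, x_test, y_test

    def test_meta_matrix_shape_n_by_9(self, separable_fit):
        model, x_train, y_train, *_ = separable_fit
        assert model.meta_features.shape == (len(y_train), 9)

    def test_probabilities_valid_and_deterministic(self, separable_fit):
        model, _, _, x_test, _ = separable_fit
        p1 = predict_proba(model, x_test)
        p2 = predict_proba(model, x_test)
        assert np.all((p1 >= 0) & (p1 <= 1))
        assert np.array_equal(p1, p2)

    def test_separable_benchmark_high_external_auroc(self, separable_fit):
        from sklearn.metrics import roc_auc_score

        # loose bound at this fixture size; the full-scale benchmark is
        # exercised in the acceptance suite
        model, _, _, x_test, y_test = separable_fit
        assert roc_auc_score(y_test, predict_proba(model, x_test)) >= 0.95

    def test_training_is_independent_of_test_data(self, separable_fit, benchmark):
        # refitting with the same training rows must be bitwise identical,
        # whatever happens to the test set (no leakage path exists)
        model, x_train, y_train, *_ = separable_fit
        refit = fit_superlearner(x_train, y_train, cv_folds=4, seed=1)
        assert np.array_equal(refit.meta_features, model.meta_features)
        assert np.array_equal(refit.meta_model.coef_, model.meta_model.coef_)

    def test_single_class_rejected(self):
        x = np.zeros((20, N_FEATURES))
        with pytest.raises(ValueError):
            fit_superlearner(x, np.ones(20, dtype=int), cv_folds=3, seed=0)

    def test_column_mismatch_rejected(self, separable_fit):
        model, *_ = separable_fit
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((3, 30)))


class TestModelPersistence:
    def test_save_load_preserves_predictions(self, tmp_path, benchmark):
        from gutperm.superlearner import load_model, save_model

        records, _ = benchmark
        x, std = build_feature_matrix(records)
        y = permanence_targets(records)
        model = fit_superlearner(x, y, cv_folds=3, seed=0, standardizer=std)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert np.array_equal(predict_proba(loaded, x), predict_proba(model, x))
        assert np.allclose(loaded.standardizer.mean, std.mean)


class TestEvaluate:
    def test_standardized_is_mean_of_subset_scopes(self):
        fl = {"accuracy": 1.0, "precision": 1.0, "recall": 1.0, "f1": 1.0, "auroc": None, "auprc": 1.0}
        nofl = {"accuracy": 0.877, "precision": 0.797, "recall": 0.702, "f1": 0.747,
                "auroc": 0.921, "auprc": 0.833}
        stand = standardized_metrics(fl, nofl)
        assert stand["recall"] == pytest.approx(0.851)
        assert stand["auroc"] is None

    def test_equal_scopes_standardized_equals_either(self):
        y = np.array([1, 0, 1, 0])
        proba = np.array([0.9, 0.1, 0.8, 0.2])
        rep = evaluate(np.tile(y, 2), np.tile(proba, 2), fl_mask=np.repeat([True, False], 4))
        for m in ("accuracy", "f1", "auroc"):
            assert rep["standardized"][m] == pytest.approx(rep["FL"][m])

    def test_perfect_predictor_all_ones(self):
        y = np.array([1, 1, 0, 0, 1])
        rep = evaluate(y, y.astype(float))
        assert all(rep["all"][m] == 1.0 for m in ("accuracy", "precision", "recall", "f1", "auroc", "auprc"))

    def test_one_class_scope_has_no_auroc(self):
        y = np.array([1, 1, 1, 0])
        rep = evaluate(y, np.array([0.9, 0.8, 0.7, 0.1]), fl_mask=np.array([True, True, True, False]))
        assert rep["FL"]["auroc"] is None
        assert rep["FL"]["accuracy"] == 1.0

    def test_threshold_half_is_positive(self):
        rep = evaluate(np.array([1]), np.array([0.5]))
        assert rep["all"]["recall"] == 1.0
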