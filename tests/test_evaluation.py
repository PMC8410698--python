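import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ramanfda as rf
import oracles


class TestMakeFolds:
    def test_balanced_two_class_stratification(self):
        labels = np.array(["normal"] * 100 + ["abnormal"] * 100)
        folds = rf.make_folds(labels, scheme="kfold", k=10, seed=1)
        assert len(folds) == 10
        for train, test in folds:
            assert len(test) == 20
            assert (labels[test] == "normal").sum() == 10
            assert len(np.intersect1d(train, test)) == 0

    def test_folds_partition_all_indices(self):
        labels = np.array(["a"] * 31 + ["b"] * 44)
        folds = rf.make_folds(labels, scheme="kfold", k=5, seed=3)
        tests = [t for _, t in folds]
        joined = np.concatenate(tests)
        assert len(joined) == len(np.unique(joined)) == 75

    def test_lobo_folds_are_exactly_the_batches(self):
        labels = np.array(["a", "b"] * 9)
        batches = np.repeat(["b1", "b2", "b3"], 6)
        folds = rf.make_folds(labels, batches, scheme="lobo")
        assert len(folds) == 3
        for (_, test), b in zip(folds, ["b1", "b2", "b3"]):
            assert np.array_equal(np.sort(test), np.flatnonzero(batches == b))

    def test_lobo_without_batches_raises(self):
        with pytest.raises(ValueError, match="batch"):
            rf.make_folds(np.array(["a", "b"]), scheme="lobo")

    def test_k_larger_than_smallest_class_raises(self):
        labels = np.array(["a"] * 3 + ["b"] * 50)
        with pytest.raises(ValueError, match="smallest class"):
            rf.make_folds(labels, scheme="kfold", k=5)

    def test_fold_assignment_reproducible(self):
        labels = np.array(["a", "b"] * 40)
        f1 = rf.make_folds(labels, scheme="kfold", k=4, seed=7)
        f2 = rf.make_folds(labels, scheme="kfold", k=4, seed=7)
        for (tr1, te1), (tr2, te2) in zip(f1, f2):
            assert np.array_equal(te1, te2) and np.array_equal(tr1, tr2)


class TestMeanSensitivity:
    def test_perfect_confusion_is_one(self):
        assert rf.mean_sensitivity(np.diag([10, 20, 5])) == 1.0

    def test_direct_arithmetic(self):
        assert rf.mean_sensitivity(np.array([[9, 1], [2, 8]])) == pytest.approx(0.85)

    def test_empty_true_class_excluded(self, caplog):
        cm = np.array([[8, 2, 0], [1, 9, 0], [0, 0, 0]])
        with caplog.at_level("WARNING", logger="ramanfda"):
            got = rf.mean_sensitivity(cm)
        assert got == pytest.approx((0.8 + 0.9) / 2)
        assert "empty" in caplog.text

    def test_random_predictions_approach_chance(self, rng):
        sens = []
        for _ in range(1000):
            true = np.repeat([0, 1, 2], 20)
            pred = rng.integers(0, 3, size=60)
            cm = rf.confusion_matrix(true, pred, [0, 1, 2])
            sens.append(rf.mean_sensitivity(cm))
        assert np.mean(sens) == pytest.approx(1 / 3, abs=0.01)


class TestKruskalWallis:
    def test_identical_samples(self):
        assert rf.kruskal_wallis([1.0, 1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)

    def test_matches_bruteforce_rank_oracle(self, rng):
        h, _ = rf.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert abs(h - oracles.kruskal_wallis_bruteforce([1, 2, 3], [4, 5, 6])) < 1e-10
        # with ties
        a = rng.integers(0, 5, size=12).astype(float)
        b = rng.integers(0, 5, size=9).astype(float)
        if np.all(np.concatenate([a, b]) == a[0]):
            a[0] += 1
        h, _ = rf.kruskal_wallis(a, b)
        assert abs(h - oracles.kruskal_wallis_bruteforce(a, b)) < 1e-10

    @settings(derandomize=True, max_examples=20)
    @given(st.lists(st.integers(-100, 100), min_size=3, max_size=10, unique=True))
    def test_invariant_under_monotone_transform(self, pooled):
        # integer inputs keep exp(x/50) strictly monotone in floating point
        pooled = [float(v) for v in pooled]
        a, b = np.array(pooled[: len(pooled) // 2 + 1]), np.array(pooled[len(pooled) // 2 + 1:])
        if len(b) < 1:
            return
        h1, p1 = rf.kruskal_wallis(a, b)
        h2, p2 = rf.kruskal_wallis(np.exp(a / 50), np.exp(b / 50))
        assert h1 == pytest.approx(h2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_too_small_samples_raise(self):
        with pytest.raises(ValueError, match=">= 3"):
            rf.kruskal_wallis([1.0], [2.0])


class TestRunMethodCv:
    def test_permuted_labels_give_chance_sensitivity(self, small_dataset, rng):
        sp = small_dataset
        shuffled = rf.SpectraMatrix(
            sp.intensities, sp.grid, rng.permutation(sp.labels)
        )
        res = rf.run_method_cv(shuffled, "pca_lda", n_components=10, k=5, seed=1)
        assert abs(res.mean - 0.5) < 0.15

    def test_full_rank_pca_equals_lda_on_raw_data(self, rng):
        # with all p components, PCA is an orthogonal rotation and the
        # Mahalanobis rule is rotation invariant
        grid = np.arange(8, dtype=float)
        X = rng.normal(size=(40, 8))
        X[:20] += 1.5
        labels = np.array(["a"] * 20 + ["b"] * 20)
        sp = rf.SpectraMatrix(X, grid, labels)
        folds = rf.make_folds(labels, scheme="kfold", k=4, seed=2)
        res = rf.run_method_cv(sp, "pca_lda", n_components=8, folds=folds)
        # direct path: LDA on raw centered data per fold
        sens = []
        for train, test in folds:
            model = rf.lda_fit(X[train], labels[train])
            pred = rf.lda_predict(model, X[test])
            cm = rf.confusion_matrix(labels[test], pred, ["a", "b"])
            sens.append(rf.mean_sensitivity(cm))
        assert np.allclose(res.fold_sensitivities, sens)

    def test_reproducible_given_seed(self, small_dataset):
        r1 = rf.run_method_cv(small_dataset, "fpca_lda", 10, seed=4, n_basis=60)
        r2 = rf.run_method_cv(small_dataset, "fpca_lda", 10, seed=4, n_basis=60)
        assert np.array_equal(r1.fold_sensitivities, r2.fold_sensitivities)
        assert r1.model_fingerprints == r2.model_fingerprints

    def test_confusions_sum_to_fold_sizes(self, small_dataset):
        res = rf.run_method_cv(small_dataset, "pca_lda", 10, k=5, seed=0)
        folds = rf.make_folds(small_dataset.labels, scheme="kfold", k=5, seed=0)
        for cm, (_, test) in zip(res.fold_confusions, folds):
            assert cm.sum() == len(test)
        assert 0.0 <= res.mean <= 1.0

    @pytest.mark.parametrize("method", ["pca_lda", "fpca_lda"])
    def test_fitted_models_ignore_test_fold_labels(self, small_dataset, method):
        sp = small_dataset
        folds = rf.make_folds(sp.labels, scheme="kfold", k=5, seed=9)
        kwargs = dict(n_components=10, folds=folds, n_basis=60)
        base = rf.run_method_cv(sp, method, **kwargs)
        # corrupt the labels of the first fold's test set only and rerun
        # with the same folds: the first fold's fitted model must not move
        corrupted_labels = sp.labels.copy()
        _, test0 = folds[0]
        corrupted_labels[test0] = np.where(
            corrupted_labels[test0] == "normal", "abnormal", "normal"
        )
        corrupted = rf.SpectraMatrix(sp.intensities, sp.grid, corrupted_labels)
        res = rf.run_method_cv(corrupted, method, **kwargs)
        assert res.model_fingerprints[0] == base.model_fingerprints[0]

    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="method"):
            rf.run_method_cv(small_dataset, "svm", 5)

    def test_small_training_fold_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="fold"):
            rf.run_method_cv(small_dataset, "pca_lda", n_components=55, k=5)


class TestRunGridComparison:
    def test_table_structure_and_difference_column(self):
        configs = [
            rf.SimulationConfig(
                n_per_class=20, n_points=128, shift=s, snr=r, seed=1
            )
            for s, r in [(0.05, 100.0), (0.05, 0.5)]
        ]
        grid = rf.run_grid_comparison(
            configs, n_components=10, n_basis=40, k=4, seed=2
        )
        t = grid.table
        assert list(t["shift"]) == [0.05, 0.05]
        assert set(
            ["sens_pca", "sd_pca", "sens_fpca", "sd_fpca", "diff", "kw_p"]
        ) <= set(t.columns)
        assert np.allclose(t["diff"], t["sens_fpca"] - t["sens_pca"])
        # sensitivity cannot fall when the SNR rises by a factor 200
        assert t.loc[0, "sens_pca"] >= t.loc[1, "sens_pca"]
        assert t.loc[0, "sens_fpca"] >= t.loc[1, "sens_fpca"]

    def test_failed_cell_recorded_as_missing(self):
        configs = [
            rf.SimulationConfig(n_per_class=20, n_points=16, shift=0.05,
                                snr=10, seed=1)  # 40-basis fit impossible
        ]
        grid = rf.run_grid_comparison(configs, n_components=10, n_basis=40, k=4)
        assert np.isnan(grid.table.loc[0, "sens_fpca"])
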