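"""Grid search, cross-validation, self-training and class balancing."""

import numpy as np
import pytest

from recurnet import (ExpressionDataset, ParameterGrid, balance_classes,
                      cv_cell_accuracy, grid_search, self_train,
                      stratified_folds, SimulationConfig, simulate)


def _quick_cfg(**kw):
    base = dict(n_genes=60, n_planted_pairs=5, n_labeled_per_class=20,
                n_unlabeled=10, rho=0.9, background_edges=20, seed=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestParameterGrid:
    def test_default_is_ten_by_ten(self):
        grid = ParameterGrid()
        assert len(grid.threshold_g_values) == 10
        assert len(grid.threshold_s_values) == 10
        assert grid.n_cells == 100
        np.testing.assert_allclose(grid.threshold_g_values,
                                   np.arange(0.15, 0.601, 0.05), atol=1e-9)
        np.testing.assert_allclose(grid.threshold_s_values,
                                   np.arange(0.72, 0.901, 0.02), atol=1e-9)

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid(threshold_g_values=[0.3, 0.2])


class TestStratifiedFolds:
    def test_balanced_ten_fold(self):
        y = np.array([-1] * 10 + [1] * 10)
        folds = stratified_folds(y, 10, seed=0)
        assert len(folds) == 10
        for fold in folds:
            assert len(fold) == 2
            assert sorted(y[fold]) == [-1, 1]

    def test_partition(self):
        y = np.array([-1] * 13 + [1] * 8)
        folds = stratified_folds(y, 4, seed=1)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(21))

    def test_deterministic(self):
        y = np.array([-1] * 12 + [1] * 9)
        f1 = stratified_folds(y, 3, seed=5)
        f2 = stratified_folds(y, 3, seed=5)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_small_class_fatal(self):
        y = np.array([-1] * 10 + [1] * 2)
        with pytest.raises(ValueError, match="cannot build"):
            stratified_folds(y, 3, seed=0)


class TestCVCellAccuracy:
    def test_separable_data_perfect_at_permissive_cell(self):
        ds, ppi, _ = simulate(_quick_cfg())
        acc = cv_cell_accuracy(ds, ppi, (0.5, 0.72), k=5, seed=0)
        assert acc == pytest.approx(1.0)

    def test_permuted_labels_near_chance(self):
        # with labels destroyed, CV accuracy collapses to the majority rate
        ds, ppi, _ = simulate(_quick_cfg())
        rng = np.random.default_rng(99)
        accs = []
        for rep in range(20):
            shuffled = ds.copy()
            lab_idx = ds.labeled_indices
            shuffled.labels[lab_idx] = rng.permutation(ds.labels[lab_idx])
            accs.append(cv_cell_accuracy(shuffled, ppi, (0.5, 0.72),
                                         k=5, seed=rep))
        assert abs(np.mean(accs) - 0.5) < 0.12  # binomial noise band

    def test_degenerate_fold_handled(self):
        # a cell whose threshold removes every pair falls back to majority
        ds, ppi, _ = simulate(_quick_cfg())
        acc = cv_cell_accuracy(ds, ppi, (1.999, 0.72), k=5, seed=0)
        assert 0.0 <= acc <= 1.0


class TestGridSearch:
    def test_cell_count(self):
        ds, ppi, _ = simulate(_quick_cfg())
        grid = ParameterGrid(threshold_g_values=[0.3, 0.5],
                             threshold_s_values=[0.72, 0.8, 0.88])
        cv = grid_search(ds, ppi, grid, k=5, seed=0)
        assert cv.mean_accuracy.shape == (2, 3)
        assert len(cv.to_frame()) == 6

    def test_single_cell(self):
        ds, ppi, _ = simulate(_quick_cfg())
        grid = ParameterGrid(threshold_g_values=[0.4],
                             threshold_s_values=[0.8])
        cv = grid_search(ds, ppi, grid, k=5, seed=0)
        assert cv.best_cell == (0.4, 0.8)

    def test_tie_breaks_to_smallest_thresholds(self):
        # perfectly separable data ties many cells at 1.0
        ds, ppi, _ = simulate(_quick_cfg())
        grid = ParameterGrid(threshold_g_values=[0.3, 0.5],
                             threshold_s_values=[0.72, 0.8])
        cv = grid_search(ds, ppi, grid, k=5, seed=0)
        winners = [(tg, ts)
                   for a, tg in enumerate(grid.threshold_g_values)
                   for b, ts in enumerate(grid.threshold_s_values)
                   if cv.mean_accuracy[a, b] == cv.best_accuracy]
        assert cv.best_cell == min(winners)

    def test_matches_cv_cell_accuracy(self):
        ds, ppi, _ = simulate(_quick_cfg())
        grid = ParameterGrid(threshold_g_values=[0.3, 1.2],
                             threshold_s_values=[0.75, 0.85])
        cv = grid_search(ds, ppi, grid, k=5, seed=7)
        for a, tg in enumerate(grid.threshold_g_values):
            for b, ts in enumerate(grid.threshold_s_values):
                single = cv_cell_accuracy(ds, ppi, (tg, ts), k=5, seed=7)
                assert cv.mean_accuracy[a, b] == pytest.approx(single,
                                                               abs=1e-12)


class TestSelfTrain:
    def _grid(self):
        return ParameterGrid(threshold_g_values=[0.4, 0.6],
                             threshold_s_values=[0.72, 0.8])

    def test_converges_on_synthetic(self):
        ds, ppi, truth = simulate(_quick_cfg())
        pred, history = self_train(ds, ppi, self._grid(), k=5, seed=0)
        assert history[-1].converged
        assert len(history) == 2  # iteration 2 reproduces iteration 1
        assert [truth[s] for s in pred.sample_ids] == list(pred.labels_u)

    def test_labeled_set_monotone(self):
        ds, ppi, _ = simulate(_quick_cfg())
        _, history = self_train(ds, ppi, self._grid(), k=5, seed=0)
        counts = [s.n_labeled for s in history]
        assert counts == sorted(counts)

    def test_max_iter_one_not_converged(self):
        ds, ppi, _ = simulate(_quick_cfg())
        _, history = self_train(ds, ppi, self._grid(), k=5, seed=0, max_iter=1)
        assert len(history) == 1 and not history[-1].converged

    def test_no_unlabeled_fatal(self):
        ds, ppi, _ = simulate(_quick_cfg(n_unlabeled=0))
        with pytest.raises(ValueError, match="no unlabeled"):
            self_train(ds, ppi, self._grid(), k=5, seed=0)

    def test_invalid_max_iter(self):
        ds, ppi, _ = simulate(_quick_cfg())
        with pytest.raises(ValueError, match="max_iter"):
            self_train(ds, ppi, self._grid(), k=5, seed=0, max_iter=0)

    def test_pipeline_pure_function_of_seed(self):
        ds, ppi, _ = simulate(_quick_cfg())
        p1, h1 = self_train(ds, ppi, self._grid(), k=5, seed=11)
        p2, h2 = self_train(ds, ppi, self._grid(), k=5, seed=11)
        np.testing.assert_array_equal(p1.labels_u, p2.labels_u)
        np.testing.assert_array_equal(p1.f_u, p2.f_u)
        assert [s.best_cell for s in h1] == [s.best_cell for s in h2]


class TestBalanceClasses:
    def _ds(self, n1, n2, n_unl=5, seed=0):
        rng = np.random.default_rng(seed)
        n = n1 + n2 + n_unl
        labels = np.array([-1] * n1 + [1] * n2 + [0] * n_unl)
        return ExpressionDataset([f"g{i}" for i in range(4)],
                                 rng.normal(size=(4, n)),
                                 [f"s{i}" for i in range(n)], labels)

    def test_table_shaped_counts(self):
        ds = balance_classes(self._ds(109, 36), seed=0)
        assert int((ds.labels == -1).sum()) == 36
        assert int((ds.labels == 1).sum()) == 36
        assert int((ds.labels == 0).sum()) == 5  # unlabeled untouched

    def test_already_balanced_noop(self, caplog):
        src = self._ds(49, 49)
        with caplog.at_level("INFO"):
            ds = balance_classes(src, seed=0)
        assert ds.sample_ids == src.sample_ids

    def test_deterministic_removal(self):
        src = self._ds(30, 12)
        d1 = balance_classes(src, seed=4)
        d2 = balance_classes(src, seed=4)
        assert d1.sample_ids == d2.sample_ids
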