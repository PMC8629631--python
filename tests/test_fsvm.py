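"""Kernel-distance statistics, candidate selection and (F)SVM training."""

import math

import numpy as np
import pytest
from sklearn.svm import SVC

from fatiguekit import (
    ConfigError,
    DataError,
    KernelSpec,
    LabeledDataset,
    TrainedModel,
    kernel_distance,
    mean_distance_table,
    pairwise_distance_matrix,
    select_candidates,
    select_training_set,
    simulate_feature_dataset,
    train_fsvm,
    train_svm,
)

from _oracles import brute_force_selection

RBF = KernelSpec()


class TestKernelDistance:
    def test_identical_points_have_zero_distance(self):
        x = np.array([3.0, -1.0, 2.5])
        assert kernel_distance(x, x, RBF) == 0.0

    def test_closed_form_at_known_separation(self):
        # gamma=0.001, ||xi-xj||^2 = 1000 -> sqrt(2 - 2 e^-1)
        x_i = np.zeros(2)
        x_j = np.array([math.sqrt(1000.0), 0.0])
        expected = math.sqrt(2.0 - 2.0 * math.exp(-1.0))
        assert kernel_distance(x_i, x_j, RBF) == pytest.approx(expected, abs=1e-12)

    def test_distance_saturates_at_sqrt2(self):
        d = kernel_distance(np.zeros(1), np.array([1e6]), RBF)
        assert d == pytest.approx(math.sqrt(2.0), abs=1e-12)
        assert d <= math.sqrt(2.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DataError):
            kernel_distance(np.zeros(2), np.zeros(3), RBF)


class TestDistanceMatrix:
    def test_identical_points_give_zero_matrix(self):
        ds = LabeledDataset(X=np.ones((4, 2)), y=np.array([1, 1, 0, 0]))
        D = pairwise_distance_matrix(ds, RBF)
        assert np.all(D.D == 0.0)

    def test_symmetry_zero_diagonal_and_range(self, rng):
        ds = LabeledDataset(
            X=rng.normal(scale=20, size=(12, 3)),
            y=np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0]),
        )
        D = pairwise_distance_matrix(ds, RBF)
        assert np.allclose(D.D, D.D.T)
        assert np.all(np.diag(D.D) == 0.0)
        assert np.all(D.D >= 0.0) and np.all(D.D <= math.sqrt(2.0) + 1e-12)

    def test_entries_match_elementwise_recomputation(self, rng):
        X = rng.normal(scale=15, size=(8, 3))
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        ds = LabeledDataset(X=X, y=y)
        D = pairwise_distance_matrix(ds, RBF)
        for a in range(8):
            for b in range(8):
                expected = kernel_distance(X[D.order[a]], X[D.order[b]], RBF)
                assert D.D[a, b] == pytest.approx(expected, abs=1e-7)

    def test_block_shapes(self, rng):
        ds = LabeledDataset(
            X=rng.normal(size=(7, 2)), y=np.array([1, 1, 1, 0, 0, 0, 0])
        )
        D = pairwise_distance_matrix(ds, RBF)
        assert D.D11.shape == (3, 3)
        assert D.D12.shape == (3, 4)
        assert D.D21.shape == (4, 3)
        assert D.D22.shape == (4, 4)


class TestMeanDistanceTable:
    def test_identical_positives_single_negative(self):
        # two identical positives, one negative at kernel distance d
        X = np.array([[0.0, 0.0], [0.0, 0.0], [40.0, 0.0]])
        ds = LabeledDataset(X=X, y=np.array([1, 1, 0]))
        V = mean_distance_table(pairwise_distance_matrix(ds, RBF))
        d = kernel_distance(X[0], X[2], RBF)
        assert np.allclose(V.V11, 0.0)
        assert np.allclose(V.V12, d)
        # single negative: opposite-class mean of the negative over 2 positives
        assert V.V21[0] == pytest.approx(d)
        assert V.V22[0] == 0.0

    def test_single_negative_means_equal_their_only_entry(self, rng):
        X = rng.normal(scale=10, size=(5, 2))
        ds = LabeledDataset(X=X, y=np.array([1, 1, 1, 1, 0]))
        D = pairwise_distance_matrix(ds, RBF)
        V = mean_distance_table(D)
        assert np.allclose(V.V12, D.D12[:, 0])

    def test_table_equals_direct_row_means(self, rng):
        X = rng.normal(scale=10, size=(6, 3))
        ds = LabeledDataset(X=X, y=np.array([1, 1, 1, 0, 0, 0]))
        D = pairwise_distance_matrix(ds, RBF)
        V = mean_distance_table(D)
        assert np.allclose(V.V11, D.D[:3, :3].mean(axis=1))
        assert np.allclose(V.V22, D.D[3:, 3:].mean(axis=1))


class TestSelection:
    def test_r_equal_one_selects_everything(self, rng):
        ds = simulate_feature_dataset(9, 7, seed=3)
        sel = select_training_set(ds, RBF, 1.0)
        assert sel.n_selected == 16
        assert np.array_equal(sel.selected, np.arange(16))

    def test_boundary_points_chosen_on_collinear_quartet(self):
        # positives at 0 and 10, negatives at 11 and 21 on a line: the two
        # facing points at 10 and 11 are the boundary pair
        X = np.array([[0.0, 0.0], [10.0, 0.0], [11.0, 0.0], [21.0, 0.0]])
        ds = LabeledDataset(X=X, y=np.array([1, 1, 0, 0]))
        sel = select_training_set(ds, RBF, 0.5)
        assert sel.selected.tolist() == [1, 2]
        bf_pos, bf_neg = brute_force_selection(X, ds.y, RBF.gamma, 0.5)
        assert sel.selected_pos.tolist() == bf_pos.tolist()
        assert sel.selected_neg.tolist() == bf_neg.tolist()

    def test_empty_intersection_falls_back_to_opposite_ranking(self):
        # at small r on overlapping clouds the same-class ranking (far-side
        # outliers) and the opposite-class ranking (boundary points) pick
        # disjoint top sets, so the fallback must engage and stay non-empty
        ds = simulate_feature_dataset(30, 30, seed=11)
        sel = select_training_set(ds, RBF, 0.1)
        assert sel.fallback_pos and sel.fallback_neg
        assert sel.selected_pos.size >= 1
        assert sel.selected_neg.size >= 1
        bf_pos, bf_neg = brute_force_selection(ds.X, ds.y, RBF.gamma, 0.1)
        assert sel.selected_pos.tolist() == bf_pos.tolist()
        assert sel.selected_neg.tolist() == bf_neg.tolist()

    def test_invalid_ratio_rejected(self, rng):
        ds = simulate_feature_dataset(4, 4, seed=0)
        for r in (0.0, -0.3, 1.5):
            with pytest.raises(ConfigError):
                select_training_set(ds, RBF, r)

    def test_matches_brute_force_on_seeded_datasets(self):
        """Selection agrees index-for-index with the naive-loop oracle."""
        rng = np.random.default_rng(2024)
        for trial in range(25):
            l_pos = int(rng.integers(3, 16))
            l_neg = int(rng.integers(3, 16))
            ds = simulate_feature_dataset(
                l_pos, l_neg, dim=int(rng.integers(2, 5)), seed=int(rng.integers(1e6))
            )
            r = float(rng.choice([0.2, 0.3, 0.5, 0.8, 1.0]))
            sel = select_training_set(ds, RBF, r)
            bf_pos, bf_neg = brute_force_selection(ds.X, ds.y, RBF.gamma, r)
            assert sel.selected_pos.tolist() == bf_pos.tolist(), (trial, r)
            assert sel.selected_neg.tolist() == bf_neg.tolist(), (trial, r)

    def test_reduction_bound_holds_over_r_grid(self):
        """|T_BD| <= ceil(l+ r) + ceil(l- r) for every r."""
        for seed in range(8):
            ds = simulate_feature_dataset(17, 13, seed=seed)
            for r in np.linspace(0.1, 1.0, 10):
                sel = select_training_set(ds, RBF, float(r))
                bound = math.ceil(17 * r) + math.ceil(13 * r)
                assert sel.n_selected <= bound

    def test_solver_input_size_nondecreasing_in_r(self):
        # the top-m sets of each ranking are nested as m grows, so while the
        # intersection rule is in effect the selected count is monotone in r;
        # the non-empty fallback can exceed a later intersection, so only
        # no-fallback selections are compared
        ds = simulate_feature_dataset(30, 30, seed=11)
        sizes = [
            sel.n_selected
            for r in (0.1, 0.2, 0.3, 0.5, 0.7, 0.9, 1.0)
            if not (
                (sel := select_training_set(ds, RBF, r)).fallback_pos
                or sel.fallback_neg
            )
        ]
        assert len(sizes) >= 4
        assert sizes == sorted(sizes)

    def test_selected_points_are_closer_to_opposite_class(self):
        """Boundary affinity: per class, the selected points' mean distance to
        the opposite class never exceeds that of the unselected points."""
        ds = simulate_feature_dataset(50, 50, separation=60.0, seed=4)
        D = pairwise_distance_matrix(ds, RBF)
        V = mean_distance_table(D)
        sel = select_candidates(V, 0.4)
        pos_opp = dict(zip(V.pos_index.tolist(), V.V12))
        neg_opp = dict(zip(V.neg_index.tolist(), V.V21))
        for chosen, table, idx in (
            (set(sel.selected_pos.tolist()), pos_opp, V.pos_index),
            (set(sel.selected_neg.tolist()), neg_opp, V.neg_index),
        ):
            inside = [table[i] for i in idx.tolist() if i in chosen]
            outside = [table[i] for i in idx.tolist() if i not in chosen]
            assert np.mean(inside) <= np.mean(outside)


class TestTraining:
    def test_r_one_reduces_to_plain_svm(self, rng):
        ds = simulate_feature_dataset(40, 35, seed=5)
        grid = rng.normal(scale=15, size=(60, 4))
        m_fast = train_fsvm(ds, r=1.0)
        m_full = train_svm(ds)
        assert np.allclose(
            m_fast.decision_function(grid), m_full.decision_function(grid), atol=1e-6
        )

    def test_solver_input_respects_ratio_bound(self):
        ds = simulate_feature_dataset(150, 150, seed=9)
        m = train_fsvm(ds, r=0.3)
        assert m.n_selected <= math.ceil(150 * 0.3) * 2
        assert m.support_vectors.shape[0] <= m.n_selected

    def test_accuracy_close_to_full_svm_on_separable_gaussians(self):
        """Mean test accuracy at r=0.5 stays within 0.03 of the full SVM
        over paired seeded splits (separable clouds, 6 sd apart)."""
        from fatiguekit import ModelSpec, repeated_eval

        ds = simulate_feature_dataset(200, 200, separation=60.0, seed=1)
        fast = repeated_eval(ds, ModelSpec(kind="fsvm", r=0.5), reps=10, base_seed=0)
        full = repeated_eval(ds, ModelSpec(kind="svm"), reps=10, base_seed=0)
        assert abs(fast.mean_accuracy - full.mean_accuracy) <= 0.03

    def test_training_errors(self):
        ds_one_class = LabeledDataset(X=np.zeros((3, 2)), y=np.array([1, 1, 1]))
        with pytest.raises(DataError):
            train_fsvm(ds_one_class)
        ds = simulate_feature_dataset(5, 5, seed=0)
        with pytest.raises(ConfigError):
            train_fsvm(ds, C=-1.0)


class TestPredictAndSerialization:
    def test_decision_matches_manual_kernel_expansion(self, rng):
        ds = simulate_feature_dataset(3, 3, separation=20.0, seed=2)
        m = train_svm(ds)
        x = rng.normal(scale=10, size=(1, 4))
        manual = (
            sum(
                a * math.exp(-RBF.gamma * float(np.sum((sv - x[0]) ** 2)))
                for a, sv in zip(m.dual_coef, m.support_vectors)
            )
            + m.intercept
        )
        assert m.decision_function(x)[0] == pytest.approx(manual, abs=1e-10)

    def test_decision_matches_solver(self, rng):
        ds = simulate_feature_dataset(30, 30, seed=8)
        m = train_svm(ds)
        svc = SVC(kernel="rbf", gamma=RBF.gamma, C=1.0).fit(ds.X, ds.y)
        grid = rng.normal(scale=15, size=(40, 4))
        assert np.allclose(m.decision_function(grid), svc.decision_function(grid))
        assert np.array_equal(m.predict(grid), svc.predict(grid))

    def test_training_points_predicted_at_least_as_well_as_reported(self):
        ds = simulate_feature_dataset(50, 50, separation=60.0, seed=3)
        m = train_fsvm(ds, r=0.5)
        idx = m.selected_indices
        acc = (m.predict(ds.X[idx]) == ds.y[idx]).mean()
        assert acc >= 0.95

    def test_point_on_distant_positive_support_vector_is_fatigue(self):
        ds = simulate_feature_dataset(20, 20, separation=80.0, seed=6)
        m = train_svm(ds)
        far_pos = ds.X[ds.idx_pos][np.argmax(ds.X[ds.idx_pos][:, 0])]
        assert m.predict(far_pos[None, :])[0] == 1

    def test_json_round_trip_preserves_decisions(self, rng, tmp_path):
        ds = simulate_feature_dataset(25, 25, seed=4)
        m = train_fsvm(ds, r=0.6)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = TrainedModel.from_json(path)
        grid = rng.normal(scale=15, size=(30, 4))
        assert np.allclose(m.decision_function(grid), m2.decision_function(grid))
        assert m2.r == m.r and m2.n_selected == m.n_selected

    def test_dimension_mismatch_rejected(self):
        ds = simulate_feature_dataset(5, 5, seed=0)
        m = train_svm(ds)
        with pytest.raises(DataError):
            m.predict(np.zeros((2, 7)))
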