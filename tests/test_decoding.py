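"""Pseudo-population assembly, k-NN cross-validation, label permutations."""

from itertools import permutations

import numpy as np
import pytest

from s1pop.decoding import (
    TrialVectorSet,
    build_trial_vectors,
    knn_cross_validate,
    label_permutation_test,
    stratified_folds,
)
from s1pop.errors import AssemblyError, ContractError
from s1pop.trace_processing import ResponseTensor


def session_tensor(n_cells, n_trials, labels=("A", "B"), peaks=None, seed=0):
    rng = np.random.default_rng(seed)
    if peaks is None:
        peaks = rng.uniform(0, 1, size=(n_cells, len(labels), n_trials))
    peaks = np.asarray(peaks, dtype=float)
    return ResponseTensor(
        peaks=peaks,
        max_per_cell=np.maximum(peaks.max(axis=(1, 2)), 1.0),
        fidelity=(peaks > 0.3).mean(axis=2),
        responder_flags=np.ones(n_cells, dtype=bool),
        stimulus_labels=tuple(labels),
        trial_indices=tuple(range(1, n_trials + 1)),
    )


def cluster_set(n_per_class=5, n_cells=4, offset=10.0, seed=0):
    """Two well-separated Gaussian clusters."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.5, size=(n_per_class, n_cells))
    b = rng.normal(offset, 0.5, size=(n_per_class, n_cells))
    return TrialVectorSet(
        vectors=np.vstack([a, b]),
        labels=np.array(["low"] * n_per_class + ["high"] * n_per_class,
                        dtype=object),
        cell_sessions=np.zeros(n_cells, dtype=int),
    )


class TestBuildTrialVectors:
    def test_single_session_counting(self):
        tvs = build_trial_vectors([session_tensor(3, 5)], ("A", "B"))
        assert tvs.vectors.shape == (10, 3)
        assert sorted(set(tvs.labels)) == ["A", "B"]

    def test_cells_concatenate_across_sessions(self):
        tvs = build_trial_vectors(
            [session_tensor(2, 5, seed=1), session_tensor(3, 5, seed=2)],
            ("A", "B"),
        )
        assert tvs.vectors.shape == (10, 5)
        assert tvs.cell_sessions.tolist() == [0, 0, 1, 1, 1]

    def test_mismatched_trial_counts_rejected(self):
        with pytest.raises(AssemblyError):
            build_trial_vectors(
                [session_tensor(2, 4), session_tensor(2, 5)], ("A", "B")
            )

    def test_missing_stimulus_rejected(self):
        with pytest.raises(AssemblyError):
            build_trial_vectors([session_tensor(2, 5)], ("A", "C"))


class TestKnnCrossValidate:
    def test_separable_clusters_decode_perfectly(self):
        result = knn_cross_validate(cluster_set(), k=3, n_folds=10, seed=0)
        assert result.mean_accuracy == 1.0

    def test_random_labels_sit_at_chance(self):
        rng = np.random.default_rng(4)
        accs = []
        for rep in range(5):
            vectors = rng.normal(size=(100, 6))
            labels = np.array(["A", "B"] * 50, dtype=object)
            tvs = TrialVectorSet(
                vectors=vectors, labels=labels,
                cell_sessions=np.zeros(6, dtype=int),
            )
            accs.append(
                knn_cross_validate(tvs, k=5, n_folds=10, seed=rep).mean_accuracy
            )
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_mean_accuracy_is_fold_average(self):
        result = knn_cross_validate(cluster_set(), k=3, n_folds=5, seed=1)
        assert result.mean_accuracy == pytest.approx(
            np.mean(result.fold_accuracies)
        )

    def test_duplicate_point_conflicting_labels_is_deterministic(self):
        from s1pop.decoding import _knn_predict

        train = np.array([[1.0, 1.0], [1.0, 1.0]])
        test = np.array([[1.0, 1.0]])
        # k=1 with two zero-distance neighbors: training order decides
        p1 = _knn_predict(train, np.array(["B", "A"]), test, 1, ("A", "B"))
        assert all(
            p1 == _knn_predict(train, np.array(["B", "A"]), test, 1, ("A", "B"))
            for _ in range(3)
        )
        assert p1[0] == "B"
        # k=2 vote tie with equal distances: lowest class index wins
        p2 = _knn_predict(train, np.array(["B", "A"]), test, 2, ("A", "B"))
        assert p2[0] == "A"

    def test_invariant_to_common_cell_permutation(self, rng):
        tvs = cluster_set(n_cells=8, offset=2.0, seed=5)
        perm = rng.permutation(8)
        permuted = TrialVectorSet(
            vectors=tvs.vectors[:, perm],
            labels=tvs.labels,
            cell_sessions=tvs.cell_sessions[perm],
        )
        r1 = knn_cross_validate(tvs, k=5, n_folds=5, seed=3)
        r2 = knn_cross_validate(permuted, k=5, n_folds=5, seed=3)
        assert r1.fold_accuracies == r2.fold_accuracies

    def test_k_larger_than_training_fold_rejected(self):
        with pytest.raises(ContractError):
            knn_cross_validate(cluster_set(n_per_class=2), k=4, n_folds=2)

    def test_stratified_folds_cover_all_trials(self, rng):
        labels = np.array(["A"] * 5 + ["B"] * 5, dtype=object)
        fold_of = stratified_folds(labels, 10, rng)
        # 5+5 trials in 10 folds degenerates to leave-one-out
        assert sorted(fold_of.tolist()) == list(range(10))


class TestLabelPermutationTest:
    def test_separable_data_is_significant(self):
        result = label_permutation_test(
            cluster_set(), k=3, n_folds=10, n_permutations=1000, seed=0
        )
        assert result.mean_accuracy == 1.0
        # partition-preserving permutations (prob 2/252) are counted, so the
        # p floor is ~0.009 rather than 1/1001
        assert result.p_label_permutation < 0.02

    def test_p_matches_exhaustive_enumeration_at_tiny_n(self):
        # 2 trials per class: the permutation null of accuracy is exactly
        # computable by enumerating all 4! label orders
        tvs = cluster_set(n_per_class=2, n_cells=3, offset=8.0, seed=2)
        obs = knn_cross_validate(tvs, k=1, n_folds=2, seed=0).mean_accuracy
        atoms = []
        for perm in permutations(range(4)):
            permuted = TrialVectorSet(
                vectors=tvs.vectors,
                labels=tvs.labels[list(perm)],
                cell_sessions=tvs.cell_sessions,
            )
            atoms.append(
                knn_cross_validate(permuted, k=1, n_folds=2, seed=0).mean_accuracy
            )
        exact_tail = np.mean(np.array(atoms) >= obs)
        result = label_permutation_test(
            tvs, k=1, n_folds=2, n_permutations=2000, seed=1
        )
        # Monte-Carlo p should approximate the exhaustive tail probability
        assert abs(result.p_label_permutation - exact_tail) < 0.05

    def test_null_p_values_are_not_extreme(self):
        rng = np.random.default_rng(8)
        ps = []
        for rep in range(10):
            vectors = rng.normal(size=(20, 4))
            labels = np.array(["A", "B"] * 10, dtype=object)
            tvs = TrialVectorSet(
                vectors=vectors, labels=labels,
                cell_sessions=np.zeros(4, dtype=int),
            )
            ps.append(
                label_permutation_test(
                    tvs, k=3, n_folds=5, n_permutations=100, seed=rep
                ).p_label_permutation
            )
        assert min(ps) > 0.01  # no spurious significance under the null
        assert max(ps) > 0.2

    def test_zero_permutations_rejected(self):
        with pytest.raises(ContractError):
            label_permutation_test(cluster_set(), n_permutations=0)
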