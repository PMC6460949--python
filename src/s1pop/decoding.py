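"""Population decoding of stimulus features with a k-nearest-neighbor rule.

Trial-wise population response vectors (one peak amplitude per cell) are
classified with a k-NN majority vote (k = 5, Euclidean metric by default)
under stratified 10-fold cross-validation, so every test vector is predicted
by a classifier that never saw it.  Chance-level performance is calibrated
with a label-permutation test: class labels are shuffled across trials and
the cross-validated accuracy recomputed, giving an empirical p-value for the
observed accuracy.

Cells from several imaging sessions are pooled into a pseudo-population by
concatenating their peak vectors at matched trial index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AssemblyError, ContractError, StratificationError
from .trace_processing import ResponseTensor


@dataclass(frozen=True)
class TrialVectorSet:
    """Trials x cells peak matrix with one class label per trial."""

    vectors: np.ndarray
    labels: np.ndarray
    cell_sessions: np.ndarray  # source session index per cell

    def __post_init__(self):
        vectors = np.asarray(self.vectors, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        sessions = np.asarray(self.cell_sessions, dtype=int)
        if vectors.ndim != 2 or labels.shape != (vectors.shape[0],):
            raise ContractError("vectors must be trials x cells with one label each")
        if sessions.shape != (vectors.shape[1],):
            raise ContractError("cell_sessions must have one entry per cell")
        if not np.all(np.isfinite(vectors)):
            raise ContractError("vectors must be finite")
        classes, counts = np.unique(labels.astype(str), return_counts=True)
        if np.any(counts < 2):
            raise ContractError("every class needs >= 2 trials")
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "cell_sessions", sessions)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels.tolist())))

    @property
    def n_trials(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class DecodingResult:
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    k: int
    n_folds: int
    seed: int | None
    p_label_permutation: float | None = None
    n_permutations: int | None = None


def build_trial_vectors(tensors, stimulus_pair) -> TrialVectorSet:
    """Assemble pseudo-population vectors for a two-stimulus discrimination.

    Each session's cells are concatenated; trial *k* of a stimulus across
    sessions forms one vector, so all sessions must share the same trial
    count per stimulus.
    """
    tensors = list(tensors)
    la, lb = stimulus_pair
    if not tensors:
        raise ContractError("need at least one session tensor")
    n_trials = None
    for s, t in enumerate(tensors):
        if not isinstance(t, ResponseTensor):
            raise ContractError("inputs must be ResponseTensor objects")
        for lab in (la, lb):
            if lab not in t.stimulus_labels:
                raise AssemblyError(f"session {s} lacks stimulus {lab!r}")
        if n_trials is None:
            n_trials = t.n_trials
        elif t.n_trials != n_trials:
            raise AssemblyError(
                f"session {s} has {t.n_trials} trials per stimulus, "
                f"expected {n_trials}"
            )
    blocks, sessions = [], []
    for s, t in enumerate(tensors):
        ja, jb = t.stimulus_labels.index(la), t.stimulus_labels.index(lb)
        # trials x cells for each stimulus, stacked a-then-b
        blocks.append(
            np.concatenate([t.peaks[:, ja, :].T, t.peaks[:, jb, :].T], axis=0)
        )
        sessions.extend([s] * t.n_cells)
    vectors = np.concatenate(blocks, axis=1)
    labels = np.array([la] * n_trials + [lb] * n_trials, dtype=object)
    return TrialVectorSet(
        vectors=vectors, labels=labels, cell_sessions=np.array(sessions)
    )


def stratified_folds(labels, n_folds: int, rng: np.random.Generator):
    """Seed-controlled stratified fold assignment.

    Each class's trials are shuffled and dealt round-robin across folds with
    a rotating starting fold, balancing fold sizes.  With 5 trials per class
    in 2 classes and 10 folds this degenerates to leave-one-out.  Returns a
    fold index per trial.
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if not (1 < n_folds <= n):
        raise ContractError("n_folds must be in (1, n_trials]")
    fold_of = np.empty(n, dtype=int)
    start = 0
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise StratificationError(f"class {cls!r} has fewer than 2 trials")
        idx = rng.permutation(idx)
        for pos, trial in enumerate(idx):
            fold_of[trial] = (start + pos) % n_folds
        start = (start + len(idx)) % n_folds
    return fold_of


def _knn_predict(train_X, train_y, test_X, k: int, classes):
    """Deterministic k-NN: vote ties go to the class with the smallest mean
    neighbor distance, then to the lowest class index; equal distances at the
    neighborhood boundary are resolved by training-set order."""
    d = cdist(test_X, train_X)
    n_train = train_X.shape[0]
    # sort neighbors by (distance, train index) for a stable, seedless order
    order = np.lexsort((np.tile(np.arange(n_train), (len(test_X), 1)), d), axis=1)
    preds = []
    class_index = {c: i for i, c in enumerate(classes)}
    for row, dist_row in zip(order, d):
        neigh = row[:k]
        votes: dict[str, list[float]] = {}
        for t in neigh:
            votes.setdefault(train_y[t], []).append(dist_row[t])
        best = min(
            votes.items(),
            key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), class_index[kv[0]]),
        )
        preds.append(best[0])
    return np.array(preds, dtype=object)


def knn_cross_validate(
    tvs: TrialVectorSet,
    k: int = 5,
    n_folds: int = 10,
    seed: int | None = 0,
) -> DecodingResult:
    """Stratified n-fold cross-validated k-NN decoding accuracy."""
    if k < 1:
        raise ContractError("k must be >= 1")
    rng = np.random.default_rng(seed)
    fold_of = stratified_folds(tvs.labels, n_folds, rng)
    classes = tvs.classes
    labels = tvs.labels.astype(str)
    accuracies = []
    for fold in range(n_folds):
        test = fold_of == fold
        if not test.any():
            continue
        train = ~test
        train_labels = labels[train]
        if len(set(train_labels)) < len(classes):
            raise StratificationError(
                f"fold {fold} training set lacks a class; use fewer folds"
            )
        if k > train.sum():
            raise ContractError("k exceeds the training-set size in a fold")
        preds = _knn_predict(
            tvs.vectors[train], train_labels, tvs.vectors[test], k, classes
        )
        accuracies.append(float(np.mean(preds == labels[test])))
    return DecodingResult(
        fold_accuracies=tuple(accuracies),
        mean_accuracy=float(np.mean(accuracies)),
        k=k,
        n_folds=n_folds,
        seed=seed,
    )


def label_permutation_test(
    tvs: TrialVectorSet,
    k: int = 5,
    n_folds: int = 10,
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> DecodingResult:
    """Label-permutation significance of the cross-validated accuracy.

    Labels are permuted across trials before each full CV run; the empirical
    p is (count{permuted accuracy >= observed} + 1) / (n_permutations + 1).
    At least 100 permutations are recommended for a usable p resolution.
    """
    if n_permutations < 1:
        raise ContractError("n_permutations must be >= 1")
    observed = knn_cross_validate(tvs, k=k, n_folds=n_folds, seed=seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    count = 0
    for _ in range(n_permutations):
        perm_labels = rng.permutation(tvs.labels)
        perm_set = replace(tvs, labels=perm_labels)
        perm_seed = int(rng.integers(0, 2**31 - 1))
        result = knn_cross_validate(perm_set, k=k, n_folds=n_folds, seed=perm_seed)
        if result.mean_accuracy >= observed.mean_accuracy:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return replace(
        observed, p_label_permutation=float(p), n_permutations=n_permutations
    )
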