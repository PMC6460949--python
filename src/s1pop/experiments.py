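"""The four cohort-level analyses, from simulation to summary numbers.

Each function simulates a multi-mouse cohort under one protocol, runs the
full pipeline on every session, and returns the experiment's headline
quantities.  These are the computations the numbered drivers under
``analysis/`` narrate and the reproduction script re-runs.

Cohort conditions (sizes, noise levels) default to the emulated study's
scale: 4 mice for the three-stimulus and texture/dynamics experiments
(~217 and ~208 pooled cells), 6 mice for graded pinch (~197 cells) and for
the single-feature-contrast session (~101 pooled non-broadly-tuned cells).
Recovery-style analyses run at low noise (sigma 0.05, trial cv 0.1); the
feature-coding session runs at sigma 0.05, trial cv 0.2, where condition
patterns remain separable trial by trial.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd

from . import synthetic_data as synth
from .cohort import (
    nonbroad_tensors,
    per_mouse_state_spaces,
    pooled_pi,
    process_session,
)
from .decoding import build_trial_vectors, label_permutation_test
from .population_geometry import cluster_stimuli
from .selectivity_permutation import selectivity_tests
from .tuning_profile import (
    categorize_intensity_cells,
    discriminative_class,
    intensity_summary,
    per_group_percentages,
    venn_categorize,
)

THREE_LABELS = ("Brush", "Press", "Pinch")
TD_LABELS = ("B-stroke", "B-press", "F-stroke", "F-press")
PINCH_LABELS = ("P0", "P1", "P2", "P3")
FC_LABELS = ("B-press", "F-stroke", "F-press", "F-pinch")

#: The three single-feature contrasts of the selectivity/decoding session.
FEATURE_PAIRS = {
    "noxiousness": ("F-press", "F-pinch"),
    "dynamics": ("F-stroke", "F-press"),
    "texture": ("B-press", "F-press"),
}


def _pooled_pair_distances(spaces, pairs):
    """Per-mouse state-space distances pooled at the pair level."""
    from .population_geometry import interstate_distance

    out = {}
    for pair in pairs:
        means, counts = [], []
        for space in spaces:
            mean, _, n = interstate_distance(space, *pair)
            means.append(mean * n)
            counts.append(n)
        total = int(np.sum(counts))
        out[pair] = (float(np.sum(means) / total), total)
    return out


def run_three_stimulus_experiment(
    seed: int = 0,
    n_mice: int = 4,
    cells_per_mouse: int = 55,
    noise_sigma: float = 0.05,
    trial_cv: float = 0.1,
    n_components: int = 3,
) -> dict:
    """Brush/Press/Pinch: Venn tuning subsets and state-space separation."""
    sessions = [
        process_session(rec, proto, canonical_labels=THREE_LABELS)
        for rec, proto, _ in synth.simulate_cohort(
            synth.three_stimulus_population,
            synth.THREE_STIMULI,
            n_mice,
            cells_per_mouse,
            seed=seed,
            noise_sigma=noise_sigma,
            trial_cv=trial_cv,
        )
    ]
    from .tuning_profile import tuned_set

    pi = pooled_pi(sessions)
    tuned = tuned_set(pi)
    cats, proportions = venn_categorize(tuned, THREE_LABELS)
    spaces = per_mouse_state_spaces(sessions, n_components=n_components)
    distances = _pooled_pair_distances(
        spaces, list(combinations(THREE_LABELS, 2))
    )
    return {
        "n_responders": pi.shape[0],
        "venn_percent": {k: 100.0 * v for k, v in proportions.items()},
        "state_distances": distances,
    }


def run_texture_dynamics_experiment(
    seed: int = 0,
    n_mice: int = 4,
    cells_per_mouse: int = 52,
    noise_sigma: float = 0.05,
    trial_cv: float = 0.1,
    n_components: int = 3,
) -> dict:
    """2x2 texture x dynamics: discriminative classes, clustering, geometry."""
    raw = synth.simulate_cohort(
        synth.texture_dynamics_population,
        synth.TEXTURE_DYNAMICS,
        n_mice,
        cells_per_mouse,
        seed=seed,
        noise_sigma=noise_sigma,
        trial_cv=trial_cv,
    )
    sessions = [
        process_session(rec, proto, canonical_labels=TD_LABELS)
        for rec, proto, _ in raw
    ]
    labels_all, mice = [], []
    for m, s in enumerate(sessions):
        cls = discriminative_class(
            s.profile.tuned, TD_LABELS, s.tensor.stimulus_info
        )
        labels_all.append(cls)
        mice.append(np.full(len(cls), m))
    classes = np.concatenate(labels_all)
    mouse_of = np.concatenate(mice)
    pct = per_group_percentages(
        classes, mouse_of, classes=["texture", "dynamics", "broad", "other", "none"]
    )
    sem = pct.std(ddof=1) / np.sqrt(len(pct))

    pi = pooled_pi(sessions)
    dendro = cluster_stimuli(pi, TD_LABELS)
    spaces = per_mouse_state_spaces(sessions, n_components=n_components)
    texture_pairs = [("B-stroke", "F-stroke"), ("B-press", "F-press")]
    dynamics_pairs = [("F-stroke", "F-press"), ("B-stroke", "B-press")]
    tex_d = _pooled_pair_distances(spaces, texture_pairs)
    dyn_d = _pooled_pair_distances(spaces, dynamics_pairs)

    def pool(groups):
        total = sum(n for _, n in groups.values())
        return (
            float(sum(m * n for m, n in groups.values()) / total),
            total,
        )

    return {
        "n_responders": pi.shape[0],
        "percent_mean": pct.mean().to_dict(),
        "percent_sem": sem.to_dict(),
        "dendrogram": dendro,
        "texture_distance": pool(tex_d),
        "dynamics_distance": pool(dyn_d),
    }


def run_graded_pinch_experiment(
    seed: int = 0,
    n_mice: int = 6,
    cells_per_mouse: int = 33,
    noise_sigma: float = 0.02,
    trial_cv: float = 0.1,
) -> dict:
    """Graded pinches: intensity categories and per-level recruitment."""
    raw = synth.simulate_cohort(
        synth.graded_pinch_population,
        synth.GRADED_PINCH,
        n_mice,
        cells_per_mouse,
        seed=seed,
        noise_sigma=noise_sigma,
        trial_cv=trial_cv,
    )
    sessions = [
        process_session(rec, proto, canonical_labels=PINCH_LABELS)
        for rec, proto, _ in raw
    ]
    cats = np.concatenate(
        [categorize_intensity_cells(s.tensor) for s in sessions]
    )
    n = len(cats)
    category_percent = {
        c: 100.0 * float(np.mean(cats == c))
        for c in ("intensity_coding", "invariant", "inverse", "irregular")
    }
    summaries = [intensity_summary(s.tensor) for s in sessions]
    recruited = sum(s["recruited_cells"] for s in summaries)
    fidelity = pd.concat(
        [s["mean_fidelity"] * len(ses.tensor.cell_ids) for s, ses in zip(summaries, sessions)],
        axis=1,
    ).sum(axis=1) / n
    amplitude = pd.concat(
        [s["mean_amplitude"] * len(ses.tensor.cell_ids) for s, ses in zip(summaries, sessions)],
        axis=1,
    ).sum(axis=1) / n
    # ground-truth intensity-coding recovery
    truth_cats, est_cats = [], []
    for (rec, proto, truth), ses in zip(raw, sessions):
        truth_cats.append(truth.cell_classes[ses.responder_mask])
        est_cats.append(categorize_intensity_cells(ses.tensor))
    truth_cats = np.concatenate(truth_cats)
    est_cats = np.concatenate(est_cats)
    coding = truth_cats == "intensity_coding"
    recovery = float(np.mean(est_cats[coding] == "intensity_coding"))
    return {
        "n_responders": n,
        "category_percent": category_percent,
        "recruited_cells": recruited.to_dict(),
        "mean_fidelity": fidelity.to_dict(),
        "mean_amplitude": amplitude.to_dict(),
        "intensity_coding_recovery": recovery,
    }


def run_feature_coding_experiment(
    seed: int = 0,
    n_mice: int = 6,
    cells_per_mouse: int = 24,
    noise_sigma: float = 0.05,
    trial_cv: float = 0.2,
    n_trials: int = 5,
    n_reshuffles: int = 10_000,
    n_permutations: int = 1000,
    k: int = 5,
    n_folds: int = 10,
) -> dict:
    """Single-feature contrasts: z-distances and population decoding.

    Selectivity pools non-broadly-tuned responders across mice into one PI
    scatter per pair; decoding assembles the same cells into
    pseudo-population trial vectors.
    """
    spec = dataclasses.replace(synth.FEATURE_CODING, n_trials=n_trials)
    raw = synth.simulate_cohort(
        synth.feature_coding_population,
        spec,
        n_mice,
        cells_per_mouse,
        seed=seed,
        noise_sigma=noise_sigma,
        trial_cv=trial_cv,
    )
    sessions = [
        process_session(rec, proto, canonical_labels=FC_LABELS)
        for rec, proto, _ in raw
    ]
    pi = pooled_pi(sessions, non_broad_only=True)
    results = selectivity_tests(
        pi,
        FC_LABELS,
        list(FEATURE_PAIRS.values()),
        n_reshuffles=n_reshuffles,
        seed=seed + 100,
    )
    selectivity = {
        feature: r
        for feature, r in zip(FEATURE_PAIRS, results)
    }
    tensors = nonbroad_tensors(sessions)
    decoding = {}
    for i, (feature, pair) in enumerate(FEATURE_PAIRS.items()):
        tvs = build_trial_vectors(tensors, pair)
        decoding[feature] = label_permutation_test(
            tvs,
            k=k,
            n_folds=min(n_folds, tvs.n_trials),
            n_permutations=n_permutations,
            seed=seed + 200 + i,
        )
    return {
        "n_nonbroad": pi.shape[0],
        "selectivity": selectivity,
        "decoding": decoding,
    }
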