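"""Preference/response indexes, the tuning rule, and categorical labels.

The preference index of cell *i* for stimulus *j* is

    PI_ij = mean_k(P_ijk) / Max_i

the trial-averaged peak normalized by the cell's highest observed amplitude,
so PI lies in [0, 1].  A cell is "tuned" (preferentially responsive) to
stimulus *j* when PI_ij exceeds 0.8 times its mean PI across stimuli; a cell
tuned to every stimulus in the session is broadly tuned.  The response index
(RI) is the identical statistic computed across graded intensities of a
single stimulus kind instead of across stimulus kinds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedPreferenceError
from .trace_processing import ResponseTensor

#: A cell is tuned to a stimulus when PI exceeds this factor times its mean PI.
TUNED_FACTOR = 0.8

DISCRIMINATIVE_CLASSES = ("texture", "dynamics", "broad", "other", "none")


@dataclass(frozen=True)
class TuningProfile:
    """PI matrix with the tuning flags and labels derived from it."""

    pi: np.ndarray
    mean_pi: np.ndarray
    tuned: np.ndarray
    stimulus_labels: tuple[str, ...]
    cell_ids: tuple[str, ...]
    tuned_factor: float = TUNED_FACTOR

    @property
    def broadly_tuned(self) -> np.ndarray:
        """True for cells tuned to every stimulus in the session."""
        return self.tuned.all(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.pi, index=list(self.cell_ids),
            columns=[f"pi_{s}" for s in self.stimulus_labels],
        )
        for j, s in enumerate(self.stimulus_labels):
            df[f"tuned_{s}"] = self.tuned[:, j]
        df["mean_pi"] = self.mean_pi
        df["broadly_tuned"] = self.broadly_tuned
        return df


def preference_index(tensor: ResponseTensor) -> np.ndarray:
    """PI matrix (cells x stimuli): trial-mean peak over Max_i.

    Negative trial means (possible when a whole window sits below baseline)
    are clipped to 0 so PI stays in [0, 1].
    """
    if np.any(tensor.max_per_cell <= 0):
        bad = np.flatnonzero(tensor.max_per_cell <= 0)
        raise UndefinedPreferenceError(
            f"Max_i <= 0 for cells {bad.tolist()}; filter non-responders first"
        )
    pi = tensor.peaks.mean(axis=2) / tensor.max_per_cell[:, None]
    return np.clip(pi, 0.0, None)


def response_index(tensor: ResponseTensor) -> np.ndarray:
    """RI matrix: the PI statistic over graded intensity levels.

    The tensor's "stimuli" axis holds the intensity levels of one stimulus
    kind (e.g. P0..P3 pinches); the formula is unchanged.
    """
    return preference_index(tensor)


def tuned_set(pi: np.ndarray, factor: float = TUNED_FACTOR) -> np.ndarray:
    """Boolean matrix: tuned[i, j] iff pi[i, j] > factor * mean_j pi[i, :].

    The inequality is strict, so an all-zero PI row is tuned to nothing.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 2:
        raise ContractError("pi must be a 2-D cells x stimuli matrix")
    if not (0 < factor):
        raise ContractError("factor must be positive")
    return pi > factor * pi.mean(axis=1, keepdims=True)


def build_tuning_profile(
    tensor: ResponseTensor, factor: float = TUNED_FACTOR
) -> TuningProfile:
    pi = preference_index(tensor)
    return TuningProfile(
        pi=pi,
        mean_pi=pi.mean(axis=1),
        tuned=tuned_set(pi, factor=factor),
        stimulus_labels=tensor.stimulus_labels,
        cell_ids=tensor.cell_ids,
        tuned_factor=factor,
    )


def venn_category_labels(stimulus_labels) -> tuple[str, ...]:
    """The 7 non-empty subsets of a 3-stimulus set, plus 'none'."""
    labels = tuple(stimulus_labels)
    cats = []
    for r in (1, 2, 3):
        for combo in combinations(labels, r):
            cats.append("+".join(combo))
    return tuple(cats) + ("none",)


def venn_categorize(tuned: np.ndarray, stimulus_labels):
    """Assign each cell to one of the 7 Venn subsets of a 3-stimulus set.

    Returns ``(categories, proportions)`` where ``categories`` is a string
    per cell (e.g. ``"Brush"``, ``"Press+Pinch"``, the all-three subset being
    the broadly tuned group) and ``proportions`` maps every subset to its
    fraction of the cells, summing to 1 together with ``"none"``.
    """
    tuned = np.asarray(tuned, dtype=bool)
    labels = tuple(stimulus_labels)
    if len(labels) != 3 or tuned.ndim != 2 or tuned.shape[1] != 3:
        raise ContractError("venn_categorize requires exactly 3 stimuli")
    categories = np.array(
        [
            "+".join(lab for lab, t in zip(labels, row) if t) or "none"
            for row in tuned
        ],
        dtype=object,
    )
    n = len(categories)
    proportions = {
        cat: float(np.sum(categories == cat)) / n
        for cat in venn_category_labels(labels)
    }
    return categories, proportions


def discriminative_class(
    tuned: np.ndarray,
    stimulus_labels,
    features: pd.DataFrame,
    mode: str = "exact",
) -> np.ndarray:
    """Classify cells as texture- or dynamics-discriminative in a 2x2 design.

    The session must cross two textures with two dynamics (four stimuli such
    as B-stroke / B-press / F-stroke / F-press).  A cell is
    texture-discriminative when its tuned set is exactly one same-texture
    pair (responsive to both brush stimuli, or both forceps stimuli,
    regardless of dynamics), dynamics-discriminative for a same-dynamics
    pair, ``broad`` when tuned to all four, ``none`` when tuned to nothing,
    and ``other`` for any remaining pattern.

    ``mode="superset"`` relaxes the rule to "tuned set contains the pair and
    is not all four".
    """
    tuned = np.asarray(tuned, dtype=bool)
    labels = tuple(stimulus_labels)
    if len(labels) != 4 or tuned.shape[1] != 4:
        raise ContractError("discriminative_class requires exactly 4 stimuli")
    if mode not in ("exact", "superset"):
        raise ContractError("mode must be 'exact' or 'superset'")
    feats = features.loc[list(labels)]
    textures = feats["texture"].unique()
    dynamics = feats["dynamics"].unique()
    if len(textures) != 2 or len(dynamics) != 2:
        raise ContractError("stimuli must form a 2x2 texture x dynamics design")
    combos = {(t, d) for t, d in zip(feats["texture"], feats["dynamics"])}
    if len(combos) != 4:
        raise ContractError("stimuli must form a 2x2 texture x dynamics design")

    texture_pairs = [
        frozenset(j for j, lab in enumerate(labels) if feats.loc[lab, "texture"] == t)
        for t in textures
    ]
    dynamics_pairs = [
        frozenset(j for j, lab in enumerate(labels) if feats.loc[lab, "dynamics"] == d)
        for d in dynamics
    ]

    def matches(cell_set: frozenset, pair: frozenset) -> bool:
        if mode == "exact":
            return cell_set == pair
        return pair <= cell_set and len(cell_set) < 4

    out = np.empty(tuned.shape[0], dtype=object)
    for i, row in enumerate(tuned):
        cell_set = frozenset(np.flatnonzero(row))
        if len(cell_set) == 0:
            out[i] = "none"
        elif len(cell_set) == 4:
            out[i] = "broad"
        elif any(matches(cell_set, p) for p in texture_pairs):
            out[i] = "texture"
        elif any(matches(cell_set, p) for p in dynamics_pairs):
            out[i] = "dynamics"
        else:
            out[i] = "other"
    return out


def per_group_percentages(labels: np.ndarray, groups: np.ndarray, classes=None):
    """Percentage of each class within each group (e.g. per mouse).

    Returns a DataFrame (groups x classes, rows summing to 100).  Averaging
    its columns gives the across-mice mean +/- s.e.m. the way population
    percentages are reported: per mouse first, then across mice.
    """
    labels = np.asarray(labels, dtype=object)
    groups = np.asarray(groups)
    if labels.shape != groups.shape:
        raise ContractError("labels and groups must align")
    if classes is None:
        classes = sorted(set(labels.tolist()))
    rows = {}
    for g in pd.unique(groups):
        sel = labels[groups == g]
        rows[g] = {c: 100.0 * np.mean(sel == c) for c in classes}
    return pd.DataFrame.from_dict(rows, orient="index")[list(classes)]


def intensity_category(mean_amplitudes, tolerance: float | None = None,
                       rel_tolerance: float = 0.1) -> str:
    """Classify a cell's mean amplitude profile across graded intensities.

    ``intensity_coding``: every adjacent step increases by more than the
    tolerance; ``inverse``: every step decreases by more; ``invariant``:
    all pairwise differences within tolerance; anything else ``irregular``.
    The default tolerance is ``rel_tolerance`` (10%) of the profile's grand
    mean — the "similar amplitude" band.
    """
    amps = np.asarray(mean_amplitudes, dtype=float)
    if amps.ndim != 1 or amps.size < 3:
        raise ContractError("need >= 3 intensity levels")
    if tolerance is None:
        tolerance = rel_tolerance * float(np.abs(amps).mean())
    diffs = np.diff(amps)
    if np.all(diffs > tolerance):
        return "intensity_coding"
    if np.all(diffs < -tolerance):
        return "inverse"
    pairwise = np.abs(amps[:, None] - amps[None, :])
    if np.all(pairwise <= tolerance):
        return "invariant"
    return "irregular"


def categorize_intensity_cells(
    tensor: ResponseTensor, tolerance: float | None = None,
    rel_tolerance: float = 0.1,
) -> np.ndarray:
    """Per-cell intensity category from trial-mean peaks across levels."""
    mean_amps = tensor.peaks.mean(axis=2)
    return np.array(
        [
            intensity_category(row, tolerance=tolerance, rel_tolerance=rel_tolerance)
            for row in mean_amps
        ],
        dtype=object,
    )


def intensity_summary(tensor: ResponseTensor) -> pd.DataFrame:
    """Per-intensity-level population summary.

    For each level: the number of recruited cells (>= 1 supra-threshold
    trial at that level), the mean response fidelity across the cells in the
    tensor, and the mean of per-cell trial-mean peak amplitudes.  Pass a
    responders-only tensor to summarize the responding population.
    """
    thr = tensor.response_threshold
    recruited = (tensor.peaks > thr).any(axis=2).sum(axis=0)
    return pd.DataFrame(
        {
            "level": list(tensor.stimulus_labels),
            "recruited_cells": recruited.astype(int),
            "mean_fidelity": tensor.fidelity.mean(axis=0),
            "mean_amplitude": tensor.peaks.mean(axis=2).mean(axis=0),
        }
    ).set_index("level")
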