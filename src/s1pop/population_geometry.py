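"""Population state space (PCA), condition distances, and stimulus clustering.

The instantaneous activity of an n-cell population is a point in an
n-dimensional space; projecting the per-cell mean-centered dF/F0 time series
onto its top principal components gives a low-dimensional state space in
which stimulus conditions occupy separable regions.  Separation between two
conditions is quantified as the mean Euclidean distance over all
cross-condition frame pairs.  Stimuli themselves are compared by
hierarchically clustering their per-cell PI columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .errors import ContractError, DegenerateProjectionError
from .trace_processing import DffRecording, StimulusProtocol

PRE_STIMULUS = "pre-stimulus"
INTER_STIMULUS = "inter-stimulus"


@dataclass(frozen=True)
class StateSpace:
    """Projected population activity with per-frame condition labels."""

    scores: np.ndarray  # frames x components
    components: np.ndarray  # components x cells (orthonormal loadings)
    explained_variance_ratio: np.ndarray
    frame_labels: np.ndarray  # condition per frame

    def frames_for(self, condition: str) -> np.ndarray:
        return self.scores[self.frame_labels == condition]


@dataclass(frozen=True)
class StimulusDendrogram:
    """Agglomerative merge history over stimulus labels (scipy linkage)."""

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]
    method: str
    metric: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def label_frames(
    protocol: StimulusProtocol,
    n_frames: int,
    frame_period_s: float,
    pre_window_s: float = 2.0,
) -> np.ndarray:
    """Condition label per frame.

    Frames in a stimulus response window (duration + post-window) carry the
    stimulus label; frames within ``pre_window_s`` before an onset are
    pre-stimulus; everything else is inter-stimulus.  Stimulus windows take
    precedence over an overlapping pre-window of the next stimulus.
    """
    labels = np.full(n_frames, INTER_STIMULUS, dtype=object)
    pre_frames = int(math.floor(pre_window_s / frame_period_s))
    for e in protocol.events:
        start = max(0, e.onset_frame - pre_frames)
        labels[start:e.onset_frame] = PRE_STIMULUS
    for e in protocol.events:
        win = protocol.window(e)
        labels[win.start:min(win.stop, n_frames)] = e.label
    return labels


def project_state_space(
    dff: DffRecording,
    protocol: StimulusProtocol,
    n_components: int = 3,
    scale: bool = False,
    pre_window_s: float = 2.0,
) -> StateSpace:
    """Project per-cell mean-centered dF/F0 onto its top principal axes.

    dF/F0 is already normalized per cell, so only mean-centering is applied
    by default; ``scale=True`` additionally divides each cell by its
    standard deviation.
    """
    if dff.n_cells < 2:
        raise ContractError("state-space projection needs >= 2 cells")
    if n_components < 1 or n_components > min(dff.n_cells, dff.n_frames):
        raise ContractError("n_components must be in [1, min(cells, frames)]")
    X = dff.dff.T.copy()  # frames x cells
    X -= X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise DegenerateProjectionError("dff carries no variance to project")
    if scale:
        nonzero = sd > 0
        X[:, nonzero] /= sd[nonzero]
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return StateSpace(
        scores=scores,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        frame_labels=label_frames(
            protocol, dff.n_frames, dff.frame_period_s, pre_window_s=pre_window_s
        ),
    )


def interstate_distance(space: StateSpace, condition_a: str, condition_b: str):
    """Mean Euclidean distance over all cross-condition frame pairs.

    Returns ``(mean, sem, n_pairs)`` where the s.e.m. is over the pooled
    pair distances.
    """
    a = space.frames_for(condition_a)
    b = space.frames_for(condition_b)
    if len(a) == 0 or len(b) == 0:
        raise ContractError(
            f"conditions must each have >= 1 frame "
            f"({condition_a!r}: {len(a)}, {condition_b!r}: {len(b)})"
        )
    d = cdist(a, b).ravel()
    sem = float(d.std(ddof=1) / math.sqrt(d.size)) if d.size > 1 else 0.0
    return float(d.mean()), sem, int(d.size)


def cluster_stimuli(
    pi: np.ndarray,
    stimulus_labels,
    method: str = "average",
    metric: str = "euclidean",
) -> StimulusDendrogram:
    """Agglomeratively cluster stimuli by their cell-PI profiles.

    Observations are stimulus columns (one PI per cell); the merge tree
    shows which stimuli evoke the most similar tuning across the population.
    """
    pi = np.asarray(pi, dtype=float)
    labels = tuple(stimulus_labels)
    if pi.ndim != 2 or pi.shape[1] != len(labels):
        raise ContractError("pi must be cells x stimuli matching the labels")
    if len(labels) < 2 or pi.shape[0] < 2:
        raise ContractError("need >= 2 stimuli and >= 2 cells")
    Z = linkage(pi.T, method=method, metric=metric)
    return StimulusDendrogram(
        linkage_matrix=Z, labels=labels, method=method, metric=metric
    )
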