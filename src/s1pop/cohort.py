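"""Convenience layer for multi-mouse (multi-session) analyses.

Stimulus order is randomized within each session, so tensors from different
mice list stimuli in different orders; everything here reorders to a
canonical label sequence before pooling.  Pooling across mice follows two
rules: preference indexes are pooled at the cell level (one scatter over all
mice), while state-space distances are computed per mouse (each mouse has
its own cells, hence its own space) and pooled at the pair level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population_geometry import StateSpace, project_state_space
from .trace_processing import (
    DffRecording,
    FluorescenceRecording,
    ResponseTensor,
    StimulusProtocol,
    compute_dff,
    detect_responders,
    extract_trial_peaks,
)
from .tuning_profile import TuningProfile, build_tuning_profile


@dataclass(frozen=True)
class SessionResult:
    """One mouse's processed session: responders-only, canonical order."""

    dff: DffRecording
    protocol: StimulusProtocol
    tensor: ResponseTensor  # responders only
    profile: TuningProfile
    responder_mask: np.ndarray
    n_cells_total: int


def process_session(
    recording: FluorescenceRecording,
    protocol: StimulusProtocol,
    response_threshold: float = 0.30,
    baseline_fraction: float = 0.30,
    tuned_factor: float = 0.8,
    canonical_labels: tuple[str, ...] | None = None,
) -> SessionResult:
    """Preprocess one session down to a responders-only tuning profile."""
    dff = compute_dff(recording, fraction=baseline_fraction)
    tensor = extract_trial_peaks(
        dff, protocol, response_threshold=response_threshold
    )
    if canonical_labels is not None:
        tensor = tensor.select_stimuli(canonical_labels)
    responders = detect_responders(tensor)
    tensor = tensor.select_cells(responders)
    profile = build_tuning_profile(tensor, factor=tuned_factor)
    return SessionResult(
        dff=dff,
        protocol=protocol,
        tensor=tensor,
        profile=profile,
        responder_mask=responders,
        n_cells_total=len(responders),
    )


def pooled_pi(sessions: list[SessionResult], non_broad_only: bool = False):
    """Stack PI matrices across mice (cells pooled into one scatter)."""
    mats = []
    for s in sessions:
        pi = s.profile.pi
        if non_broad_only:
            pi = pi[~s.profile.broadly_tuned]
        mats.append(pi)
    return np.vstack(mats)


def nonbroad_tensors(sessions: list[SessionResult]) -> list[ResponseTensor]:
    """Per-session tensors restricted to non-broadly-tuned responders."""
    return [
        s.tensor.select_cells(~s.profile.broadly_tuned) for s in sessions
    ]


def per_mouse_state_spaces(
    sessions: list[SessionResult],
    n_components: int = 3,
    pre_window_s: float = 2.0,
) -> list[StateSpace]:
    return [
        project_state_space(
            s.dff, s.protocol, n_components=n_components, pre_window_s=pre_window_s
        )
        for s in sessions
    ]
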