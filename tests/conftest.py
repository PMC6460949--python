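import numpy as np
import pytest

from s1pop.trace_processing import (
    DffRecording,
    StimulusEvent,
    StimulusProtocol,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_event(label, trial, onset, duration=3, texture="brush",
               dynamics="stroke", noxiousness="innocuous", intensity=None):
    return StimulusEvent(
        label=label,
        texture=texture,
        dynamics=dynamics,
        noxiousness=noxiousness,
        intensity_g=intensity,
        trial=trial,
        onset_frame=onset,
        duration_frames=duration,
    )


def grid_protocol(labels, n_trials, window=3, gap=4, post=0, start=2, **tags):
    """Regular protocol: stimuli cycle in order, fixed window and gap."""
    events = []
    onset = start
    for trial in range(1, n_trials + 1):
        for lab in labels:
            events.append(
                make_event(lab, trial, onset, duration=window, **tags)
            )
            onset += window + post + gap
    return StimulusProtocol(events=tuple(events), post_window_frames=post)


def dff_from_peaks(peaks, protocol, n_frames=None, base=0.0):
    """Build a DffRecording whose window maxima equal the given peaks.

    ``peaks[i, j, k]`` is written at the onset frame of trial k of stimulus
    j; everywhere else the trace is ``base``.
    """
    peaks = np.asarray(peaks, dtype=float)
    n_cells = peaks.shape[0]
    if n_frames is None:
        n_frames = protocol.n_frames_required + 2
    dff = np.full((n_cells, n_frames), base)
    labels = protocol.stimulus_labels
    trials = protocol.trial_indices
    for e in protocol.events:
        j = labels.index(e.label)
        k = trials.index(e.trial)
        dff[:, e.onset_frame] = peaks[:, j, k]
    return DffRecording(dff=dff, f0=np.ones(n_cells), frame_period_s=0.229)
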