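"""Raw fluorescence to dF/F0, responder detection, and trial-peak extraction.

The normalized activity signal throughout the package is dF/F0 with a
percentile-style baseline: F0 is the mean of the lowest 30% of a cell's raw
fluorescence samples, and dF/F0 = (F - F0) / F0.  A cell counts as responding
when at least one trial-peak dF/F0 exceeds 0.30 (i.e. a >30% fluorescence
change relative to baseline); only responders are carried into tuning and
population analyses.

Frame conventions: frames are 0-based and response windows are half-open,
``[onset, onset + duration + post_window)``.  The post-window extension
(default 2 s worth of frames) accounts for the slow decay of GCaMP6s, which
outlasts stimulus offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    BaselineDegenerateError,
    ContractError,
    MissingTrialError,
    ProtocolError,
)

TEXTURES = ("brush", "forceps", "none")
DYNAMICS = ("stroke", "press")
NOXIOUSNESS = ("innocuous", "noxious")

#: Default responder / fidelity threshold: trial-peak dF/F0 must exceed 30%.
RESPONSE_THRESHOLD = 0.30

#: Default fraction of lowest samples averaged into the baseline F0.
BASELINE_FRACTION = 0.30


@dataclass(frozen=True)
class FluorescenceRecording:
    """A cells x frames matrix of raw fluorescence (arbitrary units).

    Parameters
    ----------
    fluor
        Array of shape ``(n_cells, n_frames)``; finite and non-negative.
    frame_period_s
        Seconds per imaging frame (0.229 s in the experiments emulated here).
    cell_ids
        Unique per-cell labels; generated as ``cell000...`` when omitted.
    """

    fluor: np.ndarray
    frame_period_s: float
    cell_ids: tuple[str, ...] = ()

    def __post_init__(self):
        fluor = np.asarray(self.fluor, dtype=float)
        if fluor.ndim != 2:
            raise ContractError("fluor must be a 2-D cells x frames matrix")
        if fluor.shape[0] < 1 or fluor.shape[1] < 2:
            raise ContractError("need at least 1 cell and 2 frames")
        if not np.all(np.isfinite(fluor)):
            raise ContractError("fluorescence values must be finite")
        if np.any(fluor < 0):
            raise ContractError("fluorescence values must be >= 0")
        if not (self.frame_period_s > 0):
            raise ContractError("frame_period_s must be > 0")
        ids = tuple(self.cell_ids) or tuple(
            f"cell{i:03d}" for i in range(fluor.shape[0])
        )
        if len(ids) != fluor.shape[0]:
            raise ContractError("cell_ids length must match number of cells")
        if len(set(ids)) != len(ids):
            raise ContractError("cell_ids must be unique")
        object.__setattr__(self, "fluor", fluor)
        object.__setattr__(self, "cell_ids", ids)

    @property
    def n_cells(self) -> int:
        return self.fluor.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluor.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_period_s


@dataclass(frozen=True)
class DffRecording:
    """dF/F0 traces (dimensionless) with the per-cell baseline they used."""

    dff: np.ndarray
    f0: np.ndarray
    frame_period_s: float
    cell_ids: tuple[str, ...] = ()

    def __post_init__(self):
        dff = np.asarray(self.dff, dtype=float)
        f0 = np.asarray(self.f0, dtype=float)
        if dff.ndim != 2 or f0.shape != (dff.shape[0],):
            raise ContractError("dff must be cells x frames with one f0 per cell")
        if not np.all(np.isfinite(dff)):
            raise ContractError("dff must be finite")
        if np.any(f0 <= 0):
            raise ContractError("f0 must be > 0 for every cell")
        ids = tuple(self.cell_ids) or tuple(
            f"cell{i:03d}" for i in range(dff.shape[0])
        )
        object.__setattr__(self, "dff", dff)
        object.__setattr__(self, "f0", f0)
        object.__setattr__(self, "cell_ids", ids)

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation with its feature tags.

    ``texture`` is the contact material (brush hair vs forceps steel arm),
    ``dynamics`` distinguishes a moving stroke from a static press,
    ``noxiousness`` tags painful pinches, and ``intensity_g`` carries the
    pinch force in grams where applicable.
    """

    label: str
    texture: str
    dynamics: str
    noxiousness: str
    intensity_g: float | None
    trial: int
    onset_frame: int
    duration_frames: int

    def __post_init__(self):
        if self.texture not in TEXTURES:
            raise ContractError(f"texture must be one of {TEXTURES}")
        if self.dynamics not in DYNAMICS:
            raise ContractError(f"dynamics must be one of {DYNAMICS}")
        if self.noxiousness not in NOXIOUSNESS:
            raise ContractError(f"noxiousness must be one of {NOXIOUSNESS}")
        if self.intensity_g is not None and self.intensity_g < 0:
            raise ContractError("intensity_g must be >= 0")
        if self.trial < 1:
            raise ContractError("trial indexes are 1-based")
        if self.onset_frame < 0:
            raise ContractError("onset_frame must be >= 0")
        if self.duration_frames < 1:
            raise ContractError("duration_frames must be positive")


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered stimulus events plus the response-window extension.

    The extension ``post_window_frames`` is added to every event's duration
    when peaks are extracted and when frames are labelled by condition.
    Events must not overlap after extension, and every (label, trial) pair
    must be unique.
    """

    events: tuple[StimulusEvent, ...]
    post_window_frames: int = 0

    def __post_init__(self):
        events = tuple(self.events)
        if not events:
            raise ContractError("protocol must contain at least one event")
        if self.post_window_frames < 0:
            raise ContractError("post_window_frames must be >= 0")
        keys = [(e.label, e.trial) for e in events]
        if len(set(keys)) != len(keys):
            raise ContractError("(stimulus_label, trial) pairs must be unique")
        ordered = sorted(events, key=lambda e: e.onset_frame)
        for a, b in zip(ordered, ordered[1:]):
            if a.onset_frame + a.duration_frames + self.post_window_frames > b.onset_frame:
                raise ProtocolError(
                    f"events {a.label!r} trial {a.trial} and {b.label!r} trial "
                    f"{b.trial} overlap after window extension"
                )
        object.__setattr__(self, "events", events)

    @property
    def stimulus_labels(self) -> tuple[str, ...]:
        """Unique stimulus labels in order of first occurrence."""
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.label, None)
        return tuple(seen)

    @property
    def trial_indices(self) -> tuple[int, ...]:
        return tuple(sorted({e.trial for e in self.events}))

    @property
    def n_frames_required(self) -> int:
        return max(
            e.onset_frame + e.duration_frames + self.post_window_frames
            for e in self.events
        )

    def window(self, event: StimulusEvent) -> slice:
        """Half-open response window of an event, including the extension."""
        return slice(
            event.onset_frame,
            event.onset_frame + event.duration_frames + self.post_window_frames,
        )

    def stimulus_table(self) -> pd.DataFrame:
        """One row per stimulus label with its feature tags."""
        rows = {}
        for e in self.events:
            rows.setdefault(
                e.label,
                dict(
                    label=e.label,
                    texture=e.texture,
                    dynamics=e.dynamics,
                    noxiousness=e.noxiousness,
                    intensity_g=e.intensity_g,
                ),
            )
        return pd.DataFrame(list(rows.values())).set_index("label")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    label=e.label,
                    texture=e.texture,
                    dynamics=e.dynamics,
                    noxiousness=e.noxiousness,
                    intensity_g=e.intensity_g,
                    trial=e.trial,
                    onset_frame=e.onset_frame,
                    duration_frames=e.duration_frames,
                )
                for e in self.events
            ]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, post_window_frames: int = 0):
        events = []
        for row in df.itertuples(index=False):
            intensity = getattr(row, "intensity_g", None)
            if intensity is not None and (
                intensity == "" or (isinstance(intensity, float) and math.isnan(intensity))
            ):
                intensity = None
            events.append(
                StimulusEvent(
                    label=str(row.label),
                    texture=str(row.texture),
                    dynamics=str(row.dynamics),
                    noxiousness=str(row.noxiousness),
                    intensity_g=None if intensity is None else float(intensity),
                    trial=int(row.trial),
                    onset_frame=int(row.onset_frame),
                    duration_frames=int(row.duration_frames),
                )
            )
        return cls(events=tuple(events), post_window_frames=post_window_frames)


@dataclass(frozen=True)
class ResponseTensor:
    """Per-cell trial peaks P_ijk and derived per-cell summaries.

    ``peaks[i, j, k]`` is the maximum dF/F0 of cell *i* in the response
    window of trial *k* of stimulus *j*.  ``max_per_cell[i]`` (Max_i) is the
    highest dF/F0 the cell showed, by default over its entire recording, so
    ``peaks <= max_per_cell`` holds elementwise.  ``fidelity[i, j]`` is the
    fraction of trials whose peak exceeds the response threshold, and
    ``responder_flags`` marks cells with at least one supra-threshold peak
    anywhere.
    """

    peaks: np.ndarray
    max_per_cell: np.ndarray
    fidelity: np.ndarray
    responder_flags: np.ndarray
    stimulus_labels: tuple[str, ...]
    trial_indices: tuple[int, ...]
    response_threshold: float = RESPONSE_THRESHOLD
    cell_ids: tuple[str, ...] = ()
    stimulus_info: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self):
        peaks = np.asarray(self.peaks, dtype=float)
        if peaks.ndim != 3:
            raise ContractError("peaks must be cells x stimuli x trials")
        if not np.all(np.isfinite(peaks)):
            raise ContractError("peaks must be finite")
        n_cells, n_stim, n_trials = peaks.shape
        if len(self.stimulus_labels) != n_stim:
            raise ContractError("stimulus_labels length mismatch")
        if len(self.trial_indices) != n_trials:
            raise ContractError("trial_indices length mismatch")
        maxpc = np.asarray(self.max_per_cell, dtype=float)
        if maxpc.shape != (n_cells,):
            raise ContractError("max_per_cell must be one value per cell")
        fid = np.asarray(self.fidelity, dtype=float)
        if fid.shape != (n_cells, n_stim) or np.any((fid < 0) | (fid > 1)):
            raise ContractError("fidelity must be cells x stimuli in [0, 1]")
        ids = tuple(self.cell_ids) or tuple(f"cell{i:03d}" for i in range(n_cells))
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(self, "max_per_cell", maxpc)
        object.__setattr__(self, "fidelity", fid)
        object.__setattr__(
            self, "responder_flags", np.asarray(self.responder_flags, dtype=bool)
        )
        object.__setattr__(self, "cell_ids", ids)

    @property
    def n_cells(self) -> int:
        return self.peaks.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.peaks.shape[1]

    @property
    def n_trials(self) -> int:
        return self.peaks.shape[2]

    def select_cells(self, mask: np.ndarray) -> "ResponseTensor":
        """Subset the tensor to the cells where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype != bool:
            raise ContractError("cell mask must be boolean")
        if mask.shape != (self.n_cells,):
            raise ContractError("cell mask length mismatch")
        return replace(
            self,
            peaks=self.peaks[mask],
            max_per_cell=self.max_per_cell[mask],
            fidelity=self.fidelity[mask],
            responder_flags=self.responder_flags[mask],
            cell_ids=tuple(np.array(self.cell_ids)[mask]),
        )

    def select_stimuli(self, labels) -> "ResponseTensor":
        """Subset (and reorder) the tensor to the given stimulus labels."""
        idx = [self.stimulus_labels.index(lab) for lab in labels]
        info = self.stimulus_info
        return replace(
            self,
            peaks=self.peaks[:, idx, :],
            fidelity=self.fidelity[:, idx],
            stimulus_labels=tuple(labels),
            stimulus_info=None if info is None else info.loc[list(labels)],
        )


def compute_baseline(trace, fraction: float = BASELINE_FRACTION) -> float:
    """Baseline F0: mean of the ``floor(fraction * N)`` smallest samples.

    At least one sample is always used.  Raises
    :class:`BaselineDegenerateError` when the resulting baseline is not
    strictly positive, since dF/F0 is undefined there.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 4:
        raise ContractError("trace must be 1-D with at least 4 samples")
    if not np.all(np.isfinite(trace)):
        raise ContractError("trace must be finite")
    if not (0 < fraction < 1):
        raise ContractError("fraction must be in (0, 1)")
    k = max(1, int(math.floor(fraction * trace.size)))
    lowest = np.partition(trace, k - 1)[:k]
    baseline = float(lowest.mean())
    if baseline <= 0:
        raise BaselineDegenerateError(
            "baseline of lowest samples is not positive; dF/F0 undefined"
        )
    return baseline


def compute_dff(
    recording: FluorescenceRecording, fraction: float = BASELINE_FRACTION
) -> DffRecording:
    """Convert raw fluorescence to dF/F0 = (F - F0) / F0, cell by cell."""
    f0 = np.array(
        [compute_baseline(row, fraction=fraction) for row in recording.fluor]
    )
    dff = (recording.fluor - f0[:, None]) / f0[:, None]
    return DffRecording(
        dff=dff,
        f0=f0,
        frame_period_s=recording.frame_period_s,
        cell_ids=recording.cell_ids,
    )


def extract_trial_peaks(
    dff: DffRecording,
    protocol: StimulusProtocol,
    response_threshold: float = RESPONSE_THRESHOLD,
    max_scope: str = "trace",
) -> ResponseTensor:
    """Extract P_ijk, Max_i, response fidelity, and responder flags.

    Parameters
    ----------
    response_threshold
        dF/F0 a trial peak must strictly exceed to count as a response
        (responder rule and fidelity share this threshold).
    max_scope
        ``"trace"`` (default) takes Max_i over the whole recording of each
        cell; ``"windows"`` restricts it to the stimulus response windows.
    """
    if response_threshold <= 0:
        raise ContractError("response_threshold must be > 0")
    if max_scope not in ("trace", "windows"):
        raise ContractError("max_scope must be 'trace' or 'windows'")
    if protocol.n_frames_required > dff.n_frames:
        raise ProtocolError(
            f"protocol needs {protocol.n_frames_required} frames but the "
            f"recording has {dff.n_frames}"
        )
    labels = protocol.stimulus_labels
    trials = protocol.trial_indices
    by_key = {(e.label, e.trial): e for e in protocol.events}
    missing = [
        (lab, tr) for lab in labels for tr in trials if (lab, tr) not in by_key
    ]
    if missing:
        raise MissingTrialError(missing)

    n_cells = dff.n_cells
    peaks = np.empty((n_cells, len(labels), len(trials)))
    window_mask = np.zeros(dff.n_frames, dtype=bool)
    for j, lab in enumerate(labels):
        for k, tr in enumerate(trials):
            win = protocol.window(by_key[(lab, tr)])
            if win.stop <= win.start:
                raise ProtocolError(f"empty window for {lab!r} trial {tr}")
            peaks[:, j, k] = dff.dff[:, win].max(axis=1)
            window_mask[win] = True

    if max_scope == "trace":
        max_per_cell = dff.dff.max(axis=1)
    else:
        max_per_cell = dff.dff[:, window_mask].max(axis=1)
    fidelity = (peaks > response_threshold).mean(axis=2)
    responder = (peaks > response_threshold).any(axis=(1, 2))
    return ResponseTensor(
        peaks=peaks,
        max_per_cell=max_per_cell,
        fidelity=fidelity,
        responder_flags=responder,
        stimulus_labels=labels,
        trial_indices=trials,
        response_threshold=response_threshold,
        cell_ids=dff.cell_ids,
        stimulus_info=protocol.stimulus_table(),
    )


def detect_responders(
    tensor: ResponseTensor, threshold: float | None = None
) -> np.ndarray:
    """Boolean per cell: at least one trial peak strictly above threshold.

    Peaks exactly at the threshold do not count (the rule is a strict
    ``>30%`` fluorescence change).
    """
    thr = tensor.response_threshold if threshold is None else threshold
    if thr <= 0:
        raise ContractError("threshold must be > 0")
    return (tensor.peaks > thr).any(axis=(1, 2))
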