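"""Readers and writers for recordings, protocols, tensors and profiles.

Recordings travel as a plain CSV matrix (one row per cell, no header) with a
JSON sidecar holding the frame period and cell ids, or as an HDF5 container
with the same fields.  Protocols are tidy CSV tables, one event per row.
All load paths validate the domain invariants and raise :class:`LoadError`
with the offending location.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import LoadError, PipelineError
from .trace_processing import (
    FluorescenceRecording,
    ResponseTensor,
    StimulusProtocol,
)

PROTOCOL_COLUMNS = [
    "label",
    "texture",
    "dynamics",
    "noxiousness",
    "intensity_g",
    "trial",
    "onset_frame",
    "duration_frames",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording_csv(
    recording: FluorescenceRecording, path, sidecar=None
) -> None:
    path = Path(path)
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    np.savetxt(path, recording.fluor, delimiter=",", fmt="%.10g")
    sidecar.write_text(
        json.dumps(
            {
                "frame_period_s": recording.frame_period_s,
                "cell_ids": list(recording.cell_ids),
            },
            indent=2,
        )
    )


def read_recording_csv(path, sidecar=None) -> FluorescenceRecording:
    path = Path(path)
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    if not path.exists():
        raise LoadError(f"recording file not found: {path}")
    if not sidecar.exists():
        raise LoadError(f"recording sidecar not found: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise LoadError(f"malformed sidecar {sidecar}: {exc}") from exc
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.strip().split(",")
            row = []
            for col, tok in enumerate(fields):
                try:
                    row.append(float(tok))
                except ValueError:
                    raise LoadError(
                        f"{path}:{lineno}: non-numeric value {tok!r} in "
                        f"column {col + 1}"
                    ) from None
            rows.append(row)
    if rows and len({len(r) for r in rows}) != 1:
        raise LoadError(f"{path}: rows have inconsistent frame counts")
    try:
        return FluorescenceRecording(
            fluor=np.array(rows),
            frame_period_s=float(meta["frame_period_s"]),
            cell_ids=tuple(meta.get("cell_ids", ())),
        )
    except (PipelineError, KeyError) as exc:
        raise LoadError(f"{path}: invalid recording: {exc}") from exc


def write_recording_h5(recording: FluorescenceRecording, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("fluor", data=recording.fluor)
        ds.attrs["frame_period_s"] = recording.frame_period_s
        fh.create_dataset(
            "cell_ids", data=np.array(recording.cell_ids, dtype="S")
        )


def read_recording_h5(path) -> FluorescenceRecording:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"recording file not found: {path}")
    try:
        with h5py.File(path, "r") as fh:
            fluor = fh["fluor"][()]
            period = float(fh["fluor"].attrs["frame_period_s"])
            ids = tuple(s.decode() for s in fh["cell_ids"][()])
        return FluorescenceRecording(
            fluor=fluor, frame_period_s=period, cell_ids=ids
        )
    except (PipelineError, KeyError, OSError) as exc:
        raise LoadError(f"{path}: invalid recording: {exc}") from exc


def write_protocol_csv(protocol: StimulusProtocol, path) -> None:
    df = protocol.to_dataframe()[PROTOCOL_COLUMNS]
    df.to_csv(path, index=False)


def read_protocol_csv(path, post_window_frames: int = 0) -> StimulusProtocol:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"protocol file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise LoadError(f"malformed protocol CSV {path}: {exc}") from exc
    missing = [c for c in PROTOCOL_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    try:
        return StimulusProtocol.from_dataframe(
            df, post_window_frames=post_window_frames
        )
    except PipelineError as exc:
        raise LoadError(f"{path}: invalid protocol: {exc}") from exc


def validate_pair(
    recording: FluorescenceRecording, protocol: StimulusProtocol
) -> None:
    """Check that every protocol window fits inside the recording."""
    if protocol.n_frames_required > recording.n_frames:
        raise LoadError(
            f"protocol requires {protocol.n_frames_required} frames but the "
            f"recording has only {recording.n_frames}"
        )


def write_tensor_json(tensor: ResponseTensor, path) -> None:
    payload = {
        "peaks": tensor.peaks.tolist(),
        "max_per_cell": tensor.max_per_cell.tolist(),
        "fidelity": tensor.fidelity.tolist(),
        "responder_flags": tensor.responder_flags.tolist(),
        "stimulus_labels": list(tensor.stimulus_labels),
        "trial_indices": list(tensor.trial_indices),
        "response_threshold": tensor.response_threshold,
        "cell_ids": list(tensor.cell_ids),
        "stimulus_info": None
        if tensor.stimulus_info is None
        else tensor.stimulus_info.reset_index().to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload))


def read_tensor_json(path) -> ResponseTensor:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"tensor file not found: {path}")
    try:
        payload = json.loads(path.read_text())
        info = payload.get("stimulus_info")
        return ResponseTensor(
            peaks=np.array(payload["peaks"]),
            max_per_cell=np.array(payload["max_per_cell"]),
            fidelity=np.array(payload["fidelity"]),
            responder_flags=np.array(payload["responder_flags"], dtype=bool),
            stimulus_labels=tuple(payload["stimulus_labels"]),
            trial_indices=tuple(payload["trial_indices"]),
            response_threshold=float(payload["response_threshold"]),
            cell_ids=tuple(payload["cell_ids"]),
            stimulus_info=None
            if info is None
            else pd.DataFrame(info).set_index("label"),
        )
    except (PipelineError, KeyError, json.JSONDecodeError) as exc:
        raise LoadError(f"{path}: invalid tensor: {exc}") from exc
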