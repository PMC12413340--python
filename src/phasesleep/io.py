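"""Reading and writing recordings.

Internal exchange format: one ``.npy`` array per recording plus a JSON
sidecar holding ``{subject_id, stage, fs, channel_names, edge_pad_s}``.
Real polysomnography in EDF/EDF+ is read through MNE (optional extra).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .recording import EEGRecording

__all__ = ["save_recording", "load_recording", "save_cohort", "load_cohort", "read_edf"]


def _basename(rec: EEGRecording) -> str:
    return f"{rec.subject_id}_{rec.stage}"


def save_recording(rec: EEGRecording, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / _basename(rec)
    np.save(base.with_suffix(".npy"), rec.data)
    sidecar = {
        "subject_id": rec.subject_id,
        "stage": rec.stage,
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "edge_pad_s": rec.edge_pad_s,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".npy")


def load_recording(npy_path: str | Path) -> EEGRecording:
    npy_path = Path(npy_path)
    meta = json.loads(npy_path.with_suffix(".json").read_text())
    return EEGRecording(
        data=np.load(npy_path),
        fs=float(meta["fs"]),
        channel_names=tuple(meta["channel_names"]),
        stage=meta["stage"],
        subject_id=meta["subject_id"],
        edge_pad_s=float(meta.get("edge_pad_s", 0.0)),
    )


def save_cohort(recordings: list[EEGRecording], directory: str | Path) -> list[Path]:
    return [save_recording(r, directory) for r in recordings]


def load_cohort(directory: str | Path) -> list[EEGRecording]:
    directory = Path(directory)
    paths = sorted(directory.glob("*.npy"))
    if not paths:
        raise FileNotFoundError(f"no .npy recordings under {directory}")
    return [load_recording(p) for p in paths]


def read_edf(
    path: str | Path,
    stage: str,
    subject_id: str,
    channels: list[str] | None = None,
) -> EEGRecording:
    """Read one EDF/EDF+ file as a stage-labelled recording (needs mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels:
        raw.pick(channels)
    return EEGRecording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        stage=stage,
        subject_id=subject_id,
        edge_pad_s=0.0,
    )
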