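"""Readers and writers for recordings, events, epochs and feature tables.

Native on-disk formats are plain and dependency-free:

* recording: ``<stem>.raw`` (float32, channels × samples, C order, µV) with
  ``<stem>.json`` sidecar (subject, fs, channel names, units), or a TSV
  whose columns are channel labels and rows are samples;
* events: TSV ``onset_sample<TAB>label<TAB>subject_id``;
* epochs: ``<stem>.raw`` float32 flat array + JSON sidecar carrying shape,
  time axis, labels, subject ids and preprocessing provenance.

EDF recordings are read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, EpochSet, EventTable
from .montage import Montage


def _resolve_channels(available: list[str], montage: Montage) -> list[int]:
    """Indices of montage channels inside ``available``; error names gaps."""
    lookup = {name: i for i, name in enumerate(available)}
    missing = [ch for ch in montage if ch not in lookup]
    if missing:
        raise ValueError(
            f"recording is missing montage channel(s): {', '.join(missing)}"
        )
    return [lookup[ch] for ch in montage]


def write_raw_recording(recording: ContinuousRecording, stem: str | Path) -> Path:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    recording.data.astype(np.float32).tofile(stem.with_suffix(".raw"))
    sidecar = {
        "subject_id": recording.subject_id,
        "sampling_rate_hz": recording.sampling_rate_hz,
        "channel_names": list(recording.montage.names),
        "units": "uV",
        "n_samples": int(recording.n_samples),
        "dtype": "float32",
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return stem.with_suffix(".raw")


def read_raw_recording(stem: str | Path, montage: Montage | None = None) -> ContinuousRecording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    if meta.get("units", "uV") != "uV":
        raise ValueError(f"expected µV recording, sidecar says units={meta.get('units')!r}")
    names = meta["channel_names"]
    data = np.fromfile(stem.with_suffix(".raw"), dtype=meta.get("dtype", "float32"))
    data = data.reshape(len(names), meta["n_samples"]).astype(float)
    montage = montage or Montage(tuple(names))
    order = _resolve_channels(names, montage)
    return ContinuousRecording(
        meta["subject_id"], float(meta["sampling_rate_hz"]), montage, data[order]
    )


def write_tsv_recording(recording: ContinuousRecording, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(recording.data.T, columns=list(recording.montage.names))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_tsv_recording(
    path: str | Path,
    montage: Montage | None = None,
    *,
    subject_id: str = "unknown",
    sampling_rate_hz: float = 1024.0,
) -> ContinuousRecording:
    df = pd.read_csv(path, sep="\t")
    names = list(df.columns)
    montage = montage or Montage(tuple(names))
    order = _resolve_channels(names, montage)
    data = df.to_numpy(dtype=float).T[order]
    return ContinuousRecording(subject_id, sampling_rate_hz, montage, data)


def read_edf_recording(path: str | Path, montage: Montage | None = None) -> ContinuousRecording:
    """Read an EDF file via mne; data returned in µV, montage order."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - environment-dependent
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    montage = montage or Montage(tuple(names))
    order = _resolve_channels(names, montage)
    data = raw.get_data()[order] * 1e6  # volts -> µV
    return ContinuousRecording(Path(path).stem, float(raw.info["sfreq"]), montage, data)


def read_recording(path: str | Path, montage: Montage | None = None, **kwargs) -> ContinuousRecording:
    """Dispatch on extension: .edf, .tsv, or .raw/.json sidecar pair."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return read_edf_recording(path, montage)
    if suffix == ".tsv":
        return read_tsv_recording(path, montage, **kwargs)
    if suffix in (".raw", ".json", ""):
        return read_raw_recording(path.with_suffix(""), montage)
    raise ValueError(f"unrecognised recording format: {path.name}")


def write_events(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> EventTable:
    return EventTable.from_frame(pd.read_csv(path, sep="\t"))


def save_epochs(epochs: EpochSet, stem: str | Path, provenance: dict | None = None) -> Path:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    epochs.data.astype(np.float32).tofile(stem.with_suffix(".raw"))
    sidecar = {
        "shape": list(epochs.data.shape),
        "time_ms": epochs.time_ms.tolist(),
        "labels": [str(x) for x in epochs.labels],
        "subject_ids": [str(x) for x in epochs.subject_ids],
        "channel_names": list(epochs.montage.names),
        "sampling_rate_hz": epochs.sampling_rate_hz,
        "baseline_corrected": epochs.baseline_corrected,
        "dtype": "float32",
        "provenance": provenance or {},
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar))
    return stem.with_suffix(".raw")


def load_epochs(stem: str | Path) -> EpochSet:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".raw"), dtype=meta.get("dtype", "float32"))
    data = data.reshape(meta["shape"]).astype(float)
    return EpochSet(
        data,
        np.asarray(meta["time_ms"]),
        np.asarray(meta["labels"], dtype=object),
        np.asarray(meta["subject_ids"], dtype=object),
        Montage(tuple(meta["channel_names"])),
        float(meta["sampling_rate_hz"]),
        baseline_corrected=bool(meta["baseline_corrected"]),
    )


def write_feature_tsv(table, path: str | Path) -> Path:
    """Feature table as TSV: subject, label, then descriptor-named columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")
    return path
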