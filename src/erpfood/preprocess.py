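"""Preprocessing: band-pass filtering, epoching, baselining, artifact rejection.

The chain mirrors standard single-trial ERP practice: zero-phase 0.1–40 Hz
Butterworth band-pass on the continuous data, epoching −200..800 ms around
each stimulus marker, per-trial baseline correction over the pre-stimulus
interval, and whole-trial rejection on a peak-to-peak amplitude threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .containers import ContinuousRecording, EpochSet, EventTable, epoch_sample_counts


def bandpass(
    recording: ContinuousRecording,
    low_hz: float = 0.1,
    high_hz: float = 40.0,
) -> ContinuousRecording:
    """Zero-phase 4th-order Butterworth band-pass (forward–backward).

    The forward–backward pass squares the magnitude response and cancels
    the phase, so the effective attenuation is twice the single-pass dB.
    """
    fs = recording.sampling_rate_hz
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2, "
            f"got ({low_hz}, {high_hz}) at fs={fs}"
        )
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return replace(recording, data=filtered)


def extract_epochs(recording: ContinuousRecording, events: EventTable) -> EpochSet:
    """Cut half-open [onset − round(0.2·fs), onset + round(0.8·fs)) windows."""
    fs = recording.sampling_rate_hz
    pre, post = epoch_sample_counts(fs)
    n = recording.n_samples
    for i, onset in enumerate(events.onset_sample):
        if onset - pre < 0 or onset + post > n:
            raise ValueError(
                f"event {i} (onset sample {onset}) has its epoch window "
                f"[{onset - pre}, {onset + post}) outside the recording "
                f"of {n} samples"
            )
    data = np.stack(
        [recording.data[:, o - pre : o + post] for o in events.onset_sample]
    )
    time_ms = (np.arange(-pre, post) / fs) * 1000.0
    return EpochSet(
        data,
        time_ms,
        events.label,
        events.subject_id,
        recording.montage,
        fs,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial/channel's mean over the pre-stimulus [−200, 0) ms."""
    if epochs.baseline_corrected:
        raise ValueError("epochs are already baseline-corrected")
    mask = epochs.time_ms < 0
    if not mask.any():
        raise ValueError("epochs have no pre-stimulus interval to baseline on")
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - baseline, baseline_corrected=True)


@dataclass
class RejectionLog:
    """Outcome of artifact rejection; kept + dropped = input trial count."""

    n_input: int
    kept_index: np.ndarray
    dropped_index: np.ndarray
    offending_channels: dict[int, list[str]]
    threshold_uv: float

    @property
    def n_kept(self) -> int:
        return len(self.kept_index)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_index)


def reject_artifacts(
    epochs: EpochSet,
    ptp_threshold_uv: float = 100.0,
    predicate: Callable[[np.ndarray], bool] | None = None,
) -> tuple[EpochSet, RejectionLog]:
    """Drop whole trials whose peak-to-peak amplitude exceeds the threshold.

    A trial is rejected if any channel's max−min within the epoch exceeds
    ``ptp_threshold_uv``. An optional ``predicate(trial_data) -> bool``
    (True = reject) supplements the threshold for custom rules.
    """
    if ptp_threshold_uv <= 0:
        raise ValueError("ptp_threshold_uv must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials × channels
    bad = ptp > ptp_threshold_uv
    reject = bad.any(axis=1)
    if predicate is not None:
        reject = reject | np.array([bool(predicate(tr)) for tr in epochs.data])
    kept_index = np.flatnonzero(~reject)
    dropped_index = np.flatnonzero(reject)
    offenders = {
        int(i): [epochs.montage.names[j] for j in np.flatnonzero(bad[i])]
        for i in dropped_index
    }
    log = RejectionLog(
        epochs.n_trials, kept_index, dropped_index, offenders, ptp_threshold_uv
    )
    assert log.n_kept + log.n_dropped == epochs.n_trials
    return epochs.select(kept_index), log


def preprocess_recording(
    recording: ContinuousRecording,
    events: EventTable,
    *,
    low_hz: float = 0.1,
    high_hz: float = 40.0,
    ptp_threshold_uv: float | None = 100.0,
) -> tuple[EpochSet, RejectionLog | None]:
    """Filter → epoch → baseline → (optionally) reject, in one call."""
    filtered = bandpass(recording, low_hz, high_hz)
    epochs = baseline_correct(extract_epochs(filtered, events))
    if ptp_threshold_uv is None:
        return epochs, None
    return reject_artifacts(epochs, ptp_threshold_uv)
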