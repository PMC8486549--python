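"""In-memory containers shared across pipeline stages.

All voltages are microvolts (µV) throughout the package. Epochs live on a
−200..800 ms axis relative to stimulus onset; at the default 1024 Hz this
is exactly round(0.2·fs) + round(0.8·fs) = 205 + 819 = 1024 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .montage import Montage

FOOD = "food"
NONFOOD = "nonfood"
LABELS = (FOOD, NONFOOD)


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG for one subject.

    data is a channels × samples float array in µV, rows ordered as
    ``montage.names``.
    """

    subject_id: str
    sampling_rate_hz: float
    montage: Montage
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data must be (n_channels={len(self.montage)}, n_samples), "
                f"got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "ContinuousRecording":
        return replace(self, data=self.data.copy())


@dataclass
class EventTable:
    """Stimulus onsets (sample index), class labels, subject ids."""

    onset_sample: np.ndarray
    label: np.ndarray
    subject_id: np.ndarray

    def __post_init__(self) -> None:
        self.onset_sample = np.asarray(self.onset_sample, dtype=np.int64)
        self.label = np.asarray(self.label, dtype=object)
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        if not (len(self.onset_sample) == len(self.label) == len(self.subject_id)):
            raise ValueError("event columns have mismatched lengths")
        bad = set(np.unique(self.label)) - set(LABELS)
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")
        for sid in np.unique(self.subject_id):
            onsets = self.onset_sample[self.subject_id == sid]
            if np.any(np.diff(onsets) <= 0):
                raise ValueError(
                    f"event onsets not strictly increasing for subject {sid}"
                )

    def __len__(self) -> int:
        return len(self.onset_sample)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_sample": self.onset_sample,
                "label": self.label,
                "subject_id": self.subject_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        return cls(
            df["onset_sample"].to_numpy(),
            df["label"].to_numpy(),
            df["subject_id"].astype(str).to_numpy(),
        )


def epoch_sample_counts(fs: float, pre_s: float = 0.2, post_s: float = 0.8) -> tuple[int, int]:
    """Samples kept before / after the stimulus marker (round() per side)."""
    return int(np.round(pre_s * fs)), int(np.round(post_s * fs))


@dataclass
class EpochSet:
    """Stimulus-locked epochs: trials × channels × time, µV."""

    data: np.ndarray
    time_ms: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    montage: Montage
    sampling_rate_hz: float
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials × channels × time")
        n_trials, n_channels, n_time = self.data.shape
        if n_channels != len(self.montage):
            raise ValueError("channel axis does not match montage")
        if n_time != len(self.time_ms):
            raise ValueError("time axis length mismatch")
        if len(self.labels) != n_trials or len(self.subject_ids) != n_trials:
            raise ValueError("labels/subject_ids must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def window_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean mask of the half-open time window [start_ms, end_ms).

        The window must lie inside the epoch span, with one sample of
        tolerance so that nominal edges (e.g. 800 ms on a −200..800 ms
        axis whose last sample falls at 798.8 ms) remain valid.
        """
        dt = 1000.0 / self.sampling_rate_hz
        if start_ms < self.time_ms[0] - dt or end_ms > self.time_ms[-1] + 2 * dt:
            raise ValueError(
                f"window [{start_ms}, {end_ms}) ms outside the epoch span "
                f"[{self.time_ms[0]:.1f}, {self.time_ms[-1] + dt:.1f}) ms"
            )
        mask = (self.time_ms >= start_ms) & (self.time_ms < end_ms)
        if not mask.any():
            raise ValueError(f"window [{start_ms}, {end_ms}) ms contains no samples")
        return mask

    def select(self, index: np.ndarray) -> "EpochSet":
        return replace(
            self,
            data=self.data[index],
            labels=self.labels[index],
            subject_ids=self.subject_ids[index],
        )


@dataclass(frozen=True)
class FeatureColumn:
    """Descriptor of one feature-table column.

    family is one of {"amplitude", "band_power", "coherence"}; channels is
    a 1-tuple for per-electrode features and a 2-tuple for electrode pairs;
    band is None for amplitude features.
    """

    family: str
    component: str
    band: str | None
    channels: tuple[str, ...]

    def label(self) -> str:
        chan = "-".join(self.channels)
        band = self.band or "broadband"
        return f"{self.family}/{self.component}/{band}/{chan}"


@dataclass
class FeatureTable:
    """Trials × features matrix with per-column descriptors."""

    values: np.ndarray
    columns: list[FeatureColumn]
    labels: np.ndarray
    subject_ids: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values must be trials × len(columns)")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_labels(self) -> list[str]:
        return [c.label() for c in self.columns]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_labels())
        df.insert(0, "subject", self.subject_ids)
        df.insert(1, "label", self.labels)
        return df

    @classmethod
    def hstack(cls, tables: list["FeatureTable"]) -> "FeatureTable":
        first = tables[0]
        for t in tables[1:]:
            if t.n_trials != first.n_trials:
                raise ValueError("cannot hstack feature tables with different trial counts")
        return cls(
            np.hstack([t.values for t in tables]),
            [c for t in tables for c in t.columns],
            first.labels,
            first.subject_ids,
        )
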