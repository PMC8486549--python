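"""Electrode montage, frequency bands, and ERP component windows.

The defaults describe the 16-channel 10–20 montage, the classical EEG
frequency bands (with gamma capped at the 40 Hz low-pass corner of the
preprocessing filter), and the measurement windows of the two ERP
components of interest:

* **P300** — positive deflection peaking ~300 ms post-stimulus; measured
  here over a 200 ms window centred on the peak, [250, 450) ms.
* **LPP** (late positive potential) — sustained positivity over
  [550, 700) ms, linked to focused attention to the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "P3", "P4", "Pz",
    "C3", "C4", "Cz", "O1", "O2", "Oz", "T7", "T8",
)


@dataclass(frozen=True)
class Montage:
    """Ordered set of named scalp electrodes."""

    names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("montage needs at least 2 channels")
        if len(set(self.names)) != len(self.names):
            raise ValueError("montage channel labels must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered pairs of distinct channels, lexicographic by index."""
        n = len(self.names)
        return [
            (self.names[i], self.names[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]


#: Band edges in Hz. Delta's nominal low edge is 0.5 Hz but a 1 s epoch
#: cannot resolve it; the wavelet frequency grid starts at 1 Hz (see
#: :func:`erpfood.features.band_frequencies`). Gamma stops at the 40 Hz
#: corner of the 0.1–40 Hz acquisition band-pass.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}

#: Bands entering the default reports. Gamma is computed on request but is
#: excluded by default: the band tables of interest group four bands.
REPORT_BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta")


def band_edges(band: str) -> tuple[float, float]:
    try:
        return DEFAULT_BANDS[band]
    except KeyError:
        raise KeyError(
            f"unknown band {band!r}; known: {sorted(DEFAULT_BANDS)}"
        ) from None


@dataclass(frozen=True)
class ComponentWindow:
    """Post-stimulus measurement window of an ERP component, in ms."""

    name: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_ms < self.end_ms <= 800):
            raise ValueError(
                f"component window must satisfy 0 <= start < end <= 800 ms, "
                f"got [{self.start_ms}, {self.end_ms})"
            )


P300 = ComponentWindow("P300", 250.0, 450.0)
LPP = ComponentWindow("LPP", 550.0, 700.0)

COMPONENT_WINDOWS: dict[str, ComponentWindow] = {"P300": P300, "LPP": LPP}


def component_window(name: str) -> ComponentWindow:
    try:
        return COMPONENT_WINDOWS[name]
    except KeyError:
        raise KeyError(
            f"unknown component {name!r}; known: {sorted(COMPONENT_WINDOWS)}"
        ) from None
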