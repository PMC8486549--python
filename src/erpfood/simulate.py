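"""Synthetic evoked-EEG generator with planted food/nonfood class effects.

The generator emulates the study conditions the downstream analysis
assumes: 21 subjects viewing randomly interleaved food and nonfood images
(73 food + 28 nonfood per block, 5 blocks), recorded on a 16-channel
10–20 montage at 1024 Hz. Each trial superimposes, on 1/f background
noise, two evoked components per channel:

* a Gaussian **P300** bump centred at 300 ms (σ = 50 ms), and
* a raised-cosine-edged **LPP** plateau over 550–700 ms,

whose single-trial amplitudes are drawn from a class-conditional effect
table (per-channel mean and between-subject std, in µV) plus a shared
per-subject offset, an optional per-condition subject offset, and i.i.d.
trial jitter. Band-limited common sources injected into designated
electrode pairs (by default Fp1–Fp2 theta in the P300 window and Fp2–Fz
delta in the LPP window) plant class-dependent coherence.

Amplitude parameters are µV throughout; no reference-electrode or
head-model forward simulation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import FOOD, NONFOOD, ContinuousRecording, EventTable, EpochSet, epoch_sample_counts
from .montage import Montage, band_edges, component_window

__all__ = [
    "DEFAULT_EFFECT_TABLE",
    "CoherenceSpec",
    "SimulationConfig",
    "evoked_waveform",
    "pink_noise",
    "inject_coherent_source",
    "simulate_subject",
    "simulate_study",
    "null_epochs",
    "subject_condition_means",
]

# Default class-conditional component amplitudes: (mean µV, between-subject
# std µV) per channel × component × condition. Oz and T7 carry the P300
# food/nonfood difference; LPP differences are small everywhere.
_T = {
    #           P300 food         P300 nonfood      LPP food          LPP nonfood
    "Fp1": ((1.205, 1.144), (1.623, 1.119), (2.315, 1.142), (2.114, 1.091)),
    "Fp2": ((-0.027, 1.172), (0.054, 1.135), (1.020, 1.171), (0.445, 1.138)),
    "F3": ((-6.537, 1.155), (-6.286, 1.140), (-5.781, 1.173), (-5.822, 1.142)),
    "Fz": ((7.298, 1.008), (7.462, 1.001), (6.812, 1.016), (6.413, 0.992)),
    "F4": ((0.721, 1.014), (0.676, 1.019), (1.368, 1.026), (1.438, 1.006)),
    "P3": ((4.107, 1.008), (4.461, 0.989), (4.955, 1.030), (5.054, 1.015)),
    "P4": ((-15.839, 1.282), (-15.967, 1.300), (-15.452, 1.300), (-14.816, 1.329)),
    "Pz": ((-8.574, 1.186), (-8.037, 1.193), (-8.047, 1.200), (-8.468, 1.197)),
    "C3": ((2.556, 0.960), (3.079, 0.954), (2.109, 0.964), (1.722, 0.963)),
    "C4": ((-1.077, 0.946), (-1.092, 0.932), (-1.349, 0.955), (-1.370, 0.938)),
    "Cz": ((7.233, 0.963), (7.405, 0.949), (6.215, 0.964), (6.177, 0.940)),
    "O1": ((1.193, 0.999), (0.899, 0.996), (0.657, 1.006), (0.739, 1.035)),
    "O2": ((4.099, 0.982), (3.856, 0.989), (3.194, 0.990), (3.286, 0.997)),
    "Oz": ((5.218, 0.952), (4.275, 0.943), (4.752, 0.958), (4.681, 0.953)),
    "T7": ((-1.646, 1.187), (-2.662, 1.151), (-2.080, 1.190), (-1.683, 1.192)),
    "T8": ((0.069, 1.171), (0.254, 1.123), (-0.688, 0.091), (1.149, 1.185)),
}


def _default_effect_table() -> dict:
    """effect_table[channel][component][condition] -> (mean µV, std µV)."""
    table: dict[str, dict[str, dict[str, tuple[float, float]]]] = {}
    for ch, (pf, pn, lf, ln) in _T.items():
        table[ch] = {
            "P300": {FOOD: pf, NONFOOD: pn},
            "LPP": {FOOD: lf, NONFOOD: ln},
        }
    return table


DEFAULT_EFFECT_TABLE = _default_effect_table()


@dataclass(frozen=True)
class CoherenceSpec:
    """A band-limited common source planted into one electrode pair.

    The same noise realization (unit RMS, band-pass filtered) is added to
    both channels of ``pair`` inside each trial's ``window_ms``, scaled by
    the trial's condition gain (µV RMS). gain food ≠ gain nonfood plants a
    class-dependent coherence difference.
    """

    pair: tuple[str, str]
    band: str
    window_ms: tuple[float, float]
    gain: dict[str, float]


def _default_coherence_specs() -> list[CoherenceSpec]:
    return [
        CoherenceSpec(("Fp1", "Fp2"), "theta", (250.0, 450.0), {FOOD: 4.0, NONFOOD: 2.0}),
        CoherenceSpec(("Fp2", "Fz"), "delta", (550.0, 700.0), {FOOD: 4.0, NONFOOD: 2.0}),
    ]


@dataclass
class SimulationConfig:
    """Study-level knobs of the synthetic generator.

    Defaults reproduce the emulated study: 21 subjects × 5 blocks of
    73 food + 28 nonfood trials, 1024 Hz, 1000 ms stimulus-onset
    asynchrony. ``subject_sd_scale`` scales the between-subject offset std
    taken from the effect table; ``condition_offset_sd_uv`` adds an
    independent per-condition subject offset, so the across-subject
    difference-score sd is √2 × that value.
    """

    n_subjects: int = 21
    blocks: int = 5
    food_per_block: int = 73
    nonfood_per_block: int = 28
    sampling_rate_hz: float = 1024.0
    soa_ms: float = 1000.0
    effect_table: dict = field(default_factory=_default_effect_table)
    coherence_specs: list[CoherenceSpec] = field(default_factory=_default_coherence_specs)
    noise_exponent: float = 1.0
    noise_rms_uv: float = 10.0
    trial_jitter_uv: float = 5.0
    subject_sd_scale: float = 1.0
    condition_offset_sd_uv: float = 0.0
    montage: Montage = field(default_factory=Montage)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "blocks", "food_per_block", "nonfood_per_block"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.soa_ms < 800:
            raise ValueError(
                "soa_ms below the 800 ms stimulus duration would overlap trials"
            )
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        for ch in self.montage:
            try:
                entry = self.effect_table[ch]
                for comp in ("P300", "LPP"):
                    for cond in (FOOD, NONFOOD):
                        entry[comp][cond]
            except KeyError as err:
                raise ValueError(
                    f"effect_table incomplete for channel {ch!r}: missing {err}"
                ) from None

    @property
    def trials_per_subject(self) -> int:
        return self.blocks * (self.food_per_block + self.nonfood_per_block)

    def subject_ids(self) -> list[str]:
        width = max(2, len(str(self.n_subjects)))
        return [f"S{i + 1:0{width}d}" for i in range(self.n_subjects)]


def evoked_waveform(
    component: str,
    amplitude: float,
    time_ms: np.ndarray,
    *,
    peak_ms: float = 300.0,
    sigma_ms: float = 50.0,
    plateau_ms: tuple[float, float] = (550.0, 700.0),
    ramp_ms: float = 50.0,
) -> np.ndarray:
    """Unit evoked-component shape scaled to ``amplitude`` µV.

    P300 is a Gaussian bump with peak value ``amplitude`` at ``peak_ms``;
    LPP is a plateau at ``amplitude`` over ``plateau_ms`` with raised-cosine
    edges of width ``ramp_ms`` outside the plateau. Both are effectively
    zero (<1 % of amplitude) in the pre-stimulus interval.
    """
    if not np.isfinite(amplitude):
        raise ValueError("amplitude must be finite")
    t = np.asarray(time_ms, dtype=float)
    if component == "P300":
        return amplitude * np.exp(-0.5 * ((t - peak_ms) / sigma_ms) ** 2)
    if component == "LPP":
        lo, hi = plateau_ms
        w = np.zeros_like(t)
        w[(t >= lo) & (t <= hi)] = 1.0
        rise = (t >= lo - ramp_ms) & (t < lo)
        w[rise] = 0.5 * (1 + np.cos(np.pi * (lo - t[rise]) / ramp_ms))
        fall = (t > hi) & (t <= hi + ramp_ms)
        w[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - hi) / ramp_ms))
        return amplitude * w
    raise ValueError(f"unknown component {component!r}; expected 'P300' or 'LPP'")


def _shaped_noise(rng: np.random.Generator, shape: tuple[int, int], exponent: float) -> np.ndarray:
    """Rows of 1/f^exponent noise, unit-RMS, zero-mean."""
    n_rows, n_samples = shape
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros(n_freq)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_rows, n_freq)) + 1j * rng.standard_normal((n_rows, n_freq))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def pink_noise(
    n_samples: int,
    exponent: float = 1.0,
    rms: float = 10.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Zero-mean 1/f^exponent noise with the requested RMS (µV).

    exponent 0 is white noise; exponent 1 approximates background EEG's
    spectral tilt. Reproducible when ``rng`` is a seed or seeded Generator.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = np.random.default_rng(rng)
    if n_samples == 1:
        return np.zeros(1)
    return rms * _shaped_noise(rng, (1, n_samples), exponent)[0]


def _bandlimited_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-RMS band-passed white noise of length n, edge-tapered."""
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} must lie within (0, fs/2)")
    pad = max(n, int(2 * fs / lo))
    x = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)[pad : pad + n]
    y = y * signal.windows.tukey(n, alpha=0.2)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def inject_coherent_source(
    recording: ContinuousRecording,
    spec: CoherenceSpec,
    events: EventTable,
    rng: np.random.Generator | int | None = None,
) -> ContinuousRecording:
    """Add a shared band-limited source to both channels of a pair.

    Inside each trial's window the *same* unit-RMS realization, scaled by
    the trial's condition gain, is added to both pair members; all other
    channels and samples are untouched. Zero gain for both conditions
    leaves the recording bit-identical.
    """
    rng = np.random.default_rng(rng)
    fs = recording.sampling_rate_hz
    i0 = recording.montage.index(spec.pair[0])
    i1 = recording.montage.index(spec.pair[1])
    band = band_edges(spec.band) if isinstance(spec.band, str) else tuple(spec.band)
    w0 = int(np.round(spec.window_ms[0] / 1000.0 * fs))
    w1 = int(np.round(spec.window_ms[1] / 1000.0 * fs))
    n_win = w1 - w0
    if n_win <= 0:
        raise ValueError("coherence window must have positive length")
    out = recording.copy()
    for onset, label in zip(events.onset_sample, events.label):
        gain = float(spec.gain.get(str(label), 0.0))
        if gain == 0.0:
            continue
        a, b = onset + w0, onset + w1
        if a < 0 or b > recording.n_samples:
            raise ValueError(
                f"coherence window [{a}, {b}) outside recording of "
                f"{recording.n_samples} samples"
            )
        src = gain * _bandlimited_noise(rng, n_win, band, fs)
        out.data[i0, a:b] += src
        out.data[i1, a:b] += src
    return out


def _subject_amplitudes(
    config: SimulationConfig,
    rng: np.random.Generator,
    labels: np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-trial per-channel evoked amplitudes for one subject, by component."""
    n_trials = len(labels)
    n_ch = len(config.montage)
    is_food = labels == FOOD
    amps: dict[str, np.ndarray] = {}
    for comp in ("P300", "LPP"):
        means = np.empty((2, n_ch))  # row 0: food, row 1: nonfood
        sds = np.empty((2, n_ch))
        for j, ch in enumerate(config.montage):
            means[0, j], sds[0, j] = config.effect_table[ch][comp][FOOD]
            means[1, j], sds[1, j] = config.effect_table[ch][comp][NONFOOD]
        # shared subject offset uses the condition-averaged between-subject std
        shared = rng.normal(0.0, config.subject_sd_scale * sds.mean(axis=0))
        cond_off = rng.normal(0.0, config.condition_offset_sd_uv, size=(2, n_ch))
        base = np.where(is_food[:, None], means[0] + cond_off[0], means[1] + cond_off[1])
        jitter = rng.normal(0.0, config.trial_jitter_uv, size=(n_trials, n_ch))
        amps[comp] = base + shared[None, :] + jitter
    return amps


def _subject_rng(config: SimulationConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(subject_index)]))


def simulate_subject(
    config: SimulationConfig,
    subject_index: int,
) -> tuple[ContinuousRecording, EventTable]:
    """Continuous recording + events for one subject (0-based index).

    Deterministic in (config.seed, subject_index). Each block's food and
    nonfood trials are randomly interleaved; the recording covers the last
    epoch with padding on both sides.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(f"subject_index {subject_index} outside 0..{config.n_subjects - 1}")
    rng = _subject_rng(config, subject_index)
    fs = config.sampling_rate_hz
    subject_id = config.subject_ids()[subject_index]

    blocks = []
    for _ in range(config.blocks):
        block = np.array(
            [FOOD] * config.food_per_block + [NONFOOD] * config.nonfood_per_block,
            dtype=object,
        )
        rng.shuffle(block)
        blocks.append(block)
    labels = np.concatenate(blocks)
    n_trials = len(labels)

    soa = int(np.round(config.soa_ms / 1000.0 * fs))
    pre, post = epoch_sample_counts(fs)
    start = pre + int(np.round(0.5 * fs))
    onsets = start + soa * np.arange(n_trials)
    n_samples = int(onsets[-1] + post + np.round(0.5 * fs))

    data = config.noise_rms_uv * _shaped_noise(
        rng, (len(config.montage), n_samples), config.noise_exponent
    )

    time_ms = (np.arange(-pre, post) / fs) * 1000.0
    # Calibrate each unit shape by its mean over the component's measurement
    # window, so the window-mean amplitude feature read out downstream
    # recovers the configured µV value (the P300 Gaussian peak is therefore
    # amplitude / 0.527 at the default window).
    shapes = {}
    for comp in ("P300", "LPP"):
        shape = evoked_waveform(comp, 1.0, time_ms)
        win = component_window(comp)
        mask = (time_ms >= win.start_ms) & (time_ms < win.end_ms)
        shapes[comp] = shape / shape[mask].mean()
    amps = _subject_amplitudes(config, rng, labels)
    for i, onset in enumerate(onsets):
        sl = slice(onset - pre, onset + post)
        for comp, shape in shapes.items():
            data[:, sl] += amps[comp][i][:, None] * shape[None, :]

    recording = ContinuousRecording(subject_id, fs, config.montage, data)
    events = EventTable(onsets, labels, np.full(n_trials, subject_id, dtype=object))
    for spec in config.coherence_specs:
        recording = inject_coherent_source(recording, spec, events, rng)
    return recording, events


def simulate_study(config: SimulationConfig):
    """Yield (recording, events) per subject, each independently seeded."""
    for i in range(config.n_subjects):
        yield simulate_subject(config, i)


def null_epochs(
    n_subjects: int,
    trials_per_condition: int,
    *,
    montage: Montage | None = None,
    sampling_rate_hz: float = 1024.0,
    noise_rms_uv: float = 10.0,
    exponent: float = 0.0,
    seed: int | None = None,
) -> EpochSet:
    """Signal-free epochs for calibration runs.

    Food and nonfood trials are i.i.d. noise (white by default, 1/f^exponent
    otherwise), so the two classes are exchangeable by construction and any
    downstream test's p-values must be uniform. This is the fast path for
    type-I-error and classifier-baseline calibration; planted effects are
    exercised through :func:`simulate_subject`.
    """
    montage = montage or Montage()
    rng = np.random.default_rng(seed)
    pre, post = epoch_sample_counts(sampling_rate_hz)
    n_time = pre + post
    n_trials = n_subjects * 2 * trials_per_condition
    if exponent == 0.0:
        data = rng.standard_normal((n_trials, len(montage), n_time)) * noise_rms_uv
    else:
        flat = noise_rms_uv * _shaped_noise(
            rng, (n_trials * len(montage), n_time), exponent
        )
        data = flat.reshape(n_trials, len(montage), n_time)
    labels = np.tile(
        np.array([FOOD] * trials_per_condition + [NONFOOD] * trials_per_condition, dtype=object),
        n_subjects,
    )
    subject_ids = np.repeat(
        np.array([f"S{i + 1:02d}" for i in range(n_subjects)], dtype=object),
        2 * trials_per_condition,
    )
    time_ms = (np.arange(-pre, post) / sampling_rate_hz) * 1000.0
    return EpochSet(data, time_ms, labels, subject_ids, montage, sampling_rate_hz)


def subject_condition_means(
    food_mean: float,
    nonfood_mean: float,
    *,
    n_subjects: int = 21,
    subject_sd: float = 1.0,
    condition_offset_sd: float = 0.0,
    trial_sem: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level condition means under the generator's amplitude model.

    This is the exact marginal distribution of per-subject condition mean
    amplitudes produced by :func:`simulate_subject` for one channel and
    component: a shared subject offset (``subject_sd``), independent
    per-condition offsets (``condition_offset_sd``; the across-subject
    difference-score sd equals √2 × this), and residual trial-averaging
    noise (``trial_sem``). Useful for statistical power calibration without
    simulating continuous EEG.
    """
    rng = np.random.default_rng(rng)
    shared = rng.normal(0.0, subject_sd, n_subjects)
    food = food_mean + shared + rng.normal(0.0, condition_offset_sd, n_subjects)
    nonfood = nonfood_mean + shared + rng.normal(0.0, condition_offset_sd, n_subjects)
    if trial_sem > 0:
        food = food + rng.normal(0.0, trial_sem, n_subjects)
        nonfood = nonfood + rng.normal(0.0, trial_sem, n_subjects)
    return food, nonfood
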