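"""Single-trial feature families: amplitudes, wavelet band power, coherence.

Three feature datasets are built from a baseline-corrected
:class:`~erpfood.containers.EpochSet`:

* **dataset1** — ERP component amplitude: mean voltage per channel over the
  component window (16 columns per component on the default montage);
* **dataset2** — wavelet band power: mean squared magnitude of a complex
  Morlet CWT (ω₀ = 6) over the band's frequency grid × window samples,
  per channel;
* **dataset3** — single-trial wavelet coherence for every unordered
  electrode pair (120 columns for 16 channels), time-averaged over the
  component window and frequency-averaged over the band.

CWT details. Each epoch is reflection-padded by its own length on both
sides before the transform, and only window interiors are consumed, which
keeps cone-of-influence artifacts out of the features. Frequencies are
integer-spaced within each band; the delta grid is {1, 2, 3, 4} Hz because
a 1 s epoch cannot support 0.5 Hz. Coefficients are rescaled by 2/scale so
that a unit-amplitude sinusoid at an analyzed frequency yields its
spectral band power A²/2 (µV²), directly comparable to a Welch estimate.

Coherence smoothing. Raw single-trial wavelet coherence without averaging
is identically 1; the estimator here time-averages cross- and auto-spectra
over the component window (no scale smoothing), which is what makes the
single-trial quantity informative. Its null level is set by the window's
effective degrees of freedom and is well above zero for short windows.
"""

from __future__ import annotations

import logging
from math import ceil, floor

import numpy as np
import pywt

from .containers import EpochSet, FeatureColumn, FeatureTable
from .montage import ComponentWindow, band_edges, component_window

logger = logging.getLogger(__name__)

#: complex Morlet with ω₀ = 6: pywt's cmorB-C with B = 2, C = ω₀ / 2π
MORLET_OMEGA0 = 6.0
_WAVELET = f"cmor2.0-{MORLET_OMEGA0 / (2 * np.pi):.9f}"


def n_pairs(n_channels: int) -> int:
    """Number of unordered pairs of distinct channels; 16 -> 120."""
    if n_channels < 2:
        raise ValueError("need at least 2 channels to form pairs")
    return n_channels * (n_channels - 1) // 2


def band_frequencies(band: str | tuple[float, float], fs: float) -> np.ndarray:
    """Integer-spaced analysis frequencies within a band, capped at fs/2."""
    lo, hi = band_edges(band) if isinstance(band, str) else band
    freqs = np.arange(ceil(lo), floor(hi) + 1, dtype=float)
    freqs = freqs[freqs < fs / 2]
    if len(freqs) == 0:
        raise ValueError(f"band ({lo}, {hi}) Hz has no analyzable frequency below fs/2")
    return freqs


def _resolve_window(window, epochs: EpochSet) -> tuple[str, np.ndarray]:
    if isinstance(window, str):
        window = component_window(window)
    if isinstance(window, ComponentWindow):
        return window.name, epochs.window_mask(window.start_ms, window.end_ms)
    start, end = window
    return f"{start:g}-{end:g}ms", epochs.window_mask(start, end)


def morlet_cwt(data: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Complex Morlet CWT of rows of ``data`` with reflection padding.

    data: (..., n_time); returns (..., n_freqs, n_time) complex.
    """
    data = np.asarray(data, dtype=float)
    n_time = data.shape[-1]
    flat = data.reshape(-1, n_time)
    scales = pywt.frequency2scale(_WAVELET, np.asarray(freqs) / fs)
    # pad at least one epoch and at least the slowest wavelet's effective
    # support (4 scale units ~ e^{-8} envelope), else low-frequency
    # coefficients are quenched by the implicit zero extension
    pad = max(n_time, int(np.ceil(4 * scales.max())))
    padded = np.pad(flat, [(0, 0), (pad, pad)], mode="reflect")
    coef, _ = pywt.cwt(padded, scales, _WAVELET, method="fft", axis=-1)
    # pywt returns (n_scales, rows, time); crop the padding back off
    coef = np.moveaxis(coef, 0, 1)[:, :, pad : pad + n_time]
    return coef.reshape(*data.shape[:-1], len(freqs), n_time)


def _scales(freqs: np.ndarray, fs: float) -> np.ndarray:
    return pywt.frequency2scale(_WAVELET, np.asarray(freqs) / fs)


def component_amplitude(epochs: EpochSet, window: str | ComponentWindow = "P300") -> FeatureTable:
    """Mean voltage (µV) per channel over the component window."""
    if not epochs.baseline_corrected:
        raise ValueError("component amplitudes require baseline-corrected epochs")
    name, mask = _resolve_window(window, epochs)
    values = epochs.data[:, :, mask].mean(axis=2)
    columns = [
        FeatureColumn("amplitude", name, None, (ch,)) for ch in epochs.montage
    ]
    return FeatureTable(values, columns, epochs.labels, epochs.subject_ids)


def _iter_cwt_chunks(epochs: EpochSet, freqs: np.ndarray, mask: np.ndarray, chunk: int = 8):
    """Yield (trial_slice, W) with W = (n, n_ch, n_f, n_window) complex."""
    for start in range(0, epochs.n_trials, chunk):
        sl = slice(start, min(start + chunk, epochs.n_trials))
        W = morlet_cwt(epochs.data[sl], freqs, epochs.sampling_rate_hz)
        yield sl, W[..., mask]


def wavelet_band_power(
    epochs: EpochSet,
    band: str,
    window: str | ComponentWindow = "P300",
) -> FeatureTable:
    """Mean Morlet power (µV²) over band frequencies × window samples."""
    fs = epochs.sampling_rate_hz
    freqs = band_frequencies(band, fs)
    name, mask = _resolve_window(window, epochs)
    gain = 2.0 / _scales(freqs, fs)  # unit sine -> A²/2, flat across f
    values = np.empty((epochs.n_trials, len(epochs.montage)))
    for sl, W in _iter_cwt_chunks(epochs, freqs, mask):
        power = (np.abs(W) ** 2) * gain[None, None, :, None]
        values[sl] = power.mean(axis=(2, 3))
    columns = [
        FeatureColumn("band_power", name, band, (ch,)) for ch in epochs.montage
    ]
    return FeatureTable(values, columns, epochs.labels, epochs.subject_ids)


def wavelet_coherence(
    epochs: EpochSet,
    band: str,
    window: str | ComponentWindow = "P300",
) -> FeatureTable:
    """Single-trial magnitude-squared wavelet coherence per electrode pair.

    For each unordered pair (x, y) and frequency f,
    ``Coh(f) = |⟨W_x W_y*⟩_t|² / (⟨|W_x|²⟩_t ⟨|W_y|²⟩_t)`` with ⟨·⟩_t the
    mean over window samples; the feature is Coh averaged over the band's
    frequency grid. Values lie in [0, 1]; a degenerate (all-zero) channel
    yields 0 for its pairs, with a logged warning.
    """
    if len(epochs.montage) < 2:
        raise ValueError("coherence needs at least 2 channels")
    fs = epochs.sampling_rate_hz
    freqs = band_frequencies(band, fs)
    name, mask = _resolve_window(window, epochs)
    n_ch = len(epochs.montage)
    iu = np.triu_indices(n_ch, k=1)
    values = np.empty((epochs.n_trials, len(iu[0])))
    degenerate = 0
    for sl, W in _iter_cwt_chunks(epochs, freqs, mask):
        n_t = W.shape[-1]
        auto = (np.abs(W) ** 2).mean(axis=-1)  # (n, ch, f)
        cross = np.einsum("icft,idft->icdf", W, np.conj(W)) / n_t
        denom = auto[:, :, None, :] * auto[:, None, :, :]
        num = np.abs(cross) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            coh = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
        degenerate += int(np.sum(auto == 0))
        band_coh = coh.mean(axis=-1)  # (n, ch, ch)
        values[sl] = band_coh[:, iu[0], iu[1]]
    if degenerate:
        logger.warning(
            "wavelet_coherence: %d degenerate all-zero channel windows; "
            "their pair coherences were set to 0",
            degenerate,
        )
    np.clip(values, 0.0, 1.0, out=values)
    names = epochs.montage.names
    columns = [
        FeatureColumn("coherence", name, band, (names[i], names[j]))
        for i, j in zip(*iu)
    ]
    return FeatureTable(values, columns, epochs.labels, epochs.subject_ids)


def assemble_dataset(
    epochs: EpochSet,
    dataset: str,
    component: str | ComponentWindow = "P300",
    band: str | None = None,
) -> FeatureTable:
    """Build one of the three study datasets.

    dataset1 = component amplitudes (16 columns on the default montage);
    dataset2 = band power for one (component, band) (16 columns);
    dataset3 = pairwise coherence for one (component, band) (120 columns).
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot assemble features from an empty epoch set")
    key = str(dataset).lower().lstrip("dataset")
    if key == "1":
        return component_amplitude(epochs, component)
    if key in ("2", "3"):
        if band is None:
            raise ValueError(f"dataset{key} requires a frequency band")
        fn = wavelet_band_power if key == "2" else wavelet_coherence
        return fn(epochs, band, component)
    raise ValueError(f"unknown dataset {dataset!r}; expected 1, 2 or 3")
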