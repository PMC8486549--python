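"""Preprocessing: filter response, epoch slicing, baselining, rejection, I/O."""

import numpy as np
import pytest

import erpfood as e
from erpfood import io

from conftest import make_epochs

FS = 1024.0


def _sine_recording(f0, seconds=20, fs=FS):
    t = np.arange(int(fs * seconds)) / fs
    x = np.sin(2 * np.pi * f0 * t)
    return e.ContinuousRecording("s", fs, e.Montage(("a", "b")), np.tile(x, (2, 1))), t


def _butter_bp_mag2(f, lo=0.1, hi=40.0, order=4):
    """Closed-form analog Butterworth band-pass |H(f)|² (one pass)."""
    w = 2 * np.pi * f
    w0sq = (2 * np.pi) ** 2 * lo * hi
    bw = 2 * np.pi * (hi - lo)
    return 1.0 / (1.0 + ((w**2 - w0sq) / (w * bw)) ** (2 * order))


class TestBandpass:
    def test_dc_removed(self):
        rec = e.ContinuousRecording("s", FS, e.Montage(("a", "b")), np.full((2, 4096), 10.0))
        out = e.bandpass(rec)
        assert np.abs(out.data).mean() < 0.1

    def test_passband_gain_matches_closed_form(self):
        rec, t = _sine_recording(10.0)
        out = e.bandpass(rec)
        mid = slice(int(FS * 6), int(FS * 14))
        amp = 2 * np.abs(np.mean(out.data[0, mid] * np.exp(-2j * np.pi * 10.0 * t[mid])))
        # forward-backward pass squares the magnitude response
        assert amp == pytest.approx(_butter_bp_mag2(10.0), rel=0.02)

    def test_stopband_attenuation(self):
        rec, t = _sine_recording(60.0)
        out = e.bandpass(rec)
        mid = slice(int(FS * 6), int(FS * 14))
        amp = 2 * np.abs(np.mean(out.data[0, mid] * np.exp(-2j * np.pi * 60.0 * t[mid])))
        assert -20 * np.log10(amp) >= 20.0
        assert amp == pytest.approx(_butter_bp_mag2(60.0), rel=0.1)

    def test_linearity(self, rng):
        m = e.Montage(("a", "b"))
        x = rng.standard_normal((2, 4096))
        y = rng.standard_normal((2, 4096))
        fa = e.bandpass(e.ContinuousRecording("s", FS, m, x)).data
        fb = e.bandpass(e.ContinuousRecording("s", FS, m, y)).data
        fab = e.bandpass(e.ContinuousRecording("s", FS, m, 2.0 * x + 0.5 * y)).data
        assert np.allclose(fab, 2.0 * fa + 0.5 * fb, atol=1e-6)

    def test_invalid_edges(self):
        rec = e.ContinuousRecording("s", FS, e.Montage(("a", "b")), np.zeros((2, 100)))
        with pytest.raises(ValueError):
            e.bandpass(rec, 40.0, 0.1)
        with pytest.raises(ValueError):
            e.bandpass(rec, 0.1, 600.0)


class TestEpoching:
    def test_epoch_length_1024_at_fs1024(self):
        rec = e.ContinuousRecording("s", FS, e.Montage(("a", "b")), np.zeros((2, 4096)))
        ev = e.EventTable([2048], ["food"], ["s"])
        ep = e.extract_epochs(rec, ev)
        assert ep.data.shape == (1, 2, 1024)  # round(204.8)+round(819.2)
        assert ep.time_ms[0] == pytest.approx(-205 / FS * 1000)

    def test_ramp_slice_exact(self):
        n = 4096
        ramp = np.arange(n, dtype=float)
        rec = e.ContinuousRecording("s", FS, e.Montage(("a", "b")), np.tile(ramp, (2, 1)))
        ep = e.extract_epochs(rec, e.EventTable([2000], ["food"], ["s"]))
        assert np.array_equal(ep.data[0, 0], ramp[2000 - 205 : 2000 + 819])

    def test_out_of_bounds_event_identified(self):
        rec = e.ContinuousRecording("s", FS, e.Montage(("a", "b")), np.zeros((2, 4096)))
        with pytest.raises(ValueError, match="event 0"):
            e.extract_epochs(rec, e.EventTable([100], ["food"], ["s"]))


class TestBaseline:
    def test_pre_stimulus_mean_zero(self, rng):
        ep = make_epochs(rng.standard_normal((3, 2, 1024)), corrected=False)
        out = e.baseline_correct(ep)
        pre = out.data[:, :, out.time_ms < 0]
        assert np.all(np.abs(pre.mean(axis=2)) < 1e-9)

    def test_constant_shift_invariance(self, rng):
        x = rng.standard_normal((3, 2, 1024))
        a = e.baseline_correct(make_epochs(x, corrected=False))
        b = e.baseline_correct(make_epochs(x + 7.5, corrected=False))
        assert np.allclose(a.data, b.data)

    def test_double_correction_rejected(self, rng):
        ep = e.baseline_correct(make_epochs(rng.standard_normal((2, 2, 1024)), corrected=False))
        with pytest.raises(ValueError, match="already"):
            e.baseline_correct(ep)


class TestRejection:
    def test_clean_epochs_all_kept(self):
        ep = make_epochs(np.zeros((5, 2, 1024)))
        kept, log = e.reject_artifacts(ep)
        assert kept.n_trials == 5 and log.n_dropped == 0

    def test_spiked_trial_dropped_and_logged(self, rng):
        data = rng.standard_normal((6, 2, 1024))
        data[3, 1, 500] = 150.0
        kept, log = e.reject_artifacts(make_epochs(data), ptp_threshold_uv=100.0)
        assert list(log.dropped_index) == [3]
        assert log.offending_channels[3] == ["ch1"]
        assert log.n_kept + log.n_dropped == 6

    def test_infinite_threshold_is_identity(self, rng):
        ep = make_epochs(200 * rng.standard_normal((4, 2, 1024)))
        kept, log = e.reject_artifacts(ep, ptp_threshold_uv=np.inf)
        assert np.array_equal(kept.data, ep.data) and log.n_dropped == 0

    def test_custom_predicate(self, rng):
        ep = make_epochs(rng.standard_normal((4, 2, 1024)))
        kept, log = e.reject_artifacts(ep, 1e9, predicate=lambda tr: tr[0, 0] > 0)
        assert log.n_kept + log.n_dropped == 4
        assert all(ep.data[i, 0, 0] > 0 for i in log.dropped_index)


class TestRecordingIO:
    def test_raw_sidecar_round_trip(self, tmp_path, small_subject):
        _, recording, _ = small_subject
        io.write_raw_recording(recording, tmp_path / "sub")
        back = io.read_raw_recording(tmp_path / "sub")
        # float32 storage quantization only
        assert np.max(np.abs(back.data - recording.data)) < 1e-3
        assert back.subject_id == recording.subject_id

    def test_tsv_shuffled_columns_reordered(self, tmp_path, rng):
        montage = e.Montage(("a", "b", "c"))
        data = rng.standard_normal((3, 50))
        rec = e.ContinuousRecording("s", FS, montage, data)
        path = io.write_tsv_recording(rec, tmp_path / "r.tsv")
        # rewrite with permuted columns
        import pandas as pd

        df = pd.read_csv(path, sep="\t")[["c", "a", "b"]]
        df.to_csv(path, sep="\t", index=False)
        back = io.read_tsv_recording(path, montage)
        assert np.allclose(back.data, data, atol=1e-5)

    def test_missing_channel_named(self, tmp_path, rng):
        rec = e.ContinuousRecording("s", FS, e.Montage(("a", "b")), rng.standard_normal((2, 10)))
        path = io.write_tsv_recording(rec, tmp_path / "r.tsv")
        with pytest.raises(ValueError, match="T8"):
            io.read_tsv_recording(path, e.Montage(("a", "T8")))

    def test_events_round_trip(self, tmp_path, small_subject):
        _, _, events = small_subject
        io.write_events(events, tmp_path / "ev.tsv")
        back = io.read_events(tmp_path / "ev.tsv")
        assert np.array_equal(back.onset_sample, events.onset_sample)
        assert list(back.label) == list(events.label)

    def test_epochs_round_trip(self, tmp_path, small_epochs):
        io.save_epochs(small_epochs, tmp_path / "ep")
        back = io.load_epochs(tmp_path / "ep")
        assert back.data.shape == small_epochs.data.shape
        assert np.max(np.abs(back.data - small_epochs.data)) < 1e-3
        assert back.baseline_corrected


def test_epoch_baseline_commutes_with_channel_constant(rng):
    """Adding a per-channel constant to the recording is erased by baselining."""
    m = e.Montage(("a", "b"))
    x = rng.standard_normal((2, 4096))
    ev = e.EventTable([2000], ["food"], ["s"])
    base = e.baseline_correct(e.extract_epochs(e.ContinuousRecording("s", FS, m, x), ev))
    shifted = e.baseline_correct(
        e.extract_epochs(e.ContinuousRecording("s", FS, m, x + np.array([[3.0], [-8.0]])), ev)
    )
    assert np.allclose(base.data, shifted.data, atol=1e-9)
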