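"""Simulator: waveform shapes, noise spectrum, event schedule, planted effects."""

import numpy as np
import pytest
from scipy import signal, stats as sps

import erpfood as e
from erpfood.features import band_frequencies

FS = 1024.0
TIME_MS = (np.arange(-205, 819) / FS) * 1000.0


class TestEvokedWaveform:
    def test_p300_peak_equals_amplitude(self):
        w = e.evoked_waveform("P300", 5.0, TIME_MS)
        peak_idx = np.argmin(np.abs(TIME_MS - 300.0))
        assert w[peak_idx] == pytest.approx(5.0, abs=0.01)
        assert np.max(w) == pytest.approx(5.0, abs=0.01)

    def test_p300_zero_at_baseline(self):
        w = e.evoked_waveform("P300", 5.0, TIME_MS)
        assert np.all(np.abs(w[TIME_MS < 0]) < 0.05)

    def test_lpp_plateau_value(self):
        w = e.evoked_waveform("LPP", 3.0, TIME_MS)
        idx = np.argmin(np.abs(TIME_MS - 625.0))
        assert w[idx] == pytest.approx(3.0)
        assert np.all(np.abs(w[TIME_MS < 0]) < 0.03)

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="unknown component"):
            e.evoked_waveform("N170", 1.0, TIME_MS)
        with pytest.raises(ValueError, match="finite"):
            e.evoked_waveform("P300", np.inf, TIME_MS)


class TestPinkNoise:
    @pytest.mark.parametrize("exponent", [0.0, 1.0])
    def test_spectral_slope(self, exponent):
        x = e.pink_noise(2**16, exponent, rms=10.0, rng=0)
        f, P = signal.periodogram(x, fs=FS)
        m = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log(f[m]), np.log(P[m]), 1)[0]
        assert slope == pytest.approx(-exponent, abs=0.2)

    def test_rms_and_mean(self):
        x = e.pink_noise(4096, 1.0, rms=7.5, rng=3)
        assert np.abs(x.mean()) < 1e-9
        assert np.sqrt(np.mean(x**2)) == pytest.approx(7.5, rel=0.05)

    def test_deterministic_for_fixed_seed(self):
        assert np.array_equal(e.pink_noise(512, 1.0, 10.0, 5), e.pink_noise(512, 1.0, 10.0, 5))

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            e.pink_noise(0)


class TestEventSchedule:
    def test_default_counts_per_subject(self, small_subject):
        cfg = e.SimulationConfig(seed=1)
        assert cfg.trials_per_subject == 505
        _, _, events = small_subject
        assert len(events) == 16  # 1 block × (10 + 6)

    def test_full_scale_label_counts(self):
        cfg = e.SimulationConfig(seed=1, blocks=5, food_per_block=73, nonfood_per_block=28)
        # label bookkeeping only needs one subject
        cfg2 = e.SimulationConfig(
            seed=1, n_subjects=1, blocks=5, food_per_block=73, nonfood_per_block=28
        )
        _, events = e.simulate_subject(cfg2, 0)
        assert len(events) == 505
        assert int(np.sum(events.label == "food")) == 365
        assert int(np.sum(events.label == "nonfood")) == 140

    def test_deterministic_recording(self):
        cfg = e.SimulationConfig(n_subjects=1, blocks=1, food_per_block=4, nonfood_per_block=2, seed=9)
        r1, e1 = e.simulate_subject(cfg, 0)
        r2, e2 = e.simulate_subject(cfg, 0)
        assert np.array_equal(r1.data, r2.data)
        assert np.array_equal(e1.onset_sample, e2.onset_sample)
        assert np.array_equal(e1.label, e2.label)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_subjects"):
            e.SimulationConfig(n_subjects=0)
        with pytest.raises(ValueError, match="soa_ms"):
            e.SimulationConfig(soa_ms=500)
        bad = {k: v for k, v in e.DEFAULT_EFFECT_TABLE.items() if k != "T8"}
        with pytest.raises(ValueError, match="T8"):
            e.SimulationConfig(effect_table=bad)


class TestCoherentSource:
    def test_zero_gain_is_identity(self, small_subject):
        _, recording, events = small_subject
        spec = e.CoherenceSpec(("Fp1", "Fp2"), "theta", (250.0, 450.0), {"food": 0.0, "nonfood": 0.0})
        out = e.inject_coherent_source(recording, spec, events, rng=0)
        assert np.array_equal(out.data, recording.data)

    def test_only_pair_channels_touched(self, small_subject):
        _, recording, events = small_subject
        spec = e.CoherenceSpec(("O1", "T8"), "alpha", (250.0, 450.0), {"food": 5.0, "nonfood": 5.0})
        out = e.inject_coherent_source(recording, spec, events, rng=0)
        touched = {recording.montage.index("O1"), recording.montage.index("T8")}
        for i in range(len(recording.montage)):
            same = np.array_equal(out.data[i], recording.data[i])
            assert same == (i not in touched)

    def test_unknown_channel_rejected(self, small_subject):
        _, recording, events = small_subject
        spec = e.CoherenceSpec(("Fp1", "XX"), "theta", (250.0, 450.0), {"food": 1.0, "nonfood": 1.0})
        with pytest.raises(KeyError, match="XX"):
            e.inject_coherent_source(recording, spec, events)

    def test_injected_pair_gains_coherence(self):
        """Theta source on Fp1–Fp2 lifts that pair above untouched pairs,
        and a larger food gain yields larger food-trial coherence."""
        cfg = e.SimulationConfig(
            n_subjects=1, blocks=2, food_per_block=30, nonfood_per_block=30, seed=17,
            coherence_specs=[
                e.CoherenceSpec(("Fp1", "Fp2"), "theta", (250.0, 450.0), {"food": 5.0, "nonfood": 2.0})
            ],
        )
        recording, events = e.simulate_subject(cfg, 0)
        epochs, _ = e.preprocess_recording(recording, events, ptp_threshold_uv=None)
        coh = e.wavelet_coherence(epochs, "theta", "P300")
        pairs = [c.channels for c in coh.columns]
        inj = coh.values[:, pairs.index(("Fp1", "Fp2"))]
        clean = [i for i, p in enumerate(pairs) if "Fp1" not in p and "Fp2" not in p]
        assert inj.mean() > coh.values[:, clean].mean()
        food = epochs.labels == "food"
        assert inj[food].mean() > inj[~food].mean()


class TestPlantedRecovery:
    def test_oz_condition_means_recovered(self):
        """With subject variability off, the pipeline's Oz window-mean
        amplitudes converge to the configured class means (3 SE, >=1000
        food trials)."""
        cfg = e.SimulationConfig(n_subjects=1, blocks=14, subject_sd_scale=0.0, seed=21)
        recording, events = e.simulate_subject(cfg, 0)
        epochs, _ = e.preprocess_recording(recording, events, ptp_threshold_uv=None)
        amp = e.component_amplitude(epochs, "P300")
        oz = [c.channels for c in amp.columns].index(("Oz",))
        food = epochs.labels == "food"
        assert food.sum() >= 1000
        for mask, target in [(food, 5.218), (~food, 4.275)]:
            vals = amp.values[mask, oz]
            assert abs(vals.mean() - target) < 3 * sps.sem(vals)

    def test_null_config_classes_exchangeable(self):
        """All effects zeroed -> food/nonfood paired-t p-values uniform
        (KS test over replicates at the generator's subject-level marginal)."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(200):
            food, nonfood = e.subject_condition_means(
                0.0, 0.0, n_subjects=12, subject_sd=1.0,
                condition_offset_sd=0.5, trial_sem=0.3, rng=rng,
            )
            d = food - nonfood
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            pvals.append(2 * sps.t.sf(abs(t), len(d) - 1))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_subject_ids_and_study_iteration():
    cfg = e.SimulationConfig(n_subjects=3, blocks=1, food_per_block=2, nonfood_per_block=1, seed=4)
    assert cfg.subject_ids() == ["S01", "S02", "S03"]
    out = list(e.simulate_study(cfg))
    assert len(out) == 3
    # subjects are independently seeded and differ
    assert not np.array_equal(out[0][0].data[:, :100], out[1][0].data[:, :100])
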