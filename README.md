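# erpfood

Single-trial ERP discrimination of food versus nonfood visual stimuli:
a tested, reusable pipeline covering synthetic evoked-EEG generation,
preprocessing, three single-trial feature families, across-subject
statistics, and a seven-classifier cross-validation benchmark.

## The problem

Event-related potentials (ERPs) to food images differ from those to
neutral images, most prominently in the **P300** (a positive deflection
~300 ms post-stimulus, linked to attentional evaluation) and the **late
positive potential** (**LPP**, a sustained positivity ~550–700 ms,
linked to focused attention). The question this pipeline addresses is
whether those differences are usable at the *single-trial* level — can a
classifier tell from one sweep of 16-channel EEG whether the subject was
viewing food?

From a baseline-corrected epoch set (−200..800 ms around each stimulus,
0.1–40 Hz zero-phase Butterworth band-pass, peak-to-peak artifact
rejection) three feature datasets are built per ERP component:

1. **amplitudes** — mean voltage per electrode over the component window
   (16 features);
2. **wavelet band power** — mean |W|² of a complex Morlet CWT (ω₀ = 6)
   over a frequency band (δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–40 Hz)
   × component window, per electrode (16 features per band);
3. **wavelet coherence** — for every unordered electrode pair (x, y),

   Coh(f) = |⟨W_x W_y*⟩_t|² / (⟨|W_x|²⟩_t ⟨|W_y|²⟩_t),

   time-averaged over the component window and frequency-averaged over
   the band (120 features per band for 16 channels).

Per-feature food/nonfood differences are tested with across-subject
paired t-tests (df = n−1, uncorrected by default, Bonferroni/BH
opt-in). Each feature row is z-scored across its own columns before
classification; kNN, logistic regression, decision tree, LDA, Gaussian
naive Bayes, RBF SVM and an MLP are then benchmarked with stratified
10-fold cross-validation, pooled across subjects and per subject.

Because single-trial EEG corpora of this kind are rarely shareable, the
package ships a first-class **simulator**: 1/f background noise plus
class-conditional P300/LPP amplitudes per channel (with between-subject
and trial-level variability) and band-limited common sources planted
into chosen electrode pairs to create class-dependent coherence. Every
downstream stage is validated against what the generator planted.

## Worked example

```python
import erpfood as e

cfg = e.SimulationConfig(n_subjects=4, blocks=1, seed=1)
epochs_list = []
for i in range(cfg.n_subjects):
    recording, events = e.simulate_subject(cfg, i)
    ep, log = e.preprocess_recording(recording, events)
    epochs_list.append(ep)

import numpy as np
epochs = e.EpochSet(
    np.concatenate([p.data for p in epochs_list]),
    epochs_list[0].time_ms,
    np.concatenate([p.labels for p in epochs_list]),
    np.concatenate([p.subject_ids for p in epochs_list]),
    epochs_list[0].montage, epochs_list[0].sampling_rate_hz,
    baseline_corrected=True,
)

table = e.normalize_rows(e.assemble_dataset(epochs, "1", "P300"))
rep = e.run_pooled_cv(table, "LDA", k=10, seed=0)
print(f"LDA accuracy {100*rep.mean_accuracy:.1f}% "
      f"(baseline {100*rep.baseline_accuracy:.1f}%)")
```

prints (for this seed)

```
LDA accuracy 71.8% (baseline 72.3%)
```

i.e. 404 trials at the 73:28 food:nonfood stimulus ratio give a majority
baseline of 72.3 %, and with the default planted effect sizes (sub-µV
class differences against 5 µV trial jitter) LDA sits essentially at
that baseline — single-trial discriminability is driven by the ratio of
planted class differences to trial-level noise, which is a simulator
knob, not a constant of nature. The monotonicity tests show accuracy
rising steadily as the planted amplitude effect grows.

The same pipeline runs from the shell:

```bash
erpfood run --config config.json --out out/ --seed 1
```

writing per-subject recordings and events, the epoch container,
feature TSVs, the paired-test table, classifier results and a
`manifest.json` that reproduces the run bit-identically.

## Layout

- `src/erpfood/simulate.py` — synthetic study generator
- `src/erpfood/preprocess.py`, `io.py` — filtering, epoching, rejection, formats
- `src/erpfood/features.py` — amplitudes, Morlet band power, coherence
- `src/erpfood/stats.py` — subject summaries, paired-t battery
- `src/erpfood/classify.py` — row normalization, CV benchmark
- `src/erpfood/pipeline.py`, `cli.py` — orchestration and the `erpfood` CLI
- `docs/methods.md` — models, parameter choices, limitations
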