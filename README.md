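# sqsleep

Automatic sleep staging for two-channel subcutaneous EEG.

Ultralong-term EEG from electrodes implanted under the skin behind the
ear makes it possible to follow a patient's sleep for weeks or months —
far beyond what polysomnography can offer — but someone has to turn the
raw signal into hypnograms. `sqsleep` implements a complete automatic
staging pipeline for such recordings, aimed at researchers working on
wearable/implantable EEG sleep monitoring:

1. **Preprocessing** — zero-phase 0.5–100 Hz band-pass with a 50 Hz
   notch, polyphase downsampling to the device rate (207 Hz),
   amplitude-based artifact masking (|x| > 300 µV, masked rather than
   deleted), and per-epoch cross-correlation synchronization against a
   reference recording.
2. **Features** — for each 30-s epoch and channel, 30 descriptors of
   the time-course of spectral power from a continuous wavelet
   transform with the analytic generalized Morse wavelet
   (symmetry γ = 3, time–bandwidth P² = 60): per classical band
   (δ 0.5–4, θ 4–8, α 8–13, lower β 13–22, upper β 22–32 Hz) the mean,
   variance, skewness and kurtosis of the power samples, their Shannon
   entropy, and the *activation duration* — seconds the band's power
   exceeds 1.5× the epoch's median broadband (0.5–100 Hz) power. Each
   epoch's vector is concatenated with its predecessor's and two
   successors' (240 columns for two channels).
3. **Classification** — a bagged forest of 100 CART trees (Gini
   splits, random feature subsets, nodes of fewer than ten
   observations left unsplit), with night-grouped cross-validation:
   patient-specific (PS) leave-one-night-out, or pooled
   leave-one-night-out (LONO). Epochs from one night are never split
   across folds.
4. **Sleep measures** — TST, TATS, SE = TST/TATS × 100, SL, RL and
   WASO = TATS − SL − TST from any hypnogram, plus two-class
   wake/sleep traces.
5. **Agreement statistics** — per-night Cohen's κ, pooled confusion
   matrices (row percentages = class sensitivities; for wake/sleep the
   diagonal reads specificity, sensitivity), Deming regression,
   Pearson r, and Bland–Altman bias with 1.96·SD limits and an exact
   paired sign-flip permutation test.

Because clinical subcutaneous recordings cannot be redistributed, the
package ships a first-class synthetic generator (`sqsleep.synth`) that
emulates the study design it targets — four patients with (3, 2, 3, 3)
nights at 207 Hz — with stage-dependent spectra, spindle- and
slow-wave-like transients, per-subject gains and injected artifacts,
so the entire pipeline is testable end to end.

## Worked example

```python
import numpy as np
import sqsleep as sq
from sqsleep.config import PipelineConfig
from sqsleep.pipeline import night_features, preprocess_recording

cfg = PipelineConfig()
synth = sq.SynthConfig(n_patients=2, nights_per_patient=(2, 2),
                       epochs_per_night=120, seed=1)
study = sq.make_study(synth)

feats, labels = {}, {}
for (patient, night), (rec, hyp) in study.items():
    key = f"{patient}{night}"
    feats[key] = night_features(preprocess_recording(rec, cfg), cfg)
    labels[key] = hyp

folds = sq.make_folds(sorted(feats), {k: k[0] for k in feats}, "PS")
preds = sq.cross_validate(feats, labels, folds, sq.ForestParams(seed=1))
report = sq.evaluate_study(labels, preds)
```

Running this (it is `examples/03_stage_a_study.py`) prints

```
night A1: 5-class kappa = 0.930
night A2: 5-class kappa = 0.929
night B1: 5-class kappa = 0.944
night B2: 5-class kappa = 0.935
mean 5-class kappa = 0.934
sleep detection: sensitivity 99.1%, specificity 98.5%
```

Each κ is the chance-corrected agreement between the predicted and
true hypnogram of one held-out night (1 = perfect, 0 = chance); the
near-ceiling values reflect the strong stage-specific spectra of the
generator's defaults. Sensitivity and specificity describe wake-vs-
sleep detection after merging the four sleep stages, with sleep as the
positive class. The other scripts in `examples/` each demonstrate one
capability (simulation, band-power features, sleep measures,
agreement statistics).

There is also a thin CLI mirroring the library:

```bash
sqsleep simulate --out study/          # synthetic EDF + hypnogram CSVs
sqsleep features study/A1.edf --out A1.features.csv
sqsleep crossval --features-dir study/ --scheme ps --out preds/
sqsleep measures study/A1.hypnogram.csv --tats 480
sqsleep evaluate --truth study/ --pred preds/
sqsleep run --out results/             # the whole pipeline + manifest
```

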