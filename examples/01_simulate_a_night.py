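"""Simulate one synthetic night and write it to disk.

Generates a Markov-chain hypnogram and a matching two-channel 207 Hz
recording with stage-dependent spectra, then writes standard EDF and
hypnogram CSV files.
"""

from collections import Counter

import numpy as np

import sqsleep as sq

cfg = sq.SynthConfig(epochs_per_night=240, seed=42)  # a 2-hour night
hyp = sq.simulate_hypnogram(cfg)
rec = sq.simulate_recording(hyp, cfg)

sq.write_edf(rec, "night.edf")
sq.write_hypnogram(hyp, "night.hypnogram.csv")

print(f"night: {len(hyp)} epochs of {hyp.epoch_len:.0f} s "
      f"({hyp.duration_min:.0f} min), {rec.n_channels} channels at {rec.fs:.0f} Hz")
print("stage counts:", dict(Counter(hyp.stages)))
print(f"signal RMS: {np.sqrt(np.mean(rec.signal**2)):.1f} µV, "
      f"peak |amplitude|: {np.max(np.abs(rec.signal)):.0f} µV")
# Stage counts reflect the chain's self-transition bias (long bouts);
# peaks above 300 µV are injected artifacts the pipeline will mask.
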