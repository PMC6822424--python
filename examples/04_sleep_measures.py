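"""AASM/CTA sleep measures from a hypnogram.

A night of 20 wake epochs followed by 940 N2 epochs, assessed against
480 min time-attempting-to-sleep (TATS): sleep latency 10 min, total
sleep time 470 min, sleep efficiency 97.9%, no wake after sleep onset,
and REM latency undefined (no REM occurred).
"""

import sqsleep as sq

hyp = sq.Hypnogram(stages=["W"] * 20 + ["N2"] * 940)
m = sq.compute_measures(hyp, tats_min=480.0)

for name, value in m.as_dict().items():
    unit = "%" if name == "SE" else "min"
    print(f"{name:>5}: {value:7.1f} {unit}")

trace = sq.to_sleep_wake(hyp)
print("two-class trace preserves TST:",
      sq.compute_measures(trace, tats_min=480.0).TST == m.TST)
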