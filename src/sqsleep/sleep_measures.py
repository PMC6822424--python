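"""AASM/CTA sleep measures from a hypnogram.

All durations are in minutes on the half-minute grid implied by 30-s
epochs. TATS (time attempting to sleep) follows the wearable-monitor
convention: the device mount-to-dismount interval, defaulting to the
hypnogram's own duration when no explicit value is given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import Hypnogram, SleepWakeTrace

_WAKE_TOKENS = {"W", "wake"}
_REM_TOKENS = {"R"}

MEASURE_NAMES = ("TST", "TATS", "SE", "SL", "RL", "WASO")


@dataclass(frozen=True)
class SleepMeasures:
    """One night's summary measures (minutes; SE in percent).

    Missing quantities (REM latency on a REM-free night, sleep latency
    on an all-wake night) are NaN. When SL is defined,
    TST + SL + WASO == TATS holds exactly by construction.
    """

    TST: float
    TATS: float
    SE: float
    SL: float
    RL: float
    WASO: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in MEASURE_NAMES}


def compute_measures(
    h: Hypnogram | SleepWakeTrace, tats_min: float | None = None
) -> SleepMeasures:
    """Compute TST, TATS, SE, SL, RL and WASO for one night.

    TST sums time in any sleep stage; SL runs to the first sleep epoch
    of any stage, RL to the first REM epoch; SE = TST/TATS x 100;
    WASO = TATS - SL - TST. An explicit ``tats_min`` (or the
    hypnogram's own ``tats_min`` metadata) takes precedence over the
    recording duration.
    """
    stages = h.stages if isinstance(h, Hypnogram) else h.states
    ep_min = h.epoch_len / 60.0
    duration = len(stages) * ep_min
    if tats_min is None and isinstance(h, Hypnogram):
        tats_min = h.tats_min
    tats = duration if tats_min is None else float(tats_min)

    asleep = np.array([s not in _WAKE_TOKENS for s in stages], dtype=bool)
    tst = float(asleep.sum()) * ep_min
    se = 100.0 * tst / tats if tats > 0 else 0.0
    if not asleep.any():
        return SleepMeasures(
            TST=0.0, TATS=tats, SE=0.0,
            SL=math.nan, RL=math.nan, WASO=math.nan,
        )
    sl = float(np.flatnonzero(asleep)[0]) * ep_min
    rem = [i for i, s in enumerate(stages) if s in _REM_TOKENS]
    rl = rem[0] * ep_min if rem else math.nan
    waso = tats - sl - tst
    return SleepMeasures(TST=tst, TATS=tats, SE=se, SL=sl, RL=rl, WASO=waso)


def to_sleep_wake(h: Hypnogram) -> SleepWakeTrace:
    """Collapse the five stages into a wake/sleep trace (no retraining)."""
    states = ["wake" if s in _WAKE_TOKENS else "sleep" for s in h.stages]
    return SleepWakeTrace(states=states, epoch_len=h.epoch_len)
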