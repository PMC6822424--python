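"""Synthetic two-channel sleep EEG with stage-dependent spectra.

The generator emulates the statistical structure the staging pipeline
relies on, without claiming physiological realism: a first-order Markov
hypnogram over W/N1/N2/N3/R, per-stage band-weighted Gaussian noise on
a 1/f background, stage-appropriate transients (sleep-spindle-like
11-15 Hz bursts in N2, high-amplitude slow waves in N3), two channels
sharing a common source plus independent noise, a per-subject gain
drawn once per patient, and optional high-amplitude artifact bursts.

The default study mirrors the target study design: four patients with
(3, 2, 3, 3) nights, eleven nights in total, recorded at 207 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import scipy.fft as sfft

from .features import DEFAULT_BANDS
from .io import STAGES, Hypnogram, Recording

_BAND_EDGES = {b.name: (b.f_lo, b.f_hi) for b in DEFAULT_BANDS}
_BAND_NAMES = tuple(_BAND_EDGES)


@dataclass(frozen=True)
class StageSpectrum:
    """Relative band-power weights and amplitude for one stage."""

    weights: dict[str, float]  # per band, >= 0, not all zero
    amp_rms_uv: float  # target RMS amplitude, µV
    transient_rate_per_min: float = 0.0
    transient_band: tuple[float, float] = (11.0, 15.0)
    transient_dur_s: tuple[float, float] = (0.5, 1.0)

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(_BAND_NAMES)
        if unknown:
            raise ValueError(f"unknown bands in weights: {sorted(unknown)}")
        w = np.array([self.weights.get(b, 0.0) for b in _BAND_NAMES])
        if (w < 0).any() or not w.any():
            raise ValueError("weights must be >= 0 and not all zero")


def default_stage_spectra() -> dict[str, StageSpectrum]:
    """Stage phenomenology in broad strokes.

    Wake: low-amplitude alpha/beta; N1: low-voltage theta; N2: theta
    and delta with spindle bursts; N3: high-amplitude delta with slow
    waves; REM: low-amplitude mixed-frequency activity with a fast
    component.
    """
    return {
        "W": StageSpectrum(
            weights={"delta": 0.05, "theta": 0.10, "alpha": 0.45,
                     "lower_beta": 0.25, "upper_beta": 0.15},
            amp_rms_uv=10.0,
        ),
        "N1": StageSpectrum(
            weights={"delta": 0.10, "theta": 0.55, "alpha": 0.25,
                     "lower_beta": 0.07, "upper_beta": 0.03},
            amp_rms_uv=15.0,
        ),
        "N2": StageSpectrum(
            weights={"delta": 0.35, "theta": 0.35, "alpha": 0.10,
                     "lower_beta": 0.15, "upper_beta": 0.05},
            amp_rms_uv=20.0,
            transient_rate_per_min=3.0,
            transient_band=(11.0, 15.0),
            transient_dur_s=(0.5, 1.0),
        ),
        "N3": StageSpectrum(
            weights={"delta": 0.75, "theta": 0.15, "alpha": 0.05,
                     "lower_beta": 0.03, "upper_beta": 0.02},
            amp_rms_uv=40.0,
            transient_rate_per_min=6.0,
            transient_band=(0.5, 1.5),
            transient_dur_s=(0.8, 1.5),
        ),
        "R": StageSpectrum(
            weights={"delta": 0.05, "theta": 0.30, "alpha": 0.10,
                     "lower_beta": 0.35, "upper_beta": 0.20},
            amp_rms_uv=10.0,
        ),
    }


def default_transition_matrix() -> np.ndarray:
    """Self-transition-dominated stage dynamics (rows: W,N1,N2,N3,R)."""
    return np.array(
        [
            # W     N1    N2    N3    R
            [0.85, 0.12, 0.02, 0.00, 0.01],  # W
            [0.03, 0.85, 0.10, 0.01, 0.01],  # N1
            [0.02, 0.02, 0.85, 0.08, 0.03],  # N2
            [0.01, 0.01, 0.12, 0.85, 0.01],  # N3
            [0.04, 0.05, 0.06, 0.00, 0.85],  # R
        ]
    )


@dataclass
class SynthConfig:
    """Study design and signal parameters for the generator."""

    n_patients: int = 4
    nights_per_patient: tuple[int, ...] = (3, 2, 3, 3)
    epochs_per_night: int = 720
    fs: float = 207.0
    epoch_len: float = 30.0
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    stage_spectra: dict[str, StageSpectrum] = field(default_factory=default_stage_spectra)
    subject_gain_sd: float = 0.2  # lognormal sigma of the per-patient gain
    interchannel_corr: float = 0.7  # shared-source fraction of variance
    background_1f: float = 0.3  # 1/f floor weight relative to band weights
    epoch_amp_jitter_sd: float = 0.15  # lognormal sigma, per-epoch amplitude
    band_jitter_sd: float = 0.25  # lognormal sigma on each band weight, per epoch
    transition_blend: float = 0.3  # previous-stage spectrum fraction after a switch
    artifact_rate_per_hour: float = 2.0
    artifact_amp_uv: tuple[float, float] = (320.0, 500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5 over (W,N1,N2,N3,R)")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if (self.transition_matrix < 0).any():
            raise ValueError("transition probabilities must be >= 0")
        if self.epochs_per_night < 1:
            raise ValueError("epochs_per_night must be >= 1")
        if len(self.nights_per_patient) != self.n_patients:
            raise ValueError("nights_per_patient length must equal n_patients")


def simulate_hypnogram(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> Hypnogram:
    """First-order Markov stage sequence starting in wake."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    P = cfg.transition_matrix
    state = 0  # W
    stages = []
    for _ in range(cfg.epochs_per_night):
        stages.append(STAGES[state])
        state = int(rng.choice(5, p=P[state]))
    return Hypnogram(stages=stages, epoch_len=cfg.epoch_len)


def _shaped_noise(
    n: int, fs: float, weights: dict[str, float], one_f: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-RMS Gaussian noise with band-weighted + 1/f spectrum."""
    white = rng.standard_normal(n)
    X = sfft.rfft(white)
    f = sfft.rfftfreq(n, 1.0 / fs)
    amp2 = np.zeros_like(f)
    for name, (lo, hi) in _BAND_EDGES.items():
        amp2[(f >= lo) & (f < hi)] += weights.get(name, 0.0)
    amp2 += one_f / np.maximum(f, 0.5)
    amp = np.sqrt(amp2)
    amp[0] = 0.0
    x = sfft.irfft(X * amp, n)
    rms = float(np.sqrt(np.mean(x**2)))
    return x / rms if rms > 0 else x


def _transients(
    n: int, fs: float, spec: StageSpectrum, amp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Windowed oscillatory bursts (spindles, slow waves) for one run."""
    out = np.zeros(n)
    minutes = n / fs / 60.0
    count = rng.poisson(spec.transient_rate_per_min * minutes)
    for _ in range(count):
        dur = rng.uniform(*spec.transient_dur_s)
        m = max(int(round(dur * fs)), 8)
        t0 = int(rng.integers(0, max(n - m, 1)))
        f0 = rng.uniform(*spec.transient_band)
        t = np.arange(m) / fs
        burst = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        burst *= np.hanning(m) * 2.0 * amp
        out[t0 : t0 + m] += burst
    return out


def simulate_recording(
    h: Hypnogram,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    gain: float = 1.0,
    start_time: datetime | None = None,
) -> Recording:
    """Two-channel 207 Hz recording realizing a hypnogram's stages.

    Epochs are synthesized individually with realistic variability:
    the band weights and amplitude of each epoch are jittered
    (lognormally) around the stage's nominal spectrum, and the first
    epoch after a stage switch blends in a fraction of the previous
    stage's spectrum, mimicking scoring windows that straddle
    physiological transitions. Channels share a common source
    (fraction ``interchannel_corr`` of variance) plus independent
    noise. Artifact bursts exceeding the 300 µV rejection threshold
    are injected at ``artifact_rate_per_hour``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    es = int(round(cfg.epoch_len * cfg.fs))
    n = len(h) * es
    sig = np.zeros((2, n))
    rho = cfg.interchannel_corr
    prev_stage: str | None = None
    for k, stage in enumerate(h.stages):
        spec = cfg.stage_spectra[stage]
        weights = {b: spec.weights.get(b, 0.0) for b in _BAND_NAMES}
        amp = spec.amp_rms_uv
        if (
            prev_stage is not None
            and prev_stage != stage
            and cfg.transition_blend > 0
        ):
            prev = cfg.stage_spectra[prev_stage]
            b = cfg.transition_blend
            weights = {
                name: (1 - b) * w + b * prev.weights.get(name, 0.0)
                for name, w in weights.items()
            }
            amp = (1 - b) * amp + b * prev.amp_rms_uv
        if cfg.band_jitter_sd > 0:
            weights = {
                name: w * float(np.exp(rng.normal(0.0, cfg.band_jitter_sd)))
                for name, w in weights.items()
            }
        if cfg.epoch_amp_jitter_sd > 0:
            amp *= float(np.exp(rng.normal(0.0, cfg.epoch_amp_jitter_sd)))
        amp *= gain
        lo = k * es
        shared = _shaped_noise(es, cfg.fs, weights, cfg.background_1f, rng)
        for ch in range(2):
            ind = _shaped_noise(es, cfg.fs, weights, cfg.background_1f, rng)
            x = np.sqrt(rho) * shared + np.sqrt(1 - rho) * ind
            sig[ch, lo : lo + es] = amp * x
        if spec.transient_rate_per_min > 0:
            burst = _transients(es, cfg.fs, spec, amp, rng)
            sig[0, lo : lo + es] += burst
            sig[1, lo : lo + es] += burst
        prev_stage = stage
    if cfg.artifact_rate_per_hour > 0:
        hours = n / cfg.fs / 3600.0
        for _ in range(rng.poisson(cfg.artifact_rate_per_hour * hours)):
            m = int(round(0.2 * cfg.fs))
            t0 = int(rng.integers(0, max(n - m, 1)))
            ch = int(rng.integers(0, 2))
            a = rng.uniform(*cfg.artifact_amp_uv) * rng.choice([-1.0, 1.0])
            sig[ch, t0 : t0 + m] += a * np.hanning(m) * 1.2
    return Recording(
        signal=sig,
        fs=cfg.fs,
        channel_names=("P-C", "D-C"),
        start_time=start_time,
    )


def make_study(
    cfg: SynthConfig | None = None,
) -> dict[tuple[str, int], tuple[Recording, Hypnogram]]:
    """Simulate a whole multi-patient study.

    Returns (recording, hypnogram) pairs keyed by (patient, night).
    Each patient's multiplicative gain is drawn once and shared across
    that patient's nights; each night gets an independent child stream
    of the master seed.
    """
    if cfg is None:
        cfg = SynthConfig()
    master = np.random.SeedSequence(cfg.seed)
    gain_rng = np.random.default_rng(master.spawn(1)[0])
    study: dict[tuple[str, int], tuple[Recording, Hypnogram]] = {}
    t0 = datetime(2022, 3, 1, 23, 0, 0)
    for p in range(cfg.n_patients):
        patient = chr(ord("A") + p)
        gain = float(np.exp(gain_rng.normal(0.0, cfg.subject_gain_sd)))
        for night in range(cfg.nights_per_patient[p]):
            child = np.random.default_rng(master.spawn(1)[0])
            h = simulate_hypnogram(cfg, rng=child)
            start = t0 + timedelta(days=night, hours=24 * p)
            rec = simulate_recording(h, cfg, rng=child, gain=gain, start_time=start)
            study[(patient, night + 1)] = (rec, h)
    return study
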