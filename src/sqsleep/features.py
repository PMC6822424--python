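"""Wavelet band-power features for 30-s sleep epochs.

Each epoch of each channel is summarized by 30 descriptors of the
time-course of spectral power in the five classical EEG bands (delta
0.5-4, theta 4-8, alpha 8-13, lower beta 13-22, upper beta 22-32 Hz):
per band, the mean, variance, skewness and kurtosis of the within-epoch
power samples, their Shannon entropy, and the duration of "activation"
— time the band's power exceeds 1.5x the median broadband (0.5-100 Hz)
power of the same epoch. Power comes from a continuous wavelet
transform with the analytic generalized Morse wavelet of symmetry 3 and
time-bandwidth product 60. Finally each epoch's feature vector is
concatenated with its predecessor's and its two successors' (context
stacking), quadrupling the column count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.fft as sfft

from .io import Recording

logger = logging.getLogger(__name__)

#: Morse wavelet parameters: symmetry gamma=3, time-bandwidth P^2=60,
#: hence beta = P^2 / gamma = 20.
MORSE_GAMMA = 3.0
MORSE_BETA = 20.0

_METRICS = ("meanpower", "varpower", "skewness", "kurtosis", "entropy", "activation")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, half-open interval [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band {self.name}: [{self.f_lo}, {self.f_hi})")


DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("lower_beta", 13.0, 22.0),
    BandDefinition("upper_beta", 22.0, 32.0),
)

BROADBAND = BandDefinition("broadband", 0.5, 100.0)


@dataclass
class TimeFrequencyPower:
    """Squared CWT magnitude on a (frequency, time) grid, in µV²."""

    power: np.ndarray  # (n_freqs, n_samples), >= 0
    freqs: np.ndarray  # Hz, strictly increasing
    fs: float


@dataclass
class FeatureMatrix:
    """Epochs x named features with per-epoch validity."""

    values: np.ndarray  # (n_epochs, n_features)
    feature_names: list[str]
    epoch_valid: np.ndarray  # (n_epochs,) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.epoch_valid = np.asarray(self.epoch_valid, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (epochs x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if self.values.shape[0] != len(self.epoch_valid):
            raise ValueError("epoch_valid length must match row count")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "epoch_valid", self.epoch_valid.astype(int))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        valid = df.pop("epoch_valid").to_numpy().astype(bool)
        return cls(df.to_numpy(), list(df.columns), valid)


def cwt_frequencies(
    f_lo: float = 0.5, f_hi: float = 100.0, voices_per_octave: int = 12
) -> np.ndarray:
    """Logarithmic frequency grid spanning [f_lo, f_hi] in Hz."""
    n = int(np.ceil(voices_per_octave * np.log2(f_hi / f_lo))) + 1
    return np.geomspace(f_lo, f_hi, n)


_FILTER_CACHE: dict[tuple, np.ndarray] = {}


def _morse_filters(freqs: np.ndarray, fs: float, nfft: int) -> np.ndarray:
    """Frequency responses of scaled analytic Morse wavelets.

    Normalized so a unit-amplitude sinusoid at a grid frequency has
    |W| = 1 there (peak value 2 on the analytic half-axis). Cached per
    (grid, rate, FFT length) because chunked night processing reuses
    the same bank many times.
    """
    key = (nfft, float(fs), len(freqs), float(freqs[0]), float(freqs[-1]))
    hit = _FILTER_CACHE.get(key)
    if hit is not None:
        return hit
    gamma, beta = MORSE_GAMMA, MORSE_BETA
    w_peak = (beta / gamma) ** (1.0 / gamma)
    w = 2.0 * np.pi * sfft.fftfreq(nfft)  # rad/sample
    pos = w > 0
    filt = np.zeros((len(freqs), nfft))
    wp = w[pos]
    log_wp = np.log(wp)
    for i, fc in enumerate(freqs):
        scale = w_peak * fs / (2.0 * np.pi * fc)
        a = scale * wp
        log_psi = (
            np.log(2.0)
            + beta * (np.log(scale) + log_wp - np.log(w_peak))
            - a**gamma
            + w_peak**gamma
        )
        filt[i, pos] = np.exp(np.maximum(log_psi, -745.0))
    if len(_FILTER_CACHE) > 32:
        _FILTER_CACHE.clear()
    _FILTER_CACHE[key] = filt
    return filt


def cwt_power(
    x: np.ndarray,
    fs: float,
    mask: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    pad_s: float = 5.0,
) -> TimeFrequencyPower:
    """Morse-wavelet scalogram of a single channel.

    The signal is reflection-padded by ``pad_s`` seconds on each side
    before the transform and cropped after, suppressing cone-of-
    influence edge artifacts. Masked samples are zeroed beforehand, so
    their values can never leak into any coefficient.
    """
    x = np.asarray(x, dtype=float)
    if freqs is None:
        freqs = cwt_frequencies(f_hi=min(100.0, 0.999 * fs / 2))
    if mask is not None:
        x = np.where(np.asarray(mask, dtype=bool), x, 0.0)
    n = len(x)
    pad = min(int(round(pad_s * fs)), max(n - 1, 0))
    xp = np.pad(x, pad, mode="reflect") if pad else x
    nfft = sfft.next_fast_len(len(xp))
    X = sfft.fft(xp, nfft)
    filt = _morse_filters(freqs, fs, nfft)
    W = sfft.ifft(X[None, :] * filt, axis=1)
    power = np.abs(W[:, pad : pad + n]) ** 2
    return TimeFrequencyPower(power=power, freqs=np.asarray(freqs), fs=fs)


def band_power_series(tf: TimeFrequencyPower, band: BandDefinition) -> np.ndarray:
    """Mean power across the band's frequency rows, per time sample.

    The broadband reference uses a closed interval so the top grid
    frequency is included.
    """
    if band.f_lo < tf.freqs[0] - 1e-9 or band.f_hi > tf.freqs[-1] * (1 + 1e-9):
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}) outside the "
            f"frequency grid [{tf.freqs[0]:g}, {tf.freqs[-1]:g}]"
        )
    if band.name == "broadband":
        rows = (tf.freqs >= band.f_lo) & (tf.freqs <= band.f_hi * (1 + 1e-9))
    else:
        rows = (tf.freqs >= band.f_lo) & (tf.freqs < band.f_hi)
    if not rows.any():
        raise ValueError(f"band {band.name} matches no grid frequencies")
    return tf.power[rows].mean(axis=0)


def _moment_features(p: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean/variance/skewness/kurtosis, degenerate -> 0.

    Biased (population) moment definitions; kurtosis is the Pearson
    (non-excess) form, 3 for a Gaussian. Zero-variance epochs return
    skewness = kurtosis = 0 by convention.
    """
    mean = float(np.mean(p))
    d = p - mean
    m2 = float(np.mean(d * d))
    if m2 <= 0.0:
        return mean, m2, 0.0, 0.0
    d2 = d * d
    m3 = float(np.mean(d2 * d))
    m4 = float(np.mean(d2 * d2))
    return mean, m2, m3 / m2**1.5, m4 / (m2 * m2)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy (nats) of power samples normalized to sum to 1.

    An all-zero epoch is the uniform limit: entropy log(n).
    """
    total = float(np.sum(p))
    if total <= 0.0:
        return float(np.log(len(p)))
    q = p / total
    nz = q[q > 0]
    return float(-np.sum(nz * np.log(nz)))


def epoch_features(
    series_by_band: dict[str, np.ndarray],
    broadband_series: np.ndarray,
    mask: np.ndarray | None = None,
    epoch_len: float = 30.0,
    activation_factor: float = 1.5,
    min_valid_fraction: float = 0.10,
) -> np.ndarray | None:
    """The 30 per-band descriptors of one epoch of one channel.

    Only unmasked time samples enter any statistic. Activation duration
    is ``epoch_len`` times the fraction of unmasked samples where the
    band's power exceeds ``activation_factor`` x the median broadband
    power of the same epoch. Returns None (epoch invalid) when fewer
    than ``min_valid_fraction`` of the samples are unmasked.
    """
    n = len(broadband_series)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < min_valid_fraction * n:
        return None
    bb = broadband_series[mask]
    threshold = activation_factor * float(np.median(bb))
    out = {m: [] for m in _METRICS}
    for name, series in series_by_band.items():
        p = series[mask]
        mean, var, skew, kurt = _moment_features(p)
        out["meanpower"].append(mean)
        out["varpower"].append(var)
        out["skewness"].append(skew)
        out["kurtosis"].append(kurt)
        out["entropy"].append(_entropy(p))
        out["activation"].append(epoch_len * float(np.mean(p > threshold)))
    return np.concatenate([out[m] for m in _METRICS])


def feature_names(
    n_channels: int = 2, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> list[str]:
    """Deterministic column names, metric-major within each channel block."""
    names = []
    for ch in range(1, n_channels + 1):
        for metric in _METRICS:
            for band in bands:
                names.append(f"ch{ch}_{band.name}_{metric}")
    return names


def _night_band_series(
    x: np.ndarray,
    mask: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...],
    freqs: np.ndarray,
    pad_s: float,
    chunk_epochs: int,
    epoch_samples: int,
    n_epochs: int,
) -> dict[str, np.ndarray]:
    """Band power series for a whole channel, computed in padded chunks.

    Chunks carry ``pad_s`` seconds of real neighbouring signal on each
    side (reflection at the recording edges), so interior epochs see
    their true context and only the night's first/last seconds rely on
    reflection.
    """
    x = np.where(mask, x, 0.0)
    total = n_epochs * epoch_samples
    pad = int(round(pad_s * fs))
    series = {b.name: np.empty(total, dtype=float) for b in bands}
    series["broadband"] = np.empty(total, dtype=float)
    row_sets = {}
    for b in bands:
        row_sets[b.name] = (freqs >= b.f_lo) & (freqs < b.f_hi)
    row_sets["broadband"] = (freqs >= BROADBAND.f_lo) & (
        freqs <= BROADBAND.f_hi * (1 + 1e-9)
    )
    for c0 in range(0, n_epochs, chunk_epochs):
        c1 = min(c0 + chunk_epochs, n_epochs)
        lo, hi = c0 * epoch_samples, c1 * epoch_samples
        lpad, rpad = min(pad, lo), min(pad, len(x) - hi)
        seg = x[lo - lpad : hi + rpad]
        extra_l, extra_r = pad - lpad, pad - rpad
        if extra_l or extra_r:
            seg = np.pad(seg, (extra_l, extra_r), mode="reflect")
        nfft = sfft.next_fast_len(len(seg))
        X = sfft.fft(seg.astype(np.float32), nfft)
        key32 = ("f32", nfft, float(fs), len(freqs))
        filt = _FILTER_CACHE.get(key32)
        if filt is None:
            filt = _morse_filters(freqs, fs, nfft).astype(np.float32)
            _FILTER_CACHE[key32] = filt
        crop = slice(pad, pad + (hi - lo))
        power = np.empty((len(freqs), hi - lo), dtype=np.float32)
        block = 16  # bound transient memory: 16 rows of complex64 at a time
        for r0 in range(0, len(freqs), block):
            r1 = min(r0 + block, len(freqs))
            W = sfft.ifft(X[None, :] * filt[r0:r1], axis=1)[:, crop]
            power[r0:r1] = np.square(W.real) + np.square(W.imag)
        for name, rows in row_sets.items():
            series[name][lo:hi] = power[rows].mean(axis=0)
    return series


def extract_night(
    rec: Recording,
    epoch_len: float = 30.0,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    voices_per_octave: int = 12,
    pad_s: float = 5.0,
    activation_factor: float = 1.5,
    chunk_epochs: int = 20,
) -> FeatureMatrix:
    """Per-epoch feature matrix for all channels of a night.

    Produces 30 features per channel per epoch (channel blocks in
    channel order); an epoch is invalid when any channel has fewer than
    10% unmasked samples.
    """
    es = int(round(epoch_len * rec.fs))
    n_ep = rec.n_samples // es
    freqs = cwt_frequencies(
        f_hi=min(100.0, 0.999 * rec.fs / 2), voices_per_octave=voices_per_octave
    )
    names = feature_names(rec.n_channels, bands)
    values = np.zeros((n_ep, len(names)))
    valid = np.ones(n_ep, dtype=bool)
    n_feat = 6 * len(bands)
    for ch in range(rec.n_channels):
        series = _night_band_series(
            rec.signal[ch], rec.valid_mask[ch], rec.fs, bands, freqs,
            pad_s, chunk_epochs, es, n_ep,
        )
        for k in range(n_ep):
            sl = slice(k * es, (k + 1) * es)
            feats = epoch_features(
                {b.name: series[b.name][sl] for b in bands},
                series["broadband"][sl],
                mask=rec.valid_mask[ch][sl],
                epoch_len=epoch_len,
                activation_factor=activation_factor,
            )
            if feats is None:
                valid[k] = False
                values[k, ch * n_feat : (ch + 1) * n_feat] = np.nan
            else:
                values[k, ch * n_feat : (ch + 1) * n_feat] = feats
    return FeatureMatrix(values=values, feature_names=names, epoch_valid=valid)


_CONTEXT_OFFSETS = (-1, 0, 1, 2)
_CONTEXT_TAGS = ("prev1", "cur", "next1", "next2")


def stack_context(fm: FeatureMatrix) -> FeatureMatrix:
    """Concatenate each epoch's features with epochs k-1, k+1 and k+2.

    Edge epochs replicate the nearest existing row. A contributing
    neighbour that is itself invalid is replaced by the nearest valid
    epoch's features, so one artifact epoch does not poison its
    neighbours; row validity remains that of the epoch itself.
    """
    n = fm.n_epochs
    if n == 0:
        raise ValueError("cannot stack an empty feature matrix")
    valid_idx = np.flatnonzero(fm.epoch_valid)
    blocks = []
    for off in _CONTEXT_OFFSETS:
        idx = np.clip(np.arange(n) + off, 0, n - 1)
        if len(valid_idx):
            bad = ~fm.epoch_valid[idx]
            if bad.any():
                pos = np.searchsorted(valid_idx, idx[bad])
                lo = valid_idx[np.clip(pos - 1, 0, len(valid_idx) - 1)]
                hi = valid_idx[np.clip(pos, 0, len(valid_idx) - 1)]
                nearest = np.where(
                    np.abs(idx[bad] - lo) <= np.abs(hi - idx[bad]), lo, hi
                )
                idx = idx.copy()
                idx[bad] = nearest
        blocks.append(fm.values[idx])
    names = [
        f"{name}_{tag}" for tag in _CONTEXT_TAGS for name in fm.feature_names
    ]
    return FeatureMatrix(
        values=np.hstack(blocks),
        feature_names=names,
        epoch_valid=fm.epoch_valid.copy(),
    )
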