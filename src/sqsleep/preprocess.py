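"""Signal conditioning ahead of feature extraction.

The pipeline band-pass filters to 0.5–100 Hz with a 50 Hz notch, brings
both modalities to a common 207 Hz rate, masks samples exceeding
±300 µV (artifacts are excluded, not deleted), and aligns two
co-recorded devices with per-epoch normalized cross-correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal

from .io import Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass edges and notch frequency in Hz."""

    band_lo: float = 0.5
    band_hi: float = 100.0
    notch: float = 50.0
    notch_q: float = 30.0
    order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("require 0 < band_lo < band_hi")
        if not self.band_lo < self.notch < self.band_hi:
            raise ValueError("notch must lie inside the passband")


@dataclass
class SyncResult:
    """Per-epoch alignment of a second recording against a reference.

    ``lags[k]`` is the integer sample shift maximizing the normalized
    cross-correlation of epoch ``k`` (NaN where an epoch was fully
    masked); ``peak_corr[k]`` is that maximum, in [-1, 1].
    """

    lags: np.ndarray
    peak_corr: np.ndarray
    epoch_len: float
    fs: float


def bandpass_notch(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase Butterworth band-pass plus IIR notch.

    A 4th-order Butterworth and a Q=30 notch are each applied
    forward-backward (zero group delay), so epoch timing is untouched.
    The validity mask is propagated unchanged.
    """
    if rec.fs <= 2 * spec.band_hi:
        raise ValueError(
            f"fs={rec.fs} Hz too low for band_hi={spec.band_hi} Hz "
            "(need fs > 2*band_hi)"
        )
    sos = signal.butter(
        spec.order, [spec.band_lo, spec.band_hi], btype="bandpass",
        fs=rec.fs, output="sos",
    )
    b, a = signal.iirnotch(spec.notch, spec.notch_q, fs=rec.fs)
    out = signal.sosfiltfilt(sos, rec.signal, axis=1)
    out = signal.filtfilt(b, a, out, axis=1)
    return replace(rec, signal=out, valid_mask=rec.valid_mask.copy())


def resample_to(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling to ``target_fs`` (downsampling only).

    The rational ratio is approximated to within 1/1000 denominator;
    anti-alias filtering is inherent in the polyphase design.
    """
    if target_fs > rec.fs:
        raise ValueError(
            f"upsampling unsupported (target {target_fs} > source {rec.fs})"
        )
    if target_fs == rec.fs:
        return rec.copy()
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.signal, up, down, axis=1)
    n_out = out.shape[1]
    # Nearest-sample mapping carries the validity mask across rates.
    src_idx = np.clip(
        np.round(np.arange(n_out) * rec.fs / target_fs).astype(int),
        0, rec.n_samples - 1,
    )
    mask = rec.valid_mask[:, src_idx]
    return replace(rec, signal=out, fs=float(target_fs), valid_mask=mask)


def reject_artifacts(
    rec: Recording, threshold_uv: float = 300.0, guard_s: float = 0.5
) -> Recording:
    """Mask samples with |amplitude| above ``threshold_uv``.

    The mask is extended by ``guard_s`` seconds on each side of every
    excursion. Samples are masked, never removed, so all later
    statistics skip them while the epoch grid stays intact. Idempotent:
    sample values are untouched, so a second pass finds the same set.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    guard = int(round(guard_s * rec.fs))
    bad = np.abs(rec.signal) > threshold_uv
    if guard > 0:
        structure = np.ones(2 * guard + 1, dtype=bool)
        bad = np.stack(
            [ndimage.binary_dilation(row, structure=structure) for row in bad]
        )
    return replace(
        rec, signal=rec.signal.copy(), valid_mask=rec.valid_mask & ~bad
    )


def synchronize(
    ref: Recording,
    other: Recording,
    epoch_len: float = 30.0,
    max_lag_s: float = 2.0,
    channel: int = 0,
) -> SyncResult:
    """Per-epoch lag estimation via normalized cross-correlation.

    Both recordings must already share a sampling rate (resample
    first). Masked samples are zeroed before correlating, so large
    artifacts cannot dominate the estimate, and the normalization uses
    the unmasked energy only. A positive lag means ``other`` trails
    ``ref`` by that many samples. Ties in the correlation maximum
    resolve to the smallest |lag| (then the smaller lag).
    """
    if ref.fs != other.fs:
        raise ValueError(
            f"sampling rates differ ({ref.fs} vs {other.fs}); resample first"
        )
    fs = ref.fs
    es = int(round(epoch_len * fs))
    max_lag = int(round(max_lag_s * fs))
    n_ep = min(ref.n_samples, other.n_samples) // es
    lags = np.full(n_ep, np.nan)
    peaks = np.full(n_ep, np.nan)
    a_full = np.where(ref.valid_mask[channel], ref.signal[channel], 0.0)
    b_full = np.where(other.valid_mask[channel], other.signal[channel], 0.0)
    # Tie-break ordering: 0, -1, +1, -2, +2, ...
    lag_axis = np.arange(-max_lag, max_lag + 1)
    order = np.argsort(np.abs(lag_axis) + 1e-9 * (lag_axis > 0), kind="stable")
    for k in range(n_ep):
        sl = slice(k * es, (k + 1) * es)
        a, b = a_full[sl], b_full[sl]
        ea, eb = float(np.dot(a, a)), float(np.dot(b, b))
        if ea == 0.0 or eb == 0.0:
            logger.warning("epoch %d fully masked or silent; lag missing", k)
            continue
        # window[i] = sum_t a[t] * b[t + lag_axis[i]]
        full = signal.correlate(a, b, mode="full")
        center = len(b) - 1
        window = full[center - max_lag : center + max_lag + 1][::-1]
        norm = window / np.sqrt(ea * eb)
        best = order[np.argmax(norm[order] >= np.max(norm) - 1e-12)]
        lags[k] = lag_axis[best]
        peaks[k] = norm[best]
    return SyncResult(lags=lags, peak_corr=peaks, epoch_len=epoch_len, fs=fs)


def apply_sync(other: Recording, sync: SyncResult) -> Recording:
    """Shift each epoch of ``other`` by its estimated lag.

    Epoch ``k`` of the output is ``other`` sampled at an offset of
    ``lags[k]`` (epochs with a missing lag are copied unshifted).
    Samples requested beyond the ends are taken from the edges.
    """
    es = int(round(sync.epoch_len * other.fs))
    out = other.copy()
    for k, lag in enumerate(sync.lags):
        if np.isnan(lag):
            continue
        lo = k * es
        idx = np.clip(np.arange(lo, lo + es) + int(lag), 0, other.n_samples - 1)
        out.signal[:, lo : lo + es] = other.signal[:, idx]
        out.valid_mask[:, lo : lo + es] = other.valid_mask[:, idx]
    return out
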