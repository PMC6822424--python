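"""Signal and label I/O: EDF recordings and CSV hypnograms.

The on-disk formats are the field standards: EDF/EDF+ for raw EEG and a
small CSV dialect (``epoch_index,onset_sec,stage``) for 30-s hypnograms
scored with the AASM five-stage alphabet (W, N1, N2, N3, R).

Reading EDF goes through :mod:`mne`; writing uses a minimal EDF encoder
implemented here (16-bit samples, physical dimension µV).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical AASM stage order; also the classifier's tie-break order.
STAGES = ("W", "N1", "N2", "N3", "R")

#: Stages counted as sleep when collapsing to a two-class trace.
SLEEP_STAGES = frozenset({"N1", "N2", "N3", "R"})

#: Two-class alphabet, wake first (diagonal = specificity, sensitivity).
WAKE_SLEEP = ("wake", "sleep")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class Recording:
    """A multichannel EEG segment with a per-sample validity mask.

    Amplitudes are in µV throughout. ``valid_mask`` marks samples usable
    for analysis; artifact rejection clears mask bits but never deletes
    samples, so downstream statistics skip them while timing is preserved.
    """

    signal: np.ndarray  # (n_channels, n_samples), µV
    fs: float
    channel_names: tuple[str, ...]
    start_time: datetime | None = None
    valid_mask: np.ndarray | None = None  # bool, same shape as signal

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} channels"
            )
        self.channel_names = tuple(self.channel_names)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.signal.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.signal.shape:
                raise ValueError("valid_mask shape must match signal shape")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(
            self, signal=self.signal.copy(), valid_mask=self.valid_mask.copy()
        )


@dataclass
class Hypnogram:
    """Ordered stage labels over consecutive fixed-length epochs."""

    stages: list[str]
    epoch_len: float = 30.0
    start_time: datetime | None = None
    #: Optional time-attempting-to-sleep (device mount-to-dismount), minutes.
    tats_min: float | None = None

    def __post_init__(self) -> None:
        self.stages = list(self.stages)
        if self.epoch_len <= 0:
            raise ValueError(f"epoch_len must be positive, got {self.epoch_len}")
        alphabet = set(STAGES) | set(WAKE_SLEEP)
        for i, s in enumerate(self.stages):
            if s not in alphabet:
                raise ValueError(f"unknown stage token {s!r} at epoch {i}")

    def __len__(self) -> int:
        return len(self.stages)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.stages == other.stages
            and self.epoch_len == other.epoch_len
            and self.tats_min == other.tats_min
        )

    @property
    def duration_min(self) -> float:
        return len(self.stages) * self.epoch_len / 60.0


@dataclass
class SleepWakeTrace:
    """Two-state (wake/sleep) epoch labels derived from a hypnogram."""

    states: list[str]
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        for i, s in enumerate(self.states):
            if s not in WAKE_SLEEP:
                raise ValueError(f"unknown state token {s!r} at epoch {i}")

    def __len__(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_LABEL_LEN = 16


def _ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def _phys_str(v: float) -> str:
    """Format a physical bound into EDF's 8-char ASCII field."""
    s = f"{v:.6g}"
    if len(s) > 8:
        s = f"{v:.2e}"
    return s[:8]


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` as 16-bit EDF with µV physical units.

    The physical range of each channel is the symmetric envelope of its
    samples, so round-trip error is bounded by one digital LSB of that
    range. Channel labels longer than EDF's 16-character field are
    truncated with a logged warning.
    """
    if not np.all(np.isfinite(rec.signal)):
        raise ValueError("cannot write EDF: signal contains non-finite samples")
    path = Path(path)
    fs = rec.fs
    n = rec.n_samples
    # Whole-second signals use 1-s records; otherwise one record holds all.
    if abs(fs - round(fs)) < 1e-9 and n % int(round(fs)) == 0 and n > 0:
        spr = int(round(fs))
        n_rec = n // spr
        rec_dur = 1.0
    else:
        spr = max(n, 1)
        n_rec = 1
        rec_dur = n / fs if n else 1.0

    labels = []
    for name in rec.channel_names:
        if len(name) > _EDF_LABEL_LEN:
            logger.warning(
                "channel name %r exceeds EDF's %d-char label field; truncated",
                name,
                _EDF_LABEL_LEN,
            )
        labels.append(name[:_EDF_LABEL_LEN])

    dig_min, dig_max = -32768, 32767
    phys_lo, phys_hi, scaled = [], [], []
    for ch in range(rec.n_channels):
        x = rec.signal[ch]
        amp = float(np.max(np.abs(x))) if n else 0.0
        pmax = max(amp, 1e-3)
        # Use the value as *written* so quantization matches the header.
        pmax = float(_phys_str(pmax * 1.000001))
        pmin = -pmax
        phys_lo.append(pmin)
        phys_hi.append(pmax)
        gain = (dig_max - dig_min) / (pmax - pmin)
        d = np.clip(np.round((x - pmin) * gain + dig_min), dig_min, dig_max)
        scaled.append(d.astype("<i2"))

    t0 = rec.start_time or datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii(t0.strftime("%d.%m.%y"), 8),
            _ascii(t0.strftime("%H.%M.%S"), 8),
            _ascii(str(256 * (1 + rec.n_channels)), 8),
            _ascii("", 44),
            _ascii(str(n_rec), 8),
            _ascii(f"{rec_dur:.6g}"[:8], 8),
            _ascii(str(rec.n_channels), 4),
        ]
    )
    nch = rec.n_channels
    sig_hdr = b"".join(
        [
            b"".join(_ascii(lb, 16) for lb in labels),
            b"".join(_ascii("", 80) for _ in range(nch)),
            b"".join(_ascii("uV", 8) for _ in range(nch)),
            b"".join(_ascii(_phys_str(phys_lo[c]), 8) for c in range(nch)),
            b"".join(_ascii(_phys_str(phys_hi[c]), 8) for c in range(nch)),
            b"".join(_ascii(str(dig_min), 8) for _ in range(nch)),
            b"".join(_ascii(str(dig_max), 8) for _ in range(nch)),
            b"".join(_ascii("", 80) for _ in range(nch)),
            b"".join(_ascii(str(spr), 8) for _ in range(nch)),
            b"".join(_ascii("", 32) for _ in range(nch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_hdr)
        for r in range(n_rec):
            sl = slice(r * spr, (r + 1) * spr)
            for ch in range(nch):
                fh.write(scaled[ch][sl].tobytes())


def _validate_edf_header(path: Path) -> None:
    """Check structural integrity before handing the file to the reader."""
    size = path.stat().st_size
    if size < 256:
        raise FormatError(f"{path}: EDF header truncated ({size} < 256 bytes)")
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        try:
            header_bytes = int(hdr[184:192].decode("ascii").strip())
            n_rec = int(hdr[236:244].decode("ascii").strip())
            n_sig = int(hdr[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(
                f"{path}: unparseable EDF header field "
                "(bytes 184-256: header size / record count / signal count)"
            ) from exc
        if n_sig <= 0:
            raise FormatError(f"{path}: invalid 'number of signals' field ({n_sig})")
        if size < header_bytes:
            raise FormatError(
                f"{path}: signal headers truncated ({size} < {header_bytes} bytes)"
            )
        sig_hdr = fh.read(256 * n_sig)
        try:
            off = n_sig * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
            spr = [
                int(sig_hdr[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
                for i in range(n_sig)
            ]
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(
                f"{path}: unparseable 'samples per record' field"
            ) from exc
    if n_rec < 0:
        raise FormatError(f"{path}: 'number of data records' field is {n_rec}")
    expected = header_bytes + n_rec * sum(spr) * 2
    if size < expected:
        raise FormatError(
            f"{path}: data records truncated "
            f"({size} bytes on disk, header declares {expected})"
        )


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (µV amplitudes).

    Channels stored at different rates are resampled by the reader to a
    common sampling frequency. The validity mask starts all-true.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_edf_header(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of types for bad files
        raise FormatError(f"{path}: unreadable EDF ({exc})") from exc
    data = raw.get_data() * 1e6  # V -> µV
    meas = raw.info.get("meas_date")
    if isinstance(meas, datetime) and meas.tzinfo is not None:
        meas = meas.astimezone(timezone.utc).replace(tzinfo=None)
    return Recording(
        signal=data,
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        start_time=meas,
    )


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram as ``epoch_index,onset_sec,stage`` CSV.

    Optional metadata (epoch length when non-default, TATS minutes) is
    carried in ``# key: value`` comment lines before the header.
    """
    path = Path(path)
    lines = []
    if h.epoch_len != 30.0:
        lines.append(f"# epoch_len_s: {h.epoch_len:g}")
    if h.tats_min is not None:
        lines.append(f"# tats_min: {h.tats_min:g}")
    lines.append("epoch_index,onset_sec,stage")
    for i, s in enumerate(h.stages):
        lines.append(f"{i},{i * h.epoch_len:g},{s}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram CSV, validating the stage alphabet and epoch grid."""
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = float(val.strip())
    df = pd.read_csv(path, comment="#")
    required = {"epoch_index", "onset_sec", "stage"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    epoch_len = meta.get("epoch_len_s", 30.0)
    idx = df["epoch_index"].to_numpy()
    for row, (got, want) in enumerate(zip(idx, range(len(idx)))):
        if got != want:
            raise FormatError(
                f"{path}: epoch_index not contiguous at row {row} "
                f"(expected {want}, found {got})"
            )
    stages = []
    for row, s in enumerate(df["stage"].astype(str)):
        if s not in STAGES:
            raise ValueError(
                f"{path}: unknown stage token {s!r} at row {row} "
                f"(expected one of {STAGES})"
            )
        stages.append(s)
    return Hypnogram(
        stages=stages, epoch_len=epoch_len, tats_min=meta.get("tats_min")
    )


# ---------------------------------------------------------------------------
# Feature CSV (thin wrappers; the container lives in sqsleep.features)
# ---------------------------------------------------------------------------


def write_features(fm, path: str | Path) -> None:
    """Write a FeatureMatrix to CSV (``epoch_valid`` as the first column)."""
    fm.to_csv(path)


def read_features(path: str | Path):
    """Read a FeatureMatrix from CSV written by :func:`write_features`."""
    from .features import FeatureMatrix

    return FeatureMatrix.from_csv(path)
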