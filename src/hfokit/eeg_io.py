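"""EEG recording container, EDF input/output, montage and filtering.

All internal signals are in microvolts (µV).  Sample indices are 0-based and
intervals half-open [start, end); seconds = samples / fs.

EDF reading goes through MNE's reader.  Writing uses a compact 16-bit EDF
writer implemented here (one sampling rate across channels, 1-second data
records); round-trip fidelity against the independent MNE reader is part of
the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sp_signal

logger = logging.getLogger(__name__)

__all__ = [
    "Recording", "MontageSpec", "FilterSpec",
    "read_edf", "write_edf", "apply_montage", "select_channels", "apply_filters",
]


@dataclass
class Recording:
    """A multi-channel EEG recording.

    Parameters
    ----------
    channel_names
        Unique channel labels, one per row of ``data``.
    fs
        Sampling rate in Hz (identical across channels).
    data
        ``(n_channels, n_samples)`` float array in microvolts.
    start_time
        Optional recording-start timestamp (ISO string or datetime).
    annotations
        Free-form metadata mapping.
    """

    channel_names: list[str]
    fs: float
    data: np.ndarray
    start_time: Optional[object] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}") from None

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def copy_with(self, channel_names: list[str], data: np.ndarray) -> "Recording":
        return Recording(
            channel_names=list(channel_names),
            fs=self.fs,
            data=data,
            start_time=self.start_time,
            annotations=dict(self.annotations),
        )


@dataclass
class MontageSpec:
    """Bipolar montage: each (anode, cathode) pair yields channel "anode-cathode"."""

    pairs: list[tuple[str, str]]


@dataclass
class FilterSpec:
    """Band-pass + optional power-line notch settings.

    band_low / band_high are the pass-band edges in Hz; the notch removes the
    power-line fundamental (``powerline_hz``, typically 50 or 60) when
    ``powerline_enabled`` is set.  Optional ``powerline_harmonics`` adds
    notches at integer multiples up to band_high.
    """

    band_low: float
    band_high: float
    powerline_hz: Optional[float] = None
    powerline_enabled: bool = False
    powerline_harmonics: int = 1

    def validate(self, fs: float) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError(f"need 0 < band_low < band_high, got [{self.band_low}, {self.band_high}]")
        if self.band_high >= fs / 2:
            raise ValueError(
                f"band_high {self.band_high} Hz must be below the Nyquist frequency {fs / 2} Hz"
            )
        if self.powerline_enabled and not self.powerline_hz:
            raise ValueError("powerline_enabled requires powerline_hz")


# ---------------------------------------------------------------------------
# EDF I/O

_EDF_HEADER_BYTES = 256


def _pad_ascii(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as a standard 16-bit EDF file.

    One data record per second (so ``fs`` must be a positive integer); a
    trailing partial second is zero-padded.  The physical range is chosen
    symmetrically around zero from the data (floor of ±1 µV), giving a
    quantization step of phys_range / 2**16 per sample.

    Raises
    ------
    ValueError
        If fs is not a whole number or data amplitudes are not finite.
    """
    path = Path(path)
    if rec.n_channels == 0:
        raise ValueError("cannot write an EDF file with no signals")
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))

    n_samples = rec.n_samples
    n_records = int(np.ceil(n_samples / fs)) if n_samples else 0
    ns = rec.n_channels

    phys_max = float(np.max(np.abs(rec.data))) if rec.data.size else 1.0
    phys_max = max(1.0, phys_max) * 1.0000001  # avoid clipping the extreme sample
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    padded = np.zeros((ns, n_records * fs), dtype=np.float64)
    padded[:, :n_samples] = rec.data
    digital = np.round((padded - phys_min) * scale + dig_min)
    if np.any(digital > dig_max) or np.any(digital < dig_min):
        raise ValueError("amplitude overflow of the declared physical range")
    digital = digital.astype("<i2")

    with open(path, "wb") as fh:
        start = "01.01.2000"
        time = "00.00.00"
        header = b"".join([
            _pad_ascii("0", 8),
            _pad_ascii("X X X X", 80),        # patient id
            _pad_ascii("Startdate 01-JAN-2000 X X X", 80),  # recording id
            _pad_ascii(start, 8),
            _pad_ascii(time, 8),
            _pad_ascii(str(_EDF_HEADER_BYTES * (1 + ns)), 8),
            _pad_ascii("", 44),
            _pad_ascii(str(n_records), 8),
            _pad_ascii("1", 8),               # record duration, seconds
            _pad_ascii(str(ns), 4),
        ])
        fh.write(header)
        fields = [
            [_pad_ascii(name, 16) for name in rec.channel_names],       # label
            [_pad_ascii("", 80)] * ns,                                  # transducer
            [_pad_ascii("uV", 8)] * ns,                                 # physical dimension
            [_pad_ascii(f"{phys_min:.6g}", 8)] * ns,
            [_pad_ascii(f"{phys_max:.6g}", 8)] * ns,
            [_pad_ascii(str(dig_min), 8)] * ns,
            [_pad_ascii(str(dig_max), 8)] * ns,
            [_pad_ascii("", 80)] * ns,                                  # prefiltering
            [_pad_ascii(str(fs), 8)] * ns,                              # samples / record
            [_pad_ascii("", 32)] * ns,                                  # reserved
        ]
        for group in fields:
            fh.write(b"".join(group))
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (data in µV).

    Channels must share a single sampling rate.  Physical units are converted
    to microvolts; channels with unrecognized physical dimensions pass
    through unscaled with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        except Exception as exc:  # corrupt header, zero signals, ...
            raise ValueError(f"unsupported file: cannot read {path} as EDF ({exc})") from exc
    if len(raw.ch_names) == 0:
        raise ValueError(f"unsupported file: {path} contains no signals")
    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:
        raise ValueError("unsupported file: inconsistent channel sampling rates")
    # MNE scales channels with known physical dimensions to SI volts.
    data_uv = raw.get_data() * 1e6
    n_expected = raw.n_times
    rec = Recording(
        channel_names=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=data_uv[:, :n_expected],
        start_time=raw.info.get("meas_date"),
    )
    return rec


# ---------------------------------------------------------------------------
# Montage / selection / filtering


def apply_montage(rec: Recording, montage: MontageSpec) -> Recording:
    """Derive bipolar channels: each pair (anode, cathode) -> anode - cathode."""
    names, rows = [], []
    for anode, cathode in montage.pairs:
        ia, ic = rec.channel_index(anode), rec.channel_index(cathode)
        names.append(f"{anode}-{cathode}")
        rows.append(rec.data[ia] - rec.data[ic])
    data = np.asarray(rows, dtype=np.float64).reshape(len(names), rec.n_samples)
    return rec.copy_with(names, data)


def select_channels(rec: Recording, names: Sequence[str]) -> Recording:
    """Subset (and reorder) channels by name."""
    missing = [n for n in names if n not in rec.channel_names]
    if missing:
        raise KeyError(f"unknown channel name(s): {missing}")
    idx = [rec.channel_names.index(n) for n in names]
    return rec.copy_with(list(names), rec.data[idx].copy())


def bandpass_sos(band_low: float, band_high: float, fs: float, order: int = 4) -> np.ndarray:
    """Butterworth band-pass in second-order sections (applied forward-backward)."""
    return sp_signal.butter(order, [band_low, band_high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(x: np.ndarray, band_low: float, band_high: float, fs: float,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (effective order 2x``order``)."""
    sos = bandpass_sos(band_low, band_high, fs, order=order)
    return sp_signal.sosfiltfilt(sos, x, axis=-1)


def notch_filter(x: np.ndarray, freq: float, fs: float, q: float = 30.0) -> np.ndarray:
    """Zero-phase second-order IIR notch at ``freq`` Hz (quality factor q)."""
    b, a = sp_signal.iirnotch(freq, q, fs=fs)
    return sp_signal.filtfilt(b, a, x, axis=-1)


def apply_filters(rec: Recording, spec: FilterSpec) -> Recording:
    """Apply the zero-phase band-pass (and optional power-line notch) per channel.

    Output length equals input length; filtering is applied notch-first so the
    band-pass shapes the final spectrum.
    """
    spec.validate(rec.fs)
    data = rec.data
    if spec.powerline_enabled and spec.powerline_hz:
        for k in range(1, spec.powerline_harmonics + 1):
            f0 = spec.powerline_hz * k
            if f0 < rec.fs / 2:
                data = notch_filter(data, f0, rec.fs)
    data = bandpass_filter(data, spec.band_low, spec.band_high, rec.fs)
    return rec.copy_with(list(rec.channel_names), data)
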