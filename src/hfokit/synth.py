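"""Seeded synthetic iEEG generator with ground truth — the package's test bed.

Emulates the kind of corpus the pipeline targets: multi-channel recordings
at 2000 Hz containing 1/f^alpha background noise plus transient 80–500 Hz
oscillations (HFOs), spike-coupled oscillations (spkHFOs) and broadband
artifacts.  Background noise is calibrated to unit standard deviation inside
the 80–500 Hz band, so event amplitudes are expressed as in-band envelope
signal-to-noise ratios.

Conventions
-----------
* An HFO is a Hann-windowed sinusoid.  Its ground-truth interval is the
  half-amplitude (FWHM) support of the Hann envelope — the central half of
  the burst — which is the region where the oscillation is appreciable.
* ``snr_db`` = 10·log10( mean in-band envelope of the injected component
  over its ground-truth window / SD of the background in-band envelope ):
  a power-style decibel on the envelope ratio, the detection statistic the
  Hilbert detector thresholds, so 0 dB means the event envelope sits at one
  background-envelope SD.  The amplitude solving this is found by measuring
  the unit-amplitude waveform's band-passed envelope, so the calibration
  holds for every event type.
* A spkHFO adds a biphasic transient (difference of two Gaussians, width
  ``spike_width_s``) under the oscillation; an artifact is a sharp broadband
  biphasic impulse.

All randomness flows from a single seeded generator, so every recording is
fully determined by its configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import hilbert as analytic_signal
from scipy.signal.windows import hann as hann_window

from hfokit.eeg_io import Recording, bandpass_filter

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig", "GroundTruthEvent", "GroundTruth", "InjectionParams",
    "make_background", "inject_event", "synthesize_recording", "make_labeled_images",
]

EVENT_TYPES = ("hfo", "spk_hfo", "artifact")
_BAND = (80.0, 500.0)  # calibration band, Hz


@dataclass
class SynthConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the target corpora: 2000 Hz grid/strip recordings of a
    few minutes, ripple-band oscillations of 50–100 ms, and event rates of a
    few per channel-minute.
    """

    n_channels: int = 4
    duration_s: float = 300.0
    fs: float = 2000.0
    noise_exponent: float = 1.0                      # power ~ 1/f^alpha
    hfo_rate: float = 1.5                            # events / channel-minute
    spk_hfo_rate: float = 1.0
    artifact_rate: float = 0.5
    hfo_freq_range: tuple[float, float] = (90.0, 400.0)
    hfo_duration_range: tuple[float, float] = (0.05, 0.10)   # full burst support, s
    snr_db_range: tuple[float, float] = (12.0, 18.0)
    spike_width_s: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.fs > 2 * self.hfo_freq_range[1]:
            raise ValueError("fs must exceed twice the maximum HFO frequency")
        if min(self.hfo_rate, self.spk_hfo_rate, self.artifact_rate) < 0:
            raise ValueError("event rates must be nonnegative")
        for lo, hi in (self.hfo_freq_range, self.hfo_duration_range, self.snr_db_range):
            if lo > hi:
                raise ValueError("ranges must be ordered (low, high)")


@dataclass(frozen=True)
class GroundTruthEvent:
    channel: str
    start: int                  # sample, inclusive
    end: int                    # sample, exclusive
    type: str                   # hfo | spk_hfo | artifact
    carrier_hz: float           # 0 for pure artifacts
    snr_db: float
    fs: float = 2000.0

    @property
    def start_s(self) -> float:
        return self.start / self.fs

    @property
    def end_s(self) -> float:
        return self.end / self.fs


@dataclass
class GroundTruth:
    """Per-recording list of injected events, exportable as a CSV sidecar."""

    events: list[GroundTruthEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_type(self, kind: str) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.type == kind]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "channel": e.channel, "start_s": e.start_s, "end_s": e.end_s,
            "type": e.type, "carrier_hz": e.carrier_hz, "snr_db": e.snr_db,
        } for e in self.events]
        return pd.DataFrame(rows, columns=["channel", "start_s", "end_s", "type",
                                           "carrier_hz", "snr_db"])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, fs: float) -> "GroundTruth":
        frame = pd.read_csv(path)
        events = [GroundTruthEvent(
            channel=str(r.channel), start=int(round(r.start_s * fs)),
            end=int(round(r.end_s * fs)), type=str(r.type),
            carrier_hz=float(r.carrier_hz), snr_db=float(r.snr_db), fs=fs,
        ) for r in frame.itertuples()]
        return cls(events=events)


@dataclass
class InjectionParams:
    """Placement and shape of a single injected event."""

    start: int                       # sample where the waveform support begins
    snr_db: float = 18.0
    carrier_hz: float = 150.0
    duration_s: float = 0.08         # full support of the burst
    spike_width_s: float = 0.05
    phase: float = 0.0


# ---------------------------------------------------------------------------
# Background


def _pink_noise(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-alpha / 2.0)
    if n > 1:
        shaping[0] = shaping[1]   # keep DC finite
    return np.fft.irfft(spectrum * shaping, n=n)


def make_background(cfg: SynthConfig, rng: Optional[np.random.Generator] = None) -> Recording:
    """Seeded 1/f^alpha Gaussian background, unit SD in the 80–500 Hz band."""
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    data = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        x = _pink_noise(rng, n, cfg.fs, cfg.noise_exponent)
        band = bandpass_filter(x, *_BAND, cfg.fs)
        sd = band.std()
        data[c] = x / sd if sd > 0 else x
    names = [f"CH{c + 1}" for c in range(cfg.n_channels)]
    return Recording(channel_names=names, fs=cfg.fs, data=data,
                     annotations={"id": f"synth-seed{cfg.seed}", "generator": "hfokit.synth",
                                  "config": dataclasses.asdict(cfg)})


# ---------------------------------------------------------------------------
# Event waveforms


def _difference_of_gaussians(n: int, fs: float, width_s: float) -> np.ndarray:
    """Biphasic transient: narrow positive Gaussian minus a broader one."""
    t = (np.arange(n) - n / 2) / fs
    sigma = width_s / 6.0
    w = np.exp(-t**2 / (2 * sigma**2)) - 0.6 * np.exp(-t**2 / (2 * (2 * sigma)**2))
    return w


def _unit_waveform(kind: str, params: InjectionParams, fs: float) -> tuple[np.ndarray, tuple[int, int]]:
    """Unit-amplitude waveform and the ground-truth interval relative to its start."""
    if kind == "hfo" or kind == "spk_hfo":
        n = max(4, int(round(params.duration_s * fs)))
        t = np.arange(n) / fs
        w = hann_window(n) * np.sin(2 * np.pi * params.carrier_hz * t + params.phase)
        truth = (n // 4, n - n // 4)     # FWHM support of the Hann envelope
        if kind == "spk_hfo":
            m = max(8, int(round(3 * params.spike_width_s * fs)))
            spike = _difference_of_gaussians(m, fs, params.spike_width_s)
            full = np.zeros(max(n, m))
            off_w = (len(full) - n) // 2
            off_s = (len(full) - m) // 2
            full[off_w:off_w + n] += w
            full[off_s:off_s + m] += 4.0 * spike   # spikes dwarf the ripple
            truth = (off_w + truth[0], off_w + truth[1])
            return full, truth
        return w, truth
    if kind == "artifact":
        width = 0.004                                # sharp => broadband
        n = max(8, int(round(6 * width * fs)))
        w = _difference_of_gaussians(n, fs, width)
        return w, (0, n)
    raise ValueError(f"unknown event type {kind!r}; valid: {EVENT_TYPES}")


def band_envelope_sd(x: np.ndarray, fs: float) -> float:
    """SD of the 80–500 Hz analytic envelope — the SNR reference level."""
    band = bandpass_filter(x, *_BAND, fs)
    return float(np.abs(analytic_signal(band)).std())


def inject_event(rec: Recording, channel: str, kind: str, params: InjectionParams,
                 sigma_env: Optional[float] = None) -> tuple[Recording, GroundTruthEvent]:
    """Additively inject one event; returns the new Recording and its truth row.

    The amplitude is calibrated so the mean in-band envelope of the injected
    component over its ground-truth window is ``10**(snr_db/10)`` times
    ``sigma_env`` (measured from the channel if not supplied).
    """
    ci = rec.channel_index(channel)
    x = rec.data[ci]
    if sigma_env is None:
        sigma_env = band_envelope_sd(x, rec.fs)
    w, (t0, t1) = _unit_waveform(kind, params, rec.fs)
    if params.start < 0 or params.start + len(w) > rec.n_samples:
        raise ValueError("event waveform does not fit inside the recording")
    # zero-pad the unit waveform so the zero-phase filter has room to settle
    pad = max(0, 256 - len(w)) + 64
    w_padded = np.pad(w, pad)
    band_w = bandpass_filter(w_padded, *_BAND, rec.fs)
    unit_env = float(np.abs(analytic_signal(band_w))[pad + t0:pad + t1].mean())
    if unit_env <= 0:
        raise ValueError("degenerate waveform: no in-band energy")
    amplitude = 10.0 ** (params.snr_db / 10.0) * sigma_env / unit_env
    data = rec.data.copy()
    data[ci, params.start:params.start + len(w)] += amplitude * w
    out = rec.copy_with(list(rec.channel_names), data)
    truth = GroundTruthEvent(
        channel=channel, start=params.start + t0, end=params.start + t1, type=kind,
        carrier_hz=params.carrier_hz if kind != "artifact" else 0.0,
        snr_db=params.snr_db, fs=rec.fs)
    return out, truth


# ---------------------------------------------------------------------------
# Full recordings


def _poisson_starts(rng: np.random.Generator, n_events: int, support: int, n_samples: int,
                    occupied: list[tuple[int, int]], pad: int, margin: int,
                    max_tries: int = 100) -> list[int]:
    starts = []
    lo, hi = margin, n_samples - margin - support
    if hi <= lo:
        return starts
    for _ in range(n_events):
        for _ in range(max_tries):
            s = int(rng.integers(lo, hi))
            window = (s - pad, s + support + pad)
            if all(window[1] <= a or window[0] >= b for a, b in occupied):
                occupied.append((s, s + support))
                starts.append(s)
                break
        else:
            logger.warning("could not place an event without overlap; dropping it")
    return starts


def synthesize_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Background plus Poisson-placed events of each type, fully seeded.

    Event counts per channel are Poisson with the configured per-type rates;
    placements are rejection-resampled so event windows never overlap (with a
    0.25 s guard band) and stay 1 s clear of the recording edges.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rec = make_background(cfg, rng)
    minutes = cfg.duration_s / 60.0
    pad = int(round(0.25 * cfg.fs))
    margin = int(round(1.0 * cfg.fs))
    truth_rows: list[GroundTruthEvent] = []
    data = rec.data  # mutate in place; Recording is returned as-is

    for ci, channel in enumerate(rec.channel_names):
        sigma_env = band_envelope_sd(data[ci], cfg.fs)
        occupied: list[tuple[int, int]] = []
        for kind, rate in (("hfo", cfg.hfo_rate), ("spk_hfo", cfg.spk_hfo_rate),
                           ("artifact", cfg.artifact_rate)):
            n_events = int(rng.poisson(rate * minutes))
            for _ in range(n_events):
                params = InjectionParams(
                    start=0,
                    snr_db=float(rng.uniform(*cfg.snr_db_range)),
                    carrier_hz=float(rng.uniform(*cfg.hfo_freq_range)),
                    duration_s=float(rng.uniform(*cfg.hfo_duration_range)),
                    spike_width_s=cfg.spike_width_s,
                    phase=float(rng.uniform(0, 2 * np.pi)),
                )
                w, _ = _unit_waveform(kind, params, cfg.fs)
                placed = _poisson_starts(rng, 1, len(w), rec.n_samples, occupied, pad, margin)
                if not placed:
                    continue
                params.start = placed[0]
                updated, row = inject_event(rec, channel, kind, params, sigma_env=sigma_env)
                data[ci] = updated.data[ci]
                truth_rows.append(row)
    truth_rows.sort(key=lambda e: (e.channel, e.start))
    return rec, GroundTruth(events=truth_rows)


def make_labeled_images(n_per_class: int, classes: tuple[str, ...] = ("hfo", "artifact"),
                        seed: int = 0, fs: float = 2000.0,
                        snippet_s: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Generate labeled 3x224x224 model inputs, one centered event per snippet.

    Returns (images, labels): images of shape (n, 3, 224, 224) and integer
    labels indexing ``classes``.  Used for classifier training, distillation
    and learnability tests.
    """
    from hfokit.detect import Event
    from hfokit.features import TFRConfig, events_tfr, to_model_input

    rng = np.random.default_rng(seed)
    tfr_cfg = TFRConfig()
    base_cfg = SynthConfig(n_channels=1, duration_s=snippet_s, fs=fs, seed=seed)
    traces, events, labels = [], [], []
    for label, kind in enumerate(classes):
        for _ in range(n_per_class):
            bg_seed = int(rng.integers(0, 2**31 - 1))
            bg = make_background(dataclasses.replace(base_cfg, seed=bg_seed))
            params = InjectionParams(
                start=0,
                snr_db=float(rng.uniform(12.0, 18.0)),
                carrier_hz=float(rng.uniform(90.0, 400.0)),
                duration_s=float(rng.uniform(0.05, 0.10)),
                phase=float(rng.uniform(0, 2 * np.pi)),
            )
            w, _ = _unit_waveform(kind, params, fs)
            params.start = bg.n_samples // 2 - len(w) // 2
            rec, truth = inject_event(bg, bg.channel_names[0], kind, params)
            name = f"S{len(traces)}"
            traces.append(rec.data[0])
            events.append(Event(name, truth.start, truth.end, fs=fs))
            labels.append(label)
    # one wavelet pass over all snippets (stacked as channels of one recording)
    combined = Recording(channel_names=[e.channel for e in events], fs=fs,
                         data=np.asarray(traces))
    images = np.asarray([to_model_input(img).astype(np.float32)
                         for img in events_tfr(combined, events, tfr_cfg)])
    order = rng.permutation(len(images))
    return images[order], np.asarray(labels)[order]
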