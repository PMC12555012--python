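"""HFO event detectors: short-term energy (STE), MNI-style, and Hilbert envelope.

All three follow the same shell: band-pass the trace to the HFO band
(default 80–500 Hz), compute a per-sample activation series, threshold it,
keep maximal above-threshold runs that last at least ``min_window`` seconds,
and merge events separated by less than ``min_gap``.  They differ in the
activation series and in how the threshold is derived:

* Hilbert — activation is the magnitude of the analytic signal (envelope),
  z-scored per processing epoch; threshold is ``sd_thres`` standard
  deviations.
* STE — activation is a centered sliding-window RMS; threshold is
  mean + ``rms_thres``·SD per epoch, with an additional requirement of at
  least ``min_peaks`` rectified-signal peaks above mean + ``peak_thres``·SD
  inside each candidate.
* MNI — threshold is a high percentile of the activation restricted to
  noise-like "baseline" segments found by spectral entropy; when too little
  baseline exists, an iterative percentile scheme on ``epoch_chf`` windows
  is used instead.

Conventions (shared with the brute-force oracles in the test suite):
activation exactly equal to the threshold counts as above-threshold; a run
qualifies when its length in samples is >= round(min_window·fs); two events
merge when the gap between them is < round(min_gap·fs) samples; a flat
(zero-variance) channel or epoch yields no events.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.signal import hilbert as analytic_signal

from hfokit.eeg_io import Recording, bandpass_filter

logger = logging.getLogger(__name__)

__all__ = [
    "Event", "EventList", "HilbertConfig", "STEConfig", "MNIConfig",
    "detect_hilbert", "detect_ste", "detect_mni", "run_detector",
    "merge_close_events", "DETECTORS",
]


@dataclass(frozen=True, order=True)
class Event:
    """One detected HFO candidate: a half-open sample interval on a channel."""

    channel: str
    start: int
    end: int
    fs: float = dataclasses.field(compare=False, default=2000.0)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.fs

    @property
    def start_s(self) -> float:
        return self.start / self.fs

    @property
    def end_s(self) -> float:
        return self.end / self.fs

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class EventList:
    """Detector output: events sorted by (channel, start) plus provenance."""

    recording_id: str
    detector: str
    config: dict
    events: list[Event] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.channel, e.start, e.end))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def for_channel(self, channel: str) -> list[Event]:
        return [e for e in self.events if e.channel == channel]

    @property
    def channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.channel, None)
        return list(seen)


# ---------------------------------------------------------------------------
# Configurations (defaults follow the parameterizations these detectors are
# commonly run with in clinical HFO studies)


@dataclass
class HilbertConfig:
    filter_freq: tuple[float, float] = (80.0, 500.0)
    sd_thres: float = 5.0          # threshold in SD of the envelope, per epoch
    min_window: float = 10e-3      # minimum event duration, s
    epoch_len: float = 3600.0      # processing epoch, s
    min_gap: float = 10e-3         # merge events closer than this, s

    def validate(self) -> None:
        if self.sd_thres <= 0 or self.min_window <= 0 or self.epoch_len <= 0:
            raise ValueError("sd_thres, min_window and epoch_len must be positive")


@dataclass
class STEConfig:
    filter_freq: tuple[float, float] = (80.0, 500.0)
    rms_window: float = 3e-3       # sliding RMS window, s
    rms_thres: float = 5.0         # RMS threshold, SD units
    min_window: float = 6e-3       # minimum event duration, s
    min_gap: float = 10e-3
    peak_thres: float = 3.0        # rectified-peak threshold, SD units
    min_peaks: int = 6             # minimum rectified peaks per event
    epoch_len: float = 600.0

    def validate(self) -> None:
        if min(self.rms_window, self.rms_thres, self.min_window, self.min_gap,
               self.peak_thres, self.epoch_len) <= 0:
            raise ValueError("all STE durations and thresholds must be positive")
        if int(self.min_peaks) < 1:
            raise ValueError("min_peaks must be an integer >= 1")


@dataclass
class MNIConfig:
    filter_freq: tuple[float, float] = (80.0, 500.0)
    epoch_len: float = 10.0
    epoch_chf: float = 60.0        # window for the iterative (no-baseline) branch, s
    per_chf: float = 95.0          # percentile for the iterative branch
    min_window: float = 10e-3
    min_gap: float = 10e-3
    thrd_perc: float = 99.9999     # baseline-energy percentile threshold
    base_seg: float = 125e-3       # baseline segment length, s
    base_thrd: float = 0.67        # entropy fraction of theoretical max
    base_min: float = 5.0          # minimum total baseline, s

    def validate(self) -> None:
        for p in (self.per_chf, self.thrd_perc):
            if not 0 < p < 100:
                raise ValueError("percentiles must lie in (0, 100)")
        if min(self.epoch_len, self.epoch_chf, self.min_window, self.min_gap,
               self.base_seg, self.base_min) <= 0:
            raise ValueError("all MNI durations must be positive")


# ---------------------------------------------------------------------------
# Shared primitives


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as half-open (start, end)."""
    if mask.size == 0:
        return []
    m = mask.astype(np.int8)
    diff = np.diff(m)
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def merge_close_events(events: Sequence[Event], min_gap_s: float) -> list[Event]:
    """Merge consecutive same-channel events whose gap is < min_gap_s; idempotent."""
    by_channel: dict[str, list[Event]] = {}
    for e in sorted(events, key=lambda e: (e.channel, e.start, e.end)):
        by_channel.setdefault(e.channel, []).append(e)
    out: list[Event] = []
    for channel, evs in by_channel.items():
        gap = int(round(min_gap_s * evs[0].fs))
        merged = [evs[0]]
        for e in evs[1:]:
            prev = merged[-1]
            if e.start - prev.end < gap:
                merged[-1] = Event(channel, prev.start, max(prev.end, e.end), fs=prev.fs)
            else:
                merged.append(e)
        out.extend(merged)
    return sorted(out, key=lambda e: (e.channel, e.start, e.end))


def _epoch_slices(n_samples: int, fs: float, epoch_len: float, min_window: float) -> list[tuple[int, int]]:
    """Split [0, n) into epochs of epoch_len seconds.

    A trailing partial epoch shorter than 2·min_window is appended to the
    previous epoch (it is too short to carry its own statistics); otherwise it
    is processed with its own statistics.
    """
    step = int(round(epoch_len * fs))
    if step <= 0 or n_samples == 0:
        return [(0, n_samples)] if n_samples else []
    edges = list(range(0, n_samples, step)) + [n_samples]
    slices = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    if len(slices) > 1:
        last = slices[-1]
        if (last[1] - last[0]) < 2 * int(round(min_window * fs)):
            slices[-2] = (slices[-2][0], last[1])
            slices.pop()
    return slices


def _sliding_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding-window RMS (same length as input; edges use partial windows
    normalized by the full window length, matching plain 'same' convolution)."""
    window = max(1, window)
    kernel = np.ones(window) / window
    ms = np.convolve(x * x, kernel, mode="same")
    return np.sqrt(np.maximum(ms, 0.0))


def _events_from_runs(runs: Iterable[tuple[int, int]], offset: int, channel: str,
                      fs: float, min_len: int) -> list[Event]:
    return [Event(channel, offset + s, offset + e, fs=fs)
            for s, e in runs if (e - s) >= min_len]


# ---------------------------------------------------------------------------
# Hilbert detector


def _hilbert_channel(x: np.ndarray, fs: float, cfg: HilbertConfig, channel: str) -> list[Event]:
    filtered = bandpass_filter(x, *cfg.filter_freq, fs)
    min_len = max(1, int(round(cfg.min_window * fs)))
    events: list[Event] = []
    for lo, hi in _epoch_slices(len(x), fs, cfg.epoch_len, cfg.min_window):
        seg = filtered[lo:hi]
        if np.any(np.isnan(seg)):
            logger.warning("channel %s: NaN samples invalidate epoch [%d, %d)", channel, lo, hi)
            continue
        env = np.abs(analytic_signal(seg))
        sd = env.std()
        if sd == 0:
            logger.info("channel %s: flat epoch [%d, %d), no events", channel, lo, hi)
            continue
        z = (env - env.mean()) / sd
        events.extend(_events_from_runs(_runs_above(z >= cfg.sd_thres), lo, channel, fs, min_len))
    return merge_close_events(events, cfg.min_gap)


# ---------------------------------------------------------------------------
# STE detector


def _count_peaks(rect: np.ndarray, start: int, end: int, thr: float) -> int:
    """Strict local maxima of the rectified trace in [start, end) above thr."""
    lo = max(start, 1)
    hi = min(end, len(rect) - 1)
    if hi <= lo:
        return 0
    seg = rect[lo:hi]
    is_peak = (seg > rect[lo - 1:hi - 1]) & (seg > rect[lo + 1:hi + 1]) & (seg >= thr)
    return int(np.count_nonzero(is_peak))


def _ste_channel(x: np.ndarray, fs: float, cfg: STEConfig, channel: str) -> list[Event]:
    filtered = bandpass_filter(x, *cfg.filter_freq, fs)
    min_len = max(1, int(round(cfg.min_window * fs)))
    rms_win = max(1, int(round(cfg.rms_window * fs)))
    events: list[Event] = []
    for lo, hi in _epoch_slices(len(x), fs, cfg.epoch_len, cfg.min_window):
        seg = filtered[lo:hi]
        if np.any(np.isnan(seg)):
            logger.warning("channel %s: NaN samples invalidate epoch [%d, %d)", channel, lo, hi)
            continue
        rms = _sliding_rms(seg, rms_win)
        if rms.std() == 0:
            continue
        thr = rms.mean() + cfg.rms_thres * rms.std()
        candidates = _events_from_runs(_runs_above(rms >= thr), lo, channel, fs, min_len)
        candidates = merge_close_events(candidates, cfg.min_gap)
        rect = np.abs(seg)
        peak_thr = rect.mean() + cfg.peak_thres * rect.std()
        for ev in candidates:
            if _count_peaks(rect, ev.start - lo, ev.end - lo, peak_thr) >= int(cfg.min_peaks):
                events.append(ev)
    return merge_close_events(events, cfg.min_gap)


# ---------------------------------------------------------------------------
# MNI detector


def _spectral_entropy(seg: np.ndarray) -> tuple[float, float]:
    """Shannon entropy of the normalized power spectrum (DC excluded).

    Returns (entropy, max_entropy); a zero-power segment returns (0, max).
    """
    power = np.abs(np.fft.rfft(seg))[1:] ** 2
    h_max = np.log(len(power)) if len(power) > 1 else 1.0
    total = power.sum()
    if total <= 0:
        return 0.0, h_max
    p = power / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()), h_max


def _mni_iterative(energy: np.ndarray, per_chf: float, min_len: int,
                   max_iter: int = 10) -> list[tuple[int, int]]:
    """Repeated percentile thresholding: mark above-threshold samples, drop
    them from the percentile pool, recompute on the remainder.  The threshold
    descends toward the background level as high-energy samples leave the
    pool; the minimum-duration filter applies to the final marked mask."""
    active = np.ones(energy.size, dtype=bool)
    marked = np.zeros(energy.size, dtype=bool)
    for _ in range(max_iter):
        if active.sum() < 2:
            break
        thr = np.percentile(energy[active], per_chf)
        mask = (energy >= thr) & active
        if not mask.any():
            break
        marked |= mask
        active &= ~mask
    return [(s, e) for s, e in _runs_above(marked) if e - s >= min_len]


def _mni_channel(x: np.ndarray, fs: float, cfg: MNIConfig, channel: str,
                 branch_log: Optional[dict] = None) -> list[Event]:
    filtered = bandpass_filter(x, *cfg.filter_freq, fs)
    if filtered.std() == 0:
        if branch_log is not None:
            branch_log[channel] = "flat"
        return []
    min_len = max(1, int(round(cfg.min_window * fs)))
    energy = _sliding_rms(filtered, min_len)

    # Baseline: high-entropy (noise-like) base_seg segments across the channel.
    seg_len = max(2, int(round(cfg.base_seg * fs)))
    baseline = np.zeros(filtered.size, dtype=bool)
    for s in range(0, filtered.size - seg_len + 1, seg_len):
        h, h_max = _spectral_entropy(filtered[s:s + seg_len])
        if h >= cfg.base_thrd * h_max:
            baseline[s:s + seg_len] = True

    events: list[Event]
    if baseline.sum() / fs >= cfg.base_min:
        thr = np.percentile(energy[baseline], cfg.thrd_perc)
        runs = [(s, e) for s, e in _runs_above(energy >= thr) if e - s >= min_len]
        events = _events_from_runs(runs, 0, channel, fs, min_len)
        if branch_log is not None:
            branch_log[channel] = "baseline"
    else:
        events = []
        step = int(round(cfg.epoch_chf * fs))
        for lo in range(0, filtered.size, step):
            hi = min(lo + step, filtered.size)
            runs = _mni_iterative(energy[lo:hi], cfg.per_chf, min_len)
            events.extend(_events_from_runs(runs, lo, channel, fs, min_len))
        if branch_log is not None:
            branch_log[channel] = "iterative"
    return merge_close_events(events, cfg.min_gap)


# ---------------------------------------------------------------------------
# Public API


def _detect(rec: Recording, cfg, channel_fn: Callable, name: str,
            branch_log: Optional[dict] = None) -> EventList:
    cfg.validate()
    events: list[Event] = []
    for i, channel in enumerate(rec.channel_names):
        if name == "mni":
            events.extend(channel_fn(rec.data[i], rec.fs, cfg, channel, branch_log))
        else:
            events.extend(channel_fn(rec.data[i], rec.fs, cfg, channel))
    meta = {"branches": branch_log} if branch_log is not None else {}
    return EventList(recording_id=str(rec.annotations.get("id", "")), detector=name,
                     config=dataclasses.asdict(cfg), events=events, meta=meta)


def detect_hilbert(rec: Recording, cfg: Optional[HilbertConfig] = None) -> EventList:
    """Hilbert-envelope detector: threshold the per-epoch z-scored analytic
    envelope of the band-passed trace at ``sd_thres`` standard deviations."""
    return _detect(rec, cfg or HilbertConfig(), _hilbert_channel, "hilbert")

def detect_ste(rec: Recording, cfg: Optional[STEConfig] = None) -> EventList:
    """Short-term-energy detector: sliding-RMS threshold plus a minimum count
    of rectified-signal peaks per candidate."""
    return _detect(rec, cfg or STEConfig(), _ste_channel, "ste")

def detect_mni(rec: Recording, cfg: Optional[MNIConfig] = None) -> EventList:
    """MNI-style detector: percentile energy threshold from entropy-selected
    baseline segments, falling back to an iterative percentile scheme.

    The branch taken per channel ("baseline" / "iterative" / "flat") is
    recorded in ``EventList.meta["branches"]``.
    """
    return _detect(rec, cfg or MNIConfig(), _mni_channel, "mni", branch_log={})


_DETECT_FNS = {"hilbert": detect_hilbert, "ste": detect_ste, "mni": detect_mni}
DETECTORS = {"hilbert": HilbertConfig, "ste": STEConfig, "mni": MNIConfig}


def _single_channel(rec: Recording, i: int) -> Recording:
    sub = rec.copy_with([rec.channel_names[i]], rec.data[i:i + 1])
    return sub


def run_detector(rec: Recording, detector_name: str, cfg=None, n_jobs: int = 1) -> EventList:
    """Run a named detector ('ste' | 'mni' | 'hilbert'), optionally channel-parallel.

    Channels are independent, so the result is identical for every ``n_jobs``.
    """
    if detector_name not in _DETECT_FNS:
        raise ValueError(
            f"unknown detector {detector_name!r}; valid options: {sorted(_DETECT_FNS)}")
    fn = _DETECT_FNS[detector_name]
    if cfg is None:
        cfg = DETECTORS[detector_name]()
    if n_jobs == 1 or rec.n_channels <= 1:
        return fn(rec, cfg)
    from joblib import Parallel, delayed

    parts = Parallel(n_jobs=n_jobs)(
        delayed(fn)(_single_channel(rec, i), cfg) for i in range(rec.n_channels))
    events = [e for part in parts for e in part.events]
    meta: dict = {}
    if parts and any(p.meta for p in parts):
        branches: dict = {}
        for p in parts:
            branches.update(p.meta.get("branches") or {})
        meta["branches"] = branches
    return EventList(recording_id=str(rec.annotations.get("id", "")), detector=detector_name,
                     config=dataclasses.asdict(cfg), events=events, meta=meta)
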