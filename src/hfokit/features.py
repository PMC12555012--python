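"""Standardized time–frequency event images — the classifier input.

Each detected event is rendered as a 224x224 nonnegative image: a window
(default 2 s) of the raw trace centered on the event midpoint is transformed
with complex Morlet (Gabor) wavelets at 224 frequencies spanning 10–500 Hz,
the outermost crop (default 0.5 s per side) is discarded so the retained
1 s is centered on the event, and the magnitude map is resized to 224x224
and min–max normalized to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from hfokit.detect import Event
from hfokit.eeg_io import Recording

logger = logging.getLogger(__name__)

__all__ = ["TFRConfig", "EventImage", "event_tfr", "events_tfr", "to_model_input"]

_TFR_CHUNK = 32  # segments per wavelet pass; bounds the complex work buffer


@dataclass
class TFRConfig:
    window_s: float = 2.0            # extracted window around the event midpoint
    crop_s: float = 0.5              # trimmed from each side after the transform
    freq_lo: float = 10.0
    freq_hi: float = 500.0
    n_freq: int = 224
    out_size: tuple[int, int] = (224, 224)
    wavelet_width: float = 7.0       # Morlet cycles parameter
    freq_spacing: str = "linear"     # 'linear' | 'log'

    def validate(self, fs: float) -> None:
        if self.window_s - 2 * self.crop_s <= 0:
            raise ValueError("window_s must exceed 2 * crop_s")
        if not (self.freq_lo < self.freq_hi < fs / 2):
            raise ValueError(f"need freq_lo < freq_hi < fs/2 = {fs / 2}")
        if self.n_freq < 2:
            raise ValueError("n_freq must be >= 2")

    def frequencies(self) -> np.ndarray:
        if self.freq_spacing == "log":
            return np.geomspace(self.freq_lo, self.freq_hi, self.n_freq)
        return np.linspace(self.freq_lo, self.freq_hi, self.n_freq)


@dataclass
class EventImage:
    """Min–max-normalized time–frequency image of one event.

    ``values`` has shape ``config.out_size``, row 0 = lowest frequency.
    """

    values: np.ndarray
    event: Optional[Event] = None
    config: TFRConfig = field(default_factory=TFRConfig)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.config.out_size):
            raise ValueError(f"image shape {self.values.shape} != {self.config.out_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("image values must lie in [0, 1]")


def _extract_window(x: np.ndarray, center: int, half: int) -> np.ndarray:
    """Window of length 2*half centered at ``center``, reflect-padded at edges."""
    n = len(x)
    lo, hi = center - half, center + half
    pad_lo, pad_hi = max(0, -lo), max(0, hi - n)
    seg = x[max(0, lo):min(n, hi)]
    if pad_lo or pad_hi:
        seg = np.pad(seg, (pad_lo, pad_hi), mode="reflect")
    return seg


def morlet_tfr_batch(segments: np.ndarray, fs: float, freqs: np.ndarray,
                     n_cycles: float) -> np.ndarray:
    """Magnitude of the complex Morlet transform, shape (n_seg, n_freq, n_times).

    Rows are rescaled by sqrt(f) to undo the L2 wavelet normalization, so a
    pure tone produces the same response magnitude at every carrier and the
    peak row is the bin nearest the carrier frequency.
    """
    from mne.time_frequency import tfr_array_morlet

    data = np.asarray(segments)[:, np.newaxis, :]
    out = tfr_array_morlet(data, sfreq=fs, freqs=freqs, n_cycles=n_cycles,
                           output="complex", verbose="error")
    mag = np.abs(out[:, 0])
    return mag * np.sqrt(freqs)[np.newaxis, :, np.newaxis]


def morlet_tfr(seg: np.ndarray, fs: float, freqs: np.ndarray, n_cycles: float) -> np.ndarray:
    """Single-segment convenience wrapper around :func:`morlet_tfr_batch`."""
    return morlet_tfr_batch(seg[np.newaxis], fs, freqs, n_cycles)[0]


def event_tfr(rec: Recording, event: Event, cfg: Optional[TFRConfig] = None) -> EventImage:
    """Time–frequency image of one event (see module docstring for the recipe).

    Events near the recording edges are handled by reflection padding; an
    event longer than the retained window is still processed centered, with a
    logged warning.
    """
    cfg = cfg or TFRConfig()
    cfg.validate(rec.fs)
    retained_s = cfg.window_s - 2 * cfg.crop_s
    if event.duration_s > retained_s:
        logger.warning("event of %.3f s exceeds the retained %.3f s window; processing centered",
                       event.duration_s, retained_s)
    return events_tfr(rec, [event], cfg)[0]


def events_tfr(rec: Recording, events: Sequence[Event],
               cfg: Optional[TFRConfig] = None) -> list[EventImage]:
    """Batched :func:`event_tfr`: one wavelet pass over all event windows."""
    cfg = cfg or TFRConfig()
    cfg.validate(rec.fs)
    events = list(events)
    if not events:
        return []
    half = int(round(cfg.window_s * rec.fs / 2))
    segments = np.stack([_extract_window(rec.channel(e.channel), e.midpoint, half)
                         for e in events])
    crop = int(round(cfg.crop_s * rec.fs))
    out = []
    for i in range(0, len(segments), _TFR_CHUNK):
        tfrs = morlet_tfr_batch(segments[i:i + _TFR_CHUNK], rec.fs, cfg.frequencies(),
                                cfg.wavelet_width)
        for event, tfr in zip(events[i:i + _TFR_CHUNK], tfrs):
            if crop:
                tfr = tfr[:, crop:tfr.shape[1] - crop]
            img = _sk_resize(tfr, cfg.out_size, order=1, mode="reflect", anti_aliasing=True)
            lo, hi = img.min(), img.max()
            img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
            out.append(EventImage(values=img, event=event, config=cfg))
    return out


def to_model_input(img: EventImage) -> np.ndarray:
    """Duplicate the image across the channel dimension: (3, H, W) stack."""
    return np.repeat(img.values[np.newaxis], 3, axis=0)


def save_image_batch(images: Sequence[EventImage] | np.ndarray, path) -> None:
    """Export images as a compressed array archive for offline training."""
    if isinstance(images, np.ndarray):
        arr = images
    else:
        images = list(images)
        arr = (np.stack([im.values for im in images])
               if images and isinstance(images[0], EventImage) else np.asarray(images))
    with open(path, "wb") as fh:
        np.savez_compressed(fh, images=arr.astype(np.float32))


def load_image_batch(path) -> np.ndarray:
    with np.load(path, allow_pickle=False) as npz:
        return npz["images"]
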