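import numpy as np
import pytest

from hfokit.eeg_io import Recording
from hfokit.synth import SynthConfig, make_labeled_images, synthesize_recording


@pytest.fixture
def noise_recording():
    """Two-channel 10 s pink-noise recording, no events (seeded)."""
    cfg = SynthConfig(n_channels=2, duration_s=10.0, seed=42,
                      hfo_rate=0, spk_hfo_rate=0, artifact_rate=0)
    rec, _ = synthesize_recording(cfg)
    return rec


@pytest.fixture
def event_recording():
    """Four-channel 60 s recording with injected events and its ground truth."""
    rec, truth = synthesize_recording(SynthConfig(n_channels=4, duration_s=60.0, seed=7))
    return rec, truth


@pytest.fixture
def sine_recording():
    """Single-channel 150 Hz sinusoid, 4 s at 2000 Hz, 50 µV amplitude."""
    fs = 2000.0
    t = np.arange(int(4 * fs)) / fs
    return Recording(["A"], fs, (50 * np.sin(2 * np.pi * 150 * t))[np.newaxis])


@pytest.fixture(scope="session")
def image_pool():
    """2000 labeled event images (1000 HFO / 1000 artifact), seed 0.

    Session-scoped: shared by the classifier, cascade and distillation tests
    to keep the wavelet-transform cost paid once.
    """
    images, labels = make_labeled_images(1000, ("hfo", "artifact"), seed=0)
    return images, labels
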