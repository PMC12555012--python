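import numpy as np
import pytest

from hfokit.eeg_io import (
    FilterSpec,
    MontageSpec,
    Recording,
    apply_filters,
    apply_montage,
    read_edf,
    select_channels,
    write_edf,
)

FS = 2000.0


def _sine_rec(freq, amp=100.0, seconds=4.0, channels=("A",)):
    t = np.arange(int(seconds * FS)) / FS
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (len(channels), 1))
    return Recording(list(channels), FS, data)


class TestRecording:
    def test_rejects_duplicate_channel_names(self):
        with pytest.raises(ValueError, match="unique"):
            Recording(["A", "A"], FS, np.zeros((2, 10)))

    def test_rejects_nonfinite_data(self):
        data = np.zeros((1, 10))
        data[0, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            Recording(["A"], FS, data)

    def test_rejects_mismatched_names(self):
        with pytest.raises(ValueError):
            Recording(["A"], FS, np.zeros((2, 10)))


class TestEdfRoundTrip:
    def test_metadata_preserved(self, noise_recording, tmp_path):
        path = write_edf(noise_recording, tmp_path / "rec.edf")
        back = read_edf(path)
        assert back.channel_names == noise_recording.channel_names
        assert back.fs == noise_recording.fs
        assert back.n_samples == noise_recording.n_samples

    def test_quantization_bound(self, noise_recording, tmp_path):
        """Round-trip error is bounded by the declared 16-bit quantization step."""
        path = write_edf(noise_recording, tmp_path / "rec.edf")
        back = read_edf(path)
        phys_range = 2 * max(1.0, np.abs(noise_recording.data).max()) * 1.0000001
        step = phys_range / 2**16
        err = np.abs(back.data - noise_recording.data).max()
        assert err <= step

    def test_constant_zero_channel(self, tmp_path):
        rec = Recording(["Z"], FS, np.zeros((1, int(2 * FS))))
        back = read_edf(write_edf(rec, tmp_path / "z.edf"))
        step = 2.0 * 1.0000001 / 2**16
        assert np.abs(back.data).max() <= step

    def test_sinusoid_quantization(self, tmp_path):
        rec = _sine_rec(150, amp=100.0)
        back = read_edf(write_edf(rec, tmp_path / "s.edf"))
        phys_range = 2 * 100.0 * 1.0000001
        assert np.abs(back.data - rec.data).max() <= phys_range / 2**16

    def test_header_arithmetic(self, tmp_path):
        rec = Recording(["A", "B"], FS, np.zeros((2, int(10 * FS))))
        back = read_edf(write_edf(rec, tmp_path / "h.edf"))
        assert back.fs == 2000
        assert back.n_samples == 20_000

    def test_zero_channel_write_rejected(self, tmp_path):
        rec = Recording([], FS, np.zeros((0, 100)))
        with pytest.raises(ValueError, match="no signals"):
            write_edf(rec, tmp_path / "empty.edf")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_edf(tmp_path / "absent.edf")

    def test_corrupt_file(self, tmp_path):
        bad = tmp_path / "bad.edf"
        bad.write_bytes(b"not an edf header at all")
        with pytest.raises(ValueError, match="unsupported file"):
            read_edf(bad)


class TestMontage:
    def test_self_pair_is_zero(self, noise_recording):
        out = apply_montage(noise_recording, MontageSpec([("CH1", "CH1")]))
        assert out.channel_names == ["CH1-CH1"]
        assert np.allclose(out.data, 0)

    def test_constant_difference(self):
        rec = Recording(["A", "B"], FS, np.vstack([np.full(100, 5.0), np.full(100, 2.0)]))
        out = apply_montage(rec, MontageSpec([("A", "B")]))
        assert out.channel_names == ["A-B"]
        assert np.allclose(out.data, 3.0)

    def test_output_cardinality(self):
        rec = Recording(["A", "B", "C"], FS, np.random.default_rng(0).normal(size=(3, 50)))
        out = apply_montage(rec, MontageSpec([("A", "B"), ("B", "C")]))
        assert out.n_channels == 2

    def test_unknown_channel(self, noise_recording):
        with pytest.raises(KeyError, match="XX"):
            apply_montage(noise_recording, MontageSpec([("CH1", "XX")]))


class TestSelectChannels:
    def test_identity(self, noise_recording):
        out = select_channels(noise_recording, noise_recording.channel_names)
        assert out.channel_names == noise_recording.channel_names
        assert np.array_equal(out.data, noise_recording.data)

    def test_single(self, noise_recording):
        out = select_channels(noise_recording, ["CH2"])
        assert out.data.shape == (1, noise_recording.n_samples)

    def test_unknown_name_listed(self, noise_recording):
        with pytest.raises(KeyError, match="NOPE"):
            select_channels(noise_recording, ["CH1", "NOPE"])


class TestFilters:
    band = FilterSpec(band_low=80, band_high=500)

    def test_stopband_attenuation(self):
        rec = _sine_rec(10)
        out = apply_filters(rec, self.band)
        assert _rms(out.data) <= 0.01 * _rms(rec.data)

    def test_passband_flat(self):
        rec = _sine_rec(150)
        out = apply_filters(rec, self.band)
        mid = out.data[:, 1000:-1000]  # avoid edge transients
        assert abs(_rms(mid) - _rms(rec.data)) <= 0.05 * _rms(rec.data)

    def test_powerline_notch(self):
        rec = _sine_rec(60)
        spec = FilterSpec(band_low=1, band_high=900, powerline_hz=60, powerline_enabled=True)
        out = apply_filters(rec, spec)
        assert _rms(out.data[:, 1000:-1000]) <= 0.05 * _rms(rec.data)

    def test_band_above_nyquist_rejected(self, noise_recording):
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filters(noise_recording, FilterSpec(band_low=80, band_high=1000))

    def test_linearity(self, noise_recording):
        a, b = 2.5, -1.25
        x = noise_recording
        y = x.copy_with(x.channel_names, x.data[::-1].copy())
        lhs = apply_filters(x.copy_with(x.channel_names, a * x.data + b * y.data), self.band)
        rhs = a * apply_filters(x, self.band).data + b * apply_filters(y, self.band).data
        assert np.allclose(lhs.data, rhs, atol=1e-9)

    def test_zero_phase(self):
        """A filtered narrowband burst peaks at zero lag against its input."""
        fs = FS
        n = int(2 * fs)
        t = np.arange(n) / fs
        burst = np.exp(-((t - 1.0) ** 2) / (2 * 0.02**2)) * np.sin(2 * np.pi * 150 * t)
        rec = Recording(["A"], fs, burst[np.newaxis])
        out = apply_filters(rec, self.band).data[0]
        xc = np.correlate(out, burst, mode="full")
        assert np.argmax(xc) == n - 1  # zero lag

    def test_output_length_preserved(self, noise_recording):
        out = apply_filters(noise_recording, self.band)
        assert out.n_samples == noise_recording.n_samples


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))
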