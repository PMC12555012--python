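import dataclasses

import numpy as np
import pytest

import oracles
from hfokit.detect import (
    Event,
    HilbertConfig,
    MNIConfig,
    STEConfig,
    detect_hilbert,
    detect_mni,
    detect_ste,
    merge_close_events,
    run_detector,
)
from hfokit.eeg_io import Recording, bandpass_filter
from hfokit.match import overlap_fraction
from hfokit.synth import (
    InjectionParams,
    SynthConfig,
    inject_event,
    make_background,
    synthesize_recording,
)

FS = 2000.0


def _flat_recording(seconds=10.0):
    return Recording(["A"], FS, np.zeros((1, int(seconds * FS))))


def _noise_channel(seed, seconds=10.0):
    cfg = SynthConfig(n_channels=1, duration_s=seconds, seed=seed,
                      hfo_rate=0, spk_hfo_rate=0, artifact_rate=0)
    rec, _ = synthesize_recording(cfg)
    return rec


class TestMergeCloseEvents:
    def test_small_gap_merges(self):
        evs = [Event("A", 0, 100, fs=FS), Event("A", 105, 200, fs=FS)]
        assert merge_close_events(evs, 10e-3) == [Event("A", 0, 200, fs=FS)]

    def test_large_gap_kept(self):
        evs = [Event("A", 0, 100, fs=FS), Event("A", 150, 200, fs=FS)]
        assert merge_close_events(evs, 10e-3) == evs

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        evs = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(5, 60))
            end = pos + int(rng.integers(5, 40))
            evs.append(Event("A", pos, end, fs=FS))
            pos = end
        once = merge_close_events(evs, 10e-3)
        assert merge_close_events(once, 10e-3) == once

    def test_channels_independent(self):
        evs = [Event("A", 0, 100, fs=FS), Event("B", 105, 200, fs=FS)]
        assert merge_close_events(evs, 10e-3) == sorted(evs)


class TestHilbert:
    def test_flat_channel_no_events(self):
        assert len(detect_hilbert(_flat_recording())) == 0

    def test_injected_burst_recovered(self):
        """One high-SNR 100 ms ripple in 60 s pink noise -> exactly one event
        overlapping the injection; interval equals the brute-force oracle's."""
        bg = _noise_channel(seed=5, seconds=60.0)
        params = InjectionParams(start=60_000, snr_db=12.0, carrier_hz=150.0,
                                 duration_s=0.1)
        rec, truth = inject_event(bg, "CH1", "hfo", params)
        events = list(detect_hilbert(rec))
        assert len(events) == 1
        t_ev = Event(truth.channel, truth.start, truth.end, fs=FS)
        assert overlap_fraction(events[0], t_ev) >= 0.5
        band = bandpass_filter(rec.data[0], 80, 500, FS)
        cfg = HilbertConfig()
        expected = oracles.hilbert_events(band, FS, cfg.sd_thres, cfg.min_window,
                                          cfg.epoch_len, cfg.min_gap)
        assert [(e.start, e.end) for e in events] == expected

    def test_close_bursts_merge(self):
        """Two 30 ms constant-amplitude bursts 5 ms apart merge under the
        10 ms min_gap (the gap between threshold runs is < 20 samples)."""
        bg = _noise_channel(seed=6, seconds=30.0)
        x = bg.data[0].copy()
        burst = int(0.03 * FS)
        gap = int(0.005 * FS)
        t = np.arange(burst) / FS
        tone = 25 * np.sin(2 * np.pi * 200 * t)
        x[20_000:20_000 + burst] += tone
        x[20_000 + burst + gap:20_000 + 2 * burst + gap] += tone
        rec = Recording(["CH1"], FS, x[np.newaxis])
        events = [e for e in detect_hilbert(rec) if abs(e.start - 20_000) < 400]
        assert len(events) == 1
        assert events[0].end - events[0].start >= 2 * burst

    def test_threshold_monotonicity(self):
        rec = _noise_channel(seed=8, seconds=60.0)
        counts = [len(detect_hilbert(rec, HilbertConfig(sd_thres=s)))
                  for s in (3.0, 3.5, 4.0, 4.5, 5.0)]
        assert counts == sorted(counts, reverse=True)


class TestSTE:
    def test_flat_channel_no_events(self):
        assert len(detect_ste(_flat_recording())) == 0

    def test_high_snr_ripple_recovered(self):
        """An 80 ms ripple (12 cycles at 150 Hz) passes the peak-count rule."""
        bg = _noise_channel(seed=9, seconds=60.0)
        rec, truth = inject_event(bg, "CH1", "hfo",
                                  InjectionParams(start=50_000, snr_db=15,
                                                  carrier_hz=150, duration_s=0.08))
        t_ev = Event(truth.channel, truth.start, truth.end, fs=FS)
        hits = [e for e in detect_ste(rec) if overlap_fraction(e, t_ev) > 0]
        assert len(hits) == 1

    def test_single_cycle_rejected_by_peak_count(self):
        """A one-cycle transient cannot produce the six required rectified
        peaks: the candidate passes the RMS stage (detected with min_peaks=1)
        but is rejected at the default min_peaks=6."""
        bg = _noise_channel(seed=10, seconds=30.0)
        rec, _ = inject_event(bg, "CH1", "hfo",
                              InjectionParams(start=30_000, snr_db=16, carrier_hz=250,
                                              duration_s=0.004))  # one 250 Hz cycle
        near = lambda evl: [e for e in evl if abs(e.start - 30_000) < 200]
        assert near(detect_ste(rec)) == []
        assert len(near(detect_ste(rec, STEConfig(min_peaks=1)))) == 1


class TestMNI:
    def test_flat_channel_no_events(self):
        evl = detect_mni(_flat_recording())
        assert len(evl) == 0
        assert evl.meta["branches"]["A"] == "flat"

    def test_noise_baseline_branch_matches_oracle(self):
        """Stationary noise provides baseline; event set equals the oracle's."""
        rec = _noise_channel(seed=11, seconds=10.0)
        cfg = MNIConfig(base_min=2.0, thrd_perc=99.9)
        evl = detect_mni(rec, cfg)
        assert evl.meta["branches"]["CH1"] == "baseline"
        band = bandpass_filter(rec.data[0], 80, 500, FS)
        expected, branch = oracles.mni_events(
            band, FS, cfg.min_window, cfg.min_gap, cfg.thrd_perc, cfg.base_seg,
            cfg.base_thrd, cfg.base_min, cfg.epoch_chf, cfg.per_chf)
        assert branch == "baseline"
        assert [(e.start, e.end) for e in evl] == expected

    def test_burst_train_takes_iterative_branch(self):
        """Repeated high-energy bursts leave too little baseline; the iterative
        branch is taken and still returns events."""
        fs = FS
        n = int(10 * fs)
        t = np.arange(n) / fs
        x = 0.05 * np.sin(2 * np.pi * 140 * t)  # weak carrier keeps entropy low
        for k in range(40):  # a burst every 250 ms
            s = int(k * 0.25 * fs)
            e = s + int(0.05 * fs)
            x[s:e] += 30 * np.sin(2 * np.pi * 200 * t[s:e])
        rec = Recording(["A"], fs, x[np.newaxis])
        cfg = MNIConfig(base_min=5.0)
        evl = detect_mni(rec, cfg)
        assert evl.meta["branches"]["A"] == "iterative"
        assert len(evl) > 0


class TestRunDetector:
    def test_parallel_invariance(self, event_recording):
        rec, _ = event_recording
        serial = run_detector(rec, "hilbert", n_jobs=1)
        parallel = run_detector(rec, "hilbert", n_jobs=4)
        assert serial.events == parallel.events
        assert serial.config == parallel.config

    def test_unknown_detector_names_options(self, noise_recording):
        with pytest.raises(ValueError, match="hilbert"):
            run_detector(noise_recording, "foo")

    def test_empty_recording(self):
        rec = Recording([], FS, np.zeros((0, 100)))
        assert len(run_detector(rec, "ste")) == 0

    def test_config_snapshot_stored(self, noise_recording):
        cfg = HilbertConfig(sd_thres=6.0)
        out = run_detector(noise_recording, "hilbert", cfg)
        assert out.config == dataclasses.asdict(cfg)
        assert out.detector == "hilbert"


@pytest.mark.parametrize("seed", range(5))
def test_oracle_equivalence_all_detectors(seed):
    """Each detector's event set equals the independent brute-force run
    enumeration exactly, on dense 10 s single-channel synthetic signals
    (small epochs exercise the epoch-seam handling)."""
    cfg = SynthConfig(n_channels=1, duration_s=10.0, seed=seed,
                      hfo_rate=12, spk_hfo_rate=6, artifact_rate=6)
    rec, _ = synthesize_recording(cfg)
    band = bandpass_filter(rec.data[0], 80, 500, rec.fs)

    hc = HilbertConfig(epoch_len=3.0)
    assert [(e.start, e.end) for e in detect_hilbert(rec, hc)] == oracles.hilbert_events(
        band, rec.fs, hc.sd_thres, hc.min_window, hc.epoch_len, hc.min_gap)

    sc = STEConfig(epoch_len=4.0)
    assert [(e.start, e.end) for e in detect_ste(rec, sc)] == oracles.ste_events(
        band, rec.fs, sc.rms_window, sc.rms_thres, sc.min_window, sc.min_gap,
        sc.peak_thres, sc.min_peaks, sc.epoch_len)

    mc = MNIConfig(base_min=2.0, epoch_chf=5.0)
    evl = detect_mni(rec, mc)
    expected, branch = oracles.mni_events(
        band, rec.fs, mc.min_window, mc.min_gap, mc.thrd_perc, mc.base_seg,
        mc.base_thrd, mc.base_min, mc.epoch_chf, mc.per_chf)
    assert [(e.start, e.end) for e in evl] == expected
    assert evl.meta["branches"]["CH1"] == branch
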