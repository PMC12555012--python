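# Methods

`hfokit` is a headless toolkit for detecting and classifying high-frequency
oscillations (HFOs) — transient 80–500 Hz events in intracranial EEG that are
studied as a biomarker of epileptogenic tissue — and for relating detected
events to surgical outcome. This note documents the models, conventions and
numerical choices behind each stage, what the synthetic test bed does and
does not emulate, and the known limitations.

## Signal model and conventions

Signals are stored in microvolts as `(channels, samples)` float arrays with a
single sampling rate (2000 Hz in all defaults). Sample indices are 0-based,
intervals half-open `[start, end)`, and seconds are `samples / fs`. EDF is
the interchange format: reading goes through MNE, writing through a compact
16-bit writer (1-second records, symmetric physical range chosen from the
data), so the worst-case round-trip error is `phys_range / 2**16` per
sample — about 0.003 µV for a typical synthetic recording.

Filtering is a 4th-order Butterworth band-pass applied forward–backward
(`sosfiltfilt`), i.e. zero-phase with effective order 8. Zero-phase matters
because event boundaries are read off threshold crossings of the filtered
trace; a causal filter would bias every onset late. Power-line removal is a
second-order IIR notch (Q = 30) at the fundamental, with harmonics optional;
after the 80 Hz high-pass edge, residual harmonics below the band are
irrelevant to HFO detection.

## Detectors

All three detectors share one skeleton: band-pass to `filter_freq` (default
[80, 500] Hz), compute a per-sample activation series, threshold it, keep
maximal above-threshold runs lasting at least `min_window` (default 10 ms),
and merge events separated by less than `min_gap` (default 10 ms). Shared
tie/degenerate rules: activation exactly at the threshold counts as above;
a flat (zero-variance) channel or epoch produces no events; NaN samples
invalidate their epoch. Epochs are processed independently and events merged
across epoch seams afterwards; a trailing partial epoch shorter than
`2*min_window` is absorbed into the previous epoch, otherwise it carries its
own statistics. Epoch mean/SD are computed over the full epoch including
event samples — the simplest reading of an "SD threshold" — which is why the
synthetic generator keeps event rates sparse (see below): dense high-energy
events would inflate the epoch SD and effectively raise the threshold.

* **Hilbert** (defaults: `sd_thres` 5 SD, `min_window` 10 ms, `epoch_len`
  3600 s): activation is the magnitude of the analytic signal, z-scored per
  epoch.
* **STE** (defaults: 3 ms RMS window, 5 SD RMS threshold, 6 ms minimum
  duration, 3 SD peak threshold, ≥ 6 rectified peaks, 600 s epochs — the
  classical short-term-energy parameterization): activation is a centered
  sliding-window RMS; each candidate must additionally contain at least
  `min_peaks` strict local maxima of the rectified trace above
  mean + `peak_thres`·SD, which rejects isolated sharp transients that pass
  the energy test but do not oscillate.
* **MNI-style** (defaults: 125 ms baseline segments, entropy fraction 0.67,
  5 s minimum baseline, 99.9999th percentile threshold, 60 s iterative
  windows at the 95th percentile): the channel is segmented and each
  segment's spectral entropy (Shannon entropy of its normalized power
  spectrum, DC excluded) is compared against `base_thrd` of the theoretical
  maximum `log K`; high-entropy (noise-like) segments accumulate as
  baseline. With enough baseline, the event threshold is a high percentile
  of the activation restricted to baseline samples, applied channel-wide.
  With too little baseline (continuously oscillating channels), an iterative
  scheme runs per 60 s window: threshold at the `per_chf` percentile of the
  not-yet-marked samples, mark everything above it, recompute on the
  remainder (at most 10 rounds, so the threshold relaxes toward the
  background level), then apply the duration filter to the final mask. The
  branch taken per channel is reported in `EventList.meta["branches"]`.

The detectors' exact semantics are pinned by brute-force oracles in the test
suite — plain sample-by-sample loop implementations that must reproduce every
event boundary exactly on dense 10 s signals.

Channel-parallel dispatch (`run_detector(..., n_jobs=N)`) is a pure map over
channels, so results are identical for every `N`.

## Event matching

Two event sets are compared per channel by one-to-one greedy matching in
order of descending interval overlap (ties: earlier start). The default
overlap measure is Jaccard — intersection over union of the sample
intervals — the symmetric and strictest common convention;
intersection-over-minimum and intersection-over-reference are available.
From a single matching, counts are tallied at three levels: exact (identical
start and end), ≥ 0.90 and ≥ 0.50. On instances with ≤ 8 events per side the
greedy matched count at 0.5 is checked against an exhaustive
maximum-cardinality matching; no counterexample has been observed under the
test distributions.

## Event images

Each event becomes a 224×224 time–frequency image: a 2 s window of the raw
trace centered on the event midpoint (reflection-padded at recording edges)
is transformed with complex Morlet (Gabor) wavelets — 7 cycles — at 224
linearly spaced frequencies from 10 to 500 Hz; the outer 0.5 s on each side
is cropped (discarding the filter's worst edge effects and centering the
event in the retained 1 s), and the magnitude map is bilinearly resized to
224×224 and min–max normalized to [0, 1]. Wavelet rows are rescaled by
`sqrt(f)` to undo the L2 wavelet normalization, so a pure tone peaks at the
frequency bin nearest its carrier rather than being biased low. Min–max
normalization makes images invariant to overall signal scale, which is why
classifiers see morphology, not amplitude. The model input is the image
duplicated across three channels (3×224×224).

## Classifier cascade, training, distillation

Classification is a three-stage cascade: an artifact model labels every
event; spkHFO (spike-coupled) and eHFO (epileptogenic) models run only on
the surviving non-artifact ("real") events. Counts therefore always satisfy
`n_artifact + n_real = n_total`, `n_spk ≤ n_real`, `n_ehfo ≤ n_real`.
Decisions are argmax with ties resolved toward the non-pathological label;
the threshold is configurable.

The trainable reference model is a deliberately compact pipeline — 4×4
block-average pooling of the scalogram (56×56 patches), standardization, and
a two-hidden-layer perceptron (128, 64) with a softmax head — sharing the
exact input contract, checkpoint format and cascade semantics of any
user-supplied model while training in seconds on one CPU. It is a reference
implementation for the pipeline, not a reproduction of any published
clinical model, and its accuracies on synthetic data say nothing about
clinical performance. Checkpoints are joblib files with a format tag,
version, and declared input shape (checked at load). Model sources are
`local:<path>` or `registry:<id>`; the registry interface is a local
directory with a cache, so no code path touches the network.

Distillation trains a fresh student on the teacher's argmax pseudo-labels
(hard labels — the minimal reading of pseudo-label distillation); a
`soft` flag weights training samples by teacher confidence instead. The
reported metric is teacher–student agreement on a held-out quarter of the
image pool. Distillation aborts with a diagnostic if the teacher collapses
to a single class.

## Synthetic data

The generator emulates the kind of corpus the pipeline targets — multi-minute
multi-channel 2000 Hz recordings — as 1/f^α Gaussian background
(spectrally shaped white noise, α = 1) calibrated to unit SD in the
80–500 Hz band, plus Poisson-placed events with a 0.25 s guard band and 1 s
edge margins, rejection-resampled to avoid overlap. Event types:

* **hfo** — Hann-windowed sinusoid, carrier 90–400 Hz, support 50–100 ms.
  The ground-truth interval is the half-amplitude (FWHM) support of the
  envelope, the central half of the burst.
* **spk_hfo** — the same burst plus a biphasic transient (difference of two
  Gaussians, width 50 ms) four times its size, emulating spike-coupled HFOs.
* **artifact** — a sharp (4 ms) biphasic impulse, hence broadband.

Amplitudes are set by an in-band envelope SNR: `snr_db = 10·log10(mean
in-band envelope of the injected component over its ground-truth window /
SD of the background in-band envelope)`. The decibel is power-style on the
envelope ratio — the envelope is exactly the statistic the Hilbert detector
thresholds, so 0 dB places an event at one background-envelope SD and
12 dB (the default lower edge) at ≈ 16 SD, comfortably above the 5 SD
detection threshold. Amplitude calibration is numerical (the unit waveform
is band-passed and its envelope measured), so it is consistent across event
types. Default rates (1.5 / 1.0 / 0.5 events per channel-minute for
hfo / spkHFO / artifact) are in the clinically sparse regime; this also
keeps epoch statistics from being dominated by the events themselves.

What the generator does **not** emulate: spatial correlation across
channels, non-stationary background (sleep stages, seizures), physiological
ripples vs pathological ones, electrode-specific noise, or line noise.
Passing tests therefore demonstrate the pipeline's internal correctness and
its behavior under controlled SNR — not clinical detection accuracy.

## Outcome analysis

The resection ratio of a patient is the fraction of their detected events
lying on surgically resected channels; patients with zero events are
excluded explicitly (the ratio is undefined). Seizure freedom is regressed
on the ratio with an in-house maximum-likelihood logistic fit:
damped Newton–Raphson iterations to gradient norm < 1e-8, with a
closed-form intercept-only null. Significance defaults to the
likelihood-ratio test (χ², 1 df); Wald is available. Complete separation is
detected up front and flagged — the unpenalized MLE is unbounded there, and
a small ridge fallback gives a finite estimate when requested. A constant
predictor returns slope 0 and p = 1 rather than a singular solve.
Discrimination is summarized by the ROC area computed by trapezoidal
integration of the tie-collapsed ROC curve, which realizes the midpoint
(tie = 0.5) convention and equals the normalized Mann–Whitney U statistic.
Because outcome cohorts in this field are small (tens of patients),
validation is by synthetic parameter recovery: a true log-odds slope of 1.0
in a balanced n = 500 design is recovered within the Fisher-information
sampling band, and null p-values are uniform.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design: oracle
equivalence on 50 dense 10 s single-channel signals; injection recovery on
ten 4-channel 150 s recordings (≥ 200 events); classifier work on a pool of
2000 event images (train 400, distill 2000); 500 simulations for p-value
uniformity. Images are held in float32; wavelet transforms are chunked
(32 segments per pass) to bound the complex work buffer. All randomness
flows from explicit integer seeds; detectors, images, training and
distillation are bit-reproducible given the seed.

## Known limitations

* EDF support covers the plain 16-bit dialect with one sampling rate across
  analyzed channels; EDF+ discontinuous records, BDF and CNT are out of
  scope. BrainVision reading, where needed, can go through MNE directly.
* The MNI-style detector follows the published outline (entropy baseline +
  percentile thresholds); parameter-level fidelity to any specific legacy
  implementation is not claimed, and its exact semantics are therefore
  pinned by this package's own oracles.
* The reference classifier is a stand-in for externally trained deep
  models; published clinical accuracies cannot be reproduced without the
  original weights and patient data and are not targets here.
* Matching assumes both event sets come from the same recording at the same
  sampling rate.
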