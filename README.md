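# hfokit

Headless Python toolkit for **high-frequency oscillation (HFO) analysis in
intracranial EEG**: detection, time–frequency event imaging, deep-learning-style
classification cascades, cross-detector comparison, and surgical-outcome
statistics — with a seeded synthetic-iEEG generator as a built-in test bed.

HFOs are transient 80–500 Hz oscillations (ripples ~80–250 Hz, fast ripples
~250–500 Hz) recorded from grid/strip or depth electrodes in patients with
drug-resistant epilepsy. They are studied as a biomarker of epileptogenic
tissue: resecting HFO-generating regions correlates with better postoperative
seizure outcome. `hfokit` is aimed at researchers who need the computational
pipeline around this biomarker — reproducible detectors, standardized
classifier inputs, and outcome models — without a GUI.

## What's inside

| Module | Contents |
|---|---|
| `hfokit.eeg_io` | `Recording` container (µV), EDF read/write, bipolar montage, channel selection, zero-phase band-pass + power-line notch |
| `hfokit.detect` | Three detectors — short-term energy (STE), MNI-style entropy-baseline, Hilbert envelope — with channel-parallel dispatch |
| `hfokit.match` | One-to-one interval-overlap matching of two event sets (exact / ≥90% / ≥50% accounting) |
| `hfokit.features` | 224×224 Morlet-scalogram event images, the standardized classifier input |
| `hfokit.classify` | Artifact → spkHFO → eHFO cascade, trainable reference model, checkpoints, registry sources, teacher–student distillation |
| `hfokit.synth` | Seeded 1/f background + injected HFOs / spike-HFOs / artifacts with ground truth, EDF + CSV export |
| `hfokit.outcome` | Resection ratio, maximum-likelihood logistic outcome model (LRT/Wald), ROC/AUC |
| `hfokit.session` | Versioned NPZ result archives, XLSX export/import, annotation records, the quick-detect pipeline |
| `hfokit.cli` | `hfokit quick-detect / synth / match / outcome` |

The core detection statistic of the Hilbert detector is the z-scored analytic
envelope: with band-passed signal x(t), envelope `e(t) = |x(t) + i·H[x](t)]|`,
an event is a maximal run of `(e − μ)/σ ≥ s` lasting at least `min_window`,
where μ, σ are epoch statistics and `s` = 5 SD by default; nearby events merge
below `min_gap`. STE thresholds a 3 ms sliding RMS at mean + 5 SD and demands
≥ 6 rectified peaks above mean + 3 SD; the MNI-style detector thresholds band
energy at the 99.9999th percentile of entropy-selected baseline, falling back
to an iterative 95th-percentile scheme where no baseline exists. See
`docs/methods.md` for the full conventions.

## Worked example

Generate five minutes of synthetic iEEG, detect with the Hilbert detector,
and score against ground truth:

```python
from hfokit import (SynthConfig, synthesize_recording, detect_hilbert,
                    Event, match_events)

rec, truth = synthesize_recording(SynthConfig(n_channels=4, duration_s=300, seed=1))
detected = detect_hilbert(rec)   # defaults: [80,500] Hz, 5 SD, 10 ms, 3600 s epochs

truth_hfos = [Event(t.channel, t.start, t.end, fs=t.fs)
              for t in truth if t.type in ("hfo", "spk_hfo")]
rep = match_events(truth_hfos, list(detected))
print(f"injected HFOs: {rep.total_a}   detected events: {rep.total_b}")
print(f"matched at >=50% overlap: {rep.n_50}   at >=90%: {rep.n_90}")
```

prints

```
injected HFOs: 47   detected events: 54
matched at >=50% overlap: 47   at >=90%: 17
```

All 47 injected oscillations are recovered at the ≥50% Jaccard criterion
(the extra detections are the injected broadband artifacts — which is
expected: artifacts are meant to be detected and then removed by the
classifier stage, not missed by the detector). The same pipeline runs from
the shell:

```bash
hfokit synth --out rec.edf --channels 4 --duration 300 --seed 1
hfokit quick-detect --input rec.edf --detector hilbert --band 80 500 --out run.npz
```

## Scope notes

The package is offline/batch only; it does not render GUIs, stream data, or
ship clinical model weights. The reference classifier is a compact stand-in
exercising the same contracts as externally trained deep models — see
`docs/methods.md` for what synthetic results do and do not demonstrate.
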