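"""Independent brute-force oracles used to cross-check the detectors and
statistics.  Everything here is written as plain sample-by-sample loops with
no code shared with the package, mirroring the documented detection
semantics: threshold ties count as above-threshold, a run qualifies at
length >= round(min_window*fs), and events merge at gaps < round(min_gap*fs).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert as _hilbert


def enumerate_runs(mask) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def merge_intervals(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s - out[-1][1] < gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def epoch_bounds(n: int, fs: float, epoch_len: float, min_window: float) -> list[tuple[int, int]]:
    step = int(round(epoch_len * fs))
    if n == 0:
        return []
    bounds = []
    lo = 0
    while lo < n:
        bounds.append((lo, min(lo + step, n)))
        lo += step
    if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < 2 * int(round(min_window * fs)):
        last = bounds.pop()
        bounds[-1] = (bounds[-1][0], last[1])
    return bounds


def sliding_rms_same(x: np.ndarray, w: int) -> np.ndarray:
    """Centered sliding RMS with numpy-'same' alignment, computed by loop."""
    n = len(x)
    x2 = [float(v) * float(v) for v in x]
    full = [0.0] * (n + w - 1)
    for j in range(n + w - 1):
        acc = 0.0
        for k in range(max(0, j - w + 1), min(n, j + 1)):
            acc += x2[k]
        full[j] = acc / w
    off = (w - 1) // 2
    return np.sqrt(np.array(full[off:off + n]))


def hilbert_events(band: np.ndarray, fs: float, sd_thres: float, min_window: float,
                   epoch_len: float, min_gap: float) -> list[tuple[int, int]]:
    """Brute-force Hilbert-envelope detector on an already band-passed trace."""
    min_len = max(1, int(round(min_window * fs)))
    events: list[tuple[int, int]] = []
    for lo, hi in epoch_bounds(len(band), fs, epoch_len, min_window):
        env = np.abs(_hilbert(band[lo:hi]))
        sd = env.std()
        if sd == 0:
            continue
        mu = env.mean()
        mask = [(v - mu) / sd >= sd_thres for v in env]
        for s, e in enumerate_runs(mask):
            if e - s >= min_len:
                events.append((lo + s, lo + e))
    return merge_intervals(events, int(round(min_gap * fs)))


def ste_events(band: np.ndarray, fs: float, rms_window: float, rms_thres: float,
               min_window: float, min_gap: float, peak_thres: float, min_peaks: int,
               epoch_len: float) -> list[tuple[int, int]]:
    """Brute-force short-term-energy detector on a band-passed trace."""
    min_len = max(1, int(round(min_window * fs)))
    gap = int(round(min_gap * fs))
    w = max(1, int(round(rms_window * fs)))
    events: list[tuple[int, int]] = []
    for lo, hi in epoch_bounds(len(band), fs, epoch_len, min_window):
        seg = band[lo:hi]
        rms = sliding_rms_same(seg, w)
        if rms.std() == 0:
            continue
        thr = rms.mean() + rms_thres * rms.std()
        candidates = [(s, e) for s, e in enumerate_runs([v >= thr for v in rms])
                      if e - s >= min_len]
        candidates = merge_intervals(candidates, gap)
        rect = np.abs(seg)
        peak_thr = rect.mean() + peak_thres * rect.std()
        for s, e in candidates:
            count = 0
            for i in range(max(s, 1), min(e, len(rect) - 1)):
                if rect[i] > rect[i - 1] and rect[i] > rect[i + 1] and rect[i] >= peak_thr:
                    count += 1
            if count >= min_peaks:
                events.append((lo + s, lo + e))
    return merge_intervals(events, gap)


def spectral_entropy(seg: np.ndarray) -> tuple[float, float]:
    power = np.abs(np.fft.rfft(seg))[1:] ** 2
    h_max = np.log(len(power)) if len(power) > 1 else 1.0
    total = float(power.sum())
    if total <= 0:
        return 0.0, h_max
    h = 0.0
    for v in power:
        p = float(v) / total
        if p > 0:
            h -= p * np.log(p)
    return h, h_max


def mni_events(band: np.ndarray, fs: float, min_window: float, min_gap: float,
               thrd_perc: float, base_seg: float, base_thrd: float, base_min: float,
               epoch_chf: float, per_chf: float) -> tuple[list[tuple[int, int]], str]:
    """Brute-force MNI-style detector; returns (events, branch)."""
    if band.std() == 0:
        return [], "flat"
    min_len = max(1, int(round(min_window * fs)))
    gap = int(round(min_gap * fs))
    energy = sliding_rms_same(band, min_len)

    seg_len = max(2, int(round(base_seg * fs)))
    baseline = [False] * len(band)
    s = 0
    while s + seg_len <= len(band):
        h, h_max = spectral_entropy(band[s:s + seg_len])
        if h >= base_thrd * h_max:
            for i in range(s, s + seg_len):
                baseline[i] = True
        s += seg_len

    if sum(baseline) / fs >= base_min:
        pool = [energy[i] for i in range(len(energy)) if baseline[i]]
        thr = np.percentile(pool, thrd_perc)
        runs = [(a, b) for a, b in enumerate_runs([v >= thr for v in energy])
                if b - a >= min_len]
        return merge_intervals(runs, gap), "baseline"

    events: list[tuple[int, int]] = []
    step = int(round(epoch_chf * fs))
    for lo in range(0, len(band), step):
        hi = min(lo + step, len(band))
        e_win = energy[lo:hi]
        active = [True] * (hi - lo)
        marked = [False] * (hi - lo)
        for _ in range(10):
            pool = [e_win[i] for i in range(len(e_win)) if active[i]]
            if len(pool) < 2:
                break
            hit = False
            thr = np.percentile(pool, per_chf)
            for i in range(len(e_win)):
                if active[i] and e_win[i] >= thr:
                    marked[i] = True
                    active[i] = False
                    hit = True
            if not hit:
                break
        for a, b in enumerate_runs(marked):
            if b - a >= min_len:
                events.append((lo + a, lo + b))
    return merge_intervals(events, gap), "iterative"


# ---------------------------------------------------------------------------
# Matching and statistics oracles


def max_cardinality_overlap_matching(pairs_overlap: dict[tuple[int, int], float],
                                     n_a: int, n_b: int, threshold: float) -> int:
    """Maximum one-to-one matching count over pairs with overlap >= threshold,
    by exhaustive augmenting-path search (instances are tiny)."""
    adj = {i: [j for j in range(n_b)
               if pairs_overlap.get((i, j), 0.0) >= threshold] for i in range(n_a)}
    match_b: dict[int, int] = {}

    def try_assign(i: int, seen: set[int]) -> bool:
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if j not in match_b or try_assign(match_b[j], seen):
                match_b[j] = i
                return True
        return False

    count = 0
    for i in range(n_a):
        if try_assign(i, set()):
            count += 1
    return count


def auc_mann_whitney(scores, labels) -> float:
    """AUC via the Mann-Whitney identity with explicit pair counting."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def logistic_grid_fit(x, y, b0_range=(-6, 6), b1_range=(-12, 12), coarse=241) -> tuple[float, float]:
    """Maximize the logistic log-likelihood on successively refined grids."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def ll(b0, b1):
        z = b0 + b1 * x
        return float(np.sum(y * z - np.logaddexp(0.0, z)))

    lo0, hi0 = b0_range
    lo1, hi1 = b1_range
    best = (0.0, 0.0)
    for _ in range(6):
        g0 = np.linspace(lo0, hi0, coarse)
        g1 = np.linspace(lo1, hi1, coarse)
        vals = [(ll(b0, b1), b0, b1) for b0 in g0 for b1 in g1]
        _, b0, b1 = max(vals)
        best = (b0, b1)
        span0 = (hi0 - lo0) / coarse * 4
        span1 = (hi1 - lo1) / coarse * 4
        lo0, hi0 = b0 - span0, b0 + span0
        lo1, hi1 = b1 - span1, b1 + span1
    return best
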