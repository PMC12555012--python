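"""Overlap-based comparison of two event sets.

Used to benchmark one detector run against another (e.g. against a reference
implementation): events are paired one-to-one per channel, greedily by
descending interval overlap, and the pairing is tallied at the 100% ("exactly
same"), 90% and 50% overlap levels.  The default overlap measure is Jaccard
(intersection over union), the symmetric and strictest of the common
conventions; intersection-over-minimum and intersection-over-reference are
available behind ``denominator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from hfokit.detect import Event, EventList

__all__ = ["MatchReport", "overlap_fraction", "match_events", "report_to_frame"]

Denominator = Literal["union", "min", "reference"]


@dataclass
class MatchReport:
    """Counts of matched events between sets A and B at fixed overlap levels.

    ``rel_diff_90_50`` is (n_50 - n_90) / n_90 (NaN when n_90 == 0), the
    fractional gain from relaxing the overlap criterion from 90% to 50%.
    """

    total_a: int
    total_b: int
    n_exact: int
    n_90: int
    n_50: int

    @property
    def new_a(self) -> int:
        return self.total_a - self.n_50

    @property
    def new_b(self) -> int:
        return self.total_b - self.n_50

    @property
    def rel_diff_90_50(self) -> float:
        if self.n_90 == 0:
            return math.nan
        return (self.n_50 - self.n_90) / self.n_90


def overlap_fraction(a: Event, b: Event, denominator: Denominator = "union") -> float:
    """Overlap of two half-open sample intervals, in [0, 1].

    Events on different channels overlap 0 by contract.  ``denominator``:
    'union' (Jaccard, default), 'min' (intersection over shorter interval),
    'reference' (intersection over ``a``).
    """
    if a.channel != b.channel:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    if denominator == "union":
        denom = max(a.end, b.end) - min(a.start, b.start)
    elif denominator == "min":
        denom = min(a.end - a.start, b.end - b.start)
    elif denominator == "reference":
        denom = a.end - a.start
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return inter / denom


def _greedy_pairs(evs_a: list[Event], evs_b: list[Event],
                  denominator: Denominator) -> list[tuple[Event, Event, float]]:
    candidates = []
    for i, a in enumerate(evs_a):
        for j, b in enumerate(evs_b):
            f = overlap_fraction(a, b, denominator)
            if f > 0:
                candidates.append((f, a.start, b.start, i, j))
    # descending overlap; ties broken by earlier start (a then b)
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3], t[4]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for f, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((evs_a[i], evs_b[j], f))
    return pairs


def match_events(a: EventList | Iterable[Event], b: EventList | Iterable[Event],
                 denominator: Denominator = "union") -> MatchReport:
    """One-to-one greedy matching of two event sets, per channel.

    Pairs are chosen in order of descending overlap (ties: earlier start,
    then lexicographic channel order via per-channel processing); the same
    pairing is then counted at the exact (identical intervals), >= 0.90 and
    >= 0.50 overlap levels.
    """
    evs_a = list(a.events if isinstance(a, EventList) else a)
    evs_b = list(b.events if isinstance(b, EventList) else b)
    by_ch_a: dict[str, list[Event]] = {}
    by_ch_b: dict[str, list[Event]] = {}
    for e in evs_a:
        by_ch_a.setdefault(e.channel, []).append(e)
    for e in evs_b:
        by_ch_b.setdefault(e.channel, []).append(e)

    n_exact = n_90 = n_50 = 0
    for channel in sorted(set(by_ch_a) & set(by_ch_b)):
        for pa, pb, f in _greedy_pairs(by_ch_a[channel], by_ch_b[channel], denominator):
            if f < 0.5:
                continue
            n_50 += 1
            if f >= 0.9:
                n_90 += 1
            if pa.start == pb.start and pa.end == pb.end:
                n_exact += 1
    return MatchReport(total_a=len(evs_a), total_b=len(evs_b),
                       n_exact=n_exact, n_90=n_90, n_50=n_50)


def report_to_frame(report: MatchReport, name_a: str = "A", name_b: str = "B") -> pd.DataFrame:
    """Render a MatchReport as a one-column table (benchmark-table layout)."""
    rows = {
        "Total A": report.total_a,
        "Total B": report.total_b,
        "Exactly Same": report.n_exact,
        "90% overlap": report.n_90,
        "50% overlap": report.n_50,
        f"new-{name_a}": report.new_a,
        f"new-{name_b}": report.new_b,
        "rel diff (n50-n90)/n90": report.rel_diff_90_50,
    }
    return pd.DataFrame({"value": rows})
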