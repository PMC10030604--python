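"""Interval (MaxInterval) burst detection for single-unit spike trains.

A burst is a short bundle of spikes with high internal frequency flanked
by silence.  The five-parameter interval algorithm used here opens a
candidate burst when an inter-spike interval (ISI) falls below a start
threshold, extends it while ISIs stay below an end threshold, merges
candidates separated by less than a minimum inter-burst interval, and
finally discards candidates that are too short or too sparse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["BurstParams", "Burst", "detect_bursts", "burst_rate"]


@dataclass(frozen=True)
class BurstParams:
    """Parameters of the interval burst detector (all times in seconds).

    Defaults are the widely used MaxInterval setting for cultured networks:
    20 ms max ISI to start a burst, 100 ms max ISI to end it, 100 ms minimum
    inter-burst interval, 20 ms minimum burst duration, minimum 2 spikes.
    """

    max_isi_start: float = 0.020
    max_isi_end: float = 0.100
    min_ibi: float = 0.100
    min_duration: float = 0.020
    min_spikes: int = 2

    def __post_init__(self) -> None:
        if min(self.max_isi_start, self.max_isi_end, self.min_ibi, self.min_duration) <= 0:
            raise ValueError("all burst parameters must be positive")
        if self.max_isi_start > self.max_isi_end:
            raise ValueError("max_isi_start must not exceed max_isi_end")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be at least 2")


@dataclass(frozen=True)
class Burst:
    """A detected burst: first-spike time, last-spike time, spike count."""

    start: float
    end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_bursts(spike_times: Sequence[float], params: BurstParams | None = None) -> list[Burst]:
    """Detect bursts in a strictly increasing spike train.

    The steps run in this fixed order:

    1. open a candidate at spike ``i`` when ``ISI(i, i+1) <= max_isi_start``;
    2. extend it while subsequent ISIs are ``<= max_isi_end``;
    3. merge consecutive candidates whose gap (next start - previous end)
       is ``< min_ibi``;
    4. discard candidates with duration ``< min_duration`` or fewer than
       ``min_spikes`` spikes.

    With the default parameters (``min_ibi == max_isi_end``) step 3 can
    never fire: any gap between candidates is an ISI that exceeded
    ``max_isi_end``.  The merge step matters for other parameter choices.
    """
    if params is None:
        params = BurstParams()
    t = np.asarray(spike_times, dtype=float)
    if t.ndim != 1:
        raise ValueError("spike_times must be one-dimensional")
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("spike_times must be strictly increasing")
    if len(t) < 2:
        return []

    isi = np.diff(t)
    # (1)+(2): maximal candidate runs
    cands: list[tuple[int, int]] = []  # inclusive spike-index ranges
    i = 0
    n = len(t)
    while i < n - 1:
        if isi[i] <= params.max_isi_start:
            j = i + 1
            while j < n - 1 and isi[j] <= params.max_isi_end:
                j += 1
            cands.append((i, j))
            i = j + 1
        else:
            i += 1

    # (3): merge candidates closer than the minimum inter-burst interval
    merged: list[tuple[int, int]] = []
    for c in cands:
        if merged and t[c[0]] - t[merged[-1][1]] < params.min_ibi:
            merged[-1] = (merged[-1][0], c[1])
        else:
            merged.append(c)

    # (4): duration and spike-count filters
    out = []
    for a, b in merged:
        if t[b] - t[a] >= params.min_duration and b - a + 1 >= params.min_spikes:
            out.append(Burst(start=float(t[a]), end=float(t[b]), n_spikes=b - a + 1))
    return out


def burst_rate(bursts: Sequence[Burst], window_start: float, window_end: float) -> float:
    """Bursts per second, counting bursts by start time in [start, end).

    A burst straddling a window edge is attributed once, to the window that
    contains its start.
    """
    if window_end <= window_start:
        raise ValueError("window must have positive length")
    n = sum(1 for b in bursts if window_start <= b.start < window_end)
    return n / (window_end - window_start)
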