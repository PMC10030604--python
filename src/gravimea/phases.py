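"""Gravity-phase schedules, safety margins, and unit x phase rate tables.

A recording from a drop-tower or centrifuge run is segmented into labelled
gravity phases (baseline, microgravity, ramp, hypergravity, ...).  Mean
firing and burst rates are computed per unit inside margin-trimmed analysis
windows, units silent in any phase are removed, and rates are log10
transformed for the downstream repeated-measures statistics (firing and
bursting rates of cultured networks are approximately lognormal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .bursts import BurstParams, burst_rate, detect_bursts

__all__ = [
    "Phase",
    "PhaseSchedule",
    "Window",
    "EmptyAnalysisError",
    "analysis_windows",
    "generation_segments",
    "firing_rate",
    "build_rate_table",
    "filter_silent_units",
    "log_transform",
    "PhaseRateTable",
    "segment_g_trace",
]


class EmptyAnalysisError(RuntimeError):
    """Raised when a filtering step removes every unit."""


class Window(NamedTuple):
    """Half-open analysis window [start, end) with its phase label."""

    label: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Phase:
    """One labelled gravity phase: half-open interval [start, end) at g_level.

    ``split=True`` marks long phases whose first and last minute are
    analysed separately (hypergravity and post-exposure baselines of the
    centrifuge protocol) to expose adaptation over the phase.
    """

    label: str
    start: float
    end: float
    g_level: float = 1.0
    split: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered, non-overlapping gravity phases plus a safety margin.

    The safety margin is trimmed from both ends of every phase before any
    rate is computed, so no spike near a phase transition can be attributed
    to the wrong gravity condition.
    """

    phases: tuple[Phase, ...]
    safety_margin: float = 0.0
    platform: str = "generic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if self.safety_margin < 0:
            raise ValueError("safety_margin must be >= 0")
        labels = [p.label for p in self.phases]
        if len(set(labels)) != len(labels):
            raise ValueError(f"phase labels not unique: {labels}")
        prev_end = -np.inf
        for p in self.phases:
            if p.end <= p.start:
                raise ValueError(f"phase {p.label!r} has non-positive duration")
            if p.start < prev_end:
                raise ValueError(f"phase {p.label!r} overlaps its predecessor")
            if p.duration <= 2 * self.safety_margin:
                raise ValueError(
                    f"phase {p.label!r} ({p.duration:g} s) shorter than twice "
                    f"the safety margin ({self.safety_margin:g} s)"
                )
            prev_end = p.end

    @property
    def total_duration(self) -> float:
        return self.phases[-1].end

    def phase(self, label: str) -> Phase:
        for p in self.phases:
            if p.label == label:
                return p
        raise KeyError(label)


def _split_sub_length(phase: Phase) -> float:
    # first/last minute of the parent phase, shrunk for compressed schedules
    return min(60.0, phase.duration / 3.0)


def analysis_windows(schedule: PhaseSchedule) -> list[Window]:
    """Margin-trimmed half-open analysis windows for every phase.

    Plain phases yield one window ``[start + m, end - m)``.  Split phases
    yield two windows, ``<label>1`` over the first minute and ``<label>2``
    over the last minute of the phase, each trimmed by the margin.
    """
    m = schedule.safety_margin
    out: list[Window] = []
    for p in schedule.phases:
        if p.split:
            sub = _split_sub_length(p)
            if sub <= 2 * m:
                raise ValueError(
                    f"margin {m:g} s too large for the {sub:g} s sub-windows "
                    f"of split phase {p.label!r}"
                )
            out.append(Window(p.label + "1", p.start + m, p.start + sub - m))
            out.append(Window(p.label + "2", p.end - sub + m, p.end - m))
        else:
            out.append(Window(p.label, p.start + m, p.end - m))
    return out


def generation_segments(schedule: PhaseSchedule) -> list[Window]:
    """Piecewise-constant-rate segments covering the schedule exactly.

    Used by the synthetic generator: split phases become three segments
    (``<label>1``, ``<label>_mid``, ``<label>2``) so the first- and
    last-minute analysis windows can be modulated independently.  No margin
    is applied; segments tile each phase.
    """
    out: list[Window] = []
    for p in schedule.phases:
        if p.split:
            sub = _split_sub_length(p)
            out.append(Window(p.label + "1", p.start, p.start + sub))
            if p.duration > 2 * sub:
                out.append(Window(p.label + "_mid", p.start + sub, p.end - sub))
            out.append(Window(p.label + "2", p.end - sub, p.end))
        else:
            out.append(Window(p.label, p.start, p.end))
    return out


def firing_rate(spike_times: Sequence[float], start: float, end: float) -> float:
    """Mean firing rate (Hz) over the half-open window [start, end)."""
    if end <= start:
        raise ValueError("window must have positive length")
    t = np.asarray(spike_times, dtype=float)
    n = np.searchsorted(t, end, side="left") - np.searchsorted(t, start, side="left")
    return float(n) / (end - start)


@dataclass
class PhaseRateTable:
    """Unit x phase matrices of firing and burst rates (Hz).

    ``firing`` and ``burst`` are DataFrames indexed by unit id with one
    column per analysis window.  ``log_firing``/``log_burst`` hold the
    log10-transformed twins once :func:`log_transform` has run.  The burst
    table may hold fewer units than the firing table after filtering: the
    burst analysis is additionally restricted to units that burst in every
    phase.
    """

    firing: pd.DataFrame
    burst: pd.DataFrame
    log_firing: pd.DataFrame | None = None
    log_burst: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)
    filtered: bool = False

    @property
    def phase_labels(self) -> list[str]:
        return list(self.firing.columns)

    @property
    def unit_ids(self) -> list:
        return list(self.firing.index)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format export: unit_id, phase, firing_rate_hz, burst_rate_hz."""
        f = self.firing.stack().rename("firing_rate_hz")
        b = self.burst.stack().rename("burst_rate_hz")
        tidy = pd.concat([f, b], axis=1).reset_index()
        tidy.columns = ["unit_id", "phase", "firing_rate_hz", "burst_rate_hz"]
        return tidy


def build_rate_table(
    units: Iterable,
    schedule: PhaseSchedule,
    burst_params: BurstParams | None = None,
) -> PhaseRateTable:
    """Firing and burst rates for every (unit, analysis window).

    ``units`` may be any objects exposing ``unit_id`` and ``spike_times``
    (sorted units from the sorter, or ground-truth units from the
    generator).  Bursts are detected once per unit over the whole train;
    windowed burst rates count bursts by their start time.
    """
    if burst_params is None:
        burst_params = BurstParams()
    windows = analysis_windows(schedule)
    labels = [w.label for w in windows]
    unit_list = list(units)
    ids = [u.unit_id for u in unit_list]
    f = np.zeros((len(unit_list), len(windows)))
    b = np.zeros_like(f)
    for i, u in enumerate(unit_list):
        bursts = detect_bursts(np.asarray(u.spike_times, dtype=float), burst_params)
        for j, w in enumerate(windows):
            f[i, j] = firing_rate(u.spike_times, w.start, w.end)
            b[i, j] = burst_rate(bursts, w.start, w.end)
    prov = {
        "platform": schedule.platform,
        "safety_margin_s": schedule.safety_margin,
        "windows": [(w.label, w.start, w.end) for w in windows],
        "burst_params": vars(burst_params).copy(),
        "n_units": len(unit_list),
        "filters": [],
    }
    return PhaseRateTable(
        firing=pd.DataFrame(f, index=ids, columns=labels),
        burst=pd.DataFrame(b, index=ids, columns=labels),
        provenance=prov,
    )


def filter_silent_units(table: PhaseRateTable) -> PhaseRateTable:
    """Drop units inactive in any phase; restrict the burst table likewise.

    A unit with zero firing rate in any analysis window is removed from the
    whole analysis (its silence may reflect an artifact rather than a
    response).  The burst-rate analysis is additionally restricted to units
    with at least one burst in every window, which is why published burst
    counts are much smaller than firing-rate counts.
    """
    keep_f = (table.firing > 0).all(axis=1)
    firing = table.firing.loc[keep_f]
    if firing.empty:
        raise EmptyAnalysisError("no unit is active in every phase")
    burst = table.burst.loc[keep_f]
    burst = burst.loc[(burst > 0).all(axis=1)]
    prov = dict(table.provenance)
    prov["filters"] = list(prov.get("filters", [])) + [
        {
            "rule": "remove units silent in any phase",
            "kept_firing": int(keep_f.sum()),
            "dropped_firing": int((~keep_f).sum()),
            "kept_burst": int(len(burst)),
        }
    ]
    return PhaseRateTable(firing=firing, burst=burst, provenance=prov, filtered=True)


def log_transform(table: PhaseRateTable) -> PhaseRateTable:
    """Entrywise log10 of the firing and burst rate matrices.

    Requires a filtered table (every firing entry positive); rates are
    lognormal-like, so the statistics run on the log scale.
    """
    if not table.filtered or (table.firing.to_numpy() <= 0).any():
        raise ValueError(
            "log_transform requires filter_silent_units to have run "
            "(all firing rates must be positive)"
        )
    return replace(
        table,
        log_firing=np.log10(table.firing),
        log_burst=np.log10(table.burst) if len(table.burst) else table.burst.copy(),
    )


def segment_g_trace(
    g: np.ndarray, sampling_rate: float, threshold: float = 1.05
) -> list[tuple[float, float]]:
    """Optional helper: intervals where a g-trace exceeds ``threshold``.

    Returns (start_s, end_s) pairs from threshold crossings of an
    accelerometer trace.  Preset schedules are authoritative; this exists
    for sanity-checking telemetry against the nominal timeline.
    """
    above = np.asarray(g) > threshold
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above)]
    return [(s / sampling_rate, e / sampling_rate) for s, e in zip(starts, ends)]
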