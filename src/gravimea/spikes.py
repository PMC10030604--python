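"""Spike detection, per-channel clustering into units, and quality curation.

A transparent in-repo sorter suited to 60-electrode MEAs where a unit's
footprint is confined to one electrode: spikes are detected as negative
threshold crossings at 4.5 x a robust (MAD-based) noise scale, aligned to
the local trough, reduced to three principal components, and partitioned
into at most three clusters per channel by k-means with silhouette model
selection.  Units are curated by ISI-violation rate, template SNR, and a
minimum spike count before entering the rate analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .recording import RawRecording

__all__ = [
    "SortedUnit",
    "WaveformMetrics",
    "estimate_noise_sigma",
    "detect_spikes",
    "extract_and_cluster",
    "isi_violation_rate",
    "compute_snr",
    "curate_units",
    "waveform_metrics",
    "sort_recording",
]

MAD_TO_SIGMA = 0.6745  # Phi^{-1}(0.75): MAD of a Gaussian is 0.6745 sigma


@dataclass
class SortedUnit:
    """A putative neuron: spike times, template, and quality metrics."""

    unit_id: int
    channel_id: int
    spike_times: np.ndarray  # s, strictly increasing
    template: np.ndarray  # µV, window around the trough
    snr: float = np.nan
    isi_violation_rate: float = np.nan
    accepted: bool | None = None
    rejection_reason: str = ""

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class WaveformMetrics:
    """Template shape descriptors: trough-to-peak amplitude and half width."""

    amplitude: float  # µV
    half_width: float  # ms, width of the trough lobe at half depth


def estimate_noise_sigma(trace: np.ndarray) -> float:
    """Robust Gaussian-consistent noise scale: MAD / 0.6745.

    Insensitive to spikes (which a standard deviation would inflate); for
    pure Gaussian noise it converges to the true sigma.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 1000:
        raise ValueError("need at least 1000 samples for a stable noise estimate")
    return float(np.median(np.abs(x - np.median(x))) / MAD_TO_SIGMA)


def detect_spikes(
    trace: np.ndarray,
    sigma: float,
    sampling_rate: float,
    threshold_multiplier: float = 4.5,
    dead_time: float = 0.001,
    exclude_edges_s: float = 0.0,
) -> np.ndarray:
    """Negative-going threshold crossings aligned to the local trough.

    A spike is registered where the trace drops below
    ``-threshold_multiplier * sigma``; consecutive sub-threshold samples
    form one event whose trough (minimum) defines the spike time.  No two
    detections are closer than ``dead_time``.  Returns times in seconds.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(trace, dtype=float)
    thr = -threshold_multiplier * sigma
    below = x < thr
    if not below.any():
        return np.empty(0)
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, len(x)]
    troughs = np.array([a + np.argmin(x[a:b]) for a, b in zip(starts, ends)])
    # enforce dead time between successive troughs
    kept: list[int] = []
    min_gap = dead_time * sampling_rate
    for i in troughs:
        if not kept or i - kept[-1] >= min_gap:
            kept.append(int(i))
    times = np.array(kept) / sampling_rate
    if exclude_edges_s > 0:
        total = len(x) / sampling_rate
        times = times[(times >= exclude_edges_s) & (times < total - exclude_edges_s)]
    return times


def _snippets(
    trace: np.ndarray, idx: np.ndarray, pre: int, post: int
) -> np.ndarray:
    """Waveform snippets around sample indices, zero-padded at the edges."""
    n = len(trace)
    out = np.zeros((len(idx), pre + post))
    for k, i in enumerate(idx):
        a, b = i - pre, i + post
        sa, sb = max(a, 0), min(b, n)
        out[k, sa - a : sa - a + (sb - sa)] = trace[sa:sb]
    return out


def extract_and_cluster(
    trace: np.ndarray,
    spike_times: np.ndarray,
    sampling_rate: float,
    channel_id: int = 0,
    pre_samples: int | None = None,
    post_samples: int | None = None,
    max_clusters: int = 3,
    min_silhouette: float = 0.6,
    random_state: int = 0,
) -> list[SortedUnit]:
    """Partition a channel's spikes into 1..K units by waveform shape.

    Snippets around each trough are reduced to 3 principal components and
    clustered with k-means for K = 2..``max_clusters``; the K with the best
    silhouette wins if that silhouette exceeds ``min_silhouette``,
    otherwise a single cluster is returned (poor separation never invents
    units).  The spike times are partitioned exhaustively: every detected
    spike belongs to exactly one returned unit.
    """
    t = np.asarray(spike_times, dtype=float)
    if len(t) < 1:
        raise ValueError("need at least one spike to extract waveforms")
    if pre_samples is None:
        pre_samples = int(round(0.5e-3 * sampling_rate))
    if post_samples is None:
        post_samples = int(round(1.1e-3 * sampling_rate))
    idx = np.round(t * sampling_rate).astype(int)
    x = np.asarray(trace, dtype=float)
    # Noise can shift the detected trough by +/-1 sample, and that jitter
    # shows up as spurious discrete clusters in PCA space.  Re-align each
    # snippet against the mean template by cross-correlation over small
    # integer shifts (whole-window matching averages the noise down, unlike
    # re-finding the noisy minimum).
    jitter = 2
    wide = _snippets(x, idx, pre_samples + jitter, post_samples + jitter)
    mean_tpl = wide[:, jitter:-jitter].mean(axis=0) if len(idx) > 1 else None
    if mean_tpl is not None and np.ptp(mean_tpl) > 0:
        width = pre_samples + post_samples
        scores = np.stack(
            [wide[:, s : s + width] @ mean_tpl for s in range(2 * jitter + 1)], axis=1
        )
        idx = idx + (np.argmax(scores, axis=1) - jitter)
    snips = _snippets(x, idx, pre_samples, post_samples)

    labels = np.zeros(len(t), dtype=int)
    if len(t) >= 6:
        n_comp = min(3, snips.shape[1], len(t) - 1)
        feats = PCA(n_components=n_comp, random_state=random_state).fit_transform(snips)
        best_score, best_labels = -1.0, None
        for k in range(2, max_clusters + 1):
            if k >= len(t):
                break
            km = KMeans(n_clusters=k, n_init=5, random_state=random_state).fit(feats)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(feats, km.labels_)
            if score > best_score:
                best_score, best_labels = score, km.labels_
        if best_labels is not None and best_score >= min_silhouette:
            labels = best_labels

    units = []
    for uid, lab in enumerate(np.unique(labels)):
        sel = labels == lab
        units.append(
            SortedUnit(
                unit_id=uid,
                channel_id=channel_id,
                spike_times=t[sel],
                template=snips[sel].mean(axis=0),
            )
        )
    return units


def isi_violation_rate(spike_times: Sequence[float], refractory: float = 0.0015) -> float:
    """Fraction of consecutive ISIs strictly below the refractory bound.

    High values indicate a contaminated unit (a true neuron cannot fire
    twice within its absolute refractory period).  Zero when the train has
    fewer than two spikes.
    """
    if refractory < 0:
        raise ValueError("refractory must be non-negative")
    t = np.asarray(spike_times, dtype=float)
    if len(t) < 2:
        return 0.0
    isi = np.diff(t)
    return float(np.mean(isi < refractory))


def compute_snr(template: np.ndarray, sigma: float) -> float:
    """Trough-to-peak template amplitude divided by the channel noise scale."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    w = np.asarray(template, dtype=float)
    return float((w.max() - w.min()) / sigma)


def curate_units(
    units: Sequence[SortedUnit],
    max_isi_violation: float = 0.2,
    min_snr: float = 5.0,
    min_spikes: int = 10,
) -> list[SortedUnit]:
    """Accept units that pass all quality criteria; tag rejects with a reason.

    Criteria: ISI-violation rate <= ``max_isi_violation``, SNR >=
    ``min_snr``, and at least ``min_spikes`` spikes.  The spike-count floor
    keeps sparse noise clusters (a handful of band-limited noise excursions
    past threshold) out of the analysis; real units fire orders of
    magnitude more often over a recording.  Metrics must already be set on
    each unit.  Returns the accepted units; all inputs get their
    ``accepted`` flag and ``rejection_reason`` filled in.
    """
    accepted = []
    for u in units:
        reasons = []
        if not np.isfinite(u.isi_violation_rate) or not np.isfinite(u.snr):
            raise ValueError(f"unit {u.unit_id}: metrics not computed before curation")
        if u.isi_violation_rate > max_isi_violation:
            reasons.append(f"isi_violation {u.isi_violation_rate:.3f} > {max_isi_violation}")
        if u.snr < min_snr:
            reasons.append(f"snr {u.snr:.2f} < {min_snr}")
        if u.n_spikes < min_spikes:
            reasons.append(f"n_spikes {u.n_spikes} < {min_spikes}")
        u.accepted = not reasons
        u.rejection_reason = "; ".join(reasons)
        if u.accepted:
            accepted.append(u)
    return accepted


def waveform_metrics(template: np.ndarray, sampling_rate: float) -> WaveformMetrics:
    """Trough-to-peak amplitude (µV) and trough half width (ms).

    The half width is the time the trough lobe spends below half its depth,
    with sub-sample linear interpolation at the two crossings.
    """
    w = np.asarray(template, dtype=float)
    i = int(np.argmin(w))
    depth = w[i]
    if depth >= 0 or i == 0 or i == len(w) - 1:
        raise ValueError("template has no interior trough")
    half = depth / 2.0

    # walk outward from the trough to the half-depth crossings
    a = i
    while a > 0 and w[a - 1] <= half:
        a -= 1
    b = i
    while b < len(w) - 1 and w[b + 1] <= half:
        b += 1
    # linear interpolation beyond the last sub-half sample
    left = float(a)
    if a > 0:
        left = a - (w[a] - half) / (w[a] - w[a - 1])
    right = float(b)
    if b < len(w) - 1:
        right = b + (w[b] - half) / (w[b] - w[b + 1])
    return WaveformMetrics(
        amplitude=float(w.max() - w.min()),
        half_width=float((right - left) / sampling_rate * 1e3),
    )


def sort_recording(
    rec: RawRecording,
    threshold_multiplier: float = 4.5,
    dead_time: float = 0.001,
    refractory: float = 0.0015,
    exclude_edges_s: float = 0.050,
    max_clusters: int = 3,
    min_silhouette: float = 0.6,
) -> tuple[list[SortedUnit], dict[int, float]]:
    """Detect, cluster, and score units on every channel of a recording.

    Returns ``(units, noise_sigma_per_channel)``.  Unit ids are globally
    unique across channels.  Curation is a separate step
    (:func:`curate_units`) so rejected units remain inspectable.
    """
    units: list[SortedUnit] = []
    sigmas: dict[int, float] = {}
    next_id = 0
    for ci, cid in enumerate(rec.channel_ids):
        trace = rec.samples[ci]
        sigma = estimate_noise_sigma(trace)
        sigmas[cid] = sigma
        if sigma == 0:
            continue
        times = detect_spikes(
            trace,
            sigma,
            rec.sampling_rate,
            threshold_multiplier=threshold_multiplier,
            dead_time=dead_time,
            exclude_edges_s=exclude_edges_s,
        )
        if len(times) == 0:
            continue
        ch_units = extract_and_cluster(
            trace,
            times,
            rec.sampling_rate,
            channel_id=cid,
            max_clusters=max_clusters,
            min_silhouette=min_silhouette,
        )
        for u in ch_units:
            u.unit_id = next_id
            next_id += 1
            u.snr = compute_snr(u.template, sigma)
            u.isi_violation_rate = isi_violation_rate(u.spike_times, refractory)
            u.spike_times = u.spike_times + rec.t0
            units.append(u)
    return units, sigmas
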