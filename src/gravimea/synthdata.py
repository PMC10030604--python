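"""Synthetic MEA recordings with known ground truth.

Emulates the statistical structure the analysis chain assumes: lognormal
per-unit baseline firing rates, burst-structured spike trains with an
absolute refractory period, biphasic extracellular spike waveforms in the
tens-of-microvolts range, Gaussian channel noise plus an optional
common-mode artifact shared by all electrodes, empty channels, and
phase-dependent rate modulation with heterogeneous subgroup responses
(low / mid / high firing units reacting differently to a gravity change).

Spike counts per phase are exactly Poisson by construction: the number of
spikes in each constant-rate segment is drawn first and the spikes are then
arranged into tonic events and bursts, so empirical rates track true rates
at Poisson precision even for strongly burst-structured trains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .phases import Phase, PhaseSchedule, Window, generation_segments
from .recording import RawRecording, mea60_layout

__all__ = [
    "BurstStructure",
    "CommonMode",
    "PhaseEffect",
    "SynthConfig",
    "UnitTruth",
    "GroundTruth",
    "CalibrationError",
    "sample_unit_rates",
    "generate_spike_train",
    "biphasic_template",
    "build_ground_truth",
    "render_recording",
    "simulate_recording",
    "make_preset",
    "PRESETS",
]

INT16_MAX = 32767


class CalibrationError(ValueError):
    """Signal exceeds the int16 range at the configured calibration."""


@dataclass(frozen=True)
class BurstStructure:
    """Two-state burst modulation of the spike trains.

    A ``burst_fraction`` of each segment's spikes is grouped into bursts
    whose lengths are geometric with mean ``mean_spikes``; intra-burst ISIs
    are an absolute refractory period plus an exponential, with overall
    mean ``intra_isi_mean``.  Burst onsets are placed uniformly, so
    inter-burst gaps are exponential with a mean set by the target rate and
    burst fraction (an independent inter-burst mean would over-determine
    the rate).
    """

    intra_isi_mean: float = 0.008
    mean_spikes: float = 5.0
    burst_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.intra_isi_mean <= 0 or self.mean_spikes < 1:
            raise ValueError("invalid burst structure parameters")
        if not 0 <= self.burst_fraction <= 1:
            raise ValueError("burst_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CommonMode:
    """Sinusoidal artifact added identically to every channel (microvolts)."""

    amplitude: float = 0.0
    frequency: float = 50.0


@dataclass(frozen=True)
class PhaseEffect:
    """Per-subgroup rate modulation for one phase.

    ``mode="multiply"`` scales each unit's baseline rate; ``mode="target"``
    replaces it with an absolute rate (Hz), with optional lognormal jitter
    of log-scale ``jitter_sigma``.  A tuple of values means a per-unit
    choice among them (used to plant mixed-sign responses and bimodal
    target distributions): with ``choice="alternate"`` units cycle through
    the values in within-subgroup rank order (an exact split), with
    ``choice="random"`` each unit draws uniformly.  ``None`` leaves the
    subgroup at its baseline rate.
    """

    mode: str = "multiply"
    low: float | tuple[float, ...] | None = 1.0
    mid: float | tuple[float, ...] | None = 1.0
    high: float | tuple[float, ...] | None = 1.0
    jitter_sigma: float = 0.0
    choice: str = "alternate"

    def rate_for(
        self,
        subgroup: str,
        baseline: float,
        rng: np.random.Generator,
        rank_in_subgroup: int = 0,
    ) -> float:
        value = getattr(self, subgroup)
        if isinstance(value, tuple):
            if self.choice == "alternate":
                value = value[rank_in_subgroup % len(value)]
            elif self.choice == "random":
                value = value[rng.integers(len(value))]
            else:
                raise ValueError(f"unknown PhaseEffect choice {self.choice!r}")
        if value is None:
            return baseline
        if self.mode == "multiply":
            rate = baseline * value
        elif self.mode == "target":
            rate = float(value)
        else:
            raise ValueError(f"unknown PhaseEffect mode {self.mode!r}")
        if self.jitter_sigma > 0:
            rate *= math.exp(rng.normal(0.0, self.jitter_sigma))
        return rate


# mode of the baseline lognormal sits at 3 Hz: mode = exp(mu - sigma^2)
_RATE_SIGMA = 0.5
_RATE_MU = math.log(3.0) + _RATE_SIGMA**2


@dataclass
class SynthConfig:
    """Everything the generator needs besides the phase schedule."""

    n_channels: int = 60
    sampling_rate: float = 25000.0
    n_units: int = 63
    empty_channel_fraction: float = 0.1
    rate_lognormal_mu: float = _RATE_MU
    rate_lognormal_sigma: float = _RATE_SIGMA
    amplitude_mu: float = 30.5  # µV, lognormal median of trough-to-peak amplitude
    amplitude_sigma: float = 0.15  # log-scale spread of amplitudes
    noise_sigma: float = 4.0  # µV Gaussian noise per channel
    refractory: float = 0.002  # s, absolute
    bursts: BurstStructure | None = field(default_factory=BurstStructure)
    phase_modulation: dict[str, PhaseEffect] = field(default_factory=dict)
    common_mode: CommonMode | None = None
    uv_per_lsb: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1 or self.n_units < 1:
            raise ValueError("n_channels and n_units must be positive")
        if not 0 <= self.empty_channel_fraction < 1:
            raise ValueError("empty_channel_fraction must be in [0, 1)")
        if self.rate_lognormal_sigma < 0 or self.amplitude_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        if min(self.sampling_rate, self.noise_sigma + 1e-300, self.refractory) <= 0:
            raise ValueError("rates, noise and durations must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.bursts is not None and self.refractory >= self.bursts.intra_isi_mean:
            raise ValueError("refractory must be below the intra-burst ISI mean")
        n_empty = round(self.n_channels * self.empty_channel_fraction)
        if self.n_units > 2 * (self.n_channels - n_empty):
            raise ValueError(
                "n_units exceeds capacity (at most 2 units per non-empty channel)"
            )


@dataclass
class UnitTruth:
    """Generator-side truth for one unit."""

    unit_id: int
    channel_id: int
    subgroup: str  # "low" | "mid" | "high" by baseline-rate tertile
    amplitude: float  # µV trough-to-peak
    baseline_rate: float  # Hz
    phase_rates: dict[str, float]  # segment label -> true rate (Hz)
    spike_times: np.ndarray  # s, strictly increasing


@dataclass
class GroundTruth:
    """All planted structure of one synthetic recording."""

    units: list[UnitTruth]
    channel_has_unit: dict[int, bool]
    segments: list[Window]  # constant-rate generation segments

    def units_on(self, channel_id: int) -> list[UnitTruth]:
        return [u for u in self.units if u.channel_id == channel_id]

    def to_dict(self) -> dict:
        """JSON-serializable summary (spike times exported separately)."""
        return {
            "segments": [[w.label, w.start, w.end] for w in self.segments],
            "channel_has_unit": {str(k): bool(v) for k, v in self.channel_has_unit.items()},
            "units": [
                {
                    "unit_id": u.unit_id,
                    "channel_id": u.channel_id,
                    "subgroup": u.subgroup,
                    "amplitude_uv": u.amplitude,
                    "baseline_rate_hz": u.baseline_rate,
                    "phase_rates_hz": u.phase_rates,
                    "n_spikes": int(len(u.spike_times)),
                }
                for u in self.units
            ],
        }


def sample_unit_rates(
    n: int, mu: float, sigma: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` baseline firing rates (Hz) from a lognormal.

    ``mu``/``sigma`` parameterize the log of the rate, so ``exp(mu)`` is the
    median of the sampling distribution.  ``sigma=0`` degenerates to all
    rates equal to ``exp(mu)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def _burstify_segment(
    n_spikes: int,
    start: float,
    end: float,
    bursts: BurstStructure | None,
    refractory: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Arrange ``n_spikes`` spikes in [start, end): tonic + burst clusters."""
    if n_spikes == 0:
        return np.empty(0)
    if bursts is None or bursts.burst_fraction == 0:
        return start + rng.uniform(0.0, end - start, n_spikes)
    n_burst = rng.binomial(n_spikes, bursts.burst_fraction)
    tonic = start + rng.uniform(0.0, end - start, n_spikes - n_burst)
    times = [tonic]
    remaining = n_burst
    onsets: list[float] = []
    lengths: list[int] = []
    while remaining > 0:
        # geometric with mean `mean_spikes`, support {1, 2, ...}
        L = min(int(rng.geometric(1.0 / bursts.mean_spikes)), remaining)
        lengths.append(L)
        remaining -= L
    onsets = np.sort(rng.uniform(start, end, len(lengths)))
    for onset, L in zip(onsets, lengths):
        isis = refractory + rng.exponential(bursts.intra_isi_mean - refractory, L - 1)
        burst_times = onset + np.r_[0.0, np.cumsum(isis)]
        times.append(burst_times[burst_times < end])  # clip overflow at segment end
    return np.concatenate(times)


def generate_spike_train(
    rate_profile: float | Sequence[tuple[float, float, float]],
    duration: float | None = None,
    *,
    bursts: BurstStructure | None = None,
    refractory: float = 0.002,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate one spike train with piecewise-constant rate.

    ``rate_profile`` is either a single rate (Hz, requires ``duration``) or
    a sequence of ``(start_s, end_s, rate_hz)`` segments.  Counts per
    segment are Poisson with the exact target mean; spikes are arranged as
    tonic events plus bursts (see :class:`BurstStructure`) and thinned to
    enforce the absolute refractory period.

    Returns strictly increasing times in seconds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.isscalar(rate_profile):
        if duration is None or duration <= 0:
            raise ValueError("a scalar rate requires a positive duration")
        segments = [(0.0, float(duration), float(rate_profile))]
    else:
        segments = [(float(a), float(b), float(r)) for a, b, r in rate_profile]
    all_times = []
    for a, b, r in segments:
        if r < 0:
            raise ValueError("rates must be non-negative")
        if b <= a:
            raise ValueError("segment must have positive duration")
        n = rng.poisson(r * (b - a))
        all_times.append(_burstify_segment(n, a, b, bursts, refractory, rng))
    t = np.sort(np.concatenate(all_times)) if all_times else np.empty(0)
    if len(t) < 2:
        return t
    # enforce the absolute refractory period by dropping violators
    keep = np.ones(len(t), dtype=bool)
    last = t[0]
    for i in range(1, len(t)):
        if t[i] - last < refractory:
            keep[i] = False
        else:
            last = t[i]
    return t[keep]


def _assign_subgroups(baseline_rates: np.ndarray) -> list[str]:
    """Tertile labels by baseline rate, ties broken by index order."""
    n = len(baseline_rates)
    order = np.argsort(baseline_rates, kind="stable")
    labels = [""] * n
    k = n // 3
    for pos, idx in enumerate(order):
        if pos < k:
            labels[idx] = "low"
        elif pos >= n - k:
            labels[idx] = "high"
        else:
            labels[idx] = "mid"
    return labels


def build_ground_truth(config: SynthConfig, schedule: PhaseSchedule) -> GroundTruth:
    """Draw units, per-phase true rates, and spike trains.

    Deterministic in ``config.seed``; rendering uses an independent
    sub-stream of the same root seed, so truth and recording are jointly
    reproducible.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_truth, _ = root.spawn(2)
    rng = np.random.default_rng(ss_truth)

    if config.n_channels == 60:
        channel_ids, _ = mea60_layout()
    else:
        channel_ids = list(range(1, config.n_channels + 1))
    n_empty = round(config.n_channels * config.empty_channel_fraction)
    empty = set(rng.choice(channel_ids, size=n_empty, replace=False).tolist())
    occupied = [c for c in channel_ids if c not in empty]
    # round-robin: one unit per electrode first, doubling up only if needed
    unit_channels = [occupied[i % len(occupied)] for i in range(config.n_units)]

    rates = sample_unit_rates(
        config.n_units, config.rate_lognormal_mu, config.rate_lognormal_sigma, rng
    )
    subgroups = _assign_subgroups(rates)
    amplitudes = rng.lognormal(math.log(config.amplitude_mu), config.amplitude_sigma, config.n_units)

    # within-subgroup rank of each unit by baseline rate (for exact splits)
    rank_in_subgroup = np.zeros(config.n_units, dtype=int)
    for sg in ("low", "mid", "high"):
        members = [i for i in range(config.n_units) if subgroups[i] == sg]
        members.sort(key=lambda i: (rates[i], i))
        for r, i in enumerate(members):
            rank_in_subgroup[i] = r

    segments = generation_segments(schedule)
    units: list[UnitTruth] = []
    for i in range(config.n_units):
        phase_rates = {}
        for w in segments:
            effect = config.phase_modulation.get(w.label)
            if effect is None:
                phase_rates[w.label] = float(rates[i])
            else:
                phase_rates[w.label] = effect.rate_for(
                    subgroups[i], float(rates[i]), rng, int(rank_in_subgroup[i])
                )
        profile = [(w.start, w.end, phase_rates[w.label]) for w in segments]
        spikes = generate_spike_train(
            profile, bursts=config.bursts, refractory=config.refractory, seed=rng
        )
        units.append(
            UnitTruth(
                unit_id=i,
                channel_id=unit_channels[i],
                subgroup=subgroups[i],
                amplitude=float(amplitudes[i]),
                baseline_rate=float(rates[i]),
                phase_rates=phase_rates,
                spike_times=spikes,
            )
        )
    has_unit = {c: c not in empty for c in channel_ids}
    for c in empty:
        has_unit[c] = False
    return GroundTruth(units=units, channel_has_unit=has_unit, segments=segments)


def biphasic_template(
    amplitude: float,
    sampling_rate: float,
    trough_ms: float = 0.3,
    rebound_ms: float = 0.5,
    total_ms: float = 1.6,
    trough_frac: float = 0.75,
) -> tuple[np.ndarray, int]:
    """Trough-dominant biphasic spike waveform.

    A half-sine trough of width ``trough_ms`` and depth
    ``trough_frac * amplitude`` followed by a half-sine rebound of width
    ``rebound_ms`` and height ``(1 - trough_frac) * amplitude``, embedded
    in a ``total_ms`` window; ``amplitude`` is trough-to-peak.

    Returns ``(waveform_uv, trough_index)``.
    """
    n = max(int(round(total_ms * 1e-3 * sampling_rate)), 3)
    w = np.zeros(n)
    lead = int(round(0.2e-3 * sampling_rate))
    nt = max(int(round(trough_ms * 1e-3 * sampling_rate)), 2)
    nr = max(int(round(rebound_ms * 1e-3 * sampling_rate)), 2)
    tr = -trough_frac * amplitude * np.sin(np.pi * (np.arange(nt) + 0.5) / nt)
    rb = (1 - trough_frac) * amplitude * np.sin(np.pi * (np.arange(nr) + 0.5) / nr)
    stop_t = min(lead + nt, n)
    w[lead:stop_t] = tr[: stop_t - lead]
    stop_r = min(lead + nt + nr, n)
    w[lead + nt : stop_r] = rb[: stop_r - (lead + nt)]
    return w, int(np.argmin(w))


def render_recording(config: SynthConfig, truth: GroundTruth) -> RawRecording:
    """Render ground truth into a raw voltage recording (microvolts).

    Each spike adds one biphasic template (trough at the spike time) on the
    unit's channel; every channel gets i.i.d. Gaussian noise of
    ``noise_sigma``; an optional common-mode sinusoid is added identically
    to all channels.  Raises :class:`CalibrationError` if the signal cannot
    be represented as int16 at ``uv_per_lsb``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    _, ss_render = root.spawn(2)
    rng = np.random.default_rng(ss_render)

    if config.n_channels == 60:
        channel_ids, layout = mea60_layout()
    else:
        channel_ids = list(range(1, config.n_channels + 1))
        layout = {}
    duration = truth.segments[-1].end
    fs = config.sampling_rate
    n_samples = int(round(duration * fs))
    samples = rng.normal(0.0, config.noise_sigma, size=(config.n_channels, n_samples))

    ch_index = {c: i for i, c in enumerate(channel_ids)}
    for u in truth.units:
        if u.channel_id not in ch_index:
            raise ValueError(f"unit {u.unit_id} on unknown channel {u.channel_id}")
        w, trough = biphasic_template(u.amplitude, fs)
        row = samples[ch_index[u.channel_id]]
        idx = np.round(np.asarray(u.spike_times) * fs).astype(int) - trough
        for i0 in idx:
            a, b = max(i0, 0), min(i0 + len(w), n_samples)
            if a < b:
                row[a:b] += w[a - i0 : b - i0]

    if config.common_mode is not None and config.common_mode.amplitude != 0:
        t = np.arange(n_samples) / fs
        cm = config.common_mode.amplitude * np.sin(2 * np.pi * config.common_mode.frequency * t)
        samples += cm[None, :]

    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak / config.uv_per_lsb > INT16_MAX:
        raise CalibrationError(
            f"peak {peak:.1f} µV exceeds int16 range at {config.uv_per_lsb} µV/LSB"
        )
    return RawRecording(
        samples=samples, sampling_rate=fs, channel_ids=channel_ids, layout=layout
    )


def simulate_recording(
    config: SynthConfig, schedule: PhaseSchedule
) -> tuple[RawRecording, GroundTruth]:
    """Ground truth plus rendered recording for one (config, schedule)."""
    truth = build_ground_truth(config, schedule)
    return render_recording(config, truth), truth


def _drop_schedule(scale: float) -> PhaseSchedule:
    base = 600.0 * scale
    t = 0.0
    phases = []
    for label, dur, g in [
        ("baseline_pre", base, 1.0),
        ("microgravity", 4.7, 1e-6),  # sub-10 s phases are never compressed
        ("impact", 5.0, 35.0),
        ("baseline_post", base, 1.0),
    ]:
        phases.append(Phase(label, t, t + dur, g_level=g))
        t += dur
    return PhaseSchedule(tuple(phases), safety_margin=0.150, platform="drop")


def _centrifuge_schedule(g_level: float, scale: float) -> PhaseSchedule:
    margin = min(2.0, max(0.15, 2.0 * scale))
    t = 0.0
    phases = []
    for label, dur, g, split in [
        ("baseline", 600.0 * scale, 1.0, False),
        ("ramp_up", 30.0 * scale, (1.0 + g_level) / 2, False),
        ("hyperG", 300.0 * scale, g_level, True),
        ("ramp_down", 30.0 * scale, (1.0 + g_level) / 2, False),
        ("post", 300.0 * scale, 1.0, True),
    ]:
        phases.append(Phase(label, t, t + dur, g_level=g, split=split))
        t += dur
    return PhaseSchedule(tuple(phases), safety_margin=margin, platform=f"centrifuge_{g_level:g}g")


def _tertile_medians(mu: float, sigma: float) -> tuple[float, float, float]:
    """Theoretical medians of the low/mid/high baseline-rate tertiles."""
    from scipy.stats import norm

    return tuple(math.exp(mu + sigma * norm.ppf(q)) for q in (1 / 6, 1 / 2, 5 / 6))


def _toward(target: float, group_median: float) -> float:
    """Multiplicative factor moving a subgroup's median rate to ``target``.

    Rate modulation is multiplicative (neurons scale their rates, keeping
    the within-group rank order) rather than an absolute reset, so planted
    effects do not inject artificial unit x phase interaction.
    """
    return target / group_median


def _drop_modulation(mu: float, sigma: float) -> dict[str, PhaseEffect]:
    low_m, mid_m, high_m = _tertile_medians(mu, sigma)
    # microgravity: low & mid units up by 4/3 (3 Hz density peak -> 4 Hz);
    # high units split ~50/50 between increase and decrease.
    # impact: bimodal rate distribution with peaks at 8 Hz (low+mid) and
    # 20 Hz (high).
    return {
        "microgravity": PhaseEffect(mode="multiply", low=4 / 3, mid=4 / 3, high=(4 / 3, 3 / 4)),
        "impact": PhaseEffect(
            mode="multiply",
            low=_toward(8.0, low_m),
            mid=_toward(8.0, mid_m),
            high=_toward(20.0, high_m),
            jitter_sigma=0.1,
        ),
    }


PRESETS = ("drop", "centrifuge_6g", "centrifuge_4g")


def make_preset(name: str, scale: float = 1.0) -> tuple[SynthConfig, PhaseSchedule]:
    """Preset (config, schedule) pairs for the study protocols.

    ``scale`` in (0, 1] compresses long phases for desk-scale runs; phases
    shorter than 10 s (the 4.7 s microgravity window, the 5 s impact) are
    never compressed — they are the scientific object.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    if name == "drop":
        schedule = _drop_schedule(scale)
        modulation = _drop_modulation(_RATE_MU, _RATE_SIGMA)
    elif name in ("centrifuge_6g", "centrifuge_4g"):
        g = 6.0 if name.endswith("6g") else 4.0
        schedule = _centrifuge_schedule(g, scale)
        low_m, mid_m, high_m = _tertile_medians(_RATE_MU, _RATE_SIGMA)
        # ramps push rates toward local maxima at 8-13 Hz
        ramp = PhaseEffect(
            mode="multiply",
            low=_toward(8.0, low_m),
            mid=_toward(10.5, mid_m),
            high=_toward(13.0, high_m),
            jitter_sigma=0.15,
        )
        modulation = {
            "ramp_up": ramp,
            "ramp_down": ramp,
            # onset suppression toward 2 Hz for low/mid; high units persist
            "hyperG1": PhaseEffect(
                mode="multiply",
                low=_toward(2.0, low_m),
                mid=_toward(2.0, mid_m),
                high=None,
                jitter_sigma=0.2,
            ),
        }
    else:
        raise ValueError(f"unknown preset {name!r}; valid presets: {', '.join(PRESETS)}")
    config = SynthConfig(phase_modulation=modulation)
    return config, schedule
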