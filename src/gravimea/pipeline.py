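"""End-to-end analysis chains tying the modules together.

Two entry points:

* :func:`run_waveform_pipeline` — the full chain on rendered voltage data:
  simulate (or load) -> high-pass + common median reference -> detect /
  cluster / curate -> rate table -> filter + log -> statistics.
* :func:`run_train_pipeline` — the same analysis chain starting from
  ground-truth spike trains, bypassing rendering and sorting.  Used for
  large replicate counts where the question is statistical recovery, not
  detection fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gravistats, io, phases, preprocess, spikes, synthdata
from .bursts import BurstParams
from .phases import PhaseRateTable, PhaseSchedule
from .recording import RawRecording

__all__ = ["AnalysisResult", "analyze_units", "run_train_pipeline", "run_waveform_pipeline"]


@dataclass
class AnalysisResult:
    """Everything the analyze stage produces for one experiment."""

    table: PhaseRateTable  # filtered + log-transformed
    anova_firing: gravistats.RMAnovaResult
    tukey_firing: list[gravistats.PairwiseComparison]
    anova_burst: gravistats.RMAnovaResult | None
    tukey_burst: list[gravistats.PairwiseComparison] | None
    counts: dict

    def tukey_pair(self, a: str, b: str) -> gravistats.PairwiseComparison:
        """The firing-rate comparison between phases ``a`` and ``b``."""
        for c in self.tukey_firing:
            if {c.a, c.b} == {a, b}:
                return c
        raise KeyError(f"no comparison between {a!r} and {b!r}")

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "firing": {
                "F": self.anova_firing.F,
                "epsilon_gg": self.anova_firing.epsilon_gg,
                "p_gg": self.anova_firing.p_gg,
                "tukey": [
                    {"a": c.a, "b": c.b, "mean_diff_log10": c.mean_diff, "q": c.q, "p_adj": c.p_adj}
                    for c in self.tukey_firing
                ],
            },
            "burst": None
            if self.anova_burst is None
            else {
                "F": self.anova_burst.F,
                "epsilon_gg": self.anova_burst.epsilon_gg,
                "p_gg": self.anova_burst.p_gg,
                "tukey": [
                    {"a": c.a, "b": c.b, "mean_diff_log10": c.mean_diff, "q": c.q, "p_adj": c.p_adj}
                    for c in self.tukey_burst
                ],
            },
        }


def analyze_units(
    units,
    schedule: PhaseSchedule,
    burst_params: BurstParams | None = None,
) -> AnalysisResult:
    """Rate table -> silent-unit filter -> log10 -> RM-ANOVA + Tukey.

    The burst-rate statistics are computed only when at least 3 units
    burst in every phase.
    """
    raw_table = phases.build_rate_table(units, schedule, burst_params)
    table = phases.filter_silent_units(raw_table)
    table = phases.log_transform(table)
    labels = table.phase_labels

    mat = table.log_firing.to_numpy()
    anova_f = gravistats.rm_anova_gg(mat)
    tukey_f = gravistats.tukey_pairwise(mat, anova_f, labels=labels)

    anova_b = tukey_b = None
    if table.log_burst is not None and len(table.log_burst) >= 3:
        bmat = table.log_burst.to_numpy()
        anova_b = gravistats.rm_anova_gg(bmat)
        tukey_b = gravistats.tukey_pairwise(bmat, anova_b, labels=labels)

    counts = {
        "units_in": int(len(raw_table.firing)),
        "units_firing_analysis": int(len(table.firing)),
        "units_burst_analysis": int(len(table.burst)),
    }
    return AnalysisResult(
        table=table,
        anova_firing=anova_f,
        tukey_firing=tukey_f,
        anova_burst=anova_b,
        tukey_burst=tukey_b,
        counts=counts,
    )


def run_train_pipeline(
    preset: str = "drop",
    scale: float = 0.1,
    seed: int = 0,
    effect: bool = True,
    n_units: int | None = None,
) -> tuple[AnalysisResult, synthdata.GroundTruth, PhaseSchedule]:
    """Spike-train-level experiment: ground truth straight into the analysis.

    ``effect=False`` strips the planted phase modulation (null experiment).
    """
    config, schedule = synthdata.make_preset(preset, scale=scale)
    config.seed = seed
    if n_units is not None:
        config.n_units = n_units
    if not effect:
        config.phase_modulation = {}
    truth = synthdata.build_ground_truth(config, schedule)
    result = analyze_units(truth.units, schedule)
    return result, truth, schedule


def run_waveform_pipeline(
    preset: str = "drop",
    scale: float = 0.1,
    seed: int = 0,
    effect: bool = True,
    sampling_rate: float | None = None,
    n_channels: int | None = None,
    n_units: int | None = None,
    recording: RawRecording | None = None,
    schedule: PhaseSchedule | None = None,
) -> tuple[AnalysisResult, list[spikes.SortedUnit], synthdata.GroundTruth | None]:
    """Full voltage-level chain: render, denoise, sort, curate, analyze.

    When ``recording`` is given (with its ``schedule``) the simulation step
    is skipped and ground truth is ``None``.
    """
    truth = None
    if recording is None:
        config, schedule = synthdata.make_preset(preset, scale=scale)
        config.seed = seed
        if sampling_rate is not None:
            config.sampling_rate = sampling_rate
        if n_channels is not None:
            config.n_channels = n_channels
        if n_units is not None:
            config.n_units = n_units
        if not effect:
            config.phase_modulation = {}
        recording, truth = synthdata.simulate_recording(config, schedule)
    elif schedule is None:
        raise ValueError("an explicit recording needs an explicit schedule")

    clean = preprocess.preprocess(recording)
    all_units, _ = spikes.sort_recording(clean)
    curated = spikes.curate_units(all_units)
    result = analyze_units(curated, schedule)
    result.counts["units_detected"] = len(all_units)
    result.counts["units_curated"] = len(curated)
    return result, curated, truth
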