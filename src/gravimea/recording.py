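"""Shared container for raw multichannel extracellular recordings.

Voltages are kept in microvolts as float arrays throughout the pipeline;
integer calibration only happens at the file boundary (:mod:`gravimea.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RawRecording", "mea60_layout"]


def mea60_layout() -> tuple[list[int], dict[int, tuple[int, int]]]:
    """Channel ids and grid positions of a standard 60-electrode MEA.

    The 8x8 grid minus the four corners, with the conventional
    column-row channel naming (12 ... 87).

    Returns
    -------
    (channel_ids, layout)
        ``channel_ids`` is the ordered list of 60 integer labels;
        ``layout`` maps each label to its (row, column) position,
        1-based.
    """
    ids: list[int] = []
    layout: dict[int, tuple[int, int]] = {}
    for col in range(1, 9):
        for row in range(1, 9):
            if (row in (1, 8)) and (col in (1, 8)):
                continue  # no electrode in the corners
            cid = col * 10 + row
            ids.append(cid)
            layout[cid] = (row, col)
    return ids, layout


@dataclass
class RawRecording:
    """Multichannel voltage data with acquisition metadata.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    sampling_rate
        Samples per second per channel (Hz).
    channel_ids
        Ordered channel labels, one per row of ``samples``.
    layout
        Optional map channel id -> (row, col) grid position.
    t0
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_ids: list[int]
    layout: dict[int, tuple[int, int]] = field(default_factory=dict)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} channel rows"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, channel_id: int) -> np.ndarray:
        """Single-channel trace (microvolts) by channel id."""
        return self.samples[self.channel_ids.index(channel_id)]

    def with_samples(self, samples: np.ndarray) -> "RawRecording":
        """Copy of this recording with ``samples`` replaced."""
        return replace(self, samples=samples)
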