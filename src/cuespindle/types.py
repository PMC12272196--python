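"""Core domain containers shared across the pipeline.

The analysis operates on four kinds of objects: a multichannel EEG recording,
a hypnogram (30-s sleep-stage epochs plus scored arousal intervals), a cue log
(tone onsets grouped into replay blocks), and detected or injected sigma-band
events.  All times are seconds from recording start (origin 0); all intervals
are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SLEEP_STAGES = ("W", "N1", "N2", "N3", "REM")

#: Electrodes over left / right motor cortex used for density summaries.
LEFT_MOTOR_CHANNELS = ("FC3", "C5", "C3", "C1", "CP3")
RIGHT_MOTOR_CHANNELS = ("FC4", "C6", "C4", "C2", "CP4")
MASTOID_CHANNELS = ("TP9", "TP10")


@dataclass
class EEGRecording:
    """A multichannel EEG time series in microvolts.

    ``data`` has shape ``(n_channels, n_samples)``; channel order matches
    ``channel_names``.
    """

    channel_names: list[str]
    sampling_rate: float
    data: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names but "
                f"{self.data.shape[0]} data rows"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("EEG samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, name: str) -> int:
        """Case-insensitive lookup of a channel's row index."""
        lowered = [c.lower() for c in self.channel_names]
        try:
            return lowered.index(name.lower())
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            list(self.channel_names), self.sampling_rate, self.data.copy(),
            self.start_time,
        )


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels plus scored arousal intervals."""

    stages: list[str]
    epoch_length: float = 30.0
    arousals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(SLEEP_STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        span = self.duration
        for a, b in self.arousals:
            if not (0.0 <= a < b <= span):
                raise ValueError(f"arousal [{a}, {b}) outside recording span")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_length

    def stage_at(self, t: float) -> str:
        """Stage of the epoch containing time ``t`` (clamped to the record)."""
        idx = int(np.clip(t // self.epoch_length, 0, self.n_epochs - 1))
        return self.stages[idx]

    def stage_intervals(self, stages: Sequence[str]) -> list[tuple[float, float]]:
        """Merged half-open intervals covered by epochs in ``stages``."""
        wanted = set(stages)
        out: list[tuple[float, float]] = []
        for i, s in enumerate(self.stages):
            if s not in wanted:
                continue
            start = i * self.epoch_length
            end = start + self.epoch_length
            if out and out[-1][1] == start:
                out[-1] = (out[-1][0], end)
            else:
                out.append((start, end))
        return out

    def sample_mask(self, fs: float, n_samples: int,
                    stages: Sequence[str]) -> np.ndarray:
        """Boolean per-sample mask: sample time falls in one of ``stages``."""
        mask = np.zeros(n_samples, dtype=bool)
        for a, b in self.stage_intervals(stages):
            i0 = int(np.ceil(a * fs))
            i1 = min(int(np.ceil(b * fs)), n_samples)
            mask[i0:i1] = True
        return mask

    def overlaps_arousal(self, start: float, end: float) -> bool:
        return any(start < b and end > a for a, b in self.arousals)


@dataclass
class CueLog:
    """Tone onsets of the replay protocol, grouped into replay blocks.

    A complete block holds exactly 12 onsets with consecutive gaps jittered
    within [2.5, 3.5] s, and blocks are separated by at least 20 s of silence
    after the last tone.
    """

    blocks: list[list[float]]
    sequence_id: str = "A"

    def __post_init__(self) -> None:
        for bi, onsets in enumerate(self.blocks):
            gaps = np.diff(onsets)
            if np.any(gaps <= 0):
                raise ValueError(f"block {bi}: onsets not strictly increasing")

    @property
    def n_tones(self) -> int:
        return sum(len(b) for b in self.blocks)

    def all_onsets(self) -> np.ndarray:
        return np.concatenate([np.asarray(b) for b in self.blocks]) \
            if self.blocks else np.empty(0)


@dataclass(frozen=True)
class GroundTruthEvent:
    """An injected sigma burst; the oracle for detector validation."""

    channel: str
    onset_s: float
    duration_s: float
    frequency_hz: float
    amplitude_ratio: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SpindleEvent:
    """A detected sleep spindle with its acceptance-criteria annotations."""

    channel: str
    start_s: float
    end_s: float
    n_oscillations: int
    peak_frequency_hz: float
    peak_rms: float
    period_label: str = "unassigned"   # cue | nocue | unassigned | excluded
    stage: str = "other"               # N2 | N3 | other

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)

    def with_label(self, label: str) -> "SpindleEvent":
        return replace(self, period_label=label)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design targets for a Chebyshev Type II filter."""

    passband_hz: tuple[float, float]
    stopband_hz: tuple[float, float]
    family: str = "chebyshev2"
    passband_ripple_db: float = 1.0
    stopband_attenuation_db: float = 40.0

    def __post_init__(self) -> None:
        sl, sh = self.stopband_hz
        pl, ph = self.passband_hz
        if not (sl < pl < ph < sh):
            raise ValueError(
                "band edges must satisfy stop_low < pass_low < pass_high < stop_high"
            )
        if self.family != "chebyshev2":
            raise ValueError("only chebyshev2 designs are supported")


#: Broadband preprocessing filter: passband 0.3-35 Hz, stopband <0.1 & >45 Hz.
BROADBAND_SPEC = FilterSpec(passband_hz=(0.3, 35.0), stopband_hz=(0.1, 45.0))

#: Sigma-band detection filter: passband 11-16 Hz, stopband <9 & >18 Hz.
SIGMA_SPEC = FilterSpec(passband_hz=(11.0, 16.0), stopband_hz=(9.0, 18.0))
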