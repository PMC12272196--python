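"""Cue / no-cue period construction, spindle labelling, and density tables.

For every replay block the cue period is the union of per-tone
``[onset, onset + 3.5)`` windows — contiguous because the inter-trial
interval never exceeds 3.5 s, hence ``[first_onset, last_onset + 3.5)`` — and
the no-cue period is ``[last_onset + 3.5, last_onset + 20.0)``.  A spindle
is kept only if it falls wholly inside a single period and does not touch an
arousal; density is spindles per minute of the period time intersected with
the selected sleep stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (CueLog, Hypnogram, SpindleEvent, LEFT_MOTOR_CHANNELS,
                    RIGHT_MOTOR_CHANNELS)

CUE_WINDOW_S = 3.5
SILENCE_END_S = 20.0

STAGE_SELECTIONS = {"N2": ("N2",), "N3": ("N3",), "N2+N3": ("N2", "N3")}


@dataclass
class PeriodSet:
    """Labelled cue/no-cue intervals with the replay block each came from."""

    intervals: list[tuple[float, float, str, int]] = field(default_factory=list)

    def by_label(self, label: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, lab, _ in self.intervals if lab == label]

    @property
    def labels(self) -> set[str]:
        return {lab for _, _, lab, _ in self.intervals}


def build_periods(cues: CueLog, cue_window_s: float = CUE_WINDOW_S,
                  silence_end_s: float = SILENCE_END_S) -> PeriodSet:
    """Cue and no-cue intervals for every replay block."""
    periods = PeriodSet()
    for bi, onsets in enumerate(cues.blocks):
        if not onsets:
            continue
        first, last = onsets[0], onsets[-1]
        periods.intervals.append((first, last + cue_window_s, "cue", bi))
        periods.intervals.append(
            (last + cue_window_s, last + silence_end_s, "nocue", bi))
    return periods


def _wholly_within(ev: SpindleEvent, interval: tuple[float, float]) -> bool:
    return ev.start_s >= interval[0] and ev.end_s <= interval[1]


def label_spindles(spindles: list[SpindleEvent], periods: PeriodSet,
                   hyp: Hypnogram) -> list[SpindleEvent]:
    """Assign each spindle a period label.

    Spindles overlapping an arousal (partly or wholly) are ``excluded``;
    spindles wholly inside a cue (no-cue) interval are labelled ``cue``
    (``nocue``); anything straddling a period boundary or outside all periods
    is ``unassigned`` and drops out of density computation.
    """
    labelled = []
    for ev in spindles:
        if hyp.overlaps_arousal(ev.start_s, ev.end_s):
            labelled.append(ev.with_label("excluded"))
            continue
        label = "unassigned"
        for a, b, lab, _ in periods.intervals:
            if _wholly_within(ev, (a, b)):
                label = lab
                break
        labelled.append(ev.with_label(label))
    return labelled


def _overlap_minutes(intervals: list[tuple[float, float]],
                     stage_intervals: list[tuple[float, float]],
                     arousals: list[tuple[float, float]] | None = None,
                     ) -> float:
    """Total minutes of ``intervals`` ∩ ``stage_intervals`` (− arousals)."""
    total = 0.0
    for a, b in intervals:
        for c, d in stage_intervals:
            lo, hi = max(a, c), min(b, d)
            if hi <= lo:
                continue
            seg = hi - lo
            if arousals:
                for x, y in arousals:
                    seg -= max(0.0, min(hi, y) - max(lo, x))
            total += seg
    return total / 60.0


def spindle_density(labelled: list[SpindleEvent], periods: PeriodSet,
                    hyp: Hypnogram,
                    stages: list[str] = ("N2", "N3", "N2+N3"),
                    channels: list[str] | None = None,
                    subtract_arousal_time: bool = False) -> pd.DataFrame:
    """Per-(channel, stage selection, period) spindle density table.

    The numerator counts kept spindles of that channel, period label, and
    stage; the denominator is the period time intersected with the selected
    stages' epochs, in minutes.  Rows with zero minutes carry ``NaN`` density
    and ``undefined=True`` rather than 0.  Arousal time is by default *not*
    subtracted from denominators (``subtract_arousal_time`` flips this).
    """
    if channels is None:
        channels = sorted({ev.channel for ev in labelled})
    rows = []
    for stage_name in stages:
        stage_iv = hyp.stage_intervals(STAGE_SELECTIONS[stage_name])
        for period in ("cue", "nocue"):
            minutes = _overlap_minutes(
                periods.by_label(period), stage_iv,
                hyp.arousals if subtract_arousal_time else None)
            for ch in channels:
                n = sum(1 for ev in labelled
                        if ev.channel == ch and ev.period_label == period
                        and ev.stage in STAGE_SELECTIONS[stage_name])
                rows.append({
                    "channel": ch, "stage": stage_name, "period": period,
                    "n_spindles": n, "minutes": minutes,
                    "density": n / minutes if minutes > 0 else np.nan,
                    "undefined": minutes <= 0,
                })
    return pd.DataFrame(rows)


def motor_density_means(density: pd.DataFrame, stage: str = "N2+N3",
                        ) -> pd.DataFrame:
    """Mean density over left / right / all motor channels per period."""
    sets = {"left": LEFT_MOTOR_CHANNELS, "right": RIGHT_MOTOR_CHANNELS,
            "all": LEFT_MOTOR_CHANNELS + RIGHT_MOTOR_CHANNELS}
    sub = density[density.stage == stage]
    rows = []
    for name, chans in sets.items():
        for period in ("cue", "nocue"):
            vals = sub[(sub.period == period) & sub.channel.isin(chans)]
            rows.append({"region": name, "period": period,
                         "density": vals.density.mean()})
    return pd.DataFrame(rows)


def stage_percentages(hyp: Hypnogram) -> pd.Series:
    """Percent of total sleep time per stage; wake is excluded throughout."""
    stages = pd.Series(hyp.stages)
    sleep = stages[stages != "W"]
    if sleep.empty:
        raise ValueError("hypnogram contains no sleep epochs")
    return (100.0 * sleep.value_counts() / len(sleep)).reindex(
        ["N1", "N2", "N3", "REM"], fill_value=0.0)
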