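"""Ground-truth-annotated synthetic polysomnography, cue schedules, and SRTT behaviour.

The generator emulates the structure a cue-locked spindle analysis assumes:

* a cyclic hypnogram of 30-s AASM-style epochs with scored arousals;
* replay blocks of 12 tones (inter-trial interval jittered 2.5-3.5 s,
  followed by 20 s of silence) delivered only during stable N2/N3;
* multichannel EEG made of stage-scaled pink (1/f) background noise with
  raised-cosine-enveloped sigma bursts injected at controllable
  per-(stage, period) densities — every burst is returned as ground truth;
* SRTT reaction times with subject random intercepts, within-session
  exponential learning curves, a random-block penalty, and a
  session-dependent cued-vs-uncued effect.

All randomness flows from a single seed split into named substreams, so a
fixed (seed, config) pair reproduces byte-identical outputs and perturbing
one stage's draws leaves the others untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import behaviour as beh
from .cue_windows import build_periods
from .eeg_preproc import design_cheby2_sos, apply_zero_phase
from .types import (CueLog, EEGRecording, GroundTruthEvent, Hypnogram,
                    SIGMA_SPEC, LEFT_MOTOR_CHANNELS, RIGHT_MOTOR_CHANNELS,
                    MASTOID_CHANNELS)

logger = logging.getLogger(__name__)

DEFAULT_CHANNELS = list(LEFT_MOTOR_CHANNELS + RIGHT_MOTOR_CHANNELS
                        + MASTOID_CHANNELS)

# Substream ids: changing one stage's draws must not perturb the others.
_STREAMS = {"hypnogram": 1, "cues": 2, "eeg": 3, "behaviour": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of the run seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[name]]))


@dataclass
class StageScheduleConfig:
    """Cyclic sleep architecture: ordered (stage, mean epoch count) segments."""

    epoch_length_s: float = 30.0
    #: One sleep cycle; epoch counts are jittered multiplicatively.
    cycle: list[tuple[str, float]] = field(default_factory=lambda: [
        ("W", 2), ("N1", 3), ("N2", 30), ("N3", 25), ("N2", 15), ("REM", 15),
    ])
    jitter: float = 0.15
    arousal_rate_per_hour: float = 4.0
    arousal_duration_range_s: tuple[float, float] = (3.0, 10.0)


@dataclass
class SpindleModelConfig:
    """Injected sigma-burst model.

    ``density_per_min`` maps (stage, period-label) to events/min; periods are
    ``cue`` / ``nocue`` (from the cue log) and ``other`` (everything else).
    ``amplitude_ratio`` is the burst peak amplitude over the background
    sigma-band RMS of the same channel and stage.
    """

    density_per_min: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("N2", "cue"): 2.4, ("N2", "nocue"): 2.0, ("N2", "other"): 2.0,
        ("N3", "cue"): 1.8, ("N3", "nocue"): 1.5, ("N3", "other"): 1.5,
    })
    frequency_range_hz: tuple[float, float] = (11.5, 15.5)
    duration_range_s: tuple[float, float] = (0.6, 1.4)
    amplitude_ratio: float = 8.0
    #: Background RMS per stage, microvolts.
    background_rms_uv: dict[str, float] = field(default_factory=lambda: {
        "W": 15.0, "N1": 20.0, "N2": 30.0, "N3": 45.0, "REM": 20.0,
    })
    mastoid_scale: float = 0.3
    max_placement_retries: int = 100

    def __post_init__(self) -> None:
        lo, hi = self.frequency_range_hz
        if not (11.0 <= lo <= hi <= 16.0):
            raise ValueError("frequency range must lie within [11, 16] Hz")
        if any(d < 0 for d in self.density_per_min.values()):
            raise ValueError("densities must be nonnegative")


@dataclass
class CueModelConfig:
    tones_per_block: int = 12
    iti_range_ms: tuple[float, float] = (2500.0, 3500.0)
    silence_after_block_s: float = 20.0
    target_total_tones: int = 1000

    def __post_init__(self) -> None:
        lo, hi = self.iti_range_ms
        if not (2500.0 <= lo <= hi <= 3500.0):
            raise ValueError("iti_range_ms must lie within [2500, 3500]")


@dataclass
class BehaviourModelConfig:
    """SRTT reaction-time model, all values in milliseconds."""

    baseline_rt_ms: float = 400.0
    subject_sd_ms: float = 40.0
    residual_sd_ms: float = 80.0
    #: Per-session exponential learning curve (amplitude_ms, rate_per_block).
    learning_curve: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "S1": (120.0, 0.08), "S2": (40.0, 0.06),
        "S3": (30.0, 0.06), "S4": (30.0, 0.06),
    })
    random_block_penalty_ms: float = 60.0
    #: Cued-vs-uncued RT advantage per post-stimulation session.
    cueing_effect_ms: dict[str, float] = field(default_factory=lambda: {
        "S1": 0.0, "S2": 5.0, "S3": 10.0, "S4": 25.0,
    })
    rt_floor_ms: float = 150.0
    p_correct_first_press: float = 0.96

    def __post_init__(self) -> None:
        for v in (self.subject_sd_ms, self.residual_sd_ms,
                  self.random_block_penalty_ms):
            if v < 0:
                raise ValueError("SDs and penalties must be nonnegative")


@dataclass
class SimConfig:
    """Full configuration of a simulated study run."""

    seed: int
    n_subjects: int = 4
    raw_sampling_rate: float = 500.0
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    recording_duration_s: float = 3600.0
    stage_schedule: StageScheduleConfig = field(default_factory=StageScheduleConfig)
    spindle_model: SpindleModelConfig = field(default_factory=SpindleModelConfig)
    cue_model: CueModelConfig = field(default_factory=CueModelConfig)
    behaviour_model: BehaviourModelConfig = field(default_factory=BehaviourModelConfig)

    def __post_init__(self) -> None:
        missing = ({*LEFT_MOTOR_CHANNELS, *RIGHT_MOTOR_CHANNELS,
                    *MASTOID_CHANNELS} - set(self.channels))
        if missing:
            raise ValueError(f"channels must include the motor/mastoid set; "
                             f"missing {sorted(missing)}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.raw_sampling_rate <= 0:
            raise ValueError("raw_sampling_rate must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "stage_schedule" in d:
            sub = dict(d["stage_schedule"])
            if "cycle" in sub:
                sub["cycle"] = [tuple(x) for x in sub["cycle"]]
            if "arousal_duration_range_s" in sub:
                sub["arousal_duration_range_s"] = tuple(
                    sub["arousal_duration_range_s"])
            d["stage_schedule"] = StageScheduleConfig(**sub)
        if "spindle_model" in d:
            sub = dict(d["spindle_model"])
            if "density_per_min" in sub:
                sub["density_per_min"] = {
                    (k.split("/")[0], k.split("/")[1]) if isinstance(k, str)
                    else tuple(k): v
                    for k, v in sub["density_per_min"].items()}
            for key in ("frequency_range_hz", "duration_range_s"):
                if key in sub:
                    sub[key] = tuple(sub[key])
            d["spindle_model"] = SpindleModelConfig(**sub)
        if "cue_model" in d:
            sub = dict(d["cue_model"])
            if "iti_range_ms" in sub:
                sub["iti_range_ms"] = tuple(sub["iti_range_ms"])
            d["cue_model"] = CueModelConfig(**sub)
        if "behaviour_model" in d:
            sub = dict(d["behaviour_model"])
            for key in ("learning_curve",):
                if key in sub:
                    sub[key] = {k: tuple(v) for k, v in sub[key].items()}
            d["behaviour_model"] = BehaviourModelConfig(**sub)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spindle_model"]["density_per_min"] = {
            f"{s}/{p}": v
            for (s, p), v in self.spindle_model.density_per_min.items()}
        return d


# ---------------------------------------------------------------------------
# Hypnogram

def generate_hypnogram(config: SimConfig) -> Hypnogram:
    """Draw a cyclic stage sequence and uniformly placed arousals."""
    sched = config.stage_schedule
    n_epochs = int(config.recording_duration_s // sched.epoch_length_s)
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    rng = substream(config.seed, "hypnogram")
    stages: list[str] = []
    while len(stages) < n_epochs:
        for stage, mean_count in sched.cycle:
            count = max(0, int(round(
                mean_count * (1 + sched.jitter * rng.standard_normal()))))
            stages.extend([stage] * count)
    stages = stages[:n_epochs]

    sleep_epochs = [i for i, s in enumerate(stages) if s != "W"]
    arousals: list[tuple[float, float]] = []
    if sleep_epochs and sched.arousal_rate_per_hour > 0:
        sleep_hours = len(sleep_epochs) * sched.epoch_length_s / 3600.0
        n_arousals = rng.poisson(sched.arousal_rate_per_hour * sleep_hours)
        span = n_epochs * sched.epoch_length_s
        for _ in range(n_arousals):
            epoch = rng.choice(sleep_epochs)
            dur = rng.uniform(*sched.arousal_duration_range_s)
            start = epoch * sched.epoch_length_s + rng.uniform(
                0, sched.epoch_length_s)
            arousals.append((min(start, span - dur), min(start + dur, span)))
        arousals.sort()
    return Hypnogram(stages=stages, epoch_length=sched.epoch_length_s,
                     arousals=arousals)


# ---------------------------------------------------------------------------
# Cue log

def _stable_n2n3_intervals(hyp: Hypnogram) -> list[tuple[float, float]]:
    """Stable target sleep: the current *and previous* epoch are N2/N3."""
    good = [i for i in range(1, hyp.n_epochs)
            if hyp.stages[i] in ("N2", "N3")
            and hyp.stages[i - 1] in ("N2", "N3")]
    out: list[tuple[float, float]] = []
    for i in good:
        a, b = i * hyp.epoch_length, (i + 1) * hyp.epoch_length
        if out and out[-1][1] == a:
            out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return out


def _subtract_intervals(intervals, cuts):
    """Remove ``cuts`` from ``intervals`` (all half-open, sorted output)."""
    out = []
    for a, b in intervals:
        pieces = [(a, b)]
        for c, d in cuts:
            nxt = []
            for x, y in pieces:
                if d <= x or c >= y:
                    nxt.append((x, y))
                    continue
                if x < c:
                    nxt.append((x, c))
                if d < y:
                    nxt.append((d, y))
            pieces = nxt
        out.extend(pieces)
    return [iv for iv in out if iv[1] > iv[0]]


def generate_cue_log(config: SimConfig, hyp: Hypnogram) -> CueLog:
    """Place replay blocks inside stable, arousal-free N2/N3.

    Blocks hold exactly ``tones_per_block`` onsets with uniform inter-trial
    jitter and are followed by the configured silence; generation stops at
    ``target_total_tones`` or when eligible sleep is exhausted.
    """
    cm = config.cue_model
    rng = substream(config.seed, "cues")
    eligible = _subtract_intervals(_stable_n2n3_intervals(hyp), hyp.arousals)
    if not eligible:
        logger.warning("no stable N2/N3 sleep: cue log is empty")
        return CueLog(blocks=[])
    iti_lo, iti_hi = cm.iti_range_ms[0] / 1000.0, cm.iti_range_ms[1] / 1000.0
    blocks: list[list[float]] = []
    total = 0
    for a, b in eligible:
        t = a + rng.uniform(0.0, 1.0)
        while total + cm.tones_per_block <= cm.target_total_tones:
            gaps = rng.uniform(iti_lo, iti_hi, size=cm.tones_per_block - 1)
            onsets = t + np.concatenate(([0.0], np.cumsum(gaps)))
            if onsets[-1] + 0.5 > b:   # block must fit the stable interval
                break
            blocks.append([float(x) for x in onsets])
            total += cm.tones_per_block
            t = onsets[-1] + cm.silence_after_block_s + rng.uniform(0.2, 1.0)
        if total + cm.tones_per_block > cm.target_total_tones:
            break
    return CueLog(blocks=blocks)


# ---------------------------------------------------------------------------
# EEG

def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f ('pink') noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def sigma_burst(duration_s: float, freq_hz: float, fs: float,
                phase: float = 0.0) -> np.ndarray:
    """Raised-cosine (Hann) enveloped sinusoid with unit peak amplitude."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    envelope = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))
    return envelope * np.sin(2 * np.pi * freq_hz * t + phase)


def _stage_scale_array(hyp: Hypnogram, fs: float, n: int,
                       rms: dict[str, float]) -> np.ndarray:
    scale = np.empty(n)
    for i, stage in enumerate(hyp.stages):
        i0 = int(round(i * hyp.epoch_length * fs))
        i1 = min(int(round((i + 1) * hyp.epoch_length * fs)), n)
        scale[i0:i1] = rms.get(stage, 20.0)
    last = int(round(hyp.n_epochs * hyp.epoch_length * fs))
    if last < n:
        scale[last:] = scale[last - 1] if last > 0 else 20.0
    return scale


def _period_partition(hyp: Hypnogram, cues: CueLog, duration: float):
    """(stage, period) -> eligible, arousal-free placement intervals."""
    periods = build_periods(cues)
    labelled = {"cue": periods.by_label("cue"),
                "nocue": periods.by_label("nocue")}
    out: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for stage in ("W", "N1", "N2", "N3", "REM"):
        stage_iv = hyp.stage_intervals([stage])
        covered = labelled["cue"] + labelled["nocue"]
        for label in ("cue", "nocue"):
            iv = _intersect_lists(stage_iv, labelled[label])
            out[(stage, label)] = _subtract_intervals(iv, hyp.arousals)
        other = _subtract_intervals(stage_iv, covered)
        out[(stage, "other")] = _subtract_intervals(other, hyp.arousals)
    return out


def _intersect_lists(a, b):
    out = []
    for x0, x1 in a:
        for y0, y1 in b:
            lo, hi = max(x0, y0), min(x1, y1)
            if hi > lo:
                out.append((lo, hi))
    return sorted(out)


def generate_eeg(config: SimConfig, hyp: Hypnogram, cues: CueLog,
                 ) -> tuple[EEGRecording, list[GroundTruthEvent]]:
    """Stage-scaled pink-noise EEG with injected, ground-truthed sigma bursts.

    Burst placement is Poisson per (stage, period) at the configured density,
    uniform within the eligible arousal-free time; overlapping placements on
    a channel are re-drawn up to a bounded retry count.
    """
    sm = config.spindle_model
    fs = config.raw_sampling_rate
    n = int(round(config.recording_duration_s * fs))
    rng = substream(config.seed, "eeg")
    scale = _stage_scale_array(hyp, fs, n, sm.background_rms_uv)
    partition = _period_partition(hyp, cues, config.recording_duration_s)
    sigma_sos = design_cheby2_sos(SIGMA_SPEC, fs)

    data = np.empty((len(config.channels), n))
    truth: list[GroundTruthEvent] = []
    dur_lo, dur_hi = sm.duration_range_s
    f_lo, f_hi = sm.frequency_range_hz
    for ci, ch in enumerate(config.channels):
        noise = pink_noise(n, rng)
        ch_scale = sm.mastoid_scale if ch in MASTOID_CHANNELS else 1.0
        data[ci] = noise * scale * ch_scale
        if ch in MASTOID_CHANNELS:
            continue   # reference channels carry no injected bursts
        # Background sigma RMS of the *unit* noise; per-stage RMS scales it.
        sigma_rms_unit = float(np.sqrt(
            np.mean(apply_zero_phase(sigma_sos, noise) ** 2)))
        placed: list[tuple[float, float]] = []
        for (stage, label), intervals in partition.items():
            density = sm.density_per_min.get((stage, label), 0.0)
            if density <= 0 or not intervals:
                continue
            lengths = np.array([b - a for a, b in intervals])
            total_min = lengths.sum() / 60.0
            n_events = rng.poisson(density * total_min)
            for _ in range(n_events):
                dur = rng.uniform(dur_lo, dur_hi)
                ok = False
                for _try in range(sm.max_placement_retries):
                    seg = rng.choice(len(intervals), p=lengths / lengths.sum())
                    a, b = intervals[seg]
                    if b - a <= dur:
                        continue
                    onset = rng.uniform(a, b - dur)
                    if all(onset + dur <= s or onset >= e
                           for s, e in placed):
                        ok = True
                        break
                if not ok:
                    raise RuntimeError(
                        f"could not place a {dur:.2f}s burst on {ch} "
                        f"({stage}/{label}): density too high")
                freq = rng.uniform(f_lo, f_hi)
                phase = rng.uniform(0, 2 * np.pi)
                amp = sm.amplitude_ratio * sigma_rms_unit * scale[
                    int(onset * fs)]
                i0 = int(round(onset * fs))
                wave = amp * sigma_burst(dur, freq, fs, phase)
                data[ci, i0:i0 + wave.size] += wave[:n - i0]
                placed.append((onset, onset + dur))
                truth.append(GroundTruthEvent(ch, float(onset), float(dur),
                                              float(freq), sm.amplitude_ratio))
    rec = EEGRecording(list(config.channels), fs, data)
    truth.sort(key=lambda e: (e.channel, e.onset_s))
    return rec, truth


def single_channel_burst_record(
        seed: int, durations: tuple[float, ...] = (0.8,), repeats: int = 10,
        frequency_hz: float = 13.0, amplitude_ratio: float = 10.0,
        fs: float = 250.0, record_s: float = 600.0,
        gap_range_s: tuple[float, float] = (8.0, 12.0), channel: str = "C3",
        ) -> tuple[EEGRecording, Hypnogram, list[GroundTruthEvent]]:
    """One channel of pink noise with well-separated injected sigma bursts.

    Each entry of ``durations`` is injected ``repeats`` times in shuffled
    order, separated by uniform gaps; ``amplitude_ratio`` is peak amplitude
    over the channel's background sigma-band RMS.  The companion hypnogram
    stages the whole record as N2.  The workhorse fixture for detector
    validation.
    """
    rng = np.random.default_rng(seed)
    n = int(round(record_s * fs))
    noise = pink_noise(n, rng)
    sos = design_cheby2_sos(SIGMA_SPEC, fs)
    sigma_rms = float(np.sqrt(np.mean(apply_zero_phase(sos, noise) ** 2)))
    data = noise.copy()
    schedule = list(durations) * repeats
    rng.shuffle(schedule)
    truth: list[GroundTruthEvent] = []
    t = gap_range_s[0]
    for dur in schedule:
        if t + dur + gap_range_s[1] > record_s:
            raise ValueError("record too short for the requested bursts")
        wave = amplitude_ratio * sigma_rms * sigma_burst(
            dur, frequency_hz, fs, rng.uniform(0, 2 * np.pi))
        i0 = int(round(t * fs))
        data[i0:i0 + wave.size] += wave
        truth.append(GroundTruthEvent(channel, float(t), float(dur),
                                      frequency_hz, amplitude_ratio))
        t += dur + rng.uniform(*gap_range_s)
    rec = EEGRecording([channel], fs, data[None, :])
    hyp = Hypnogram(stages=["N2"] * int(record_s // 30))
    return rec, hyp, truth


# ---------------------------------------------------------------------------
# Behaviour

def _interleave_block_types(rng: np.random.Generator, n_each: int = 24,
                            max_run: int = 2) -> list[str]:
    """Pseudo-random cued/uncued order with runs of at most ``max_run``."""
    counts = {"cued_seq": n_each, "uncued_seq": n_each}
    order: list[str] = []
    while counts["cued_seq"] or counts["uncued_seq"]:
        options = [t for t, c in counts.items() if c > 0]
        if len(order) >= max_run and len(set(order[-max_run:])) == 1:
            options = [t for t in options if t != order[-1]]
        if not options:   # dead end: forced run; restart (rare)
            counts = {"cued_seq": n_each, "uncued_seq": n_each}
            order = []
            continue
        weights = np.array([counts[t] for t in options], dtype=float)
        pick = options[rng.choice(len(options), p=weights / weights.sum())]
        order.append(pick)
        counts[pick] -= 1
    return order


def generate_behaviour(config: SimConfig) -> pd.DataFrame:
    """Simulated SRTT trial table for all subjects and sessions.

    Per session: 48 sequence blocks (24 cued + 24 uncued, interleaved with
    no more than two of a type in a row) followed by 4 random blocks
    (alternating tone sets); each block holds 36 trials (3 repetitions of 12
    items).  ``rt_ms = baseline + subject intercept + learning curve +
    random-block penalty - cueing effect (cued sequence) + noise``, floored
    at 150 ms.
    """
    bm = config.behaviour_model
    rng = substream(config.seed, "behaviour")
    item_seq = {"cued_seq": beh.SEQUENCE_A, "uncued_seq": beh.SEQUENCE_B}
    rows = []
    for subj in range(config.n_subjects):
        subject_id = f"sub{subj + 1:02d}"
        intercept = rng.normal(0.0, bm.subject_sd_ms)
        for session in ("S1", "S2", "S3", "S4"):
            amp, rate = bm.learning_curve[session]
            effect = bm.cueing_effect_ms.get(session, 0.0)
            order = _interleave_block_types(rng)
            order += ["rand_cuedtones", "rand_uncuedtones"] * 2
            for bi, btype in enumerate(order):
                if btype in beh.RANDOM_BLOCK_TYPES:
                    items = list(beh.generate_random_block(rng)) * 3
                else:
                    items = list(item_seq[btype]) * 3
                curve = amp * np.exp(-rate * bi)
                for ti, item in enumerate(items):
                    rt = (bm.baseline_rt_ms + intercept + curve
                          + (bm.random_block_penalty_ms
                             if btype in beh.RANDOM_BLOCK_TYPES else 0.0)
                          - (effect if btype == "cued_seq" else 0.0)
                          + rng.normal(0.0, bm.residual_sd_ms))
                    rows.append((
                        subject_id, session, bi, btype, ti, item,
                        beh.ITEM_HAND[item], max(rt, bm.rt_floor_ms),
                        bool(rng.random() < bm.p_correct_first_press),
                    ))
    return pd.DataFrame(rows, columns=[
        "subject_id", "session", "block_index", "block_type", "trial_index",
        "item", "hand", "rt_ms", "correct_first_press"])
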