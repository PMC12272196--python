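"""File formats: EDF, hypnogram/cue TSV, trial and event CSV.

EEG is written as 16-bit EDF with physical units in microvolts and read back
through MNE's EDF reader.  Writing uses a small built-in EDF encoder (one
1-second data record per block, one channel per signal); reading any
standards-compliant EDF goes through ``mne.io.read_raw_edf``, and BrainVision
triplets through ``mne.io.read_raw_brainvision``.

Tabular sidecars are plain TSV/CSV: hypnogram (epoch_index, stage) with a
companion arousal table (start_s, end_s; half-open), cue log (block_index,
tone_index, onset_s), trials, ground-truth bursts, detected spindles, and
density tables.
"""

from __future__ import annotations

import dataclasses
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (CueLog, EEGRecording, GroundTruthEvent, Hypnogram,
                    SpindleEvent)


# ---------------------------------------------------------------------------
# EDF

def _pad(text: str, width: int) -> bytes:
    return text.encode("ascii")[:width].ljust(width)


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as 16-bit EDF (physical units microvolts).

    Uses 1-second data records, so the sampling rate must be a whole number;
    a trailing partial second is zero-padded.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = int(np.ceil(rec.n_samples / fs))
    nch = rec.n_channels
    data = np.zeros((nch, n_rec * fs))
    data[:, :rec.n_samples] = rec.data

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_max, dig_min = 32767, -32768
    scaled = np.clip(data / phys_max[:, None] * dig_max, dig_min, dig_max)
    digital = np.round(scaled).astype("<i2")

    header = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(str(256 * (nch + 1)), 8), _pad("", 44),
        _pad(str(n_rec), 8), _pad("1", 8), _pad(str(nch), 4),
    ])
    fields = [
        ("%s" % ch, 16) for ch in rec.channel_names
    ]
    sig_header = b"".join(_pad(label, w) for label, w in fields)
    sig_header += b"".join(_pad("", 80) for _ in range(nch))          # transducer
    sig_header += b"".join(_pad("uV", 8) for _ in range(nch))         # unit
    sig_header += b"".join(_pad(f"{-m:.6g}"[:8], 8) for m in phys_max)
    sig_header += b"".join(_pad(f"{m:.6g}"[:8], 8) for m in phys_max)
    sig_header += b"".join(_pad(str(dig_min), 8) for _ in range(nch))
    sig_header += b"".join(_pad(str(dig_max), 8) for _ in range(nch))
    sig_header += b"".join(_pad("", 80) for _ in range(nch))          # prefilter
    sig_header += b"".join(_pad(str(fs), 8) for _ in range(nch))
    sig_header += b"".join(_pad("", 32) for _ in range(nch))

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            for c in range(nch):
                fh.write(digital[c, r * fs:(r + 1) * fs].tobytes())


def read_edf(path, duration_s: float | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts)."""
    import mne
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6   # MNE holds volts
    rec = EEGRecording(list(raw.ch_names), float(raw.info["sfreq"]), data)
    if duration_s is not None:
        n = int(round(duration_s * rec.sampling_rate))
        rec = EEGRecording(rec.channel_names, rec.sampling_rate,
                           rec.data[:, :n])
    return rec


def read_brainvision(vhdr_path) -> EEGRecording:
    """Read a BrainVision triplet (.vhdr/.eeg/.vmrk) into an EEGRecording."""
    import mne
    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return EEGRecording(list(raw.ch_names), float(raw.info["sfreq"]),
                        raw.get_data() * 1e6)


# ---------------------------------------------------------------------------
# Tabular sidecars

def write_hypnogram(hyp: Hypnogram, stage_path, arousal_path) -> None:
    pd.DataFrame({"epoch_index": range(hyp.n_epochs), "stage": hyp.stages}) \
        .to_csv(stage_path, sep="\t", index=False)
    pd.DataFrame(hyp.arousals, columns=["start_s", "end_s"]) \
        .to_csv(arousal_path, sep="\t", index=False)


def read_hypnogram(stage_path, arousal_path=None,
                   epoch_length: float = 30.0) -> Hypnogram:
    stages = pd.read_csv(stage_path, sep="\t").sort_values("epoch_index")
    arousals = []
    if arousal_path is not None and Path(arousal_path).exists():
        ar = pd.read_csv(arousal_path, sep="\t")
        arousals = list(zip(ar.start_s, ar.end_s))
    return Hypnogram(stages=list(stages.stage), epoch_length=epoch_length,
                     arousals=arousals)


def write_cue_log(cues: CueLog, path) -> None:
    rows = [(bi, ti, onset) for bi, block in enumerate(cues.blocks)
            for ti, onset in enumerate(block)]
    pd.DataFrame(rows, columns=["block_index", "tone_index", "onset_s"]) \
        .to_csv(path, sep="\t", index=False)


def read_cue_log(path) -> CueLog:
    df = pd.read_csv(path, sep="\t")
    blocks = [list(grp.sort_values("tone_index").onset_s)
              for _, grp in df.groupby("block_index")]
    return CueLog(blocks=blocks)


def write_ground_truth(events: list[GroundTruthEvent], path) -> None:
    pd.DataFrame([dataclasses.asdict(e) for e in events]) \
        .to_csv(path, index=False)


def read_ground_truth(path) -> list[GroundTruthEvent]:
    df = pd.read_csv(path)
    return [GroundTruthEvent(**row) for row in df.to_dict("records")]


def write_spindles(events: list[SpindleEvent], path) -> None:
    pd.DataFrame([{**dataclasses.asdict(e), "duration_s": e.duration_s}
                  for e in events]).to_csv(path, index=False)


def read_spindles(path) -> list[SpindleEvent]:
    df = pd.read_csv(path)
    fields = {f.name for f in dataclasses.fields(SpindleEvent)}
    return [SpindleEvent(**{k: v for k, v in row.items() if k in fields})
            for row in df.to_dict("records")]
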