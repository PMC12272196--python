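"""EEG preprocessing: resampling, broadband filtering, interpolation, re-referencing.

The chain mirrors standard overnight-EEG preparation for spindle analysis:
down-sample to 250 Hz, zero-phase Chebyshev Type II band-pass (0.3-35 Hz
passband, <0.1 / >45 Hz stopbands), interpolate bad channels from named
neighbours, and re-reference to the linked mastoids (TP9, TP10).

Filters are applied forward-backward (zero phase) so that event timing is
preserved for cue-locked windowing.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .types import EEGRecording, FilterSpec, BROADBAND_SPEC, MASTOID_CHANNELS

TARGET_RATE_HZ = 250.0


def design_cheby2_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Minimum-order Chebyshev II band-pass meeting ``spec`` at rate ``fs``.

    The order is the smallest satisfying the passband ripple and stopband
    attenuation targets given the printed band edges.
    """
    nyq = fs / 2.0
    if spec.stopband_hz[1] >= nyq:
        raise ValueError(
            f"stopband edge {spec.stopband_hz[1]} Hz at or above Nyquist ({nyq} Hz)"
        )
    order, wn = signal.cheb2ord(
        wp=list(spec.passband_hz), ws=list(spec.stopband_hz),
        gpass=spec.passband_ripple_db, gstop=spec.stopband_attenuation_db,
        fs=fs,
    )
    return signal.cheby2(order, spec.stopband_attenuation_db, wn,
                         btype="bandpass", output="sos", fs=fs)


def apply_zero_phase(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Forward-backward (zero-phase) filtering along the last axis."""
    return signal.sosfiltfilt(sos, data, axis=-1)


def resample(rec: EEGRecording, target_hz: float) -> EEGRecording:
    """Down-sample with polyphase anti-alias filtering.

    Upsampling is out of contract and raises.
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if target_hz > rec.sampling_rate:
        raise ValueError(
            f"upsampling {rec.sampling_rate} -> {target_hz} Hz is out of contract"
        )
    if target_hz == rec.sampling_rate:
        return rec.copy()
    frac = Fraction(target_hz / rec.sampling_rate).limit_denominator(1000)
    # linear-extension padding keeps edges faithful for constant/slow signals
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                axis=-1, padtype="line")
    return EEGRecording(list(rec.channel_names), target_hz, data, rec.start_time)


def broadband_filter(rec: EEGRecording,
                     spec: FilterSpec = BROADBAND_SPEC) -> EEGRecording:
    """Zero-phase broadband Chebyshev II filtering of every channel."""
    if rec.sampling_rate <= 2 * spec.stopband_hz[1]:
        raise ValueError("sampling rate too low for the requested stopband")
    sos = design_cheby2_sos(spec, rec.sampling_rate)
    return EEGRecording(list(rec.channel_names), rec.sampling_rate,
                        apply_zero_phase(sos, rec.data), rec.start_time)


def interpolate_channel(rec: EEGRecording, bad: str,
                        neighbours: list[str]) -> EEGRecording:
    """Replace ``bad`` with the unweighted mean of its ``neighbours``.

    Channel lookup is case-insensitive; unknown labels raise ``KeyError``
    naming the missing channel.
    """
    if not neighbours:
        raise ValueError("neighbours must be nonempty")
    out = rec.copy()
    bad_idx = out.channel_index(bad)
    neighbour_idx = [out.channel_index(n) for n in neighbours]
    out.data[bad_idx] = out.data[neighbour_idx].mean(axis=0)
    return out


def rereference_mastoids(rec: EEGRecording) -> EEGRecording:
    """Subtract the mean of (TP9, TP10) from every non-mastoid channel."""
    idx = [rec.channel_index(m) for m in MASTOID_CHANNELS]
    ref = rec.data[idx].mean(axis=0)
    out = rec.copy()
    mastoids = set(idx)
    for i in range(out.n_channels):
        if i not in mastoids:
            out.data[i] = out.data[i] - ref
    return out


def preprocess(rec: EEGRecording, target_hz: float = TARGET_RATE_HZ,
               spec: FilterSpec = BROADBAND_SPEC) -> EEGRecording:
    """Full chain: resample to 250 Hz, broadband filter, mastoid re-reference."""
    out = resample(rec, min(target_hz, rec.sampling_rate))
    out = broadband_filter(out, spec)
    return rereference_mastoids(out)
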