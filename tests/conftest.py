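"""Shared fixtures: small synthetic nights and behaviour tables.

Expensive generator outputs are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import dataclasses

import pytest

from cuespindle import pipeline as pl
from cuespindle import synthetic_data as syn


@pytest.fixture(scope="session")
def small_cfg() -> syn.SimConfig:
    """A 20-minute two-subject study at the default generator settings."""
    return syn.SimConfig(seed=11, n_subjects=2, recording_duration_s=1200)


@pytest.fixture(scope="session")
def night(small_cfg):
    """(hypnogram, cue log, raw EEG, ground truth) of subject 0."""
    return pl.simulate_subject(small_cfg, 0)


@pytest.fixture(scope="session")
def behaviour_cfg() -> syn.SimConfig:
    """20 subjects for behaviour-level parameter recovery."""
    return syn.SimConfig(seed=5, n_subjects=20, recording_duration_s=600)


@pytest.fixture(scope="session")
def trials(behaviour_cfg):
    return syn.generate_behaviour(behaviour_cfg)


@pytest.fixture(scope="session")
def null_behaviour_trials():
    """Behaviour with zero cueing effect and flat learning, 20 subjects."""
    cfg = syn.SimConfig(
        seed=17, n_subjects=20, recording_duration_s=600,
        behaviour_model=syn.BehaviourModelConfig(
            cueing_effect_ms={s: 0.0 for s in ("S1", "S2", "S3", "S4")},
            learning_curve={s: (0.0, 0.06) for s in ("S1", "S2", "S3", "S4")},
        ))
    return syn.generate_behaviour(cfg)


@pytest.fixture(scope="session")
def burst_night():
    """Single-channel record with in- and out-of-criterion 13 Hz bursts."""
    return syn.single_channel_burst_record(
        seed=1, durations=(0.3, 0.8, 1.2, 2.5), repeats=8, record_s=600.0)
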