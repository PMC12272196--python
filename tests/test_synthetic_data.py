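"""Generator contracts: determinism, cue-log legality, injected-burst realism."""

import dataclasses

import numpy as np
import pytest
from scipy import signal

from cuespindle import synthetic_data as syn
from cuespindle.types import MASTOID_CHANNELS


def _replace_schedule(cfg, **kw):
    return dataclasses.replace(
        cfg, stage_schedule=dataclasses.replace(cfg.stage_schedule, **kw))


class TestHypnogram:
    def test_epoch_count_matches_duration(self, small_cfg):
        hyp = syn.generate_hypnogram(small_cfg)
        assert hyp.n_epochs == int(small_cfg.recording_duration_s // 30)

    def test_zero_arousal_rate_gives_no_arousals(self, small_cfg):
        cfg = _replace_schedule(small_cfg, arousal_rate_per_hour=0.0)
        assert syn.generate_hypnogram(cfg).arousals == []

    def test_arousals_lie_within_recording(self, small_cfg):
        hyp = syn.generate_hypnogram(small_cfg)
        for a, b in hyp.arousals:
            assert 0 <= a < b <= hyp.duration

    def test_subepoch_duration_rejected(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, recording_duration_s=10.0)
        with pytest.raises(ValueError):
            syn.generate_hypnogram(cfg)

    def test_seed_determinism(self, small_cfg):
        a = syn.generate_hypnogram(small_cfg)
        b = syn.generate_hypnogram(small_cfg)
        assert a.stages == b.stages and a.arousals == b.arousals


class TestCueLog:
    def test_pure_wake_yields_no_blocks(self, small_cfg, caplog):
        cfg = _replace_schedule(small_cfg, cycle=[("W", 10)])
        hyp = syn.generate_hypnogram(cfg)
        with caplog.at_level("WARNING"):
            cues = syn.generate_cue_log(cfg, hyp)
        assert cues.blocks == []
        assert any("N2/N3" in r.message or "stable" in r.message
                   for r in caplog.records)

    def test_blocks_have_12_tones_with_legal_jitter(self, small_cfg, night):
        _, cues, _, _ = night
        assert cues.blocks, "expected at least one replay block"
        for block in cues.blocks:
            assert len(block) == small_cfg.cue_model.tones_per_block == 12
            gaps = np.diff(block)
            assert gaps.min() >= 2.5 and gaps.max() <= 3.5

    def test_onsets_in_stable_sleep_outside_arousals(self, night):
        hyp, cues, _, _ = night
        for block in cues.blocks:
            for onset in block:
                epoch = int(onset // hyp.epoch_length)
                assert hyp.stages[epoch] in ("N2", "N3")
                assert hyp.stages[epoch - 1] in ("N2", "N3")
                assert not hyp.overlaps_arousal(onset, onset + 0.2)

    def test_silence_between_blocks(self, night):
        _, cues, _, _ = night
        for prev, nxt in zip(cues.blocks, cues.blocks[1:]):
            assert nxt[0] - prev[-1] >= 20.0

    def test_respects_target_total_tones(self, small_cfg):
        cfg = dataclasses.replace(
            small_cfg, cue_model=syn.CueModelConfig(target_total_tones=36))
        hyp = syn.generate_hypnogram(cfg)
        cues = syn.generate_cue_log(cfg, hyp)
        assert cues.n_tones <= 36


class TestEEG:
    def test_zero_density_gives_pure_noise(self, small_cfg):
        cfg = dataclasses.replace(
            small_cfg, recording_duration_s=300.0,
            spindle_model=dataclasses.replace(
                small_cfg.spindle_model, density_per_min={}))
        hyp = syn.generate_hypnogram(cfg)
        cues = syn.generate_cue_log(cfg, hyp)
        rec, truth = syn.generate_eeg(cfg, hyp, cues)
        assert truth == []
        assert rec.n_samples == int(300 * cfg.raw_sampling_rate)

    def test_burst_metadata_within_configured_ranges(self, small_cfg, night):
        _, _, _, truth = night
        sm = small_cfg.spindle_model
        for ev in truth:
            assert sm.duration_range_s[0] <= ev.duration_s <= sm.duration_range_s[1]
            assert 11.0 <= ev.frequency_hz <= 16.0
            assert ev.channel not in MASTOID_CHANNELS

    def test_bursts_avoid_arousals_and_overlaps(self, night):
        hyp, _, _, truth = night
        for ev in truth:
            assert not hyp.overlaps_arousal(ev.onset_s, ev.end_s)
        by_channel = {}
        for ev in truth:
            by_channel.setdefault(ev.channel, []).append((ev.onset_s, ev.end_s))
        for intervals in by_channel.values():
            intervals.sort()
            for (_, e1), (s2, _) in zip(intervals, intervals[1:]):
                assert s2 >= e1

    def test_period_densities_match_poisson_expectation(self):
        """Cue 4/min vs no-cue 2/min over >=30 min of N2: counts in 3 SE."""
        cfg = syn.SimConfig(
            seed=23, n_subjects=1, recording_duration_s=2400.0,
            stage_schedule=syn.StageScheduleConfig(
                cycle=[("N2", 80)], arousal_rate_per_hour=0.0),
            spindle_model=dataclasses.replace(
                syn.SimConfig(seed=0).spindle_model,
                density_per_min={("N2", "cue"): 4.0, ("N2", "nocue"): 2.0}),
            cue_model=syn.CueModelConfig(target_total_tones=360))
        hyp = syn.generate_hypnogram(cfg)
        cues = syn.generate_cue_log(cfg, hyp)
        rec, truth = syn.generate_eeg(cfg, hyp, cues)
        from cuespindle.cue_windows import build_periods
        periods = build_periods(cues)
        n_channels = len([c for c in cfg.channels if c not in MASTOID_CHANNELS])
        for label, density in (("cue", 4.0), ("nocue", 2.0)):
            minutes = sum(b - a for a, b in periods.by_label(label)) / 60.0
            expected = density * minutes * n_channels
            observed = sum(
                1 for ev in truth
                if any(a <= ev.onset_s and ev.end_s <= b
                       for a, b in periods.by_label(label)))
            assert abs(observed - expected) <= 3 * np.sqrt(expected), label

    def test_injected_burst_raises_sigma_band_power(self):
        """Band power 11-16 Hz during a burst exceeds the flanking noise."""
        rec, _, truth = syn.single_channel_burst_record(
            seed=2, durations=(1.0,), repeats=3, amplitude_ratio=10.0)
        fs = rec.sampling_rate
        x = rec.data[0]

        def band_power(seg):
            f, p = signal.periodogram(seg, fs=fs)
            return p[(f >= 11) & (f <= 16)].sum()

        for ev in truth:
            i0, i1 = int(ev.onset_s * fs), int(ev.end_s * fs)
            n = i1 - i0
            burst = band_power(x[i0:i1])
            flank = band_power(x[i0 - n - 10:i0 - 10])
            assert burst > flank

    def test_eeg_seed_determinism(self, small_cfg, night):
        from cuespindle.pipeline import _subject_config
        hyp, cues, rec, truth = night
        rec2, truth2 = syn.generate_eeg(
            _subject_config(small_cfg, 0), hyp, cues)
        assert np.array_equal(rec.data, rec2.data)
        assert truth == truth2


class TestBehaviour:
    def test_block_structure_per_session(self, trials):
        one = trials[(trials.subject_id == "sub01") & (trials.session == "S2")]
        counts = one.groupby("block_type").block_index.nunique()
        assert counts["cued_seq"] == 24 and counts["uncued_seq"] == 24
        assert counts["rand_cuedtones"] == 2 and counts["rand_uncuedtones"] == 2
        assert (one.groupby("block_index").size() == 36).all()

    def test_no_more_than_two_sequence_blocks_in_a_row(self, trials):
        for (_, _), grp in trials.groupby(["subject_id", "session"]):
            order = (grp[grp.block_type.isin(["cued_seq", "uncued_seq"])]
                     .drop_duplicates("block_index")
                     .sort_values("block_index").block_type.tolist())
            run = 1
            for a, b in zip(order, order[1:]):
                run = run + 1 if a == b else 1
                assert run <= 2

    def test_item_hand_mapping(self, trials):
        assert (trials[trials.item.isin([1, 2])].hand == "L").all()
        assert (trials[trials.item.isin([3, 4])].hand == "R").all()

    def test_rt_floor(self, trials):
        assert (trials.rt_ms >= 150.0).all()

    def test_null_cueing_effect_gives_zero_mean_difference(
            self, null_behaviour_trials):
        t = null_behaviour_trials
        t = t[t.session != "S1"]
        block_means = (t[t.block_type.isin(["cued_seq", "uncued_seq"])]
                       .groupby(["subject_id", "session", "block_type",
                                 "block_index"]).rt_ms.mean().reset_index())
        per_subj = (block_means.pivot_table(index="subject_id",
                                            columns="block_type",
                                            values="rt_ms"))
        diff = per_subj.cued_seq - per_subj.uncued_seq
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) <= 3 * se

    def test_trial_table_determinism(self, behaviour_cfg, trials):
        again = syn.generate_behaviour(behaviour_cfg)
        assert again.equals(trials)
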