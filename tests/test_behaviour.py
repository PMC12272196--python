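"""SRTT scoring: trial filter, SeqSpecS, cueing benefit, random blocks, recall."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from cuespindle import behaviour as beh


def _trial_rows(subject, session, block_type, block_index, rts, items=None):
    items = items or ([1, 2, 3, 4] * 9)[:len(rts)]
    return pd.DataFrame({
        "subject_id": subject, "session": session,
        "block_index": block_index, "block_type": block_type,
        "trial_index": range(len(rts)), "item": items,
        "hand": [beh.ITEM_HAND[i] for i in items], "rt_ms": rts,
        "correct_first_press": True,
    })


class TestFilterTrials:
    def test_strictly_exceeding_cutoff_dropped(self):
        t = _trial_rows("s1", "S2", "cued_seq", 0, [300, 999, 1000, 1001])
        assert sorted(beh.filter_trials(t).rt_ms) == [300, 999, 1000]

    def test_all_within_cutoff_identity(self):
        t = _trial_rows("s1", "S2", "cued_seq", 0, [300, 400])
        assert beh.filter_trials(t).equals(t)

    def test_incorrect_first_press_retained(self):
        t = _trial_rows("s1", "S2", "cued_seq", 0, [800])
        t["correct_first_press"] = False
        assert len(beh.filter_trials(t)) == 1


def _session_table(rand_rt, seq_rts_cued, seq_rts_uncued):
    """One subject/session: 4 random blocks + n sequence blocks per type."""
    frames = []
    bi = 0
    for seq_type, rts in (("cued_seq", seq_rts_cued),
                          ("uncued_seq", seq_rts_uncued)):
        for rt in rts:
            frames.append(_trial_rows("s1", "S2", seq_type, bi, [rt] * 36))
            bi += 1
    for rt_type in ("rand_cuedtones", "rand_uncuedtones"):
        for _ in range(2):
            frames.append(_trial_rows("s1", "S2", rt_type, bi, [rand_rt] * 36))
            bi += 1
    return pd.concat(frames, ignore_index=True)


class TestSeqSpecS:
    def test_formula_arithmetic(self):
        t = _session_table(500.0, [450.0] * 4, [500.0] * 4)
        early = beh.seq_spec_skill(t, "early")
        cued = early[early.sequence == "cued"].value.iloc[0]
        assert cued == pytest.approx(50.0)

    def test_equal_blocks_give_zero(self):
        t = _session_table(500.0, [500.0] * 4, [500.0] * 4)
        out = beh.seq_spec_skill(t, "late")
        assert np.allclose(out.value, 0.0)

    def test_early_late_use_first_last_four(self):
        rts = [480, 470, 460, 450, 420, 410, 400, 390]
        t = _session_table(500.0, rts, [500.0] * 8)
        early = beh.seq_spec_skill(t, "early")
        late = beh.seq_spec_skill(t, "late")
        cued_e = early[early.sequence == "cued"].value.iloc[0]
        cued_l = late[late.sequence == "cued"].value.iloc[0]
        assert cued_e == pytest.approx(500 - np.mean(rts[:4]))
        assert cued_l == pytest.approx(500 - np.mean(rts[4:]))

    def test_too_few_blocks_raises_with_context(self):
        t = _session_table(500.0, [450.0] * 3, [500.0] * 4)
        with pytest.raises(ValueError, match="s1"):
            beh.seq_spec_skill(t, "early")

    def test_shift_invariance(self):
        t = _session_table(500.0, [480, 470, 460, 450], [500.0] * 4)
        shifted = t.copy()
        shifted.rt_ms = shifted.rt_ms + 123.0
        a = beh.seq_spec_skill(t, "early")
        b = beh.seq_spec_skill(shifted, "early")
        assert np.allclose(a.value, b.value)

    def test_penalty_recovery_from_generator(self, null_behaviour_trials):
        """Flat learning, zero cueing: late SeqSpecS ~ random-block penalty."""
        kept = beh.filter_trials(null_behaviour_trials)
        late = beh.seq_spec_skill(kept[kept.session == "S2"], "late")
        se = late.value.std(ddof=1) / np.sqrt(len(late))
        assert abs(late.value.mean() - 60.0) <= 3 * se


class TestCueingBenefit:
    def _seqspecs(self, cued, uncued):
        return pd.DataFrame({
            "subject_id": "s1", "session": "S2", "timepoint": "late",
            "sequence": ["cued", "uncued"], "value": [cued, uncued]})

    def test_difference(self):
        out = beh.cueing_benefit(self._seqspecs(60.0, 40.0))
        assert out.value.iloc[0] == pytest.approx(20.0)
        assert out.days_post_tmr.iloc[0] == 1

    def test_equal_sequences_zero(self):
        assert beh.cueing_benefit(self._seqspecs(33.0, 33.0)).value.iloc[0] == 0.0

    def test_antisymmetry_under_label_swap(self):
        ss = self._seqspecs(60.0, 40.0)
        swapped = ss.copy()
        swapped.sequence = swapped.sequence.map(
            {"cued": "uncued", "uncued": "cued"})
        a = beh.cueing_benefit(ss).value.iloc[0]
        b = beh.cueing_benefit(swapped).value.iloc[0]
        assert a == -b

    def test_missing_counterpart_skipped(self, caplog):
        ss = self._seqspecs(60.0, 40.0).iloc[:1]
        with caplog.at_level("WARNING"):
            out = beh.cueing_benefit(ss)
        assert out.empty

    def test_session_ordering_recovered_from_generator(self, trials):
        """Configured effects S2 < S3 < S4 appear in the recovered means."""
        kept = beh.filter_trials(trials)
        seqspecs = beh.seq_spec_skill(
            kept[kept.session.isin(["S2", "S3", "S4"])], "late")
        benefits = beh.cueing_benefit(seqspecs)
        means = benefits.groupby("session").value.mean()
        assert means["S2"] < means["S3"] < means["S4"]


class TestSplitByHand:
    def test_single_item_table(self):
        t = _trial_rows("s1", "S2", "cued_seq", 0, [400] * 6, items=[1] * 6)
        lh, rh = beh.split_by_hand(t)
        assert len(lh) == 6 and rh.empty

    def test_sequence_block_splits_evenly(self):
        items = list(beh.SEQUENCE_A) * 3
        t = _trial_rows("s1", "S2", "cued_seq", 0, [400] * 36, items=items)
        lh, rh = beh.split_by_hand(t)
        assert len(lh) == 18 and len(rh) == 18

    def test_partition_conserves_rows(self, trials):
        lh, rh = beh.split_by_hand(trials)
        assert len(lh) + len(rh) == len(trials)


def _brute_force_max_shared_run(cand, seq):
    best = 0
    for i in range(len(cand)):
        for j in range(len(seq)):
            k = 0
            while (i + k < len(cand) and j + k < len(seq)
                   and cand[i + k] == seq[j + k]):
                k += 1
            best = max(best, k)
    return best


class TestRandomBlocks:
    def test_constraints_over_seeded_draws(self):
        for seed in range(200):
            cand = beh.generate_random_block(seed)
            assert sorted(cand) == [1, 1, 1, 2, 2, 2, 3, 3, 3, 4, 4, 4]
            assert all(a != b for a, b in zip(cand, cand[1:]))
            for seq in (beh.SEQUENCE_A, beh.SEQUENCE_B):
                assert _brute_force_max_shared_run(cand, seq) <= 4

    def test_seeded_reproducibility(self):
        assert beh.generate_random_block(7) == beh.generate_random_block(7)


class TestExplicitMemory:
    def test_perfect_recall_scores_twelve(self):
        assert beh.score_explicit(beh.SEQUENCE_A, beh.SEQUENCE_A) == 12

    def test_isolated_match_scores_nothing(self):
        truth = (1, 2, 3, 4, 1, 2, 3, 4, 1, 2, 3, 4)
        resp = (1, 3, 2, 1, 4, 3, 2, 1, 4, 3, 2, 1)   # only position 0 matches
        assert beh.score_explicit(resp, truth) == 0

    def test_adjacent_pair_scores_two(self):
        truth = (1, 2, 3, 4, 1, 2, 3, 4, 1, 2, 3, 4)
        resp = [t if i in (3, 4) else (t % 4) + 1 for i, t in enumerate(truth)]
        assert beh.score_explicit(resp, truth) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            beh.score_explicit((1, 2), (1, 2, 3))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st_h.lists(st_h.integers(1, 4), min_size=12, max_size=12),
           st_h.lists(st_h.integers(1, 4), min_size=12, max_size=12))
    def test_score_range_and_no_singleton(self, resp, truth):
        score = beh.score_explicit(resp, truth)
        assert 0 <= score <= 12
        assert score != 1

    def test_chance_level_scatter_around_large_sample_reference(self):
        truth = beh.SEQUENCE_A
        reference = beh.explicit_chance(truth, rng=0, n_draws=20000)
        means = [beh.explicit_chance(truth, rng=seed) for seed in range(1, 51)]
        spread = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - reference) <= 4 * spread

    def test_chance_in_score_range_for_degenerate_truth(self):
        val = beh.explicit_chance((1,) * 12, rng=3)
        assert 0.0 <= val <= 12.0
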