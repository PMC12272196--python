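"""Serial-reaction-time-task (SRTT) scoring.

The task: two 12-item sequences of cued key presses (items 1-4; items 1-2
under the left hand, 3-4 under the right), learned in 36-trial blocks.
Sequence-specific skill (SeqSpecS) is the mean random-block reaction time
minus the mean of the first four (early) or last four (late) sequence blocks;
the cueing benefit is cued-sequence SeqSpecS minus uncued-sequence SeqSpecS.

Trial tables are pandas DataFrames with columns ``subject_id, session,
block_index, block_type, trial_index, item, hand, rt_ms,
correct_first_press``; ``block_type`` is one of ``cued_seq, uncued_seq,
rand_cuedtones, rand_uncuedtones``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The two fixed task sequences.
SEQUENCE_A = (1, 2, 1, 4, 2, 3, 4, 1, 3, 2, 4, 3)
SEQUENCE_B = (2, 4, 3, 2, 3, 1, 4, 2, 3, 1, 4, 1)

#: Key assignment: items 1-2 left hand, items 3-4 right hand.
ITEM_HAND = {1: "L", 2: "L", 3: "R", 4: "R"}

RT_CUTOFF_MS = 1000.0
SEQUENCE_BLOCK_TYPES = ("cued_seq", "uncued_seq")
RANDOM_BLOCK_TYPES = ("rand_cuedtones", "rand_uncuedtones")

#: Days post-stimulation attached to each re-test session.
SESSION_DAYS = {"S2": 1, "S3": 10, "S4": 20}


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop trials with reaction time exceeding 1,000 ms.

    'Exceeding' is read strictly: rt == 1000 ms is retained.  Trials with
    incorrect presses before the correct one are retained.
    """
    return trials[trials.rt_ms <= RT_CUTOFF_MS].copy()


def _block_means(trials: pd.DataFrame) -> pd.DataFrame:
    return (trials.groupby(["subject_id", "session", "block_type",
                            "block_index"], as_index=False)
            .rt_ms.mean())


def seq_spec_skill(trials: pd.DataFrame, timepoint: str) -> pd.DataFrame:
    """Per subject x session x sequence SeqSpecS at ``timepoint``.

    ``value = mean(random-block means) - mean(first-4 | last-4
    sequence-block means)``; random blocks are pooled across the two tone
    sets.  Raises if a subject/session has fewer than 4 blocks of a sequence
    or no random blocks.
    """
    if timepoint not in ("early", "late"):
        raise ValueError("timepoint must be 'early' or 'late'")
    means = _block_means(trials)
    rows = []
    for (subj, sess), grp in means.groupby(["subject_id", "session"]):
        rand = grp[grp.block_type.isin(RANDOM_BLOCK_TYPES)]
        if rand.empty:
            raise ValueError(f"no random blocks for {subj}/{sess}")
        rand_mean = rand.rt_ms.mean()
        for seq_type, seq_name in zip(SEQUENCE_BLOCK_TYPES, ("cued", "uncued")):
            blocks = (grp[grp.block_type == seq_type]
                      .sort_values("block_index"))
            if len(blocks) < 4:
                raise ValueError(
                    f"fewer than 4 {seq_type} blocks for {subj}/{sess}")
            window = blocks.head(4) if timepoint == "early" else blocks.tail(4)
            rows.append({
                "subject_id": subj, "session": sess, "sequence": seq_name,
                "timepoint": timepoint,
                "value": rand_mean - window.rt_ms.mean(),
            })
    return pd.DataFrame(rows)


def cueing_benefit(seqspecs: pd.DataFrame, timepoint: str = "late",
                   session_days: dict[str, int] = SESSION_DAYS,
                   ) -> pd.DataFrame:
    """Cued minus uncued SeqSpecS per subject x session.

    Subject/session cells missing either sequence are skipped with a warning.
    ``days_post_tmr`` is attached from the session metadata (sessions not in
    the map get ``NaN``).
    """
    sub = seqspecs[seqspecs.timepoint == timepoint]
    rows = []
    for (subj, sess), grp in sub.groupby(["subject_id", "session"]):
        vals = grp.set_index("sequence").value
        if not {"cued", "uncued"} <= set(vals.index):
            logger.warning("missing cued/uncued counterpart for %s/%s",
                           subj, sess)
            continue
        rows.append({
            "subject_id": subj, "session": sess,
            "days_post_tmr": session_days.get(sess, np.nan),
            "value": vals["cued"] - vals["uncued"],
        })
    return pd.DataFrame(rows)


def split_by_hand(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(left-hand, right-hand) partition of the trial table by item."""
    lh = trials[trials.item.isin([1, 2])].copy()
    rh = trials[trials.item.isin([3, 4])].copy()
    return lh, rh


def longest_shared_run(a, b) -> int:
    """Length of the longest contiguous subsequence shared by ``a`` and ``b``."""
    a, b = list(a), list(b)
    best = 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0] * (len(b) + 1)
        for j, y in enumerate(b, start=1):
            if x == y:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def generate_random_block(rng: np.random.Generator | int,
                          forbidden=(SEQUENCE_A, SEQUENCE_B),
                          max_tries: int = 10_000) -> tuple[int, ...]:
    """A pseudo-random 12-item sequence under the task's constraints.

    Rejection-samples permutations of three repetitions of each item until
    (1) items are equally represented, (2) no item repeats in consecutive
    trials, and (3) no run of more than four items is shared with either
    fixed sequence.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    pool = np.repeat([1, 2, 3, 4], 3)
    for _ in range(max_tries):
        cand = tuple(rng.permutation(pool))
        if any(cand[i] == cand[i + 1] for i in range(11)):
            continue
        if any(longest_shared_run(cand, seq) > 4 for seq in forbidden):
            continue
        return cand
    raise RuntimeError("random-block rejection sampling exhausted retries")


def score_explicit(response, truth) -> int:
    """Free-recall score: correct-position items adjacent to another correct one.

    Position ``i`` scores iff ``response[i] == truth[i]`` and at least one
    neighbouring position also matches; isolated matches score nothing, so a
    score of exactly 1 is impossible.
    """
    response, truth = list(response), list(truth)
    if len(response) != len(truth):
        raise ValueError("response and truth must have equal length")
    n = len(truth)
    match = [r == t for r, t in zip(response, truth)]
    return sum(
        1 for i in range(n)
        if match[i] and ((i > 0 and match[i - 1]) or (i < n - 1 and match[i + 1]))
    )


def explicit_chance(truth, rng: np.random.Generator | int,
                    n_draws: int = 10, equal_representation: bool = True,
                    ) -> float:
    """Chance level: mean score of ``n_draws`` random sequences against truth.

    Random sequences are drawn with equal item representation (three of each,
    matching task structure) by default; ``equal_representation=False`` draws
    items i.i.d. uniform instead.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    truth = list(truth)
    scores = []
    for _ in range(n_draws):
        if equal_representation:
            draw = rng.permutation(np.repeat([1, 2, 3, 4], len(truth) // 4))
        else:
            draw = rng.integers(1, 5, size=len(truth))
        scores.append(score_explicit(draw, truth))
    return float(np.mean(scores))
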