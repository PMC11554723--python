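"""Raw-session scoring: span 2-of-3 rule, partial credit, criterion fill."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corsinorm.errors import (
    InvalidResponseError,
    MalformedProtocolError,
    MalformedSessionError,
    ProtocolOrderError,
)
from corsinorm.session import (
    CSSL_TARGET,
    CORRECT_SCORE,
    MAX_TRIALS,
    SpanBlock,
    SpanSession,
    SupraspanSession,
    SupraspanTrial,
    TrialScoreTable,
    classify_response,
    score_span,
    score_supraspan_learning,
    score_supraspan_recall,
    score_supraspan_trial,
)

from .conftest import passed_block, span_session


class TestSpanScoring:
    def test_highest_passed_block_is_the_span(self):
        # blocks 2..5 passed, block 6 with only one correct response
        session = span_session([2, 3, 4, 5], failed_length=6)
        assert score_span(session) == 5

    def test_all_blocks_passed_up_to_eight(self):
        assert score_span(span_session(range(2, 9))) == 8

    def test_failing_the_starting_block_scores_one_less(self):
        assert score_span(span_session([], failed_length=2)) == 1

    def test_one_failed_response_still_passes(self):
        block = passed_block(4, fail=1)
        assert block.n_correct == 2
        assert score_span(SpanSession(blocks=[block])) == 4

    def test_responses_after_a_failed_block_are_a_protocol_error(self):
        blocks = [passed_block(2), passed_block(3, fail=2), passed_block(4)]
        with pytest.raises(ProtocolOrderError):
            score_span(SpanSession(blocks=blocks))

    def test_unadministered_trailing_block_is_fine(self):
        blocks = [passed_block(2), passed_block(3, fail=2)]
        tail = passed_block(4)
        tail.responses = []
        blocks.append(tail)
        assert score_span(SpanSession(blocks=blocks)) == 2

    def test_block_needs_exactly_three_targets(self):
        with pytest.raises(MalformedProtocolError):
            SpanBlock(length=2, targets=[(1, 2), (3, 4)], responses=[])

    def test_block_lengths_must_increase(self):
        with pytest.raises(MalformedProtocolError):
            SpanSession(blocks=[passed_block(3), passed_block(3)])

    def test_adding_a_passed_longer_block_never_decreases_span(self):
        short = span_session([2, 3])
        longer = span_session([2, 3, 4])
        assert score_span(longer) >= score_span(short)


# ---------------------------------------------------------------------------
# Partial-credit classification
# ---------------------------------------------------------------------------

def brute_force_category(target, response):
    """Independent classifier: exhaustive checks instead of DP/precedence code."""
    target, response = tuple(target), tuple(response)[:8]
    if response == target:
        return "exact"
    if sorted(response) == sorted(target):
        swaps = [
            (i, j)
            for i, j in itertools.combinations(range(len(target)), 2)
            if _swap(target, i, j) == response
        ]
        if swaps:
            return "transposition"
    best = 0
    for r in range(len(target), 0, -1):
        for sub in itertools.combinations(target, r):
            if _is_subsequence(sub, response):
                best = r
                break
        if best:
            break
    return f"overlap_{best}" if best else "none"


def _swap(seq, i, j):
    out = list(seq)
    out[i], out[j] = out[j], out[i]
    return tuple(out)


def _is_subsequence(sub, seq):
    it = iter(seq)
    return all(c in it for c in sub)


class TestTrialClassification:
    def test_exact_reproduction_scores_correct(self, score_table):
        assert score_supraspan_trial(CSSL_TARGET, CSSL_TARGET, score_table) == CORRECT_SCORE

    def test_empty_response_scores_zero(self, score_table):
        assert score_supraspan_trial(CSSL_TARGET, (), score_table) == 0.0

    def test_last_two_swapped_is_a_transposition(self, score_table):
        response = CSSL_TARGET[:-2] + (CSSL_TARGET[-1], CSSL_TARGET[-2])
        assert classify_response(CSSL_TARGET, response) == "transposition"
        assert score_supraspan_trial(CSSL_TARGET, response, score_table) == pytest.approx(
            score_table.score("transposition")
        )

    def test_response_with_no_target_cubes_gets_no_credit(self, score_table):
        # cube 4 does not occur in the learning sequence
        assert classify_response(CSSL_TARGET, (4,) * 8) == "none"
        assert score_supraspan_trial(CSSL_TARGET, (4,) * 8, score_table) == 0.0

    def test_only_first_eight_touches_count(self, score_table):
        padded = CSSL_TARGET + (1, 2, 3)
        assert score_supraspan_trial(CSSL_TARGET, padded, score_table) == CORRECT_SCORE

    def test_cube_id_outside_board_rejected(self, score_table):
        with pytest.raises(InvalidResponseError):
            score_supraspan_trial(CSSL_TARGET, (5, 8, 0), score_table)

    def test_classifier_agrees_with_brute_force_on_toy_target(self):
        target = (2, 7, 4)
        pool = [2, 7, 4, 9]
        for length in range(0, 4):
            for response in itertools.product(pool, repeat=length):
                assert classify_response(target, response) == brute_force_category(
                    target, response
                ), response

    def test_classifier_agrees_with_brute_force_on_full_permutations(self):
        target = (5, 8, 3, 2)
        for response in itertools.permutations(target):
            assert classify_response(target, response) == brute_force_category(target, response)

    def test_score_table_validation(self):
        with pytest.raises(MalformedProtocolError):
            TrialScoreTable(scores={"exact": 1.62})  # categories missing
        bad = TrialScoreTable().scores.copy()
        bad["exact"] = 1.5
        with pytest.raises(MalformedProtocolError):
            TrialScoreTable(scores=bad)
        bad = TrialScoreTable().scores.copy()
        bad["overlap_3"] = 2.0
        with pytest.raises(MalformedProtocolError):
            TrialScoreTable(scores=bad)


# ---------------------------------------------------------------------------
# Supraspan learning totals
# ---------------------------------------------------------------------------

def _correct_trial():
    return SupraspanTrial(CSSL_TARGET)


def _zero_trial():
    return SupraspanTrial((4,) * 8)


def _overlap5_trial():
    # keep an ordered 5-cube overlap, break the rest (cube 4 is off-target)
    return SupraspanTrial((5, 8, 3, 2, 6, 4, 4, 4))


class TestLearningScore:
    def test_criterion_on_first_three_trials_gives_maximum(self, score_table):
        session = SupraspanSession(trials=[_correct_trial()] * 3)
        assert score_supraspan_learning(session, score_table) == pytest.approx(29.16)

    def test_maximum_is_eighteen_times_correct_score(self):
        assert MAX_TRIALS * CORRECT_SCORE == pytest.approx(29.16)

    def test_eighteen_failures_score_zero(self, score_table):
        session = SupraspanSession(trials=[_zero_trial()] * 18)
        assert score_supraspan_learning(session, score_table) == 0.0

    def test_partial_then_criterion_hand_sum(self, score_table):
        # two 0.50 trials, then criterion at trial 5: 0.5 + 0.5 + 1.62*16
        assert score_table.score("overlap_5") == 0.50
        session = SupraspanSession(
            trials=[_overlap5_trial(), _overlap5_trial()] + [_correct_trial()] * 3
        )
        assert score_supraspan_learning(session, score_table) == pytest.approx(26.92)

    def test_trials_after_criterion_rejected(self, score_table):
        session = SupraspanSession(trials=[_correct_trial()] * 3 + [_zero_trial()])
        with pytest.raises(ProtocolOrderError):
            score_supraspan_learning(session, score_table)

    def test_more_than_eighteen_trials_rejected(self):
        with pytest.raises(MalformedSessionError):
            SupraspanSession(trials=[_zero_trial()] * 19)

    @settings(derandomize=True, max_examples=40)
    @given(
        cats=st.lists(
            st.sampled_from(["none", "overlap_3", "overlap_5", "transposition"]),
            min_size=0,
            max_size=15,
        ),
    )
    def test_criterion_fill_rule_and_bounds(self, score_table, cats):
        """total = prefix sum + 1.62*(18-k) when criterion hits at trial k."""
        prefix = []
        responses = {
            "none": (4,) * 8,
            "overlap_3": (5, 8, 3, 4, 4, 4, 4, 4),
            "overlap_5": (5, 8, 3, 2, 6, 4, 4, 4),
            "transposition": CSSL_TARGET[:-2] + (CSSL_TARGET[-1], CSSL_TARGET[-2]),
        }
        for c in cats[: MAX_TRIALS - 3]:
            prefix.append(SupraspanTrial(responses[c]))
        trials = prefix + [_correct_trial()] * 3
        k = len(trials)
        session = SupraspanSession(trials=trials)
        total = score_supraspan_learning(session, score_table)
        expected = sum(score_table.score(c) for c in cats[: MAX_TRIALS - 3])
        expected += 3 * CORRECT_SCORE + CORRECT_SCORE * (MAX_TRIALS - k)
        assert total == pytest.approx(expected)
        assert 0.0 <= total <= 29.16 + 1e-12


class TestRecallScore:
    def test_correct_recall_scores_full(self, score_table):
        assert score_supraspan_recall(
            SupraspanTrial(CSSL_TARGET), CSSL_TARGET, score_table
        ) == pytest.approx(1.62)

    def test_empty_recall_scores_zero(self, score_table):
        assert score_supraspan_recall(SupraspanTrial(()), CSSL_TARGET, score_table) == 0.0

    def test_reversed_recall_classified_by_oracle(self, score_table):
        response = tuple(reversed(CSSL_TARGET))
        cat = brute_force_category(CSSL_TARGET, response)
        assert classify_response(CSSL_TARGET, response) == cat
        assert score_supraspan_recall(
            SupraspanTrial(response), CSSL_TARGET, score_table
        ) == pytest.approx(score_table.score(cat))
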