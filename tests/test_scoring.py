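"""Response classification and range scoring, checked against first principles."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcst import (
    Card,
    Dimension,
    InvalidSessionError,
    ResponseFlags,
    ScoreSummary,
    SessionConfig,
    classify_response,
    completing_trials,
    run_session,
    score_range,
    score_session,
)
from bcst.session import TrialRecord
from conftest import make_random_session, naive_flags


def _trial(card, active, previous, chosen, correct, index=1, set_index=1):
    return TrialRecord(
        trial_index=index,
        card=card,
        active_rule=active,
        previous_rule=previous,
        chosen_pile=chosen,
        correct=correct,
        set_index=set_index,
    )


class TestClassifyResponse:
    def test_first_set_responses_are_never_perseverative(self, keys):
        t = _trial(Card("red", "star", 3), Dimension.COLOR, None, chosen=4, correct=False)
        flags = classify_response(t, keys)
        assert not flags.perseverative_response
        assert not flags.perseverative_error
        assert flags.error

    def test_wrong_choice_matching_previous_rule_is_perseverative_error(self, keys):
        # Pile 4 holds the circle key; under the active COLOR rule green
        # belongs on pile 2, so choosing 4 is both wrong and a carry-over
        # of the old SHAPE rule.
        t = _trial(
            Card("green", "circle", 3),
            Dimension.COLOR,
            Dimension.SHAPE,
            chosen=4,
            correct=False,
        )
        flags = classify_response(t, keys)
        assert flags.error
        assert flags.perseverative_response
        assert flags.perseverative_error

    def test_correct_choice_can_still_be_perseverative(self, keys):
        # Pile 2 matches (yellow, star, 2) on both NUMBER (active) and
        # SHAPE (previous): correct yet perseverative — the reason raw PR
        # can exceed raw total errors.
        t = _trial(
            Card("yellow", "star", 2),
            Dimension.NUMBER,
            Dimension.SHAPE,
            chosen=2,
            correct=True,
        )
        flags = classify_response(t, keys)
        assert flags.correct
        assert flags.perseverative_response
        assert not flags.perseverative_error

    def test_flag_invariants_are_enforced(self):
        with pytest.raises(ValueError):
            ResponseFlags(correct=True, error=True, perseverative_response=False,
                          perseverative_error=False)
        with pytest.raises(ValueError):
            ResponseFlags(correct=True, error=False, perseverative_response=False,
                          perseverative_error=True)

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_naive_scorer_on_random_sessions(self, keys, seed):
        session = make_random_session(seed)
        expected = naive_flags(session)
        for t, flags in zip(session.trials, expected):
            got = classify_response(t, keys)
            assert (got.correct, got.error, got.perseverative_response,
                    got.perseverative_error) == flags


class TestScoreRange:
    def test_oracle_full_range_is_error_free_with_9_categories(self, oracle_session):
        s = score_range(oracle_session, 1, 90)
        assert s.total_errors_raw == 0
        assert s.persev_errors_raw == 0
        assert s.categories_completed == 9
        assert s.total_errors_pct == 0.0

    def test_short_form_denominator_is_64(self, oracle_session):
        assert score_range(oracle_session, 1, 64).trials_scored == 64

    @pytest.mark.parametrize("first, last", [(0, 10), (5, 4), (1, 999)])
    def test_invalid_ranges_rejected(self, oracle_session, first, last):
        with pytest.raises(ValueError):
            score_range(oracle_session, first, last)

    def test_errors_monotone_as_range_grows(self):
        session = make_random_session(7)
        n = len(session.trials)
        previous = 0
        for last in range(1, n + 1):
            te = score_range(session, 1, last).total_errors_raw
            assert te >= previous
            previous = te

    def test_set_in_progress_at_boundary_counts_for_neither_side(self):
        session = make_random_session(3)
        completions = set(completing_trials(session).values())
        n = len(session.trials)
        boundary = 64
        first = score_range(session, 1, boundary)
        second = score_range(session, boundary + 1, n)
        assert first.categories_completed == sum(c <= boundary for c in completions)
        assert second.categories_completed == sum(c > boundary for c in completions)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), split=st.integers(1, 89))
    def test_counts_are_additive_over_disjoint_ranges(self, seed, split):
        session = make_random_session(seed)
        n = len(session.trials)
        split = min(split, n - 1)
        left = score_range(session, 1, split)
        right = score_range(session, split + 1, n)
        full = score_range(session, 1, n)
        for field in ("total_errors_raw", "persev_responses_raw",
                      "persev_errors_raw", "categories_completed"):
            assert getattr(left, field) + getattr(right, field) == getattr(full, field)


class TestScoreSession:
    def test_oracle_second_half_is_26_trials(self, oracle_session):
        _, _, second = score_session(oracle_session)
        assert second.trials_scored == 26

    def test_full_deck_session_second_half_is_64_trials(self):
        session = make_random_session(5)
        assert len(session.trials) == 128
        _, _, second = score_session(session)
        assert second.trials_scored == 64

    @pytest.mark.parametrize("seed", range(10))
    def test_flag_implications_bound_every_summary(self, seed):
        for s in score_session(make_random_session(seed)):
            assert s.persev_errors_raw <= min(
                s.persev_responses_raw, s.total_errors_raw
            )
            for pct in (s.total_errors_pct, s.persev_responses_pct,
                        s.persev_errors_pct):
                assert 0.0 <= pct <= 100.0

    def test_short_session_rejected(self):
        from bcst import oracle_policy

        cfg = SessionConfig(max_categories=2, deck_seed=1)
        short = run_session(oracle_policy(), cfg)  # 20 error-free trials
        assert len(short.trials) == 20
        with pytest.raises(InvalidSessionError):
            score_session(short)


class TestScoreSummaryInvariants:
    def test_percentages_derive_from_raw_counts(self):
        s = ScoreSummary(
            trials_scored=64,
            total_errors_raw=16,
            persev_responses_raw=20,
            persev_errors_raw=10,
            categories_completed=3,
        )
        assert s.total_errors_pct == 25.0
        assert s.persev_responses_pct == 31.25
        assert s.persev_errors_pct == 100 * 10 / 64

    def test_impossible_count_combinations_rejected(self):
        with pytest.raises(ValueError):
            ScoreSummary(64, total_errors_raw=5, persev_responses_raw=3,
                         persev_errors_raw=4, categories_completed=0)
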