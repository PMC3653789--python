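"""PEBL/Berg-style response classification and score summaries.

The four reported measures are total errors, perseverative responses (PR),
perseverative errors (PE), and categories completed. A response is
*perseverative* when the chosen pile is the pile that would be correct
under the rule of the immediately preceding set — the liberal criterion
used by the PEBL implementation, deliberately simpler than the multi-clause
Heaton rules for the Wisconsin test. A perseverative response may itself be
correct under the active rule (when the two rules map the card to the same
pile), which is why raw PR can exceed raw total errors. In the first set no
response is perseverative because no prior rule exists.

Scores are reported for arbitrary trial ranges; the short form (BCST-64)
is simply the range 1..64. Percentages use the number of trials in the
range as the denominator. A category is attributed to the trial on which
the set's criterion-th consecutive correct response occurs; a set still in
progress at a range boundary counts for neither side.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cards import KeyCardSet, build_key_cards, correct_pile
from .session import SessionRecord, TrialRecord

__all__ = [
    "ResponseFlags",
    "ScoreSummary",
    "InvalidSessionError",
    "classify_response",
    "completing_trials",
    "score_range",
    "score_session",
    "SHORT_FORM_TRIALS",
]

#: Trial count of the short form (BCST-64).
SHORT_FORM_TRIALS = 64


class InvalidSessionError(ValueError):
    """A session is too short (or otherwise unusable) for the requested scores."""


@dataclass(frozen=True)
class ResponseFlags:
    """Classification of a single response."""

    correct: bool
    error: bool
    perseverative_response: bool
    perseverative_error: bool

    def __post_init__(self) -> None:
        if self.error == self.correct:
            raise ValueError("error must equal (not correct)")
        if self.perseverative_error and not (
            self.perseverative_response and self.error
        ):
            raise ValueError(
                "perseverative_error implies perseverative_response and error"
            )


@dataclass(frozen=True)
class ScoreSummary:
    """Raw and percent measures over a trial range.

    Percentages are ``100 * raw / trials_scored`` and therefore live in
    [0, 100]. ``categories_completed`` counts the sets whose completing
    trial falls inside the range.
    """

    trials_scored: int
    total_errors_raw: int
    persev_responses_raw: int
    persev_errors_raw: int
    categories_completed: int

    @property
    def total_errors_pct(self) -> float:
        return 100.0 * self.total_errors_raw / self.trials_scored

    @property
    def persev_responses_pct(self) -> float:
        return 100.0 * self.persev_responses_raw / self.trials_scored

    @property
    def persev_errors_pct(self) -> float:
        return 100.0 * self.persev_errors_raw / self.trials_scored

    def __post_init__(self) -> None:
        if self.trials_scored < 1:
            raise ValueError("trials_scored must be >= 1")
        counts = (
            self.total_errors_raw,
            self.persev_responses_raw,
            self.persev_errors_raw,
            self.categories_completed,
        )
        if any(c < 0 for c in counts):
            raise ValueError("raw counts must be non-negative")
        if self.persev_errors_raw > self.persev_responses_raw:
            raise ValueError("PE cannot exceed PR")
        if self.persev_errors_raw > self.total_errors_raw:
            raise ValueError("PE cannot exceed total errors")


def classify_response(trial: TrialRecord, keys: KeyCardSet | None = None) -> ResponseFlags:
    """Classify one trial's response.

    Perseverative response: the previous set's rule exists and the chosen
    pile equals the correct pile under that rule — regardless of whether the
    response is also correct under the active rule.
    """
    keys = keys if keys is not None else build_key_cards()
    persev = (
        trial.previous_rule is not None
        and trial.chosen_pile == correct_pile(trial.card, trial.previous_rule, keys)
    )
    return ResponseFlags(
        correct=trial.correct,
        error=not trial.correct,
        perseverative_response=persev,
        perseverative_error=persev and not trial.correct,
    )


def completing_trials(session: SessionRecord) -> dict[int, int]:
    """Map each completed set index to the trial index on which it completed.

    Re-derived from the trial stream itself (not the engine's counters), so
    it also works for logs read from disk: a run of ``run_criterion``
    consecutive correct responses within one set completes it, counted at
    most once per set.
    """
    criterion = session.config.run_criterion
    completed: dict[int, int] = {}
    run = 0
    current_set = None
    for t in session.trials:
        if t.set_index != current_set:
            current_set = t.set_index
            run = 0
        if t.correct:
            run += 1
            if run == criterion and t.set_index not in completed:
                completed[t.set_index] = t.trial_index
        else:
            run = 0
    return completed


def score_range(
    session: SessionRecord,
    first_trial: int,
    last_trial: int,
    keys: KeyCardSet | None = None,
) -> ScoreSummary:
    """Score the inclusive trial range ``first_trial..last_trial``."""
    n = len(session.trials)
    if not (1 <= first_trial <= last_trial <= n):
        raise ValueError(
            f"invalid trial range {first_trial}..{last_trial} for a "
            f"{n}-trial session"
        )
    keys = keys if keys is not None else build_key_cards()

    errors = pr = pe = 0
    for t in session.trials[first_trial - 1 : last_trial]:
        flags = classify_response(t, keys)
        errors += flags.error
        pr += flags.perseverative_response
        pe += flags.perseverative_error

    categories = sum(
        first_trial <= idx <= last_trial for idx in completing_trials(session).values()
    )
    return ScoreSummary(
        trials_scored=last_trial - first_trial + 1,
        total_errors_raw=errors,
        persev_responses_raw=pr,
        persev_errors_raw=pe,
        categories_completed=categories,
    )


def score_session(
    session: SessionRecord, keys: KeyCardSet | None = None
) -> tuple[ScoreSummary, ScoreSummary, ScoreSummary]:
    """Full-length, first-64 (short form) and remaining-trial summaries.

    Requires at least 65 trials; every complete administration has >= 90.
    """
    n = len(session.trials)
    if n < SHORT_FORM_TRIALS + 1:
        raise InvalidSessionError(
            f"session has {n} trials; need at least {SHORT_FORM_TRIALS + 1} "
            "to score the short form against the remainder"
        )
    full = score_range(session, 1, n, keys)
    first = score_range(session, 1, SHORT_FORM_TRIALS, keys)
    second = score_range(session, SHORT_FORM_TRIALS + 1, n, keys)
    return full, first, second
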