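"""Task engine: run a full card-sorting session against a respondent policy.

A session deals the shuffled deck one card at a time. The respondent sorts
each card to a pile and receives correct/wrong feedback. After
``run_criterion`` consecutive correct sorts the current set (category) is
complete and the sorting rule silently advances along a fixed cycle. The
session ends when ``max_categories`` sets are completed or the deck is
exhausted, whichever comes first. With the defaults (10-in-a-row criterion,
9 categories, 128 cards) an error-free respondent finishes in exactly 90
trials.

Rule changes are silent: the policy contract never exposes the active rule.
A policy is any callable ``policy(obs) -> pile_index`` receiving an
:class:`Observation` (key cards, current card, trial index, and the full
feedback history). Test-harness policies may declare ``sees_rule = True``
to receive the active rule in the observation (the oracle uses this).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional

import numpy as np

from .cards import (
    DIMENSIONS,
    Card,
    Deck,
    Dimension,
    KeyCardSet,
    build_deck,
    build_key_cards,
    correct_pile,
    next_rule,
)

__all__ = [
    "SessionConfig",
    "Feedback",
    "Observation",
    "TrialRecord",
    "SessionRecord",
    "InvalidResponseError",
    "run_session",
]


class InvalidResponseError(ValueError):
    """A policy returned something other than a pile index 1..4."""

    def __init__(self, trial_index: int, value) -> None:
        self.trial_index = trial_index
        self.value = value
        super().__init__(
            f"policy returned invalid pile {value!r} on trial {trial_index}; "
            "expected an integer in 1..4"
        )


@dataclass(frozen=True)
class SessionConfig:
    """Settings for one test administration.

    ``rule_order`` is the fixed cycle of sorting rules; the starting rule is
    drawn uniformly at random from the three dimensions using
    ``start_rule_seed`` and the cycle is entered at that point.
    """

    max_categories: int = 9
    run_criterion: int = 10
    deck_seed: int = 0
    start_rule_seed: int = 0
    rule_order: tuple[Dimension, ...] = DIMENSIONS
    exclude_key_identical: bool = False

    def __post_init__(self) -> None:
        if self.run_criterion < 1:
            raise ValueError("run_criterion must be >= 1")
        if self.max_categories < 1:
            raise ValueError("max_categories must be >= 1")
        if sorted(d.value for d in self.rule_order) != sorted(
            d.value for d in DIMENSIONS
        ):
            raise ValueError("rule_order must be a permutation of the 3 dimensions")


class Feedback(NamedTuple):
    """One past trial as the respondent saw it: card, choice, outcome."""

    card: Card
    chosen_pile: int
    correct: bool


@dataclass(frozen=True)
class Observation:
    """What a policy sees when choosing a pile for the current card."""

    keys: KeyCardSet
    card: Card
    trial_index: int
    history: tuple[Feedback, ...]
    #: Populated only for policies declaring ``sees_rule = True``.
    active_rule: Optional[Dimension] = None


@dataclass(frozen=True)
class TrialRecord:
    """One scored trial of a session log."""

    trial_index: int
    card: Card
    active_rule: Dimension
    previous_rule: Optional[Dimension]
    chosen_pile: int
    correct: bool
    set_index: int


@dataclass(frozen=True)
class SessionRecord:
    """Ordered trial-by-trial log of one complete administration."""

    trials: tuple[TrialRecord, ...]
    categories_completed: int
    config: SessionConfig

    def __len__(self) -> int:
        return len(self.trials)


Policy = Callable[[Observation], int]


def run_session(
    policy: Policy,
    config: SessionConfig | None = None,
    keys: KeyCardSet | None = None,
    deck: Deck | None = None,
) -> SessionRecord:
    """Administer one session and return its trial log.

    The deck is built from ``config.deck_seed`` unless ``deck`` is given.
    Policies with a ``reset()`` method are reset before the first trial so
    replays with the same seeds are bit-identical.
    """
    config = config if config is not None else SessionConfig()
    keys = keys if keys is not None else build_key_cards()
    if deck is None:
        deck = build_deck(config.deck_seed, config.exclude_key_identical)

    rng = np.random.default_rng(config.start_rule_seed)
    order = config.rule_order
    active = order[int(rng.integers(len(order)))]
    previous: Optional[Dimension] = None

    if hasattr(policy, "reset"):
        policy.reset()

    sees_rule = bool(getattr(policy, "sees_rule", False))
    trials: list[TrialRecord] = []
    history: list[Feedback] = []
    set_index = 1
    run = 0
    categories = 0

    for i, card in enumerate(deck.cards, start=1):
        obs = Observation(
            keys=keys,
            card=card,
            trial_index=i,
            history=tuple(history),
            active_rule=active if sees_rule else None,
        )
        choice = policy(obs)
        if not isinstance(choice, (int, np.integer)) or isinstance(choice, bool):
            raise InvalidResponseError(i, choice)
        pile = int(choice)
        if not 1 <= pile <= 4:
            raise InvalidResponseError(i, choice)

        correct = pile == correct_pile(card, active, keys)
        trials.append(
            TrialRecord(
                trial_index=i,
                card=card,
                active_rule=active,
                previous_rule=previous,
                chosen_pile=pile,
                correct=correct,
                set_index=set_index,
            )
        )
        history.append(Feedback(card, pile, correct))

        if correct:
            run += 1
            if run == config.run_criterion:
                categories += 1
                if categories >= config.max_categories:
                    break
                previous = active
                active = next_rule(active, order)
                set_index += 1
                run = 0
        else:
            run = 0

    return SessionRecord(
        trials=tuple(trials), categories_completed=categories, config=config
    )
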