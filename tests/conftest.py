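"""Shared fixtures and the deliberately naive reference scorer.

The naive scorer is an independent re-implementation of response
classification: it never calls the package's ``classify_response`` or
``correct_pile``; it matches card attributes against the key cards by a
direct scan, so agreement with the main scorer is a genuine cross-check.
"""

from __future__ import annotations

import pytest

from bcst import (
    SessionConfig,
    SessionRecord,
    build_key_cards,
    oracle_policy,
    random_policy,
    run_session,
)


def naive_flags(session: SessionRecord):
    """Classify every trial of a session from first principles.

    Returns a list of (correct, error, perseverative_response,
    perseverative_error) tuples, one per trial.
    """
    keys = build_key_cards()

    def attr(card, dim):
        return {"COLOR": card.color, "SHAPE": card.shape, "NUMBER": card.number}[
            dim.value
        ]

    def matching_pile(card, dim):
        hits = [
            i
            for i, key in enumerate(keys.piles, start=1)
            if attr(key, dim) == attr(card, dim)
        ]
        assert len(hits) == 1
        return hits[0]

    out = []
    for t in session.trials:
        correct = t.chosen_pile == matching_pile(t.card, t.active_rule)
        persev = t.previous_rule is not None and t.chosen_pile == matching_pile(
            t.card, t.previous_rule
        )
        out.append((correct, not correct, persev, persev and not correct))
    return out


@pytest.fixture(scope="session")
def keys():
    return build_key_cards()


@pytest.fixture(scope="session")
def oracle_session():
    return run_session(oracle_policy(), SessionConfig(deck_seed=11, start_rule_seed=5))


def make_random_session(seed: int) -> SessionRecord:
    cfg = SessionConfig(deck_seed=seed, start_rule_seed=seed + 1)
    return run_session(random_policy(seed + 2), cfg)
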