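"""Stimulus geometry for the Berg Card Sorting Test (BCST).

The BCST presents a deck of cards that vary on three dimensions — color,
shape, and number — each with four levels. Every card is sorted to one of
four piles, each headed by a fixed *key card*. The key cards are built so
that each level of each dimension appears on exactly one key card, which
makes the correct pile under any sorting rule unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Iterable

import numpy as np

__all__ = [
    "COLORS",
    "SHAPES",
    "NUMBERS",
    "Dimension",
    "DIMENSIONS",
    "Card",
    "KeyCardSet",
    "Deck",
    "build_key_cards",
    "build_deck",
    "correct_pile",
    "next_rule",
]

COLORS = ("red", "green", "yellow", "blue")
SHAPES = ("triangle", "star", "cross", "circle")
NUMBERS = (1, 2, 3, 4)


class Dimension(str, Enum):
    """A sortable card dimension. Exactly three exist."""

    COLOR = "COLOR"
    SHAPE = "SHAPE"
    NUMBER = "NUMBER"


#: Canonical ordering of the three dimensions, also the default rule cycle.
DIMENSIONS = (Dimension.COLOR, Dimension.SHAPE, Dimension.NUMBER)


@dataclass(frozen=True)
class Card:
    """One stimulus: a color, a shape, and a quantity (1–4)."""

    color: str
    shape: str
    number: int

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise ValueError(f"color must be one of {COLORS}, got {self.color!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if self.number not in NUMBERS:
            raise ValueError(f"number must be in 1..4, got {self.number!r}")

    def attribute(self, dim: Dimension):
        """The card's value on ``dim``."""
        if dim is Dimension.COLOR:
            return self.color
        if dim is Dimension.SHAPE:
            return self.shape
        return self.number


@dataclass(frozen=True)
class KeyCardSet:
    """The four fixed reference cards, one per pile (pile indices 1..4).

    Invariant: across the four key cards every color, shape and number
    appears exactly once, so each card attribute maps to exactly one pile
    per dimension.
    """

    piles: tuple[Card, Card, Card, Card]

    def __post_init__(self) -> None:
        if len(self.piles) != 4:
            raise ValueError("a key card set has exactly 4 piles")
        for dim, levels in (
            (Dimension.COLOR, COLORS),
            (Dimension.SHAPE, SHAPES),
            (Dimension.NUMBER, NUMBERS),
        ):
            seen = [k.attribute(dim) for k in self.piles]
            if sorted(map(str, seen)) != sorted(map(str, levels)):
                raise ValueError(
                    f"key cards must cover each {dim.value.lower()} exactly once"
                )

    def pile_for(self, card: Card, dim: Dimension) -> int:
        """1-based index of the unique pile matching ``card`` on ``dim``."""
        value = card.attribute(dim)
        for i, key in enumerate(self.piles, start=1):
            if key.attribute(dim) == value:
                return i
        raise AssertionError("unreachable: key cards cover every level")


@dataclass(frozen=True)
class Deck:
    """An ordered deck of cards together with the seed that shuffled it."""

    cards: tuple[Card, ...]
    seed: int


def build_key_cards() -> KeyCardSet:
    """The canonical key cards: one red triangle, two green stars, three
    yellow crosses, four blue circles."""
    return KeyCardSet(
        piles=(
            Card("red", "triangle", 1),
            Card("green", "star", 2),
            Card("yellow", "cross", 3),
            Card("blue", "circle", 4),
        )
    )


def _all_combinations() -> list[Card]:
    return [Card(c, s, n) for c, s, n in product(COLORS, SHAPES, NUMBERS)]


def build_deck(seed: int, exclude_key_identical: bool = False) -> Deck:
    """Build the standard 128-card deck: each of the 64 color×shape×number
    combinations exactly twice, in a seed-determined shuffled order.

    Parameters
    ----------
    seed
        Shuffle seed; the card order is a deterministic function of it.
    exclude_key_identical
        If True, the four combinations identical to a key card are dropped
        (leaving 120 cards). Off by default: the standard deck keeps all 64
        combinations.
    """
    combos = _all_combinations()
    if exclude_key_identical:
        keys = set(build_key_cards().piles)
        combos = [c for c in combos if c not in keys]
    cards = combos * 2
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cards))
    return Deck(cards=tuple(cards[i] for i in order), seed=seed)


def correct_pile(card: Card, rule: Dimension, keys: KeyCardSet) -> int:
    """The unique pile whose key card shares ``card``'s attribute on ``rule``."""
    return keys.pile_for(card, rule)


def next_rule(current: Dimension, order: Iterable[Dimension] = DIMENSIONS) -> Dimension:
    """Successor of ``current`` in the fixed rule cycle (wrapping)."""
    order = tuple(order)
    i = order.index(current)
    return order[(i + 1) % len(order)]
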