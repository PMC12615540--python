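"""Four-deck economy of the play-or-pass Iowa Gambling Task.

The task presents one of four decks (A-D) per trial; playing draws the next
card of that deck and yields a single net monetary outcome.  Decks A and B
are disadvantageous (long-run mean -$25/card), C and D advantageous
(+$20 and +$25).  Each deck holds 30 cards, giving a 120-trial task.

Published deck descriptives pin most compositions exactly; where a deck's
loss set is underdetermined (deck A), a graded loss ladder mirroring the
classic IGT deck A is used.  All card orders are deterministic permutations
of the deck multiset: ``seed=None`` selects the documented canonical order
(a fixed shuffle), any integer seed another reproducible permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DECK_LABELS = ("A", "B", "C", "D")

#: canonical shuffle seed for within-deck card order and the trial schedule
CANONICAL_SEED = 0

# Published per-deck descriptives: mean, sum, gain/zero/loss counts, extremes.
DECK_TABLE = {
    "A": {"mean": -25, "sum": -750, "gain_freq": 15, "zero_freq": 0,
          "loss_freq": 15, "highest_gain": 100, "highest_loss": -250},
    "B": {"mean": -25, "sum": -750, "gain_freq": 27, "zero_freq": 0,
          "loss_freq": 3, "highest_gain": 100, "highest_loss": -1150},
    "C": {"mean": 20, "sum": 600, "gain_freq": 15, "zero_freq": 9,
          "loss_freq": 6, "highest_gain": 50, "highest_loss": -25},
    "D": {"mean": 25, "sum": 750, "gain_freq": 27, "zero_freq": 0,
          "loss_freq": 3, "highest_gain": 50, "highest_loss": -200},
}


class DeckError(ValueError):
    """Raised for malformed deck specifications or sequences."""


@dataclass(frozen=True)
class DeckSpec:
    """Composition of one deck: every card's value, grouped by sign."""

    label: str
    gain_values: tuple[float, ...]
    zero_count: int
    loss_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.label not in DECK_LABELS:
            raise DeckError(f"unknown deck label {self.label!r}")
        if any(g <= 0 for g in self.gain_values):
            raise DeckError(f"deck {self.label}: gains must be positive")
        if any(l >= 0 for l in self.loss_values):
            raise DeckError(f"deck {self.label}: losses must be negative")
        if self.zero_count < 0:
            raise DeckError(f"deck {self.label}: negative zero_count")

    @property
    def n_cards(self) -> int:
        return len(self.gain_values) + self.zero_count + len(self.loss_values)

    @property
    def card_values(self) -> tuple[float, ...]:
        """The full card multiset (gains, zeros, losses; unordered)."""
        return self.gain_values + (0.0,) * self.zero_count + self.loss_values

    @property
    def total(self) -> float:
        return float(sum(self.card_values))

    @property
    def long_run_mean(self) -> float:
        return self.total / self.n_cards


@dataclass(frozen=True)
class OutcomeSequence:
    """A fixed card order for one deck (a permutation of its spec)."""

    deck: str
    outcomes: tuple[float, ...]
    seed: int | str

    def __len__(self) -> int:
        return len(self.outcomes)


@dataclass(frozen=True)
class TaskSchedule:
    """Which deck is highlighted on each trial."""

    presented_deck: tuple[str, ...]

    @property
    def n_trials(self) -> int:
        return len(self.presented_deck)

    def deck_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.presented_deck:
            key = str(d)
            out[key] = out.get(key, 0) + 1
        return out


def build_deck_specs() -> list[DeckSpec]:
    """The four play-or-pass IGT decks.

    Decks B, C and D are uniquely pinned by the published descriptives once
    all gains sit at the deck's highest gain and all losses at its highest
    loss.  Deck A's 15 losses must sum to -$2250 with extreme -$250; the
    graded ladder {-50,-100,-150,-200,-250} x3 satisfies every constraint.
    """
    return [
        DeckSpec("A", (100.0,) * 15, 0,
                 tuple(float(v) for v in (-50, -100, -150, -200, -250) for _ in range(3))),
        DeckSpec("B", (100.0,) * 27, 0, (-1150.0,) * 3),
        DeckSpec("C", (50.0,) * 15, 9, (-25.0,) * 6),
        DeckSpec("D", (50.0,) * 27, 0, (-200.0,) * 3),
    ]


def _resolve_seed(seed: int | None | str) -> tuple[int, int | str]:
    """Map the user-facing seed to (shuffle seed, recorded tag)."""
    if seed is None or seed == "canonical":
        return CANONICAL_SEED, "canonical"
    return int(seed), int(seed)


def generate_payout_sequence(spec: DeckSpec, seed: int | None | str = None) -> OutcomeSequence:
    """A reproducible card order for ``spec``: a seeded permutation of its multiset."""
    if spec.n_cards == 0:
        raise DeckError(f"deck {spec.label}: empty spec")
    shuffle_seed, tag = _resolve_seed(seed)
    rng = np.random.default_rng(shuffle_seed)
    cards = np.array(spec.card_values, dtype=float)
    order = rng.permutation(len(cards))
    return OutcomeSequence(spec.label, tuple(float(v) for v in cards[order]),
                           tag)


def build_trial_schedule(specs: Sequence[DeckSpec], seed: int | None | str = None) -> TaskSchedule:
    """Interleaved deck-presentation order: each deck appears once per card."""
    labels: list[str] = []
    for spec in specs:
        labels.extend([spec.label] * spec.n_cards)
    shuffle_seed, _ = _resolve_seed(seed)
    rng = np.random.default_rng(shuffle_seed)
    arr = np.array(labels)
    return TaskSchedule(tuple(str(d) for d in arr[rng.permutation(len(arr))]))


def validate_against_table3(sequences: Iterable[OutcomeSequence]) -> pd.DataFrame:
    """Check generated sequences against the published deck descriptives.

    Returns a tidy frame with one row per (deck, statistic) and a boolean
    ``passed`` column; all 28 cells must pass on generator output.
    """
    seqs = {s.deck: s for s in sequences}
    if not seqs:
        raise DeckError("no sequences supplied")
    missing = [d for d in DECK_LABELS if d not in seqs]
    if missing:
        raise DeckError(f"missing deck sequence(s): {', '.join(missing)}")

    rows = []
    for deck in DECK_LABELS:
        x = np.array(seqs[deck].outcomes, dtype=float)
        observed = {
            "mean": float(x.mean()),
            "sum": float(x.sum()),
            "gain_freq": int((x > 0).sum()),
            "zero_freq": int((x == 0).sum()),
            "loss_freq": int((x < 0).sum()),
            "highest_gain": float(x.max()),
            "highest_loss": float(x.min()),
        }
        for stat, expected in DECK_TABLE[deck].items():
            rows.append({
                "deck": deck,
                "statistic": stat,
                "expected": float(expected),
                "observed": float(observed[stat]),
                "passed": bool(np.isclose(observed[stat], expected)),
            })
    return pd.DataFrame(rows)


def deck_table_frame(specs: Sequence[DeckSpec] | None = None) -> pd.DataFrame:
    """Per-deck descriptives of ``specs`` in the published table layout."""
    specs = list(specs) if specs is not None else build_deck_specs()
    cols = {}
    for spec in specs:
        x = np.array(spec.card_values, dtype=float)
        cols[spec.label] = {
            "mean": x.mean(), "sum": x.sum(),
            "gain_freq": int((x > 0).sum()), "zero_freq": int((x == 0).sum()),
            "loss_freq": int((x < 0).sum()),
            "highest_gain": x.max(), "highest_loss": x.min(),
        }
    return pd.DataFrame(cols)


def sequences_frame(schedule: TaskSchedule,
                    sequences: Iterable[OutcomeSequence]) -> pd.DataFrame:
    """Long-format export: one row per trial with the card that a play would draw.

    Card positions advance per presentation of the deck (the draw order a
    subject who always plays would experience).
    """
    seqs = {s.deck: s for s in sequences}
    pos = {d: 0 for d in seqs}
    rows = []
    for t, deck in enumerate(schedule.presented_deck, start=1):
        rows.append({"trial": t, "deck": deck,
                     "card_value": seqs[deck].outcomes[pos[deck]]})
        pos[deck] += 1
    return pd.DataFrame(rows)
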