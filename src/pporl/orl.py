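"""Trial-level play-or-pass Outcome-Representation-Learning (PP-ORL) model.

On each trial one deck ``j`` is highlighted and the agent plays (``Y=1``,
drawing the deck's next card for a net outcome ``x``) or passes (``Y=0``,
no outcome).  The probability of playing is a logistic function of the value
of playing

    V_j = EV_j + EF_j * beta_f + beta_b

with the value of passing pinned at 0.  ``EV_j`` tracks the deck's expected
outcome and ``EF_j`` its expected win frequency (the running sign of
outcomes); both update only on played trials by delta rules whose learning
rate depends on the outcome's sign: gains (``x >= 0``) update the played
deck with ``a_rew``, losses with ``a_pun``.  Unplayed decks receive a
counterfactual ("fictive") win-frequency update toward ``-sgn(x)/C`` with
the *opposite* learning rate, where ``C = 3`` is the number of other decks.

Monetary outcomes are divided by ``OUTCOME_SCALE`` (=100) before entering
the delta rule so that deck values and the two beta weights live on
comparable unit scales; ``sgn(0) = 0``, so zero-outcome cards take the gain
branch and decay ``EF`` toward zero.  Timeouts are scored as passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .decks import DECK_LABELS, OutcomeSequence, TaskSchedule

#: dollars per model outcome unit
OUTCOME_SCALE = 100.0

#: number of alternative decks receiving fictive updates
N_OTHER_DECKS = 3

DECK_INDEX = {d: i for i, d in enumerate(DECK_LABELS)}


class ModelError(ValueError):
    """Raised for invalid parameters, states or inconsistent trial data."""


@dataclass(frozen=True)
class ORLParams:
    """One agent's four PP-ORL parameters."""

    a_rew: float  #: reward learning rate, in (0, 1)
    a_pun: float  #: punishment learning rate, in (0, 1)
    beta_f: float  #: win-frequency sensitivity (unbounded)
    beta_b: float  #: response bias: >0 favours playing on every deck

    def __post_init__(self) -> None:
        if not (0.0 < self.a_rew < 1.0) or not (0.0 < self.a_pun < 1.0):
            raise ModelError("learning rates must lie strictly in (0, 1)")
        if not (math.isfinite(self.beta_f) and math.isfinite(self.beta_b)):
            raise ModelError("beta_f and beta_b must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.a_rew, self.a_pun, self.beta_f, self.beta_b])


@dataclass(frozen=True)
class AgentState:
    """Per-deck expectations carried across trials (scaled-outcome units)."""

    ev: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    ef: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def play_value(self, deck: str, params: ORLParams) -> float:
        """V for the presented deck under ``params`` (value of passing = 0)."""
        j = _deck_index(deck)
        return self.ev[j] + self.ef[j] * params.beta_f + params.beta_b

    def play_values(self, params: ORLParams) -> np.ndarray:
        return (np.asarray(self.ev) + np.asarray(self.ef) * params.beta_f
                + params.beta_b)


@dataclass(frozen=True)
class TrialRecord:
    """One trial: presented deck, play/pass choice, outcome if played."""

    trial: int
    deck: str
    choice: int
    outcome: float | None = None  #: dollars; None on pass trials
    timeout: bool = False

    def __post_init__(self) -> None:
        if self.choice not in (0, 1):
            raise ModelError(f"trial {self.trial}: choice must be 0 or 1")
        if self.timeout and self.choice != 0:
            raise ModelError(f"trial {self.trial}: timeouts are scored as passes")
        if self.choice == 1 and self.outcome is None:
            raise ModelError(f"trial {self.trial}: played trial lacks an outcome")
        if self.choice == 0 and self.outcome is not None:
            raise ModelError(f"trial {self.trial}: outcome recorded on a pass")
        if self.deck not in DECK_INDEX:
            raise ModelError(f"trial {self.trial}: unknown deck {self.deck!r}")


@dataclass(frozen=True)
class SubjectData:
    """One participant's full trial sequence."""

    subject_id: str
    trials: tuple[TrialRecord, ...]

    def __post_init__(self) -> None:
        idx = [t.trial for t in self.trials]
        if idx != list(range(1, len(idx) + 1)):
            raise ModelError(
                f"subject {self.subject_id}: trial indices must be 1..n contiguous")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _deck_index(deck: str) -> int:
    try:
        return DECK_INDEX[deck]
    except KeyError:
        raise ModelError(f"unknown deck {deck!r}") from None


def play_probability(v: float | np.ndarray) -> float | np.ndarray:
    """Probability of playing at value-of-playing ``v``: logistic(v)."""
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ModelError("value of playing must be finite")
    # equivalent to 1/(1+exp(-v)), overflow-safe on both tails
    out = np.where(arr >= 0,
                   1.0 / (1.0 + np.exp(-np.clip(arr, 0, None))),
                   np.exp(np.clip(arr, None, 0))
                   / (1.0 + np.exp(np.clip(arr, None, 0))))
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def update_state(state: AgentState, deck: str, choice: int,
                 outcome: float | None, params: ORLParams) -> AgentState:
    """Advance the agent one trial.

    ``outcome`` is on the model (scaled) scale and must be supplied exactly
    when ``choice == 1``.  Passes leave all expectations untouched; plays
    update the presented deck's EV and EF with the sign-appropriate learning
    rate and give every other deck a fictive EF update with the opposite
    rate toward ``-sgn(x)/3``.
    """
    j = _deck_index(deck)
    if choice == 0:
        if outcome is not None:
            raise ModelError("outcome supplied on a pass trial")
        return state
    if outcome is None:
        raise ModelError("played trial requires an outcome")

    x = float(outcome)
    sgn = float(np.sign(x))
    if x >= 0:
        a_self, a_other = params.a_rew, params.a_pun
    else:
        a_self, a_other = params.a_pun, params.a_rew

    ev = list(state.ev)
    ef = list(state.ef)
    ev[j] += a_self * (x - ev[j])
    ef[j] += a_self * (sgn - ef[j])
    fictive_target = -sgn / N_OTHER_DECKS
    for d in range(4):
        if d != j:
            ef[d] += a_other * (fictive_target - ef[d])
    return AgentState(tuple(ev), tuple(ef))


def _bernoulli_logpmf(y: int, v: float) -> float:
    """log P(Y=y) for play value v: y*v - log(1+exp(v)), overflow-safe."""
    softplus = max(v, 0.0) + math.log1p(math.exp(-abs(v)))
    return y * v - softplus


def subject_log_likelihood(
    data: SubjectData,
    params: ORLParams,
    sequences: Mapping[str, OutcomeSequence] | None = None,
    outcome_scale: float = OUTCOME_SCALE,
) -> float:
    """Total Bernoulli log-likelihood of one subject's choices.

    State is threaded trial by trial through :func:`update_state`; the
    choice on trial ``t`` is evaluated at the value of playing implied by
    trials ``1..t-1``.  When ``sequences`` is given, each played trial's
    recorded outcome is checked against the deck's fixed card order (plays
    consume cards in order); a mismatch raises listing the trial.
    """
    positions = {d: 0 for d in DECK_LABELS}
    state = AgentState()
    total = 0.0
    for rec in data.trials:
        v = state.play_value(rec.deck, params)
        total += _bernoulli_logpmf(rec.choice, v)
        if rec.choice == 1:
            if sequences is not None:
                expected = sequences[rec.deck].outcomes[positions[rec.deck]]
                if not math.isclose(expected, rec.outcome, abs_tol=1e-9):
                    raise ModelError(
                        f"subject {data.subject_id} trial {rec.trial}: outcome "
                        f"{rec.outcome} does not match deck {rec.deck} card "
                        f"{positions[rec.deck] + 1} (= {expected})")
            positions[rec.deck] += 1
            state = update_state(state, rec.deck, 1,
                                 rec.outcome / outcome_scale, params)
    if not math.isfinite(total):
        raise ModelError("non-finite log-likelihood")
    return total


def simulate_agent(
    params: ORLParams,
    schedule: TaskSchedule,
    sequences: Mapping[str, OutcomeSequence],
    seed: int,
    subject_id: str = "sim",
    timeout_prob: float = 0.0,
    outcome_scale: float = OUTCOME_SCALE,
) -> SubjectData:
    """Generate one agent's choices on the task.

    Each trial the agent plays with probability ``logistic(V)``; a play
    draws the presented deck's next unconsumed card.  With probability
    ``timeout_prob`` the trial times out and is scored as a pass before any
    choice is made.
    """
    rng = np.random.default_rng(seed)
    positions = {d: 0 for d in DECK_LABELS}
    state = AgentState()
    records: list[TrialRecord] = []
    for t, deck in enumerate(schedule.presented_deck, start=1):
        if timeout_prob > 0 and rng.random() < timeout_prob:
            records.append(TrialRecord(t, deck, 0, None, timeout=True))
            continue
        p = play_probability(state.play_value(deck, params))
        if rng.random() < p:
            outcome = sequences[deck].outcomes[positions[deck]]
            positions[deck] += 1
            records.append(TrialRecord(t, deck, 1, outcome))
            state = update_state(state, deck, 1, outcome / outcome_scale, params)
        else:
            records.append(TrialRecord(t, deck, 0, None))
    return SubjectData(subject_id, tuple(records))


def subject_arrays(data: SubjectData,
                   outcome_scale: float = OUTCOME_SCALE
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(deck_idx, choice, scaled outcome) arrays for the fast kernels."""
    n = data.n_trials
    deck = np.empty(n, dtype=np.int64)
    choice = np.empty(n, dtype=np.int64)
    outcome = np.zeros(n, dtype=np.float64)
    for k, rec in enumerate(data.trials):
        deck[k] = DECK_INDEX[rec.deck]
        choice[k] = rec.choice
        if rec.choice == 1:
            outcome[k] = rec.outcome / outcome_scale
    return deck, choice, outcome
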