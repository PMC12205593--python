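"""Rules and sampling for the blind-blackjack ("twenty-one") card task.

The task is a two-choice game played in 16-trial games. On every trial the
player holds a visible face-up card (score 8-18) and a hidden face-down card
(score 1 or 4, drawn from a deck whose composition is announced at game
start). The player may *hit* — add one card drawn from a hidden *additional*
deck, either B(10, 0.4) ("Deck 4") or B(10, 0.6) ("Deck 6") — or *stay*.
Totals of at most 21 pay their own score; busting pays nothing. The
additional card is revealed at the end of every trial, hit or stay, so
evidence about the hidden deck accrues across trials within a game.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DeckType",
    "FaceDownDeckType",
    "GameConfig",
    "TrialRecord",
    "SessionData",
    "TrialResponse",
    "Policy",
    "additional_pmf",
    "expected_scores",
    "resolve_payoff",
    "build_schedule",
    "play_game",
    "PROTOCOL_GAMES",
]

FACEUP_MIN, FACEUP_MAX = 8, 18
N_TRIALS_PER_GAME = 16
BUST_THRESHOLD = 21

#: games per protocol; each 2x2 deck cell appears count/4 times
PROTOCOL_GAMES = {"behavioral": 20, "scanning": 8, "training": 4}


class DeckType(enum.Enum):
    """Hidden additional-card deck: binomial score distributions on 0..10."""

    DECK4 = "4"
    DECK6 = "6"

    @property
    def p(self) -> float:
        return 0.4 if self is DeckType.DECK4 else 0.6

    @property
    def expected_score(self) -> float:
        return 10.0 * self.p

    @property
    def other(self) -> "DeckType":
        return DeckType.DECK6 if self is DeckType.DECK4 else DeckType.DECK4


class FaceDownDeckType(enum.Enum):
    """Announced face-down deck; cards score 1 (prob ``p_low``) or 4."""

    L = "L"
    H = "H"

    @property
    def p_low(self) -> float:
        return 0.2 if self is FaceDownDeckType.L else 0.5

    @property
    def expected_score(self) -> float:
        return self.p_low * 1.0 + (1.0 - self.p_low) * 4.0


@dataclass(frozen=True)
class GameConfig:
    additional_deck: DeckType
    facedown_deck: FaceDownDeckType
    n_trials: int = N_TRIALS_PER_GAME

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")


@dataclass
class TrialRecord:
    """One trial: dealt cards, the four behavioral reports, and the payoff.

    ``additional`` is always recorded — the additional card is revealed even
    on stay trials — but only contributes to the total when the action was
    hit. Reports may be ``None`` (missed responses).
    """

    game_index: int
    trial_index: int
    faceup: int
    facedown: int
    additional: int
    deck_report: DeckType | None
    deck_conf_report: int | None
    action: str | None
    dec_conf_report: int | None
    payoff: int


@dataclass
class SessionData:
    participant_id: str
    protocol: str
    games: list[tuple[GameConfig, list[TrialRecord]]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return sum(len(trials) for _, trials in self.games)

    def iter_trials(self):
        for config, trials in self.games:
            for rec in trials:
                yield config, rec


def additional_pmf(deck: DeckType) -> np.ndarray:
    """Probability of each additional-card score 0..10 under ``deck``."""
    if not isinstance(deck, DeckType):
        raise TypeError(f"expected DeckType, got {deck!r}")
    return stats.binom.pmf(np.arange(11), 10, deck.p)


def expected_scores(
    facedown_deck: FaceDownDeckType, additional_deck: DeckType
) -> tuple[float, float]:
    """(expected face-down score, expected additional score) for a game."""
    return facedown_deck.expected_score, additional_deck.expected_score


def resolve_payoff(faceup: int, facedown: int, additional: int, action: str) -> int:
    """Payoff: the hand total, or zero on a bust (total above 21)."""
    if action not in ("hit", "stay"):
        raise ValueError(f"invalid action {action!r}; expected 'hit' or 'stay'")
    total = faceup + facedown + (additional if action == "hit" else 0)
    return total if total <= BUST_THRESHOLD else 0


def build_schedule(protocol: str, seed: int) -> list[GameConfig]:
    """Balanced 2x2 deck schedule for a protocol, shuffled by ``seed``.

    behavioral: 20 games (5 per cell); scanning: 8 (2 per cell);
    training: 4 (1 per cell).
    """
    if protocol not in PROTOCOL_GAMES:
        raise ValueError(f"unknown protocol {protocol!r}")
    per_cell = PROTOCOL_GAMES[protocol] // 4
    cells = [
        GameConfig(a, f)
        for a in (DeckType.DECK4, DeckType.DECK6)
        for f in (FaceDownDeckType.L, FaceDownDeckType.H)
    ]
    schedule = [c for c in cells for _ in range(per_cell)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(schedule))
    return [schedule[i] for i in order]


@dataclass(frozen=True)
class TrialResponse:
    """A policy's four responses on one trial."""

    deck_report: DeckType | None
    deck_conf_report: int | None
    action: str | None
    dec_conf_report: int | None


class Policy(Protocol):
    """Per-game agent callback for :func:`play_game`.

    ``begin_game`` receives only what the player observes at game start (the
    announced face-down deck); ``decide`` receives the current face-up score
    and the additional card revealed on the *previous* trial (``None`` on the
    first trial).
    """

    def begin_game(self, facedown_deck: FaceDownDeckType) -> None: ...

    def decide(
        self, trial_index: int, faceup: int, prev_additional: int | None
    ) -> TrialResponse: ...


def _validate_response(resp: TrialResponse) -> None:
    if resp.deck_report is not None and not isinstance(resp.deck_report, DeckType):
        raise ValueError(f"invalid deck report {resp.deck_report!r}")
    if resp.action is not None and resp.action not in ("hit", "stay"):
        raise ValueError(f"invalid action {resp.action!r}")
    for conf in (resp.deck_conf_report, resp.dec_conf_report):
        if conf is not None and conf not in (1, 2, 3, 4):
            raise ValueError(f"invalid 4-point confidence report {conf!r}")


def play_game(
    config: GameConfig,
    policy: Policy,
    seed: int | np.random.Generator,
    game_index: int = 0,
) -> list[TrialRecord]:
    """Simulate one game, querying ``policy`` for the four reports per trial.

    Cards are drawn from the game's decks; the additional card is revealed
    (recorded) on every trial regardless of the action. Payoff for missed
    actions is resolved as stay (the hand is kept).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = config.n_trials
    faceups = rng.integers(FACEUP_MIN, FACEUP_MAX + 1, size=n)
    facedowns = np.where(
        rng.random(n) < config.facedown_deck.p_low, 1, 4
    )
    additionals = rng.binomial(10, config.additional_deck.p, size=n)

    policy.begin_game(config.facedown_deck)
    records: list[TrialRecord] = []
    prev_additional: int | None = None
    for t in range(n):
        resp = policy.decide(t, int(faceups[t]), prev_additional)
        _validate_response(resp)
        effective_action = resp.action if resp.action is not None else "stay"
        payoff = resolve_payoff(
            int(faceups[t]), int(facedowns[t]), int(additionals[t]), effective_action
        )
        records.append(
            TrialRecord(
                game_index=game_index,
                trial_index=t,
                faceup=int(faceups[t]),
                facedown=int(facedowns[t]),
                additional=int(additionals[t]),
                deck_report=resp.deck_report,
                deck_conf_report=resp.deck_conf_report,
                action=resp.action,
                dec_conf_report=resp.dec_conf_report,
                payoff=payoff,
            )
        )
        prev_additional = int(additionals[t])
    return records
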