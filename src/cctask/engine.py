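"""State machines for the Cold, Warm, Toasty, and Hot CCT versions.

The four versions differ only in when the player commits to reveals and when
feedback arrives:

* **Cold** — one blind commitment of ``n`` cards; no per-round feedback
  (one implicit batch, zero feedback requests). Never censored.
* **Warm** — one commitment of ``n`` cards, revealed one by one at the end
  of the round (one feedback request). Never censored.
* **Toasty** — an initial committed batch, then repeated continue/stop
  decisions, each continuation committing a further batch; feedback after
  every batch. A loss card inside a batch ends the round before the player
  could stop, so the round is right-censored.
* **Hot** — card-by-card decisions with immediate feedback; equivalent to
  Toasty with all batches of size 1. A revealed loss always censors.

Scoring: gain cards are worth ``g`` each; the first loss card ends the round
and costs ``l``; at most one loss card is ever revealed. Session bonus is $1
per 100 points, floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import GAIN, LOSS, DeckLayout, RoundParams

__all__ = [
    "VERSIONS",
    "RoundTranscript",
    "SessionRecord",
    "Policy",
    "FixedCountPolicy",
    "InvalidActionError",
    "ProtocolError",
    "play_round",
    "replay_round",
    "score_round",
    "score_session",
]

VERSIONS = ("cold", "warm", "toasty", "hot")


class InvalidActionError(ValueError):
    """A policy requested an action the rules do not allow."""


class ProtocolError(RuntimeError):
    """A policy was consulted after the round had already ended."""


@dataclass
class RoundState:
    """What a policy may observe mid-round (Toasty/Hot)."""

    params: RoundParams
    cards_revealed: int = 0
    gains_revealed: int = 0
    committed: int = 0
    n_requests: int = 0

    @property
    def remaining(self) -> int:
        return self.params.n_total_cards - self.cards_revealed


class Policy:
    """Per-version decision interface.

    Cold/Warm consult :meth:`choose_count` once. Toasty consults
    :meth:`next_batch` repeatedly (first call = initial batch; return 0 to
    stop). Hot consults :meth:`take_another` before each reveal.
    """

    def choose_count(self, params: RoundParams, rng: np.random.Generator) -> int:
        raise NotImplementedError

    def next_batch(self, state: RoundState, rng: np.random.Generator) -> int:
        raise NotImplementedError

    def take_another(self, state: RoundState, rng: np.random.Generator) -> bool:
        raise NotImplementedError


class FixedCountPolicy(Policy):
    """Reveal exactly ``n`` cards (unless a loss intervenes).

    For Toasty, ``batch_sizes`` optionally splits the target into committed
    batches (default: a single Warm-like batch of ``n``).
    """

    def __init__(self, n: int, batch_sizes: list[int] | None = None):
        if batch_sizes is not None and sum(batch_sizes) != n:
            raise InvalidActionError("batch_sizes must sum to n")
        self.n = n
        self.batch_sizes = list(batch_sizes) if batch_sizes is not None else None

    def choose_count(self, params, rng):
        return self.n

    def next_batch(self, state, rng):
        plan = self.batch_sizes if self.batch_sizes is not None else [self.n]
        if state.n_requests >= len(plan):
            return 0
        return min(plan[state.n_requests], state.remaining)

    def take_another(self, state, rng):
        return state.cards_revealed < self.n


@dataclass(frozen=True)
class RoundTranscript:
    """Complete record of one played round."""

    version: str
    params: RoundParams
    reveals: tuple[tuple[int, str], ...]  # (1-based reveal position, identity)
    batch_sizes: tuple[int, ...]
    n_feedback_requests: int
    intended_count: int
    cards_revealed: int
    loss_revealed: bool
    censored: bool
    ended_by: str  # stop | loss | deck_exhausted
    score: int
    scored: bool = True

    @property
    def gains_revealed(self) -> int:
        return self.cards_revealed - (1 if self.loss_revealed else 0)


def score_round(transcript: RoundTranscript) -> int:
    """Points for a round: g x (gain cards revealed) - l x (loss revealed)."""
    p = transcript.params
    return p.gain_amount * transcript.gains_revealed - (
        p.loss_amount if transcript.loss_revealed else 0
    )


def _finish(
    version: str,
    params: RoundParams,
    reveals: list[tuple[int, str]],
    batches: list[int],
    n_requests: int,
    intended: int,
    ended_by: str,
    scored: bool,
    censor_at: str,
    committed: int,
) -> RoundTranscript:
    loss = bool(reveals) and reveals[-1][1] == LOSS
    censored = loss and version in ("toasty", "hot") and ended_by == "loss"
    if censored:
        # right-censoring lower bound on intent: the flip count, or the total
        # committed through the batch in which the loss occurred
        intended = len(reveals) if censor_at == "revealed" else committed
    gains = len(reveals) - (1 if loss else 0)
    score = params.gain_amount * gains - (params.loss_amount if loss else 0)
    return RoundTranscript(
        version=version,
        params=params,
        reveals=tuple(reveals),
        batch_sizes=tuple(batches),
        n_feedback_requests=n_requests,
        intended_count=intended,
        cards_revealed=len(reveals),
        loss_revealed=loss,
        censored=censored,
        ended_by=ended_by,
        score=score,
        scored=scored,
    )


def play_round(
    version: str,
    params: RoundParams,
    layout: DeckLayout,
    policy: Policy,
    rng: np.random.Generator,
    censor_at: str = "committed",
) -> RoundTranscript:
    """Run one round of the given version against ``layout``.

    ``censor_at`` selects the intended-count convention for censored rounds:
    ``committed`` (total committed through the batch holding the loss — the
    sharpest valid lower bound) or ``revealed`` (the flip count).
    """
    if version not in VERSIONS:
        raise ValueError(f"unknown version {version!r}")
    if layout.n_total_cards != params.n_total_cards:
        raise InvalidActionError("layout size does not match round params")
    if censor_at not in ("committed", "revealed"):
        raise ValueError(f"unknown censor_at {censor_at!r}")

    N = params.n_total_cards
    reveals: list[tuple[int, str]] = []

    def reveal_next() -> str:
        pos = len(reveals) + 1
        identity = layout.card(pos)
        reveals.append((pos, identity))
        return identity

    if version in ("cold", "warm"):
        n = int(policy.choose_count(params, rng))
        if not 0 <= n <= N:
            raise InvalidActionError(f"committed count {n} outside [0, {N}]")
        ended_by = "stop"
        for _ in range(n):
            if reveal_next() == LOSS:
                ended_by = "loss"
                break
        if ended_by != "loss" and n == N:
            ended_by = "deck_exhausted"
        batches = [n]
        n_requests = 0 if version == "cold" else (1 if n > 0 else 0)
        return _finish(
            version, params, reveals, batches, n_requests, n, ended_by, layout.scored,
            censor_at, n,
        )

    state = RoundState(params)
    batches: list[int] = []
    if version == "toasty":
        while True:
            b = int(policy.next_batch(state, rng))
            if b == 0:
                return _finish(
                    version, params, reveals, batches, state.n_requests, state.committed,
                    "stop", layout.scored, censor_at, state.committed,
                )
            if b < 0 or b > state.remaining:
                raise InvalidActionError(
                    f"batch of {b} with {state.remaining} cards remaining"
                )
            batches.append(b)
            state.committed += b
            state.n_requests += 1
            for _ in range(b):
                identity = reveal_next()
                state.cards_revealed += 1
                if identity == LOSS:
                    return _finish(
                        version, params, reveals, batches, state.n_requests,
                        state.committed, "loss", layout.scored, censor_at, state.committed,
                    )
                state.gains_revealed += 1
            if state.remaining == 0:
                return _finish(
                    version, params, reveals, batches, state.n_requests, state.committed,
                    "deck_exhausted", layout.scored, censor_at, state.committed,
                )

    # hot: card-by-card, every reveal is its own request/batch
    while True:
        if state.remaining == 0:
            return _finish(
                version, params, reveals, batches, state.n_requests, state.committed,
                "deck_exhausted", layout.scored, censor_at, state.committed,
            )
        if not policy.take_another(state, rng):
            return _finish(
                version, params, reveals, batches, state.n_requests, state.committed,
                "stop", layout.scored, censor_at, state.committed,
            )
        batches.append(1)
        state.committed += 1
        state.n_requests += 1
        identity = reveal_next()
        state.cards_revealed += 1
        if identity == LOSS:
            return _finish(
                version, params, reveals, batches, state.n_requests, state.committed,
                "loss", layout.scored, censor_at, state.committed,
            )
        state.gains_revealed += 1


def replay_round(transcript: RoundTranscript, layout: DeckLayout) -> RoundTranscript:
    """Re-run a transcript's committed decisions against a stored layout."""
    version = transcript.version
    if version in ("cold", "warm"):
        policy = FixedCountPolicy(transcript.intended_count)
    elif version == "toasty":
        policy = FixedCountPolicy(
            sum(transcript.batch_sizes), batch_sizes=list(transcript.batch_sizes)
        )
    else:
        policy = FixedCountPolicy(transcript.intended_count)
    return play_round(
        version, transcript.params, layout, policy, np.random.default_rng(0)
    )


@dataclass(frozen=True)
class SessionRecord:
    """All rounds of one participant plus totals and the dollar bonus."""

    participant_id: str
    version: str
    incentivized: bool
    transcripts: tuple[RoundTranscript, ...]
    total_score: int
    bonus: float  # dollars, $1 per 100 points, floored at 0


def score_session(
    participant_id: str,
    version: str,
    incentivized: bool,
    transcripts: list[RoundTranscript],
    scored_only: bool = True,
) -> SessionRecord:
    """Total a session and apply the bonus rule (no bonus for negative totals)."""
    counted = [t for t in transcripts if t.scored] if scored_only else list(transcripts)
    total = sum(t.score for t in counted)
    bonus = round(max(0, total) / 100.0, 2)
    return SessionRecord(
        participant_id, version, incentivized, tuple(transcripts), total, bonus
    )
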