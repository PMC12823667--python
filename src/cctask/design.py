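"""Factorial round designs and loss-card placement for the Columbia Card Task.

A CCT session is a sequence of rounds; each round is parameterized by a gain
amount ``g`` (points per gain card), a loss amount ``l`` (points forfeited on
the single loss card that ends the round), a number of loss cards ``m``, and a
deck size ``N`` (32 in the standard task, displayed as a 4x8 grid — the grid
geometry is cosmetic; only the reveal order matters).

Two placement traditions exist for the loss cards:

* ``random`` — loss cards occupy a uniformly random subset of reveal
  positions, consistent with the instructions given to players;
* ``stacked_end`` — the historical deceptive scheme that defers all loss
  cards to the last ``m`` reveal positions so the player's intended count is
  always observed, optionally masked by unscored "rigged" rounds
  (``stacked_with_rigged``) in which a single loss card appears early.

Reveal positions are 1-based throughout: card 1 is the first card flipped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RoundParams",
    "PlacementScheme",
    "DesignSpec",
    "DeckLayout",
    "DesignRow",
    "InvalidDesignError",
    "generate_design",
    "place_loss_cards",
    "design_to_frame",
]

GAIN = "gain"
LOSS = "loss"


class InvalidDesignError(ValueError):
    """Raised when a design specification cannot produce a valid session."""


@dataclass(frozen=True)
class RoundParams:
    """Parameters of a single CCT round: (g, l, m, N)."""

    gain_amount: int
    loss_amount: int
    n_loss_cards: int
    n_total_cards: int = 32

    def __post_init__(self) -> None:
        if self.gain_amount <= 0:
            raise InvalidDesignError(f"gain_amount must be > 0, got {self.gain_amount}")
        if self.loss_amount <= 0:
            raise InvalidDesignError(f"loss_amount must be > 0, got {self.loss_amount}")
        if self.n_total_cards < 1:
            raise InvalidDesignError("n_total_cards must be >= 1")
        if not 0 <= self.n_loss_cards <= self.n_total_cards:
            raise InvalidDesignError(
                f"n_loss_cards must lie in [0, {self.n_total_cards}], got {self.n_loss_cards}"
            )


@dataclass(frozen=True)
class PlacementScheme:
    """How loss cards are positioned in the reveal order.

    ``early_max`` is the latest reveal position allowed for the loss card of a
    rigged (unscored) round; it is ignored for the other two modes.
    """

    mode: str = "random"
    early_max: int = 3

    _MODES = ("random", "stacked_end", "stacked_with_rigged")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise InvalidDesignError(f"mode must be one of {self._MODES}, got {self.mode!r}")
        if self.early_max < 1:
            raise InvalidDesignError("early_max must be >= 1")


@dataclass(frozen=True)
class DesignSpec:
    """Full factorial design: factor levels x repetitions, plus rigged rounds.

    ``rigged_rounds`` lists 1-based positions in the final round sequence at
    which unscored rigged rounds are inserted (each carries a single early
    loss card). Rigged rounds require the ``stacked_with_rigged`` scheme.
    """

    gain_levels: tuple[int, ...] = (10, 30)
    loss_levels: tuple[int, ...] = (250, 750)
    loss_card_levels: tuple[int, ...] = (1, 3)
    n_repetitions: int = 3
    n_total_cards: int = 32
    scheme: PlacementScheme = field(default_factory=PlacementScheme)
    block_randomize: bool = True
    rigged_positions: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gain_levels", "loss_levels", "loss_card_levels"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise InvalidDesignError(f"{name} must be non-empty")
        if self.n_repetitions < 1:
            raise InvalidDesignError("n_repetitions must be >= 1")
        if self.rigged_positions:
            if self.scheme.mode != "stacked_with_rigged":
                raise InvalidDesignError(
                    "rigged rounds are only supported with the stacked_with_rigged scheme"
                )
            if len(set(self.rigged_positions)) != len(self.rigged_positions):
                raise InvalidDesignError("rigged positions must be distinct")
            if min(self.rigged_positions) < 1 or max(self.rigged_positions) > self.n_rounds:
                raise InvalidDesignError(
                    f"rigged positions must lie in [1, {self.n_rounds}]"
                )

    @property
    def n_scored_rounds(self) -> int:
        return (
            len(self.gain_levels)
            * len(self.loss_levels)
            * len(self.loss_card_levels)
            * self.n_repetitions
        )

    @property
    def n_rounds(self) -> int:
        return self.n_scored_rounds + len(self.rigged_positions)


@dataclass(frozen=True)
class DeckLayout:
    """Card identity (gain/loss) at each 1-based reveal position."""

    labels: tuple[str, ...]
    scored: bool = True

    def __post_init__(self) -> None:
        bad = set(self.labels) - {GAIN, LOSS}
        if bad:
            raise InvalidDesignError(f"unknown card labels: {bad}")

    @property
    def n_total_cards(self) -> int:
        return len(self.labels)

    @property
    def loss_positions(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, lab in enumerate(self.labels) if lab == LOSS)

    def card(self, position: int) -> str:
        """Identity of the card at 1-based reveal ``position``."""
        if not 1 <= position <= len(self.labels):
            raise IndexError(f"position {position} outside deck of {len(self.labels)}")
        return self.labels[position - 1]


@dataclass(frozen=True)
class DesignRow:
    """One round slot of a generated design."""

    round_index: int  # 1-based position in the session
    block: int  # 1-based repetition block; 0 for rigged rounds
    params: RoundParams
    scored: bool


def generate_design(spec: DesignSpec) -> list[DesignRow]:
    """Expand a :class:`DesignSpec` into an ordered session of rounds.

    Each repetition block contains every factor combination exactly once.
    With ``block_randomize`` the order within each block is a seeded
    permutation, so the output is a pure function of ``spec`` (including its
    seed). Rigged rounds (single early loss card, unscored) are spliced in at
    the requested 1-based sequence positions.
    """
    rng = np.random.default_rng(spec.seed)
    combos = [
        RoundParams(g, l, m, spec.n_total_cards)
        for g, l, m in itertools.product(
            spec.gain_levels, spec.loss_levels, spec.loss_card_levels
        )
    ]
    scored_rows: list[tuple[int, RoundParams]] = []
    for block in range(1, spec.n_repetitions + 1):
        order = rng.permutation(len(combos)) if spec.block_randomize else np.arange(len(combos))
        scored_rows.extend((block, combos[i]) for i in order)

    rigged_at = set(spec.rigged_positions)
    rows: list[DesignRow] = []
    scored_iter = iter(scored_rows)
    for pos in range(1, spec.n_rounds + 1):
        if pos in rigged_at:
            # rigged rounds show one loss card that appears early; gain/loss
            # amounts are drawn from the factor levels so the round looks
            # like any other to the player
            g = spec.gain_levels[int(rng.integers(len(spec.gain_levels)))]
            l = spec.loss_levels[int(rng.integers(len(spec.loss_levels)))]
            rows.append(
                DesignRow(pos, 0, RoundParams(g, l, 1, spec.n_total_cards), scored=False)
            )
        else:
            block, params = next(scored_iter)
            rows.append(DesignRow(pos, block, params, scored=True))
    return rows


def place_loss_cards(
    params: RoundParams,
    scheme: PlacementScheme,
    rng: np.random.Generator,
    *,
    rigged: bool = False,
) -> DeckLayout:
    """Lay out one deck according to the placement scheme.

    ``random`` draws the loss positions as a uniform random subset;
    ``stacked_end`` puts all ``m`` loss cards in the last ``m`` positions.
    A rigged layout (only under ``stacked_with_rigged``) contains exactly one
    loss card at a uniform position within the first ``early_max`` reveals
    and is flagged unscored.
    """
    N, m = params.n_total_cards, params.n_loss_cards
    if rigged:
        if scheme.mode != "stacked_with_rigged":
            raise InvalidDesignError("rigged layouts require the stacked_with_rigged scheme")
        if m != 1:
            raise InvalidDesignError("rigged rounds carry exactly one loss card")
        pos = int(rng.integers(1, min(scheme.early_max, N) + 1))
        labels = [GAIN] * N
        labels[pos - 1] = LOSS
        return DeckLayout(tuple(labels), scored=False)

    if scheme.mode == "random":
        loss_idx = rng.choice(N, size=m, replace=False)
    else:  # stacked_end / stacked_with_rigged scored rounds
        loss_idx = np.arange(N - m, N)
    labels = np.full(N, GAIN, dtype=object)
    labels[loss_idx] = LOSS
    return DeckLayout(tuple(labels), scored=True)


def design_to_frame(rows: list[DesignRow], scheme: PlacementScheme | None = None) -> pd.DataFrame:
    """Serialize a design to the flat CSV schema."""
    return pd.DataFrame(
        {
            "round_index": [r.round_index for r in rows],
            "block": [r.block for r in rows],
            "gain": [r.params.gain_amount for r in rows],
            "loss": [r.params.loss_amount for r in rows],
            "n_loss_cards": [r.params.n_loss_cards for r in rows],
            "n_total_cards": [r.params.n_total_cards for r in rows],
            "scored": [r.scored for r in rows],
            "scheme": (scheme.mode if scheme is not None else ""),
        }
    )


def frame_to_design(frame: pd.DataFrame) -> list[DesignRow]:
    """Inverse of :func:`design_to_frame`."""
    rows = []
    for rec in frame.itertuples(index=False):
        rows.append(
            DesignRow(
                int(rec.round_index),
                int(rec.block),
                RoundParams(
                    int(rec.gain), int(rec.loss), int(rec.n_loss_cards), int(rec.n_total_cards)
                ),
                bool(rec.scored),
            )
        )
    return rows
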