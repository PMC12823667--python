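"""Exact probability and expected-value analysis of a CCT round.

With ``m`` loss cards placed uniformly at random in a deck of ``N`` cards,
the reveal order is a draw without replacement, so the position ``J`` of the
first loss card among ``k`` intended reveals follows the order-statistic form
of the (negative) hypergeometric model:

    P(no loss in k draws) = C(N-m, k) / C(N, k)
    P(J = j)              = [ prod_{i=0}^{j-2} (N-m-i)/(N-i) ] * m/(N-j+1)

The expected score of committing to ``k`` reveals at gain ``g`` and loss
penalty ``l`` is

    EV(k) = g*k*P(no loss) + sum_{j=1}^{k} (g*(j-1) - l) * P(J = j),

and the optimal fixed count is argmax_k EV(k). Under uniform placement a
fixed-count policy is sufficient for EV maximization (revealed gains carry no
information about future cards beyond the updated composition, and the
argmax over remaining draws is what the full EV(k) enumeration captures), so
no dynamic programming over information states is needed.

All probabilities are exact :class:`fractions.Fraction` ratios, so argmax
sets and ties are exact, not floating-point artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .design import DesignRow, RoundParams

__all__ = [
    "FirstLossDistribution",
    "EVCurve",
    "first_loss_pmf",
    "expected_score",
    "ev_curve",
    "optimal_reveal",
    "deviation_score",
    "recovery_cards",
    "expected_bonus",
]


@dataclass(frozen=True)
class FirstLossDistribution:
    """Exact distribution of the first-loss position among ``k`` draws."""

    n_total_cards: int
    n_loss_cards: int
    k: int
    p_no_loss: Fraction
    pmf: tuple[Fraction, ...]  # pmf[j-1] = P(first loss at draw j), j = 1..k

    def p_first_loss_at(self, j: int) -> float:
        return float(self.pmf[j - 1])

    @property
    def p_any_loss(self) -> Fraction:
        return 1 - self.p_no_loss


def first_loss_pmf(N: int, m: int, k: int) -> FirstLossDistribution:
    """Exact pmf of the first loss position for ``k`` draws from (N, m)."""
    if not 0 <= m <= N:
        raise ValueError(f"need 0 <= m <= N, got m={m}, N={N}")
    if not 0 <= k <= N:
        raise ValueError(f"need 0 <= k <= N, got k={k}, N={N}")
    pmf = []
    p_clear = Fraction(1)  # P(first j-1 draws are all gains)
    for j in range(1, k + 1):
        pmf.append(p_clear * Fraction(m, N - j + 1))
        p_clear *= Fraction(N - m - (j - 1), N - (j - 1))
    return FirstLossDistribution(N, m, k, p_clear, tuple(pmf))


def _expected_score_exact(params: RoundParams, k: int) -> Fraction:
    g, l = params.gain_amount, params.loss_amount
    dist = first_loss_pmf(params.n_total_cards, params.n_loss_cards, k)
    ev = g * k * dist.p_no_loss
    for j, pj in enumerate(dist.pmf, start=1):
        ev += (g * (j - 1) - l) * pj
    return ev


def expected_score(params: RoundParams, k: int) -> float:
    """Expected round score of committing to reveal ``k`` cards."""
    return float(_expected_score_exact(params, k))


@dataclass(frozen=True)
class EVCurve:
    """Expected score as a function of the committed reveal count."""

    params: RoundParams
    values: tuple[float, ...]  # index k = 0..N
    argmax_set: tuple[int, ...]

    def __getitem__(self, k: int) -> float:
        return self.values[k]


def ev_curve(params: RoundParams) -> EVCurve:
    """Exact EV(k) for k = 0..N with the exact argmax set."""
    exact = [_expected_score_exact(params, k) for k in range(params.n_total_cards + 1)]
    best = max(exact)
    argmax = tuple(k for k, v in enumerate(exact) if v == best)
    return EVCurve(params, tuple(float(v) for v in exact), argmax)


def optimal_reveal(
    params: RoundParams, tie_break: str = "all"
) -> int | tuple[int, ...]:
    """EV-maximizing reveal count(s).

    Exact ties do occur in the standard parameter grid (e.g. {6, 7} at
    g=10, l=250, m=1); ``tie_break`` selects ``smallest``, ``largest``, the
    full ``all`` set, or ``published`` — the convention of the canonical
    printed optimum table for the standard 2x2x2 parameters, which reports
    the larger maximizer for (g=10, l=250, m=1) and the smaller one
    elsewhere.
    """
    argmax = ev_curve(params).argmax_set
    if tie_break == "all":
        return argmax
    if tie_break == "smallest":
        return argmax[0]
    if tie_break == "largest":
        return argmax[-1]
    if tie_break == "published":
        key = (params.gain_amount, params.loss_amount, params.n_loss_cards)
        return argmax[-1] if key == (10, 250, 1) else argmax[0]
    raise ValueError(f"unknown tie_break {tie_break!r}")


def deviation_score(
    observed_mean_cards: float, params: RoundParams, tie_break: str = "published"
) -> float:
    """Observed mean reveal count minus the optimal count (+ = over-revealing)."""
    if not 0 <= observed_mean_cards <= params.n_total_cards:
        raise ValueError("observed mean must lie within [0, deck size]")
    return observed_mean_cards - optimal_reveal(params, tie_break)


def recovery_cards(loss_amount: int, gain_amount: int) -> int:
    """Gain cards needed to recoup one loss penalty: ceil(l / g)."""
    if gain_amount <= 0:
        raise ValueError("gain_amount must be > 0")
    if loss_amount < 0:
        raise ValueError("loss_amount must be >= 0")
    return math.ceil(loss_amount / gain_amount)


def _expected_floored_score_exact(params: RoundParams, k: int) -> Fraction:
    """E[max(score, 0)] for a committed count ``k`` (exact)."""
    g, l = params.gain_amount, params.loss_amount
    dist = first_loss_pmf(params.n_total_cards, params.n_loss_cards, k)
    ev = max(g * k, 0) * dist.p_no_loss
    for j, pj in enumerate(dist.pmf, start=1):
        ev += max(g * (j - 1) - l, 0) * pj
    return ev


def expected_bonus(
    design: list[DesignRow],
    counts,
    floor_mode: str = "total",
    n_sims: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Expected dollar bonus of a deterministic count-per-round policy.

    ``counts`` maps a :class:`RoundParams` (or ``(g, l, m)`` tuple) to the
    committed reveal count, or is a callable ``params -> k``. The bonus rule
    pays $1 per 100 points. Three quantities are reported:

    * ``raw`` — sum of per-round EVs / 100, no floor (diagnostic);
    * ``per_round`` — exact sum of E[max(round score, 0)] / 100, i.e. the
      floor applied round-wise;
    * ``total`` — Monte-Carlo estimate of E[max(session total, 0)] / 100
      (the stated rule), with its standard error (``total_se``) —
      only computed when ``floor_mode == 'total'``.
    """

    def k_for(params: RoundParams) -> int:
        if callable(counts):
            return int(counts(params))
        key = (params.gain_amount, params.loss_amount, params.n_loss_cards)
        if params in counts:
            return int(counts[params])
        return int(counts[key])

    scored = [row for row in design if row.scored]
    raw = sum(_expected_score_exact(r.params, k_for(r.params)) for r in scored)
    per_round = sum(_expected_floored_score_exact(r.params, k_for(r.params)) for r in scored)
    out = {"raw": float(raw) / 100.0, "per_round": float(per_round) / 100.0}

    if floor_mode == "per_round":
        return out
    if floor_mode != "total":
        raise ValueError(f"unknown floor_mode {floor_mode!r}")

    rng = np.random.default_rng(0) if rng is None else rng
    totals = np.zeros(n_sims)
    for row in scored:
        p = row.params
        k = k_for(p)
        dist = first_loss_pmf(p.n_total_cards, p.n_loss_cards, k)
        # outcome index 0 = no loss; j = first loss at draw j
        probs = np.array([float(dist.p_no_loss)] + [float(x) for x in dist.pmf])
        scores = np.array(
            [p.gain_amount * k]
            + [p.gain_amount * (j - 1) - p.loss_amount for j in range(1, k + 1)],
            dtype=float,
        )
        draws = rng.choice(len(probs), size=n_sims, p=probs / probs.sum())
        totals += scores[draws]
    floored = np.maximum(totals, 0.0) / 100.0
    out["total"] = float(floored.mean())
    out["total_se"] = float(floored.std(ddof=1) / math.sqrt(n_sims))
    return out
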