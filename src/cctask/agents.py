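"""Synthetic CCT players whose generative structure mirrors the fitted model.

Each agent's intended reveal count for a round is a rounded, clamped draw
from the same linear mixed model the censored regression estimates:

    y* = grand_mean + sum(fixed effects) + b_i0 + z' b_i + N(0, residual_sd)
    intended = clip(round(y*), 0, N)

with per-participant random effects ``b_i`` (intercept + sum-to-zero coded
slopes for the within-subject factors) drawn from a multivariate normal.
Because the response the model fits is continuous while agents emit integer
counts, rounding and boundary clamping are part of any recovery-error
budget.

Toasty continuation behavior is a descriptive batching device (not a
cognitive model): a round is a single committed batch with probability
``p_single_request``; otherwise an initial fraction of the target is
committed and subsequent batches shrink geometrically, reproducing the
empirical pattern of per-request reveal counts declining toward one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .design import (
    DesignRow,
    DesignSpec,
    PlacementScheme,
    RoundParams,
    generate_design,
    place_loss_cards,
)
from .engine import (
    FixedCountPolicy,
    RoundTranscript,
    SessionRecord,
    play_round,
    score_session,
)
from .strategy import optimal_reveal

__all__ = [
    "PopulationParams",
    "PolicyParams",
    "AgentParams",
    "make_population",
    "intended_count",
    "toasty_batch_plan",
    "simulate_experiment",
    "sessions_to_frame",
    "study_scale_population",
]


@dataclass(frozen=True)
class PopulationParams:
    """Generative population: grand mean, fixed effects, random-effect scales.

    ``fixed_effects`` maps factor name -> {level: deviation in cards}; each
    factor's deviations must sum to zero. ``random_slope_sds`` maps a
    within-subject factor to the sd shared by that factor's coded slope
    columns. ``random_correlations`` is either a scalar (exchangeable
    correlation among all random effects) or a full correlation matrix over
    [intercept, slope columns...].
    """

    grand_mean: float
    fixed_effects: Mapping[str, Mapping] = field(default_factory=dict)
    random_intercept_sd: float = 0.0
    random_slope_sds: Mapping[str, float] = field(default_factory=dict)
    random_correlations: float | np.ndarray = 0.0
    residual_sd: float = 0.0
    n_participants: int = 100
    n_total_cards: int = 32

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for f, sd in self.random_slope_sds.items():
            if sd < 0:
                raise ValueError(f"negative slope sd for factor {f!r}")
        for f, effects in self.fixed_effects.items():
            total = sum(effects.values())
            if abs(total) > 1e-8:
                raise ValueError(
                    f"effects of factor {f!r} must sum to zero (sum = {total})"
                )

    def slope_columns(self) -> list[tuple[str, object]]:
        """(factor, explicit level) pairs carrying a random slope."""
        cols = []
        for f in self.random_slope_sds:
            levels = self._levels(f)
            cols.extend((f, lev) for lev in levels[1:])
        return cols

    def _levels(self, factor: str) -> list:
        if factor in self.fixed_effects:
            return list(self.fixed_effects[factor])
        raise ValueError(
            f"random slope for factor {factor!r} needs its levels; list the "
            "factor in fixed_effects (possibly with all-zero deviations)"
        )


@dataclass(frozen=True)
class PolicyParams:
    """Descriptive policy knobs (Toasty batching and policy style)."""

    style: str = "target_count"  # target_count | myopic_ev
    p_single_request: float = 0.77
    initial_fraction: float = 0.7
    continuation_decay: float = 0.5
    stop_noise: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_single_request <= 1:
            raise ValueError("p_single_request must lie in [0, 1]")
        if not 0 < self.initial_fraction <= 1:
            raise ValueError("initial_fraction must lie in (0, 1]")
        if not 0 < self.continuation_decay <= 1:
            raise ValueError("continuation_decay must lie in (0, 1]")
        if not 0 <= self.stop_noise <= 1:
            raise ValueError("stop_noise must lie in [0, 1]")
        if self.style not in ("target_count", "myopic_ev"):
            raise ValueError(f"unknown policy style {self.style!r}")


@dataclass(frozen=True)
class AgentParams:
    """One simulated participant: intercept and slope deviations (cards)."""

    participant_id: str
    intercept: float
    slopes: Mapping[tuple[str, object], float] = field(default_factory=dict)


def _random_effect_cov(pop: PopulationParams) -> np.ndarray:
    cols = pop.slope_columns()
    sds = [pop.random_intercept_sd] + [pop.random_slope_sds[f] for f, _ in cols]
    sds = np.asarray(sds, dtype=float)
    q = len(sds)
    if np.isscalar(pop.random_correlations) or np.ndim(pop.random_correlations) == 0:
        rho = float(pop.random_correlations)
        R = np.full((q, q), rho)
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(pop.random_correlations, dtype=float)
        if R.shape != (q, q):
            raise ValueError(f"correlation matrix must be {q}x{q}, got {R.shape}")
    cov = np.outer(sds, sds) * R
    # PSD check (zero sds legitimately give a singular covariance)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-10:
        raise ValueError("random-effect correlation structure is not positive semi-definite")
    return cov


def make_population(pop: PopulationParams, seed: int) -> list[AgentParams]:
    """Draw ``n_participants`` agents' random effects from the population."""
    rng = np.random.default_rng(seed)
    cov = _random_effect_cov(pop)
    cols = pop.slope_columns()
    draws = rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=pop.n_participants,
                                    method="svd")
    agents = []
    for i in range(pop.n_participants):
        agents.append(
            AgentParams(
                participant_id=f"P{i + 1:04d}",
                intercept=float(draws[i, 0]),
                slopes={col: float(v) for col, v in zip(cols, draws[i, 1:])},
            )
        )
    return agents


def intended_count(
    agent: AgentParams,
    pop: PopulationParams,
    factors: Mapping,
    rng: np.random.Generator,
) -> int:
    """Latent linear predictor -> rounded count clamped to [0, N]."""
    mu = pop.grand_mean + agent.intercept
    for f, effects in pop.fixed_effects.items():
        if f not in factors:
            raise ValueError(f"round factors are missing {f!r}")
        level = factors[f]
        if level not in effects:
            raise ValueError(f"unknown level {level!r} for factor {f!r}")
        mu += effects[level]
    for (f, col_level), b in agent.slopes.items():
        levels = pop._levels(f)
        level = factors[f]
        if level == levels[0]:
            mu -= b
        elif level == col_level:
            mu += b
    if pop.residual_sd > 0:
        mu += rng.normal(0.0, pop.residual_sd)
    return int(np.clip(round(mu), 0, pop.n_total_cards))


def toasty_batch_plan(
    target: int, policy: PolicyParams, rng: np.random.Generator
) -> list[int]:
    """Split a target count into committed Toasty batches.

    With probability ``p_single_request`` the whole target is one batch.
    Otherwise the first batch commits ``initial_fraction`` of the target and
    later batches shrink by ``continuation_decay`` (never below one card)
    until the target is reached or a ``stop_noise`` coin ends the round.
    """
    if target <= 0:
        return []
    if rng.uniform() < policy.p_single_request:
        return [int(target)]
    first = max(1, round(policy.initial_fraction * target))
    plan = [min(first, target)]
    size = float(first)
    while sum(plan) < target:
        if policy.stop_noise > 0 and rng.uniform() < policy.stop_noise:
            break
        size = max(1.0, size * policy.continuation_decay)
        plan.append(min(int(round(size)), target - sum(plan)))
    return plan


def simulate_experiment(
    design: list[DesignRow],
    version: str,
    pop: PopulationParams,
    policy: PolicyParams,
    scheme: PlacementScheme,
    seed: int,
    incentivized: bool = True,
    censor_at: str = "committed",
    participant_prefix: str = "P",
) -> list[SessionRecord]:
    """Play every agent through the design under one CCT version.

    The master seed spawns independent named streams for population draws,
    loss-card placement, and policy noise, so each component is
    independently reproducible.
    """
    ss = np.random.SeedSequence(seed)
    pop_ss, place_ss, pol_ss = ss.spawn(3)
    agents = make_population(pop, pop_ss)
    place_rng = np.random.default_rng(place_ss)
    pol_rng = np.random.default_rng(pol_ss)

    sessions = []
    for agent in agents:
        transcripts: list[RoundTranscript] = []
        for row in design:
            params = row.params
            layout = place_loss_cards(
                params, scheme, place_rng, rigged=not row.scored
            )
            if policy.style == "myopic_ev":
                target = int(optimal_reveal(params, tie_break="smallest"))
            else:
                factors = {
                    "version": version,
                    "incentive": incentivized,
                    "gain": params.gain_amount,
                    "loss": params.loss_amount,
                    "n_loss_cards": params.n_loss_cards,
                    "block": row.block if row.block > 0 else 1,
                }
                target = intended_count(agent, pop, factors, pol_rng)
            if version == "toasty":
                plan = toasty_batch_plan(target, policy, pol_rng)
                p = FixedCountPolicy(sum(plan), batch_sizes=plan or None)
            else:
                p = FixedCountPolicy(target)
            transcripts.append(
                play_round(version, params, layout, p, pol_rng, censor_at=censor_at)
            )
        pid = participant_prefix + agent.participant_id[1:]
        sessions.append(score_session(pid, version, incentivized, transcripts))
    return sessions


def sessions_to_frame(
    sessions: list[SessionRecord], design: list[DesignRow] | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Long-format trial table (one row per played round)."""
    rows = []
    for s in sessions:
        for i, t in enumerate(s.transcripts):
            row_index = design[i].round_index if design else i + 1
            block = design[i].block if design else 1
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "version": s.version,
                    "incentive": s.incentivized,
                    "round_index": row_index,
                    "block": block,
                    "gain": t.params.gain_amount,
                    "loss": t.params.loss_amount,
                    "n_loss_cards": t.params.n_loss_cards,
                    "scored": t.scored,
                    "cards_revealed": t.cards_revealed,
                    "intended_count": t.intended_count,
                    "censored": t.censored,
                    "loss_revealed": t.loss_revealed,
                    "n_feedback_requests": t.n_feedback_requests,
                    "batch_sizes": ";".join(str(b) for b in t.batch_sizes),
                    "round_score": t.score,
                    "seed": seed if seed is not None else -1,
                }
            )
    return pd.DataFrame(rows)


def simulate_recovery_dataset(
    n_participants: int, seed: int, pop: PopulationParams | None = None
) -> pd.DataFrame:
    """Hot-version trial table for parameter-recovery studies.

    Half the participants are incentivized, half not; loss cards are placed
    randomly, so roughly half the rounds are right-censored. The generating
    population is :func:`recovery_population` unless overridden.
    """
    base = recovery_population(n_participants) if pop is None else pop
    design = generate_design(DesignSpec(seed=seed))
    scheme = PlacementScheme("random")
    half = base.n_participants // 2
    sessions = simulate_experiment(
        design, "hot", replace(base, n_participants=half), PolicyParams(),
        scheme, seed=seed + 1, incentivized=True, participant_prefix="I",
    ) + simulate_experiment(
        design, "hot", replace(base, n_participants=base.n_participants - half),
        PolicyParams(), scheme, seed=seed + 2, incentivized=False,
        participant_prefix="N",
    )
    return sessions_to_frame(sessions, design, seed=seed)


def recovery_population(n_participants: int = 100, **overrides) -> PopulationParams:
    """Generating parameters for parameter-recovery studies.

    Fixed effects at the scale of the published regression table, with
    random-effect and residual scales kept modest so that the rounding and
    boundary clamping of agent counts stay a negligible part of the
    recovery error budget.
    """
    defaults = dict(
        grand_mean=11.0,
        fixed_effects={
            "incentive": {True: 0.16, False: -0.16},
            "gain": {10: -1.24, 30: 1.24},
            "loss": {250: 1.19, 750: -1.19},
            "n_loss_cards": {1: 2.51, 3: -2.51},
            "block": {1: 0.43, 2: -0.26, 3: -0.17},
        },
        random_intercept_sd=2.0,
        random_slope_sds={"gain": 0.4, "loss": 0.4, "n_loss_cards": 0.4, "block": 0.3},
        random_correlations=0.0,
        residual_sd=2.5,
        n_participants=n_participants,
    )
    defaults.update(overrides)
    return PopulationParams(**defaults)


def study_scale_population(n_participants: int = 100, **overrides) -> PopulationParams:
    """Population at the scale of the published human study.

    Grand mean ~10.7 cards, residual variance ~26.7, intercept variance
    ~46.9, and fixed effects matching the published regression table
    (version and incentive effects included so a single population serves
    all four versions). These values make synthetic data resemble the
    study's scale without claiming to replicate its participants.
    """
    defaults = dict(
        grand_mean=10.69,
        fixed_effects={
            "version": {"cold": 2.98, "hot": -0.98, "toasty": -0.36, "warm": -1.64},
            "incentive": {True: 0.16, False: -0.16},
            "gain": {10: -1.24, 30: 1.24},
            "loss": {250: 1.19, 750: -1.19},
            "n_loss_cards": {1: 2.51, 3: -2.51},
            "block": {1: 0.43, 2: -0.26, 3: -0.17},
        },
        random_intercept_sd=6.85,
        random_slope_sds={"gain": 0.5, "loss": 0.5, "n_loss_cards": 0.5, "block": 0.5},
        random_correlations=0.0,
        residual_sd=5.17,
        n_participants=n_participants,
    )
    defaults.update(overrides)
    return PopulationParams(**defaults)
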