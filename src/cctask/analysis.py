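"""Descriptive summaries of trial-level CCT data (real or simulated).

These tables mirror the standard reporting surfaces of a version-comparison
study: total scores, loss-card counts, deviations from the EV-optimal reveal
count, and a profile of Toasty feedback-request behavior. Inferential tests
on them (ANOVA, pairwise t tests, Fisher's exact) are deliberately left to
standard statistical routines; the tables emitted here are tidy inputs for
them. All summaries are invariant to row order and participant relabeling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .design import RoundParams
from .strategy import deviation_score

__all__ = [
    "summarize_scores",
    "loss_card_counts",
    "toasty_profile",
    "deviation_table",
]

_GROUP = ["version", "incentive"]


def _scored(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["scored"].astype(bool)] if "scored" in trials else trials


def summarize_scores(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean total score and share of participants with a positive total.

    One row per version x incentive group; empty groups are omitted (with a
    warning upstream of pandas' own behavior).
    """
    scored = _scored(trials)
    totals = (
        scored.groupby(_GROUP + ["participant_id"], observed=True)["round_score"]
        .sum()
        .reset_index()
    )
    out = (
        totals.groupby(_GROUP, observed=True)["round_score"]
        .agg(mean_total_score="mean", pct_positive=lambda s: (s > 0).mean())
        .reset_index()
    )
    if out.empty:
        warnings.warn("no complete groups to summarize", stacklevel=2)
    return out


def loss_card_counts(trials: pd.DataFrame, conf_level: float = 0.95) -> pd.DataFrame:
    """Mean rounds (of the session) ending in a revealed loss card, per group.

    Per participant, the number of rounds with ``loss_revealed`` is counted;
    groups report the mean with a normal-approximation confidence interval
    (the interval construction is a labelled choice, not canonical).
    """
    scored = _scored(trials)
    per = (
        scored.groupby(_GROUP + ["participant_id"], observed=True)["loss_revealed"]
        .sum()
        .reset_index(name="n_loss_rounds")
    )
    z = stats.norm.ppf(0.5 + conf_level / 2)

    def _ci(s):
        m = s.mean()
        se = s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan
        return pd.Series(
            {"mean_loss_rounds": m, "ci_lower": m - z * se, "ci_upper": m + z * se}
        )

    return per.groupby(_GROUP, observed=True)["n_loss_rounds"].apply(_ci).unstack().reset_index()


def toasty_profile(trials: pd.DataFrame) -> dict:
    """Feedback-request profile of Toasty sessions.

    Returns the proportion of rounds with exactly one feedback request, the
    per-participant distribution of the maximum requests used in any round,
    and, for each request index r, the mean committed batch size across all
    rounds that made at least r requests.
    """
    if not (trials["version"] == "toasty").all():
        raise ValueError("toasty_profile expects Toasty rounds only")
    scored = _scored(trials)
    active = scored[scored["n_feedback_requests"] > 0]
    single = float((active["n_feedback_requests"] == 1).mean())

    max_requests = (
        scored.groupby("participant_id", observed=True)["n_feedback_requests"]
        .max()
        .value_counts()
        .sort_index()
        .rename_axis("max_requests")
        .reset_index(name="n_participants")
    )

    batch_lists = [
        [int(b) for b in s.split(";") if b != ""]
        for s in scored["batch_sizes"].fillna("")
    ]
    depth = max((len(b) for b in batch_lists), default=0)
    mean_by_request = []
    for r in range(depth):
        sizes = [b[r] for b in batch_lists if len(b) > r]
        mean_by_request.append(
            {"request_index": r + 1, "n_rounds": len(sizes), "mean_cards": float(np.mean(sizes))}
        )
    return {
        "single_request_proportion": single,
        "max_requests_distribution": max_requests,
        "mean_cards_by_request": pd.DataFrame(mean_by_request),
    }


def deviation_table(
    trials: pd.DataFrame, tie_break: str = "published", use_intended: bool | None = None
) -> pd.DataFrame:
    """Average deviation from the EV-optimal reveal count per group.

    For each version x incentive group, the mean reveal count of each
    parameter combination is reduced by that combination's optimal count and
    the deviations averaged over combinations (positive = over-revealing).
    By default the observed intent (``intended_count``) is used for the
    uncensorable Cold/Warm versions and the raw flip count elsewhere;
    ``use_intended`` forces one column for all rows.
    """
    scored = _scored(trials).copy()
    if use_intended is None:
        obs = np.where(
            scored["version"].isin(["cold", "warm"]),
            scored["intended_count"],
            scored["cards_revealed"],
        )
    else:
        col = "intended_count" if use_intended else "cards_revealed"
        obs = scored[col].to_numpy()
    scored["observed"] = obs
    n_total = int(scored.get("n_total_cards", pd.Series([32] * len(scored))).iloc[0]) \
        if "n_total_cards" in scored else 32

    cell = (
        scored.groupby(_GROUP + ["gain", "loss", "n_loss_cards"], observed=True)["observed"]
        .mean()
        .reset_index()
    )
    cell["deviation"] = [
        deviation_score(
            row.observed,
            RoundParams(int(row.gain), int(row.loss), int(row.n_loss_cards), n_total),
            tie_break=tie_break,
        )
        for row in cell.itertuples(index=False)
    ]
    return (
        cell.groupby(_GROUP, observed=True)["deviation"]
        .mean()
        .reset_index(name="mean_deviation")
    )
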