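"""Trial-table I/O, schema validation, fixtures, seeds, and run manifests.

The interchange format is a long-format CSV, one row per played round:
UTF-8, comma-separated, header row, "." decimal, floats at full precision.
``batch_sizes`` is a semicolon-joined list (empty for rounds with no
committed batch). Validation enforces the structural invariants of the
task: censoring only in Toasty/Hot, request counts consistent with batch
lists, reveal counts within the committed total.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import (
    PolicyParams,
    study_scale_population,
    recovery_population,
    sessions_to_frame,
    simulate_experiment,
    simulate_recovery_dataset,
)
from .design import DesignSpec, PlacementScheme, generate_design

__all__ = [
    "TRIAL_COLUMNS",
    "SchemaError",
    "read_trials",
    "write_trials",
    "validate_trials",
    "make_fixtures",
    "seed_streams",
    "write_manifest",
    "get_logger",
]

logger = logging.getLogger("cctask")

TRIAL_COLUMNS = [
    "participant_id",
    "version",
    "incentive",
    "round_index",
    "block",
    "gain",
    "loss",
    "n_loss_cards",
    "scored",
    "cards_revealed",
    "intended_count",
    "censored",
    "loss_revealed",
    "n_feedback_requests",
    "batch_sizes",
    "round_score",
    "seed",
]

_BOOL_COLUMNS = ["incentive", "scored", "censored", "loss_revealed"]


class SchemaError(ValueError):
    """Trial table violates the schema; carries row-level messages."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "\n".join(problems[:20])
        more = "" if len(problems) <= 20 else f"\n... and {len(problems) - 20} more"
        super().__init__(f"trial table failed validation:\n{preview}{more}")


def get_logger() -> logging.Logger:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def _parse_batches(value) -> list[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return []
    return [int(b) for b in str(value).split(";")]


def validate_trials(trials: pd.DataFrame) -> list[str]:
    """Return row-level violation messages (empty list = valid)."""
    problems = []
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        return [f"missing columns: {missing}"]
    for idx, row in trials.iterrows():
        where = f"row {idx}"
        version = row["version"]
        if version not in ("cold", "warm", "toasty", "hot"):
            problems.append(f"{where}: unknown version {version!r}")
            continue
        batches = _parse_batches(row["batch_sizes"])
        if bool(row["censored"]) and version not in ("toasty", "hot"):
            problems.append(f"{where}: censored=True is impossible in the {version} version")
        if bool(row["censored"]) and not bool(row["loss_revealed"]):
            problems.append(f"{where}: censored requires a revealed loss card")
        if version == "cold":
            if int(row["n_feedback_requests"]) != 0:
                problems.append(f"{where}: cold rounds provide no per-round feedback")
            if len(batches) > 1:
                problems.append(f"{where}: cold rounds have a single implicit batch")
        else:
            if len(batches) != int(row["n_feedback_requests"]):
                problems.append(
                    f"{where}: {len(batches)} batch sizes but "
                    f"n_feedback_requests={int(row['n_feedback_requests'])}"
                )
        if batches and int(row["cards_revealed"]) > sum(batches):
            problems.append(f"{where}: cards_revealed exceeds the committed total")
        if int(row["cards_revealed"]) < 0 or int(row["intended_count"]) < 0:
            problems.append(f"{where}: negative counts")
    return problems


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a validated trial table as CSV."""
    problems = validate_trials(trials)
    if problems:
        raise SchemaError(problems)
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV (lossless round-trip with write_trials)."""
    trials = pd.read_csv(path, keep_default_na=False, na_values=[])
    for col in _BOOL_COLUMNS:
        if trials[col].dtype == object:
            trials[col] = trials[col].map({"True": True, "False": False})
        trials[col] = trials[col].astype(bool)
    trials["batch_sizes"] = trials["batch_sizes"].astype(str)
    problems = validate_trials(trials)
    if problems:
        raise SchemaError(problems)
    return trials


def seed_streams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Spawn independent named RNG streams from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def write_manifest(path, **entries) -> None:
    """Machine-readable run manifest placed next to an output file."""
    import cctask

    manifest = {"package": "cctask", "version": cctask.__version__, **entries}
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_PROFILES = ("recovery_small", "study_scale_toasty")


def make_fixtures(profile: str, seed: int, out_dir=None) -> dict:
    """Deterministic bundled datasets for testing and demos.

    ``recovery_small`` — 50 Hot-version agents x 24 rounds with known,
    recorded generating parameters (for parameter-recovery checks).
    ``study_scale_toasty`` — a Toasty dataset whose batching matches the
    published single-request proportion (~0.77).
    """
    if profile not in FIXTURE_PROFILES:
        raise ValueError(f"unknown fixture profile {profile!r}; choose from {FIXTURE_PROFILES}")

    design = generate_design(DesignSpec(seed=seed))
    scheme = PlacementScheme("random")
    if profile == "recovery_small":
        pop = recovery_population(n_participants=50)
        trials = simulate_recovery_dataset(pop.n_participants, seed, pop=pop)
        truth = {
            "grand_mean": pop.grand_mean,
            "fixed_effects": {k: {str(l): v for l, v in d.items()}
                              for k, d in pop.fixed_effects.items()},
            "random_intercept_sd": pop.random_intercept_sd,
            "residual_sd": pop.residual_sd,
        }
        out = {"trials": trials, "truth": truth, "population": pop, "design": design}
    else:
        pop = study_scale_population(n_participants=50)
        policy = PolicyParams(p_single_request=0.77)
        sessions = simulate_experiment(
            design, "toasty", pop, policy, scheme, seed=seed + 1
        )
        trials = sessions_to_frame(sessions, design, seed=seed)
        out = {"trials": trials, "population": pop, "design": design}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        trial_path = out_dir / f"{profile}.csv"
        write_trials(out["trials"], trial_path)
        if "truth" in out:
            (out_dir / f"{profile}_truth.json").write_text(json.dumps(out["truth"], indent=2))
        write_manifest(trial_path, profile=profile, seed=seed)
        out["path"] = trial_path
    return out
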