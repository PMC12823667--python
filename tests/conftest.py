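import warnings

import numpy as np
import pytest

import cctask.censored_model as cm
from cctask.agents import simulate_recovery_dataset

# generating fixed effects of the recovery population (sum-to-zero scale)
RECOVERY_TRUTH = {
    "intercept": 11.0,
    "incentive[False]": -0.16,
    "gain[30]": 1.24,
    "loss[750]": -1.19,
    "n_loss_cards[3]": -2.51,
    "block[2]": -0.26,
    "block[3]": -0.17,
}

RECOVERY_BASE_SEED = 20260923
N_REPLICATES = 20


@pytest.fixture(scope="session")
def recovery_study():
    """20 replicate simulate-and-fit runs of the recovery study.

    Each replicate simulates 100 Hot-version agents x 24 rounds (half the
    rounds right-censored by randomly placed loss cards), fits the censored
    multilevel model with the test sampler profile, and records interval
    coverage of every generating fixed effect plus the three grand-mean
    estimators.
    """
    coverage = {k: 0 for k in RECOVERY_TRUTH}
    estimates = []
    for rep in range(N_REPLICATES):
        trials = simulate_recovery_dataset(100, RECOVERY_BASE_SEED + 1000 * rep)
        spec = cm.default_model_spec(trials).with_sampler(
            chains=2, iterations=1500, warmup=750, seed=RECOVERY_BASE_SEED + rep
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = cm.fit(trials, spec)
            est = cm.compare_estimators(
                trials,
                sampler=dict(
                    chains=2, iterations=800, warmup=400,
                    seed=RECOVERY_BASE_SEED + rep,
                ),
            )
        for name, truth in RECOVERY_TRUTH.items():
            row = result.coef.loc[name]
            coverage[name] += int(row["ci_lower"] <= truth <= row["ci_upper"])
        estimates.append(est)
    return {"coverage": coverage, "estimates": estimates}
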