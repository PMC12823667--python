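import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cctask.censored_model as cm
from cctask.agents import (
    PolicyParams,
    recovery_population,
    sessions_to_frame,
    simulate_experiment,
)
from cctask.design import DesignSpec, PlacementScheme, generate_design

QUIET = dict(chains=2, iterations=800, warmup=400)


def warm_dataset(n_participants=40, seed=9):
    """Uncensored (Warm-version) data from the recovery population."""
    design = generate_design(DesignSpec(seed=3))
    pop = recovery_population(n_participants)
    sessions = simulate_experiment(design, "warm", pop, PolicyParams(),
                                   PlacementScheme("random"), seed=seed)
    return sessions_to_frame(sessions, design, seed=seed)


def quiet_fit(data, spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cm.fit(data, spec)


class TestSumToZeroCoding:
    def test_columns_and_implied_level(self):
        cols, codes = cm.encode_sum_to_zero("version", ["cold", "hot", "toasty", "warm"])
        assert cols == ["version[hot]", "version[toasty]", "version[warm]"]
        assert np.array_equal(codes["cold"], [-1, -1, -1])
        assert np.array_equal(codes["hot"], [1, 0, 0])
        # the implied (reference) effect is minus the sum of the explicit ones
        assert cm.implied_reference_effect([-0.98, -0.36, -1.64]) == pytest.approx(2.98)

    def test_two_level_antisymmetry(self):
        _, codes = cm.encode_sum_to_zero("gain", [10, 30])
        assert codes[30] == pytest.approx([1.0])
        assert codes[10] == pytest.approx([-1.0])

    def test_level_average_of_codes_is_zero(self):
        # averaging the linear predictor over a factor's levels removes that
        # factor's contribution: the mean code vector is exactly zero
        for levels in (["a", "b"], ["a", "b", "c"], list(range(5))):
            _, codes = cm.encode_sum_to_zero("f", levels)
            assert np.mean(list(codes.values()), axis=0) == pytest.approx(
                np.zeros(len(levels) - 1)
            )

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            cm.encode_sum_to_zero("f", ["only"])

    def test_prediction_invariant_to_reference_choice(self):
        # the same cell means expressed in two codings give identical
        # predictions for every cell
        rng = np.random.default_rng(0)
        levels = ["a", "b", "c"]
        cell_means = dict(zip(levels, rng.normal(size=3)))
        for order in (levels, ["b", "c", "a"]):
            _, codes = cm.encode_sum_to_zero("f", order)
            Xc = np.array([codes[l] for l in order])
            target = np.array([cell_means[l] for l in order])
            mu = target.mean()
            beta = np.linalg.lstsq(Xc, target - mu, rcond=None)[0]
            pred = {l: mu + codes[l] @ beta for l in levels}
            for l in levels:
                assert pred[l] == pytest.approx(cell_means[l])


class TestCensoredLoglik:
    def test_reduces_to_gaussian_without_censoring(self):
        rng = np.random.default_rng(1)
        y = rng.normal(2.0, 1.5, size=50)
        mu = rng.normal(2.0, 0.5, size=50)
        ll = cm.censored_loglik(y, np.zeros(50, bool), mu, 1.5)
        assert ll == pytest.approx(stats.norm.logpdf(y, mu, 1.5))

    def test_censored_at_the_mean_is_log_half(self):
        ll = cm.censored_loglik([5.0], [True], [5.0], 2.0)
        assert ll[0] == pytest.approx(np.log(0.5))

    def test_deep_tail_censoring_is_nearly_free(self):
        ll = cm.censored_loglik([0.0], [True], [10.0], 1.0)  # bound 10 sd below mu
        assert ll[0] == pytest.approx(0.0, abs=1e-20)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            cm.censored_loglik([1.0], [False], [0.0], 0.0)


class TestFit:
    def test_matches_mixed_model_oracle_on_uncensored_data(self):
        """Posterior means agree with REML mixed-model estimates (an
        independent route) within a fraction of a posterior sd."""
        import statsmodels.formula.api as smf

        trials = warm_dataset()
        assert not trials["censored"].any()
        spec = cm.default_model_spec(trials).with_sampler(seed=2, **QUIET)
        result = quiet_fit(trials, spec)

        X, names = cm.build_fixed_matrix(trials, spec)
        df = pd.DataFrame(X[:, 1:], columns=[f"c{i}" for i in range(X.shape[1] - 1)])
        df["y"] = trials["intended_count"].to_numpy()
        df["g"] = trials["participant_id"].to_numpy()
        slope_cols = [f"c{i}" for i, nm in enumerate(names[1:])
                      if not nm.startswith("incentive")]
        md = smf.mixedlm("y ~ " + " + ".join(df.columns[:-2]), df, groups=df["g"],
                         re_formula="~ " + " + ".join(slope_cols))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oracle = md.fit()
        for i, nm in enumerate(names):
            key = "Intercept" if nm == "intercept" else f"c{i - 1}"
            post = result.coef.loc[nm]
            assert abs(post["mean"] - oracle.params[key]) < 3 * post["sd"]

    def test_reports_diagnostics_for_every_parameter(self):
        trials = warm_dataset(n_participants=20)
        spec = cm.default_model_spec(trials).with_sampler(seed=4, **QUIET)
        result = quiet_fit(trials, spec)
        for frame in (result.coef, result.variance):
            assert {"mean", "sd", "ci_lower", "ci_upper", "rhat", "ess_bulk",
                    "ess_tail"} <= set(frame.columns)
            assert frame["rhat"].notna().all()
            assert (frame["ci_lower"] <= frame["ci_upper"]).all()

    def test_zero_variance_response_fails_informatively(self):
        trials = warm_dataset(n_participants=5)
        trials["intended_count"] = 7
        spec = cm.null_model_spec(trials)
        with pytest.raises(ValueError, match="zero variance"):
            cm.fit(trials, spec)

    def test_single_participant_rejected(self):
        trials = warm_dataset(n_participants=5)
        trials["participant_id"] = "P0001"
        with pytest.raises(ValueError, match="participants"):
            cm.fit(trials, cm.null_model_spec(trials))

    def test_fully_censored_data_is_flagged(self):
        trials = warm_dataset(n_participants=6)
        trials["censored"] = True
        trials["version"] = "hot"
        trials["loss_revealed"] = True
        spec = cm.null_model_spec(trials).with_sampler(
            chains=2, iterations=300, warmup=150, seed=0
        )
        result = quiet_fit(trials, spec)
        assert any("censored" in w for w in result.warnings)


def _toy_fit(beta_draws, sigma2_draws, Sigma_draws, names, Cx=None, Mz=None):
    """Assemble a FitResult directly from draw arrays (bypassing sampling)."""
    p = beta_draws.shape[-1]
    q = Sigma_draws.shape[-1]
    return cm.FitResult(
        spec=cm.ModelSpec(factors={}, fixed_terms=(),
                          response="y", chains=2, iterations=2, warmup=1),
        coef=pd.DataFrame(index=names),
        variance=pd.DataFrame(),
        draws={"beta": beta_draws, "sigma2": sigma2_draws, "Sigma": Sigma_draws},
        coef_names=names,
        ranef_names=["intercept"],
        meta={"Cx": np.eye(p) if Cx is None else Cx,
              "Mz": np.eye(q) if Mz is None else Mz},
    )


class TestDerivedQuantities:
    @pytest.mark.parametrize("tau, sig, expected", [(0.0, 50.0, 0.0),
                                                    (26.0, 74.0, 0.26),
                                                    (33.3, 33.3, 0.5)])
    def test_icc_formula(self, tau, sig, expected):
        draws = _toy_fit(
            beta_draws=np.zeros((2, 10, 1)),
            sigma2_draws=np.full((2, 10), sig),
            Sigma_draws=np.full((2, 10, 1, 1), tau),
            names=["intercept"],
        )
        assert cm.icc(draws) == pytest.approx(expected)

    def test_r2_trivial_cases(self):
        # no fixed effects -> marginal 0; no random variance -> marginal == conditional
        zero_beta = _toy_fit(np.zeros((2, 5, 2)), np.full((2, 5), 4.0),
                             np.full((2, 5, 1, 1), 1.0), ["intercept", "x"],
                             Cx=np.diag([0.0, 1.0]))
        marg, cond = cm.r2_decomposition(zero_beta)
        assert marg == 0.0
        no_ranef = _toy_fit(np.full((2, 5, 2), 1.0), np.full((2, 5), 4.0),
                            np.zeros((2, 5, 1, 1)), ["intercept", "x"],
                            Cx=np.diag([0.0, 2.0]))
        marg, cond = cm.r2_decomposition(no_ranef)
        assert marg == pytest.approx(cond)
        assert marg == pytest.approx(2.0 / 6.0)

    def test_emm_balanced_averaging_identity(self):
        trials = warm_dataset(n_participants=15)
        spec = cm.default_model_spec(trials).with_sampler(
            chains=2, iterations=400, warmup=200, seed=1
        )
        result = quiet_fit(trials, spec)
        table = cm.emm(result, ["gain"])
        full = cm.emm(result, ["gain", "loss"])
        for level in (10, 30):
            marginal = table.loc[table["gain"] == level, "emm"].item()
            cells = full.loc[full["gain"] == level, "emm"]
            assert marginal == pytest.approx(cells.mean(), abs=1e-9)
        # grid shape: one row per requested cell
        both = cm.emm(result, ["gain", "n_loss_cards"])
        assert len(both) == 4

    def test_emm_unknown_factor_rejected(self):
        trials = warm_dataset(n_participants=10)
        spec = cm.default_model_spec(trials).with_sampler(
            chains=2, iterations=300, warmup=150, seed=1
        )
        result = quiet_fit(trials, spec)
        with pytest.raises(ValueError):
            cm.emm(result, ["version"])  # single-version data has no version term


class TestCompareEstimators:
    def test_agreement_without_censoring(self):
        trials = warm_dataset(n_participants=25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = cm.compare_estimators(
                trials, response="intended_count",
                sampler=dict(seed=0, **QUIET),
            )
        # no losses were revealed before intent, so exclusion changes little,
        # and the model's grand mean tracks the raw mean
        assert est["censored_model"] == pytest.approx(est["raw"], abs=0.5)

    def test_exclusion_selects_against_high_counts(self):
        from cctask.agents import simulate_recovery_dataset

        trials = simulate_recovery_dataset(40, seed=17)
        kept = trials.loc[~trials["loss_revealed"].astype(bool), "cards_revealed"]
        # rounds that survive without a loss over-sample short intents, so the
        # surviving-rounds mean sits below the generating grand mean (11)
        true_mean = 11.0
        assert kept.mean() < true_mean
        # and the fully raw mean is attenuated even further
        assert trials["cards_revealed"].mean() < kept.mean()
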