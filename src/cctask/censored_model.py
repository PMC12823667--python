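"""Right-censored multilevel Gaussian regression for cards-revealed data.

The number of cards a player reveals in a round is modelled as

    y*_ij = x_ij' beta + z_ij' b_i + eps_ij,   eps_ij ~ N(0, sigma^2)
    b_i ~ MVN(0, Sigma)     (random intercept + within-subject slopes,
                             fully correlated)

where ``i`` indexes participants and ``j`` rounds. In the Hot and Toasty
versions a revealed loss card ends the round before the player could stop,
so the observed count is only a lower bound on intent: those rows enter the
likelihood through the normal upper-tail probability (right-censoring).

All categorical predictors are sum-to-zero coded: each factor's first level
is the reference whose implied effect is the negative sum of the explicit
coefficients, so the intercept is the grand mean across conditions and each
coefficient is a deviation from it.

Inference is by a fully conjugate data-augmentation Gibbs sampler:

* censored responses are imputed from truncated normals,
* ``beta`` and the ``b_i`` have conjugate normal updates,
* ``sigma`` and ``Sigma`` use parameter-expanded (Huang-Wand) inverse-gamma /
  inverse-Wishart updates, which induce weakly-informative half-t priors on
  every standard deviation and a marginally uniform prior on each
  correlation.

Convergence is summarized by split-R-hat and bulk/tail effective sample
sizes (via arviz) for every reported parameter.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "encode_sum_to_zero",
    "sum_to_zero_row",
    "implied_reference_effect",
    "censored_loglik",
    "fit",
    "emm",
    "icc",
    "r2_decomposition",
    "compare_estimators",
]


# ---------------------------------------------------------------------------
# sum-to-zero coding

def encode_sum_to_zero(factor: str, levels: Sequence) -> tuple[list[str], dict]:
    """Sum-to-zero (deviation) coding for a categorical factor.

    The first level is the reference: it is coded -1 on every column and its
    implied effect is ``-sum(explicit coefficients)``. Levels ``2..L`` each
    get one indicator column named ``"factor[level]"``.

    Returns ``(column_names, codes)`` where ``codes[level]`` is the length
    ``L-1`` code vector for that level.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels, got {levels}")
    if len(set(levels)) != len(levels):
        raise ValueError(f"factor {factor!r} has duplicate levels")
    columns = [f"{factor}[{lev}]" for lev in levels[1:]]
    codes = {}
    for i, lev in enumerate(levels):
        if i == 0:
            codes[lev] = -np.ones(len(columns))
        else:
            v = np.zeros(len(columns))
            v[i - 1] = 1.0
            codes[lev] = v
    return columns, codes


def sum_to_zero_row(value, factor: str, levels: Sequence) -> np.ndarray:
    """Code a single observed level (convenience wrapper)."""
    _, codes = encode_sum_to_zero(factor, levels)
    try:
        return codes[value]
    except KeyError:
        raise ValueError(f"unknown level {value!r} for factor {factor!r}") from None


def implied_reference_effect(explicit_effects: Sequence[float]) -> float:
    """Effect of the omitted (reference) level: -sum of the explicit ones."""
    return -float(np.sum(explicit_effects))


# ---------------------------------------------------------------------------
# model specification

def _version_interactions(fixed_terms: Sequence[str]) -> tuple[tuple[str, str], ...]:
    return tuple(("version", t) for t in fixed_terms if t != "version")


@dataclass(frozen=True)
class ModelSpec:
    """Model formula, coding, priors, and sampler settings.

    ``factors`` maps each factor name (a column of the trial table) to its
    ordered level tuple; the first level of each is the sum-to-zero
    reference. ``random_slopes`` lists the within-subject factors that get
    per-participant slopes (plus the always-present random intercept), all
    correlations estimated.
    """

    factors: Mapping[str, tuple]
    fixed_terms: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    random_slopes: tuple[str, ...] = ()
    response: str = "intended_count"
    censor_col: str = "censored"
    participant_col: str = "participant_id"
    coef_prior_scale: float = 10.0
    sd_prior_scale: float = 10.0
    chains: int = 4
    iterations: int = 8000
    warmup: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        for f, levels in self.factors.items():
            if len(levels) < 2:
                raise ValueError(f"factor {f!r} has < 2 levels")
        unknown = [t for t in self.fixed_terms if t not in self.factors]
        if unknown:
            raise ValueError(f"fixed terms without level sets: {unknown}")
        for a, b in self.interactions:
            if a not in self.fixed_terms or b not in self.fixed_terms:
                raise ValueError(f"interaction ({a}, {b}) uses a term not in the model")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for split-R-hat")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("need 0 < warmup < iterations")

    def with_sampler(self, chains: int | None = None, iterations: int | None = None,
                     warmup: int | None = None, seed: int | None = None) -> "ModelSpec":
        kw = {}
        if chains is not None:
            kw["chains"] = chains
        if iterations is not None:
            kw["iterations"] = iterations
        if warmup is not None:
            kw["warmup"] = warmup
        if seed is not None:
            kw["seed"] = seed
        return replace(self, **kw)


CANONICAL_LEVELS = {
    "version": ("cold", "hot", "toasty", "warm"),
    "incentive": (True, False),  # reference = incentivized; coefficient = non-incentivized
}


def default_model_spec(data: pd.DataFrame, response: str = "intended_count",
                       **overrides) -> ModelSpec:
    """The full analysis model for a trial table.

    Fixed effects: version, incentive, gain, loss, n_loss_cards, repetition
    (block), plus version x each-other-term interactions; random intercept
    and slopes for the within-subject factors. Factors with a single
    observed level (e.g. a one-version dataset) are dropped from the
    formula.
    """
    factors: dict[str, tuple] = {}
    for col in ("version", "incentive", "gain", "loss", "n_loss_cards", "block"):
        observed = sorted(data[col].unique().tolist())
        if col in CANONICAL_LEVELS:
            levels = tuple(l for l in CANONICAL_LEVELS[col] if l in observed)
        else:
            levels = tuple(observed)
        if len(levels) >= 2:
            factors[col] = levels
    fixed = tuple(factors)
    interactions = _version_interactions(fixed) if "version" in factors else ()
    slopes = tuple(t for t in ("gain", "loss", "n_loss_cards", "block") if t in factors)
    spec = ModelSpec(
        factors=factors,
        fixed_terms=fixed,
        interactions=interactions,
        random_slopes=slopes,
        response=response,
    )
    return replace(spec, **overrides) if overrides else spec


def null_model_spec(data: pd.DataFrame, response: str = "intended_count",
                    **overrides) -> ModelSpec:
    """Intercept + random-intercept model (for the ICC and grand mean)."""
    # a dummy 2-level factor is never used: fixed_terms empty
    spec = ModelSpec(
        factors={}, fixed_terms=(), interactions=(), random_slopes=(),
        response=response,
    )
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# design-matrix construction

def _term_columns(spec: ModelSpec) -> list[tuple[str, ...]]:
    """Expand the formula into labelled column builders."""
    names: list[str] = []
    builders: list[tuple] = []  # ("main", factor, idx) | ("inter", fa, ia, fb, ib)
    for term in spec.fixed_terms:
        cols, _ = encode_sum_to_zero(term, spec.factors[term])
        for i, c in enumerate(cols):
            names.append(c)
            builders.append(("main", term, i))
    for fa, fb in spec.interactions:
        cols_a, _ = encode_sum_to_zero(fa, spec.factors[fa])
        cols_b, _ = encode_sum_to_zero(fb, spec.factors[fb])
        for ia, ca in enumerate(cols_a):
            for ib, cb in enumerate(cols_b):
                names.append(f"{ca}:{cb}")
                builders.append(("inter", fa, ia, fb, ib))
    return names, builders


def _code_matrix(values: pd.Series, factor: str, levels: tuple) -> np.ndarray:
    """(n, L-1) coded matrix for one factor column."""
    _, codes = encode_sum_to_zero(factor, levels)
    unknown = set(values.unique()) - set(levels)
    if unknown:
        raise ValueError(f"unknown level(s) {unknown} for factor {factor!r}")
    return np.stack([codes[v] for v in values])


def build_fixed_matrix(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix (leading intercept column)."""
    n = len(data)
    main = {
        t: _code_matrix(data[t], t, spec.factors[t]) for t in spec.fixed_terms
    }
    names, builders = _term_columns(spec)
    cols = [np.ones(n)]
    for b in builders:
        if b[0] == "main":
            _, t, i = b
            cols.append(main[t][:, i])
        else:
            _, fa, ia, fb, ib = b
            cols.append(main[fa][:, ia] * main[fb][:, ib])
    return np.column_stack(cols), ["intercept"] + names


def build_random_matrix(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Per-participant random-effect covariates (intercept + slope columns)."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    for t in spec.random_slopes:
        cnames, _ = encode_sum_to_zero(t, spec.factors[t])
        mat = _code_matrix(data[t], t, spec.factors[t])
        for i, c in enumerate(cnames):
            cols.append(mat[:, i])
            names.append(c)
    return np.column_stack(cols), names


def factor_row(values: Mapping, spec: ModelSpec) -> np.ndarray:
    """Fixed-effect design row for a single factor-level assignment."""
    frame = pd.DataFrame({k: [v] for k, v in values.items()})
    X, _ = build_fixed_matrix(frame, spec)
    return X[0]


# ---------------------------------------------------------------------------
# likelihood

def censored_loglik(y, censored, mu, sigma) -> np.ndarray:
    """Per-row log-likelihood of a right-censored Gaussian observation.

    Uncensored rows contribute the normal log-density at ``y``; censored
    rows contribute ``log P(Y > y)`` (the true value is only known to be at
    least the observed one).
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be > 0")
    y = np.asarray(y, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    z = (y - mu) / sigma
    out = np.where(
        censored,
        special.log_ndtr(-z),  # log upper-tail probability
        -0.5 * z**2 - 0.5 * np.log(2 * np.pi) - np.log(sigma),
    )
    return out


def _sample_truncnorm_lower(rng, lower, mu, sigma):
    """Draw from N(mu, sigma^2) truncated to [lower, inf), vectorized."""
    alpha = (lower - mu) / sigma
    tail = special.ndtr(-alpha)  # P(Z > alpha)
    u = rng.uniform(size=np.shape(alpha)) * tail
    u = np.clip(u, 1e-300, None)
    return mu - sigma * special.ndtri(u)


def _inv_gamma(rng, shape, scale):
    """Draw from InvGamma(shape, scale) (scale = rate of the reciprocal)."""
    size = np.broadcast(np.asarray(shape), np.asarray(scale)).shape
    return scale / rng.gamma(shape, 1.0, size=size or None)


# ---------------------------------------------------------------------------
# fit result

@dataclass
class FitResult:
    """Posterior summaries and raw draws of the censored multilevel model."""

    spec: ModelSpec
    coef: pd.DataFrame  # per fixed effect: mean, sd, 2.5%, 97.5%, rhat, ess
    variance: pd.DataFrame  # sigma2, tau00, slope sds
    draws: dict = field(repr=False)  # beta (C,D,p), sigma2 (C,D), Sigma (C,D,q,q), loglik (C,D)
    coef_names: list[str] = field(default_factory=list)
    ranef_names: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict, repr=False)

    @property
    def sigma2(self) -> float:
        return float(self.draws["sigma2"].mean())

    @property
    def tau00(self) -> float:
        return float(self.draws["Sigma"][..., 0, 0].mean())

    def beta_flat(self) -> np.ndarray:
        b = self.draws["beta"]
        return b.reshape(-1, b.shape[-1])

    def coefficient(self, name: str) -> pd.Series:
        return self.coef.loc[name]


def _relocation_groups(X, Z, pid, J, tol=1e-8):
    """Detect fixed columns of the form x_c = w_j * z_k (w participant-constant).

    Returns ``(k, fixed-column indices, W)`` triples where ``W`` is the
    (J, n_cols) participant-level weight matrix; used for the exact
    location-resampling Gibbs moves in :func:`fit`.
    """
    n, p = X.shape
    q = Z.shape[1]
    groups = []
    for k in range(q):
        z = Z[:, k]
        nz = np.abs(z) > tol
        cols, weights = [], []
        for c in range(p):
            x = X[:, c]
            if np.any(np.abs(x[~nz]) > tol):  # x must vanish wherever z does
                continue
            ratio = np.zeros(n)
            ratio[nz] = x[nz] / z[nz]
            wmax = np.full(J, -np.inf)
            wmin = np.full(J, np.inf)
            np.maximum.at(wmax, pid[nz], ratio[nz])
            np.minimum.at(wmin, pid[nz], ratio[nz])
            missing = ~np.isfinite(wmax)
            wmax[missing] = 0.0
            wmin[missing] = 0.0
            if np.any(wmax - wmin > tol):  # weight varies within a participant
                continue
            if np.all(np.abs(wmax) < tol):
                continue
            cols.append(c)
            weights.append(wmax)
        if cols:
            groups.append((k, np.asarray(cols), np.column_stack(weights)))
    return groups


def _summaries(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """mean/sd/CI/R-hat/ESS table from (chain, draw) sample arrays."""
    import arviz as az

    idata = az.from_dict(posterior=samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess_b = az.ess(idata, method="bulk")
        ess_t = az.ess(idata, method="tail")
    rows = {}
    for name, arr in samples.items():
        flat = arr.reshape(-1)
        rows[name] = {
            "mean": flat.mean(),
            "sd": flat.std(ddof=1),
            "ci_lower": np.quantile(flat, 0.025),
            "ci_upper": np.quantile(flat, 0.975),
            "rhat": float(rhat[name].values),
            "ess_bulk": float(ess_b[name].values),
            "ess_tail": float(ess_t[name].values),
        }
    return pd.DataFrame(rows).T


def fit(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Posterior sampling for the right-censored multilevel model.

    Runs ``spec.chains`` independent Gibbs chains of ``spec.iterations``
    sweeps each (first ``spec.warmup`` discarded). Central 95% quantile
    intervals are reported. A warning is attached (and emitted) if any
    R-hat exceeds 1.05.
    """
    required = [spec.response, spec.censor_col, spec.participant_col]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing required columns: {missing}")
    if data[spec.participant_col].nunique() < 2:
        raise ValueError("need at least 2 participants for a multilevel model")
    y = data[spec.response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance; nothing to model")
    cens = data[spec.censor_col].to_numpy(dtype=bool)

    X, coef_names = build_fixed_matrix(data, spec)
    Z, ranef_names = build_random_matrix(data, spec)
    pid, _ = pd.factorize(data[spec.participant_col], sort=True)
    n, p = X.shape
    q = Z.shape[1]
    J = pid.max() + 1

    fit_warnings: list[str] = []
    if cens.all():
        fit_warnings.append(
            "every observation is censored: the posterior is prior-dominated"
        )

    XtX = X.T @ X
    # per-participant Z_j' Z_j (constant across sweeps)
    C = np.zeros((J, q, q))
    np.add.at(C, pid, Z[:, :, None] * Z[:, None, :])
    prior_prec_beta = np.eye(p) / spec.coef_prior_scale**2

    # Translation moves: a fixed column x_c that equals a random column z_k
    # times a participant-constant weight w_j (the intercept, between-subject
    # factors, and between x within interactions all have this form) shares a
    # location with the b_{jk}; resampling that location jointly — an exact
    # Gibbs step on the translation group — removes the random walk between
    # such coefficients and the group means of the random effects.
    relocations = _relocation_groups(X, Z, pid, J)

    nu_e, nu_q, A = 3.0, 2.0, spec.sd_prior_scale
    n_keep = spec.iterations - spec.warmup
    beta_draws = np.empty((spec.chains, n_keep, p))
    sigma2_draws = np.empty((spec.chains, n_keep))
    Sigma_draws = np.empty((spec.chains, n_keep, q, q))
    loglik_draws = np.empty((spec.chains, n_keep))

    root = np.random.SeedSequence(spec.seed)
    for chain, ss in enumerate(root.spawn(spec.chains)):
        rng = np.random.default_rng(ss)
        # initialization: least squares on the observed response
        beta = np.linalg.lstsq(X + 0.0, y, rcond=None)[0]
        beta += rng.normal(0, 0.1, size=p)  # overdispersed starts across chains
        resid0 = y - X @ beta
        sigma2 = max(resid0.var(), 1e-3) * rng.uniform(0.5, 2.0)
        Sigma = np.eye(q)
        Sigma_inv = np.eye(q)
        b = np.zeros((J, q))
        a_e = 1.0
        a_q = np.ones(q)
        y_lat = y.copy()

        for sweep in range(spec.iterations):
            sigma = np.sqrt(sigma2)
            mu = X @ beta + np.einsum("ij,ij->i", Z, b[pid])
            if cens.any():
                y_lat[cens] = _sample_truncnorm_lower(rng, y[cens], mu[cens], sigma)

            # random effects b_j | rest
            resid_f = y_lat - X @ beta
            rhs = np.zeros((J, q))
            np.add.at(rhs, pid, Z * resid_f[:, None])
            rhs /= sigma2
            prec = C / sigma2 + Sigma_inv
            cov = np.linalg.inv(prec)
            mean = np.einsum("jab,jb->ja", cov, rhs)
            Lc = np.linalg.cholesky(cov)
            b = mean + np.einsum("jab,jb->ja", Lc, rng.standard_normal((J, q)))

            # fixed effects beta | rest
            resid_b = y_lat - np.einsum("ij,ij->i", Z, b[pid])
            prec_b = XtX / sigma2 + prior_prec_beta
            cov_b = np.linalg.inv(prec_b)
            mean_b = cov_b @ (X.T @ resid_b) / sigma2
            beta = mean_b + np.linalg.cholesky(cov_b) @ rng.standard_normal(p)

            # joint relocation of (beta, b) along shared directions
            for k, cols, W in relocations:
                Db = np.diag(prior_prec_beta)[cols]
                bSi = b @ Sigma_inv[:, k]
                P = np.diag(Db) + Sigma_inv[k, k] * (W.T @ W)
                rhs_d = -Db * beta[cols] + W.T @ bSi
                cov_d = np.linalg.inv(P)
                delta = cov_d @ rhs_d + np.linalg.cholesky(cov_d) @ rng.standard_normal(
                    len(cols)
                )
                beta[cols] += delta
                b[:, k] -= W @ delta

            # residual variance (parameter-expanded half-t prior on sigma)
            resid = y_lat - X @ beta - np.einsum("ij,ij->i", Z, b[pid])
            ssr = resid @ resid
            sigma2 = _inv_gamma(rng, (nu_e + n) / 2.0, nu_e / a_e + ssr / 2.0)
            a_e = _inv_gamma(rng, (nu_e + 1) / 2.0, nu_e / sigma2 + 1.0 / A**2)

            # random-effect covariance (parameter-expanded inverse-Wishart)
            S_b = b.T @ b
            df = nu_q + q - 1 + J
            scale = 2.0 * nu_q * np.diag(1.0 / a_q) + S_b
            Sigma = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
            Sigma = np.atleast_2d(Sigma)
            Sigma_inv = np.linalg.inv(Sigma)
            a_q = _inv_gamma(
                rng, (nu_q + q) / 2.0,
                nu_q * np.diag(Sigma_inv) + 1.0 / A**2,
            )

            if sweep >= spec.warmup:
                keep = sweep - spec.warmup
                beta_draws[chain, keep] = beta
                sigma2_draws[chain, keep] = sigma2
                Sigma_draws[chain, keep] = Sigma
                mu_now = X @ beta + np.einsum("ij,ij->i", Z, b[pid])
                loglik_draws[chain, keep] = censored_loglik(
                    y, cens, mu_now, np.sqrt(sigma2)
                ).sum()

    samples = {name: beta_draws[:, :, i] for i, name in enumerate(coef_names)}
    samples["sigma2"] = sigma2_draws
    samples["tau00"] = Sigma_draws[:, :, 0, 0]
    for i, name in enumerate(ranef_names[1:], start=1):
        samples[f"sd({name})"] = np.sqrt(Sigma_draws[:, :, i, i])
    table = _summaries(samples)

    bad = table[table["rhat"] > 1.05]
    if len(bad):
        msg = f"R-hat above 1.05 for: {', '.join(bad.index)} — do not trust summaries"
        fit_warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    coef = table.loc[coef_names]
    variance = table.loc[[r for r in table.index if r not in coef_names]]

    # second moments needed by emm / r2 without retaining the data
    Xc = X - X.mean(axis=0)
    meta = {
        "Cx": (Xc.T @ Xc) / n,
        "Mz": (Z.T @ Z) / n,
        "n": n,
        "n_participants": int(J),
        "n_censored": int(cens.sum()),
    }
    return FitResult(
        spec=spec,
        coef=coef,
        variance=variance,
        draws={
            "beta": beta_draws,
            "sigma2": sigma2_draws,
            "Sigma": Sigma_draws,
            "loglik": loglik_draws,
        },
        coef_names=coef_names,
        ranef_names=ranef_names,
        warnings=fit_warnings,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# derived quantities

def emm(fit_result: FitResult, grid: Sequence[str]) -> pd.DataFrame:
    """Estimated marginal means over a factor grid.

    For each combination of levels of the ``grid`` factors, the
    population-level prediction (random effects at zero) is averaged over
    all levels of the remaining model factors with equal cell weights; the
    posterior mean and central 95% interval are reported.
    """
    spec = fit_result.spec
    unknown = [g for g in grid if g not in spec.fixed_terms]
    if unknown:
        raise ValueError(f"grid factors not in the model: {unknown}")
    beta = fit_result.beta_flat()
    rows = []
    others = [t for t in spec.fixed_terms if t not in grid]
    for cell in itertools.product(*(spec.factors[g] for g in grid)):
        assignment = dict(zip(grid, cell))
        xs = []
        for rest in itertools.product(*(spec.factors[t] for t in others)):
            values = dict(assignment)
            values.update(zip(others, rest))
            xs.append(factor_row(values, spec))
        x_avg = np.mean(xs, axis=0) if xs else factor_row(assignment, spec)
        pred = beta @ x_avg
        rows.append(
            {
                **{g: v for g, v in assignment.items()},
                "emm": pred.mean(),
                "ci_lower": np.quantile(pred, 0.025),
                "ci_upper": np.quantile(pred, 0.975),
            }
        )
    return pd.DataFrame(rows)


def icc(fit_null: FitResult) -> float:
    """Intraclass correlation tau00 / (tau00 + sigma^2) from a null model."""
    tau = fit_null.draws["Sigma"][..., 0, 0]
    sig = fit_null.draws["sigma2"]
    return float((tau / (tau + sig)).mean())


def r2_decomposition(fit_result: FitResult) -> tuple[float, float]:
    """Marginal and conditional R-squared (variance-partition form).

    Marginal: fixed-effect variance over total (fixed + random + residual);
    conditional: fixed + random over total. Posterior means are returned.
    """
    Cx = fit_result.meta["Cx"]
    Mz = fit_result.meta["Mz"]
    beta = fit_result.beta_flat()
    var_f = np.einsum("dp,pq,dq->d", beta, Cx, beta)
    Sig = fit_result.draws["Sigma"].reshape(-1, *fit_result.draws["Sigma"].shape[-2:])
    var_r = np.einsum("dab,ba->d", Sig, Mz)
    sig2 = fit_result.draws["sigma2"].reshape(-1)
    total = var_f + var_r + sig2
    return float((var_f / total).mean()), float(((var_f + var_r) / total).mean())


def compare_estimators(
    data: pd.DataFrame,
    response: str = "cards_revealed",
    sampler: dict | None = None,
) -> dict[str, float]:
    """Three estimates of the population mean reveal count.

    ``raw``: mean of the observed counts (biased low under censoring);
    ``loss_rounds_excluded``: mean over rounds without a revealed loss
    (selects against high counts); ``censored_model``: grand-mean posterior
    mean of an intercept + random-intercept censored model.
    """
    spec = null_model_spec(data, response=response)
    if sampler:
        spec = spec.with_sampler(**sampler)
    result = fit(data, spec)
    return {
        "raw": float(data[response].mean()),
        "loss_rounds_excluded": float(
            data.loc[~data["loss_revealed"].astype(bool), response].mean()
        ),
        "censored_model": float(result.coef.loc["intercept", "mean"]),
    }
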