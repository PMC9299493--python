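"""Bayesian linear mixed models for haemoglobin, and the previous-Hb baseline.

The model for donor i at donation t is

    y_it = x_it' beta + c_i' phi + b_i + eps_it,
    b_i ~ N(0, sigma_b^2),   eps_it ~ N(0, sigma_eps^2),

where x_it are donation-varying covariates, c_i donor-constant covariates,
and b_i the donor random intercept capturing unobserved donor-level Hb
determinants.  When the previous Hb measurement is among the predictors the
model is a *dynamic* linear mixed model (DLMM).

Inference is a blocked Gibbs sampler exploiting full conjugacy: normal
priors on all coefficients, inverse-gamma priors on both variances.  The
update blocks are (all coefficients | b, variances), (b | coefficients,
variances), and each variance given the rest.  Convergence is summarized by
rank-normalized split R-hat per parameter.

Deferral probabilities come from the posterior predictive: for a test
donation with linear predictor draw mu and residual SD draw sigma_eps, the
probability that Hb falls below the sex-specific limit is
Phi((limit - mu) / sigma_eps), averaged over draws.

The baseline comparator is a plain logistic regression of deferral on the
previous Hb measurement alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import linalg, stats

from .preprocessing import DEFERRAL_LIMITS, ModelFrame, Scaling

__all__ = [
    "MCMCConfig",
    "Priors",
    "LinearFit",
    "BaselineFit",
    "PredictionSet",
    "fit_linear_mixed",
    "posterior_predict_last",
    "fit_baseline_logistic",
    "predict_baseline",
    "effect_sizes_2sd",
    "two_sd_effect_sizes",
]


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    draws: int = 1000
    warmup: int = 500
    seed: int = 0


@dataclass(frozen=True)
class Priors:
    """Weakly informative conjugate priors.

    Coefficients: Normal(0, coef_sd^2) on the standardized design scale,
    with optional per-variable overrides (a near-zero SD pins a coefficient
    at zero, nesting a sub-model).  Variances: Inverse-Gamma(ig_shape,
    ig_rate) on sigma_b^2 and sigma_eps^2.
    """

    coef_sd: float = 10.0
    ig_shape: float = 2.0
    ig_rate: float = 1.0
    coef_sd_overrides: tuple[tuple[str, float], ...] = ()

    def precision_diag(self, names: list[str]) -> np.ndarray:
        over = dict(self.coef_sd_overrides)
        return np.array(
            [1.0 / over.get(v, self.coef_sd) ** 2 for v in names]
        )


@dataclass
class PredictionSet:
    """Per-test-donation predictions (one row per donor)."""

    frame: pd.DataFrame  # donor_id, sex, observed_hb, observed_deferral,
    # predicted_hb (NaN for classifiers), deferral_probability

    def __post_init__(self) -> None:
        p = self.frame["deferral_probability"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("deferral probabilities outside [0, 1]")


@dataclass
class LinearFit:
    """Posterior draws from the (D)LMM Gibbs sampler.

    ``coef_draws`` has one column per design variable (standardized scale);
    the beta/phi split into donation-varying and donor-constant streams is
    available through ``beta_draws`` / ``phi_draws``.
    """

    variable_list: list[str]
    donor_ids: list[str]
    coef_draws: np.ndarray  # (n_draws_total, p)
    b_draws: np.ndarray  # (n_draws_total, n_donors)
    sigma_b_draws: np.ndarray
    sigma_eps_draws: np.ndarray
    n_chains: int
    scaling: Scaling
    diagnostics: pd.DataFrame  # parameter, rhat
    dynamic: bool
    sex_stratum: str
    donor_constant_vars: list[str] = field(default_factory=list)

    @property
    def beta_draws(self) -> np.ndarray:
        idx = [
            j
            for j, v in enumerate(self.variable_list)
            if v not in self.donor_constant_vars
        ]
        return self.coef_draws[:, idx]

    @property
    def phi_draws(self) -> np.ndarray:
        idx = [
            j
            for j, v in enumerate(self.variable_list)
            if v in self.donor_constant_vars
        ]
        return self.coef_draws[:, idx]

    @property
    def converged(self) -> bool:
        return bool((self.diagnostics["rhat"] < 1.05).all())

    def coefficient_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable_list,
                "mean": self.coef_draws.mean(axis=0),
                "sd": self.coef_draws.std(axis=0),
            }
        )

    def to_draws_table(self) -> pd.DataFrame:
        """Long-format draws table: chain, draw, parameter, value."""
        n_total = len(self.sigma_eps_draws)
        per_chain = n_total // self.n_chains
        chain = np.repeat(np.arange(self.n_chains), per_chain)
        draw = np.tile(np.arange(per_chain), self.n_chains)
        frames = []
        for j, v in enumerate(self.variable_list):
            frames.append(
                pd.DataFrame(
                    {"chain": chain, "draw": draw, "parameter": v,
                     "value": self.coef_draws[:, j]}
                )
            )
        for name, arr in (
            ("sigma_b", self.sigma_b_draws),
            ("sigma_eps", self.sigma_eps_draws),
        ):
            frames.append(
                pd.DataFrame(
                    {"chain": chain, "draw": draw, "parameter": name, "value": arr}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def save(self, prefix) -> tuple:
        """Serialize: draws table as CSV plus a JSON scaling/diagnostics
        sidecar. Donor intercepts are omitted from the table (one stream
        per donor would dominate the file without aiding reuse)."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        draws_path = prefix.with_suffix(".draws.csv")
        self.to_draws_table().to_csv(draws_path, index=False)
        sidecar = {
            "variable_list": self.variable_list,
            "sex_stratum": self.sex_stratum,
            "dynamic": self.dynamic,
            "n_chains": self.n_chains,
            "scaling": {
                "mean": self.scaling.mean,
                "std": self.scaling.std,
                "binary": self.scaling.binary,
            },
            "diagnostics": self.diagnostics.to_dict(orient="records"),
        }
        json_path = prefix.with_suffix(".meta.json")
        json_path.write_text(json.dumps(sidecar, indent=2))
        return draws_path, json_path


@dataclass
class BaselineFit:
    """Logistic regression of deferral on previous Hb only (raw g/L scale)."""

    intercept: float
    slope: float
    sex_stratum: str
    separation_warning: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("non-finite baseline coefficients")

    def probability(self, previous_hb: np.ndarray) -> np.ndarray:
        eta = self.intercept + self.slope * np.asarray(previous_hb, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        collinear = [names[j] for j in piv[r:]]
        raise ValueError(f"rank-deficient design; collinear variables: {collinear}")


def _gibbs_chain(
    y: np.ndarray,
    X: np.ndarray,
    z: np.ndarray,
    n_donors: int,
    priors: Priors,
    n_iter: int,
    warmup: int,
    rng: np.random.Generator,
    fixed_variances: tuple[float, float] | None,
    names: list[str],
) -> dict[str, np.ndarray]:
    n, p = X.shape
    counts = np.bincount(z, minlength=n_donors).astype(float)
    XtX = X.T @ X
    prior_prec = np.diag(priors.precision_diag(names))

    # init: ridge solve for coefficients, residual variance for sigmas
    beta = np.linalg.solve(XtX + prior_prec, X.T @ y)
    b = np.zeros(n_donors)
    resid0 = y - X @ beta
    s2 = max(float(np.var(resid0)), 1e-6)
    if fixed_variances is not None:
        sigma_b2, sigma_e2 = fixed_variances[0] ** 2, fixed_variances[1] ** 2
    else:
        sigma_b2 = s2 / 2
        sigma_e2 = s2 / 2

    keep = n_iter - warmup
    out_coef = np.empty((keep, p))
    out_b = np.empty((keep, n_donors))
    out_sb = np.empty(keep)
    out_se = np.empty(keep)

    for it in range(n_iter):
        # coefficients | b, variances  (multivariate normal, Cholesky solve)
        A = XtX / sigma_e2 + prior_prec
        rhs = X.T @ (y - b[z]) / sigma_e2
        L = np.linalg.cholesky(A)
        mean = linalg.cho_solve((L, True), rhs)
        beta = mean + linalg.solve_triangular(L.T, rng.standard_normal(p))

        # donor intercepts | coefficients, variances (independent normals)
        r = y - X @ beta
        sums = np.bincount(z, weights=r, minlength=n_donors)
        var_b = 1.0 / (counts / sigma_e2 + 1.0 / sigma_b2)
        mean_b = var_b * sums / sigma_e2
        b = mean_b + np.sqrt(var_b) * rng.standard_normal(n_donors)

        if fixed_variances is None:
            # variances | rest (inverse-gamma)
            ssr = float(np.sum((r - b[z]) ** 2))
            sigma_e2 = 1.0 / rng.gamma(
                priors.ig_shape + n / 2.0, 1.0 / (priors.ig_rate + ssr / 2.0)
            )
            ssb = float(np.sum(b**2))
            sigma_b2 = 1.0 / rng.gamma(
                priors.ig_shape + n_donors / 2.0, 1.0 / (priors.ig_rate + ssb / 2.0)
            )

        if it >= warmup:
            j = it - warmup
            out_coef[j] = beta
            out_b[j] = b
            out_sb[j] = np.sqrt(sigma_b2)
            out_se[j] = np.sqrt(sigma_e2)

    return {"coef": out_coef, "b": out_b, "sigma_b": out_sb, "sigma_eps": out_se}


def fit_linear_mixed(
    frame: ModelFrame,
    priors: Priors | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int | None = None,
    fixed_variances: tuple[float, float] | None = None,
    donor_constant_vars: list[str] | None = None,
) -> LinearFit:
    """Fit the (D)LMM by blocked conjugate Gibbs sampling.

    Parameters
    ----------
    frame : design frame from :func:`~hbdefer.preprocessing.make_model_frame`.
    priors : conjugate prior hyperparameters (default weakly informative).
    mcmc : chains / draws / warmup / seed.
    seed : overrides ``mcmc.seed`` when given.
    fixed_variances : optional (sigma_b, sigma_eps) to hold fixed — used for
        validation against the analytic conjugate posterior.
    donor_constant_vars : variables forming c_i (phi stream) rather than
        x_it (beta stream); informational split only, the sampler treats all
        coefficients as one block.

    Non-convergence (any R-hat > 1.05) sets a diagnostics flag, it does not
    raise.
    """
    priors = priors or Priors()
    mcmc = mcmc or MCMCConfig()
    base_seed = mcmc.seed if seed is None else seed

    train = frame.train_rows
    if len(train) == 0:
        raise ValueError("empty training rows")
    donor_ids = sorted(train["donor_id"].unique())
    donor_index = {d: i for i, d in enumerate(donor_ids)}
    z = train["donor_id"].map(donor_index).to_numpy()
    y = train["hb"].to_numpy(dtype=float)
    X = train[frame.variable_list].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    names = ["intercept"] + list(frame.variable_list)
    _check_rank(X, names)

    n_iter = mcmc.draws + mcmc.warmup
    chains = []
    ss = np.random.SeedSequence(base_seed)
    for child in ss.spawn(mcmc.chains):
        rng = np.random.default_rng(child)
        chains.append(
            _gibbs_chain(
                y, X, z, len(donor_ids), priors, n_iter, mcmc.warmup, rng,
                fixed_variances, names,
            )
        )

    coef = np.concatenate([c["coef"] for c in chains], axis=0)
    b = np.concatenate([c["b"] for c in chains], axis=0)
    sb = np.concatenate([c["sigma_b"] for c in chains])
    se = np.concatenate([c["sigma_eps"] for c in chains])

    # split R-hat on coefficients and variances (donor intercepts omitted:
    # thousands of well-behaved conditionally-conjugate normals)
    diag_rows = []
    for j, v in enumerate(names):
        arr = np.stack([c["coef"][:, j] for c in chains])
        diag_rows.append((v, _rhat(arr)))
    if fixed_variances is None:
        diag_rows.append(("sigma_b", _rhat(np.stack([c["sigma_b"] for c in chains]))))
        diag_rows.append(
            ("sigma_eps", _rhat(np.stack([c["sigma_eps"] for c in chains])))
        )
    diagnostics = pd.DataFrame(diag_rows, columns=["parameter", "rhat"])
    if (diagnostics["rhat"] > 1.05).any():
        warnings.warn("R-hat > 1.05 for some parameters; inspect diagnostics",
                      stacklevel=2)

    return LinearFit(
        variable_list=names,
        donor_ids=donor_ids,
        coef_draws=coef,
        b_draws=b,
        sigma_b_draws=sb,
        sigma_eps_draws=se,
        n_chains=mcmc.chains,
        scaling=frame.scaling,
        diagnostics=diagnostics,
        dynamic=frame.dynamic,
        sex_stratum=frame.sex_stratum,
        donor_constant_vars=donor_constant_vars or [],
    )


def _rhat(chains_draws: np.ndarray) -> float:
    """Rank-normalized split R-hat of an array shaped (chains, draws)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(chains_draws[..., None])
        return float(np.asarray(az.rhat(ds)["x"]).ravel()[0])


def posterior_predict_last(
    fit: LinearFit,
    frame: ModelFrame,
    limits: dict[str, float] | None = None,
    marginal_for_unseen: bool = False,
) -> PredictionSet:
    """Posterior-predictive mean Hb and deferral probability per test row.

    For each posterior draw the linear predictor mu includes the donor's own
    fitted intercept b_i; the deferral probability is the draw-averaged
    Normal CDF mass below the sex-specific limit.  A test donor without a
    fitted intercept is an error unless ``marginal_for_unseen`` is set, in
    which case the random intercept is integrated out (predictive SD
    sqrt(sigma_eps^2 + sigma_b^2), mean without b).
    """
    lims = limits if limits is not None else DEFERRAL_LIMITS
    test = frame.test_rows
    missing = set(test["donor_id"]) - set(fit.donor_ids)
    if missing and not marginal_for_unseen:
        raise ValueError(
            f"test donors without fitted intercepts: {sorted(missing)[:5]}"
        )
    donor_index = {d: i for i, d in enumerate(fit.donor_ids)}
    cols = [v for v in fit.variable_list if v != "intercept"]
    Xt = np.column_stack(
        [np.ones(len(test)), test[cols].to_numpy(dtype=float)]
    )
    mu = fit.coef_draws @ Xt.T  # (draws, n_test)
    seen = test["donor_id"].isin(donor_index).to_numpy()
    idx = np.array(
        [donor_index.get(d, 0) for d in test["donor_id"]], dtype=int
    )
    mu[:, seen] += fit.b_draws[:, idx[seen]]

    lim = test["sex"].map(lims).to_numpy(dtype=float)
    sd = np.tile(fit.sigma_eps_draws[:, None], (1, len(test)))
    if (~seen).any():
        sd[:, ~seen] = np.sqrt(
            fit.sigma_eps_draws[:, None] ** 2 + fit.sigma_b_draws[:, None] ** 2
        )
    zscore = (lim[None, :] - mu) / sd
    prob = stats.norm.cdf(zscore).mean(axis=0)
    out = pd.DataFrame(
        {
            "donor_id": test["donor_id"].to_numpy(),
            "sex": test["sex"].to_numpy(),
            "observed_hb": test["hb"].to_numpy(dtype=float),
            "observed_deferral": test["deferred"].to_numpy(dtype=bool),
            "predicted_hb": mu.mean(axis=0),
            "deferral_probability": prob,
        }
    )
    return PredictionSet(out)


def fit_baseline_logistic(frame: ModelFrame) -> BaselineFit:
    """Maximum-likelihood logistic fit of deferral on previous Hb alone.

    Complete separation (or a degenerate all-one-class outcome) falls back
    to an L2-penalized fit and sets ``separation_warning``.
    """
    import statsmodels.api as sm

    train = frame.train_rows[frame.train_rows["previous_hb"].notna()]
    x = train["previous_hb"].to_numpy(dtype=float)
    if "previous_hb" in frame.scaling.mean:  # undo standardization: g/L scale
        x = x * frame.scaling.std["previous_hb"] + frame.scaling.mean["previous_hb"]
    yv = train["deferred"].to_numpy(dtype=float)

    X = sm.add_constant(x)
    warn = False
    if yv.min() == yv.max():
        warn = True
        intercept, slope = _penalized_logistic(x, yv)
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                res = sm.Logit(yv, X).fit(disp=0)
            intercept, slope = float(res.params[0]), float(res.params[1])
            if not np.all(np.isfinite(res.bse)):
                raise ValueError("separation")
        except Exception:
            warn = True
            intercept, slope = _penalized_logistic(x, yv)
    if warn:
        warnings.warn(
            "separation or degenerate labels in baseline logistic; "
            "penalized fallback used",
            stacklevel=2,
        )
    return BaselineFit(
        intercept=intercept, slope=slope, sex_stratum=frame.sex_stratum,
        separation_warning=warn,
    )


def _penalized_logistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    from sklearn.linear_model import LogisticRegression

    if y.min() == y.max():
        # degenerate: flat probability at the observed rate, zero slope
        p = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        return float(np.log(p / (1 - p))), 0.0
    xs = (x - x.mean()) / (x.std() or 1.0)
    lr = LogisticRegression(C=1.0).fit(xs[:, None], y)
    slope = float(lr.coef_[0, 0]) / (x.std() or 1.0)
    intercept = float(lr.intercept_[0]) - slope * x.mean()
    return intercept, slope


def predict_baseline(fit: BaselineFit, frame: ModelFrame) -> PredictionSet:
    """Apply the previous-Hb logistic baseline to the test rows."""
    test = frame.test_rows
    if test["previous_hb"].isna().any():
        raise ValueError("test rows with missing previous_hb")
    x = test["previous_hb"].to_numpy(dtype=float)
    if "previous_hb" in frame.scaling.mean:
        x = x * frame.scaling.std["previous_hb"] + frame.scaling.mean["previous_hb"]
    out = pd.DataFrame(
        {
            "donor_id": test["donor_id"].to_numpy(),
            "sex": test["sex"].to_numpy(),
            "observed_hb": test["hb"].to_numpy(dtype=float),
            "observed_deferral": test["deferred"].to_numpy(dtype=bool),
            "predicted_hb": np.nan,
            "deferral_probability": fit.probability(x),
        }
    )
    return PredictionSet(out)


def two_sd_effect_sizes(
    variables: list[str],
    coef_draws_raw: np.ndarray,
    raw_sd: dict[str, float],
    binary: dict[str, bool],
    credible_mass: float = 0.95,
) -> pd.DataFrame:
    """2-SD standardized effect sizes with HPDIs from raw-scale draws.

    Binary-variable coefficients are reported as they are; continuous
    coefficients are multiplied by twice the raw variable's SD so all
    effects share a comparable scale.
    """
    rows = []
    for j, v in enumerate(variables):
        draws = coef_draws_raw[:, j]
        if not binary.get(v, False):
            draws = draws * 2.0 * raw_sd[v]
        low, high = az.hdi(np.asarray(draws), hdi_prob=credible_mass)
        rows.append((v, float(draws.mean()), float(low), float(high)))
    return pd.DataFrame(rows, columns=["variable", "mean", "hpdi_low", "hpdi_high"])


def effect_sizes_2sd(fit: LinearFit, credible_mass: float = 0.95) -> pd.DataFrame:
    """2-SD effect-size table for a fitted (D)LMM.

    The fit's coefficients live on the standardized design scale; they are
    converted back to raw g/L-per-unit before the 2-SD scaling, so a
    continuous variable's reported effect equals (raw coefficient) x 2 x SD.
    """
    vars_no_int = [v for v in fit.variable_list if v != "intercept"]
    idx = [fit.variable_list.index(v) for v in vars_no_int]
    draws = fit.coef_draws[:, idx].copy()
    raw_sd = {}
    for j, v in enumerate(vars_no_int):
        if v in fit.scaling.std:  # standardized: undo to raw scale
            s = fit.scaling.std[v] or 1.0
            draws[:, j] /= s
            raw_sd[v] = s
        else:
            raw_sd[v] = 1.0
    binary = {v: fit.scaling.binary.get(v, False) for v in vars_no_int}
    return two_sd_effect_sizes(vars_no_int, draws, raw_sd, binary, credible_mass)
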