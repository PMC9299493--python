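"""Gibbs sampler correctness, posterior prediction, baseline logistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hbdefer.linear import (
    BaselineFit,
    LinearFit,
    MCMCConfig,
    Priors,
    effect_sizes_2sd,
    fit_baseline_logistic,
    fit_linear_mixed,
    posterior_predict_last,
    predict_baseline,
    two_sd_effect_sizes,
)
from hbdefer.preprocessing import ModelFrame, Scaling, make_model_frame


def build_frame(train: pd.DataFrame, test: pd.DataFrame, variables, dynamic=False):
    """ModelFrame straight from arrays (no standardization)."""
    return ModelFrame(
        train_rows=train,
        test_rows=test,
        variable_list=list(variables),
        sex_stratum="both",
        dynamic=dynamic,
        scaling=Scaling(mean={}, std={}, binary={}),
    )


def _grid_posterior_sigma_b(df, names, tau2=100.0, a0=2.0, b0=1.0):
    """Exact posterior of sigma_b for a balanced random-intercept model,
    collapsing b analytically (Woodbury per donor) and the coefficients by
    Gaussian integration, on a (sigma_b, sigma_eps) grid."""
    y = df["hb"].to_numpy()
    X = np.column_stack([np.ones(len(df)), df[names].to_numpy()])
    codes = pd.factorize(df["donor_id"])[0]
    N = codes.max() + 1
    n_per = np.bincount(codes)[0]
    p = X.shape[1]
    GS_X = np.array(
        [np.bincount(codes, weights=X[:, j], minlength=N) for j in range(p)]
    )
    GS_y = np.bincount(codes, weights=y, minlength=N)

    def logpost(sb2, se2):
        lam = sb2 / (se2 * (se2 + n_per * sb2))
        XtSiX = X.T @ X / se2 - lam * (GS_X @ GS_X.T)
        XtSiy = X.T @ y / se2 - lam * (GS_X @ GS_y)
        ytSiy = y @ y / se2 - lam * (GS_y @ GS_y)
        logdetS = N * ((n_per - 1) * np.log(se2) + np.log(se2 + n_per * sb2))
        A = XtSiX + np.eye(p) / tau2
        mu = np.linalg.solve(A, XtSiy)
        _, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * (logdetS + logdetA + ytSiy - XtSiy @ mu)
        lp = -(a0 + 1) * np.log(sb2) - b0 / sb2
        lp += -(a0 + 1) * np.log(se2) - b0 / se2
        return ll + lp

    sb = np.linspace(0.01, 2.0, 80)
    se = np.linspace(4.5, 5.5, 30)
    L = np.array([[logpost(b**2, e**2) for e in se] for b in sb])
    P = np.exp(L - L.max())
    pb = P.sum(axis=1)
    pb /= pb.sum()
    cdf = np.cumsum(pb)
    return float((sb * pb).sum()), float(sb[np.searchsorted(cdf, 0.95)])


def simulate_lmm(n_donors, n_events, beta, sigma_b, sigma_eps, seed,
                 var_names=None):
    """Draw directly from y = intercept + X beta + b_i + eps."""
    rng = np.random.default_rng(seed)
    p = len(beta) - 1  # beta[0] = intercept
    n = n_donors * n_events
    X = rng.standard_normal((n, p))
    z = np.repeat(np.arange(n_donors), n_events)
    b = rng.normal(0, sigma_b, n_donors)
    y = beta[0] + X @ beta[1:] + b[z] + rng.normal(0, sigma_eps, n)
    names = var_names or [f"x{j}" for j in range(p)]
    df = pd.DataFrame(X, columns=names)
    df["donor_id"] = [f"d{i}" for i in z]
    df["hb"] = y
    df["sex"] = "female"
    df["deferred"] = y < np.quantile(y, 0.05)
    return df, names


class TestGibbsCorrectness:
    def test_matches_analytic_conjugate_posterior(self):
        """Tiny dataset, variances held fixed: the Gibbs posterior mean of
        the coefficients must match the closed-form GLS conjugate posterior
        of the model with the random intercepts marginalized out."""
        sigma_b, sigma_eps, tau = 2.0, 3.0, 10.0
        df, names = simulate_lmm(3, 3, np.array([140.0, 1.5]), sigma_b,
                                 sigma_eps, seed=42)
        frame = build_frame(df, df.groupby("donor_id").tail(1), names)
        fit = fit_linear_mixed(
            frame,
            priors=Priors(coef_sd=tau),
            mcmc=MCMCConfig(chains=2, draws=8000, warmup=1000),
            seed=5,
            fixed_variances=(sigma_b, sigma_eps),
        )
        X = np.column_stack([np.ones(len(df)), df[names].to_numpy()])
        z = df["donor_id"].str[1:].astype(int).to_numpy()
        Z = np.eye(3)[z]
        Sigma = sigma_eps**2 * np.eye(len(df)) + sigma_b**2 * Z @ Z.T
        Si = np.linalg.inv(Sigma)
        prec = X.T @ Si @ X + np.eye(2) / tau**2
        mean_analytic = np.linalg.solve(prec, X.T @ Si @ df["hb"].to_numpy())
        sd_analytic = np.sqrt(np.diag(np.linalg.inv(prec)))
        gibbs_mean = fit.coef_draws.mean(axis=0)
        # within Monte-Carlo error (a few posterior-SD/sqrt(ESS) units)
        mc_tol = 5 * sd_analytic / np.sqrt(1000)
        assert np.all(np.abs(gibbs_mean - mean_analytic) < np.maximum(mc_tol, 0.05))

    def test_parameter_recovery_sanity(self):
        beta = np.array([140.0, 2.0, -1.0, 0.5])
        df, names = simulate_lmm(500, 7, beta, sigma_b=4.0, sigma_eps=6.0, seed=9)
        frame = build_frame(df, df.groupby("donor_id").tail(1), names)
        fit = fit_linear_mixed(
            frame, mcmc=MCMCConfig(chains=2, draws=500, warmup=300), seed=2
        )
        mean = fit.coef_draws.mean(axis=0)
        sd = fit.coef_draws.std(axis=0)
        assert np.all(np.abs(mean - beta) < 4 * sd)
        assert abs(fit.sigma_eps_draws.mean() - 6.0) < 0.5
        assert abs(fit.sigma_b_draws.mean() - 4.0) < 0.8

    def test_zero_donor_variance_recovered(self):
        """True sigma_b = 0: the posterior must concentrate near zero (well
        below any realistic donor SD) and agree with the exact collapsed
        posterior computed on a (sigma_b, sigma_eps) grid."""
        df, names = simulate_lmm(1000, 7, np.array([140.0, 1.0]), sigma_b=0.0,
                                 sigma_eps=5.0, seed=3)
        frame = build_frame(df, df.groupby("donor_id").tail(1), names)
        fit = fit_linear_mixed(
            frame, mcmc=MCMCConfig(chains=2, draws=1200, warmup=400), seed=4
        )
        gibbs_mean = fit.sigma_b_draws.mean()
        gibbs_q95 = np.quantile(fit.sigma_b_draws, 0.95)
        assert gibbs_q95 < 1.0  # far below e.g. the generator's 6 g/L

        oracle_mean, oracle_q95 = _grid_posterior_sigma_b(df, names)
        assert gibbs_mean == pytest.approx(oracle_mean, abs=0.1)
        assert gibbs_q95 == pytest.approx(oracle_q95, abs=0.15)

    def test_duplicate_column_raises_rank_error(self):
        df, names = simulate_lmm(20, 4, np.array([140.0, 1.0]), 2.0, 3.0, seed=1)
        df["x0_copy"] = df["x0"]
        frame = build_frame(df, df.groupby("donor_id").tail(1),
                            names + ["x0_copy"])
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_mixed(frame, mcmc=MCMCConfig(chains=1, draws=10, warmup=5))

    def test_seeded_determinism(self):
        df, names = simulate_lmm(30, 4, np.array([140.0, 1.0]), 2.0, 3.0, seed=6)
        frame = build_frame(df, df.groupby("donor_id").tail(1), names)
        kw = dict(mcmc=MCMCConfig(chains=2, draws=100, warmup=50), seed=11)
        f1 = fit_linear_mixed(frame, **kw)
        f2 = fit_linear_mixed(frame, **kw)
        assert np.array_equal(f1.coef_draws, f2.coef_draws)
        assert np.array_equal(f1.sigma_b_draws, f2.sigma_b_draws)

    def test_dlmm_nests_lmm_when_lag_coefficient_pinned(self):
        """Pinning the previous-Hb coefficient at zero (near-zero prior SD)
        must reproduce the static model's posterior on the same rows."""
        rng = np.random.default_rng(16)
        df, names = simulate_lmm(200, 6, np.array([140.0, 2.0]), 3.0, 5.0, seed=15)
        df["previous_hb"] = rng.standard_normal(len(df))
        test = df.groupby("donor_id").tail(1)
        frame_d = build_frame(df, test, names + ["previous_hb"], dynamic=True)
        frame_s = build_frame(df, test, names)
        mc = MCMCConfig(chains=2, draws=1500, warmup=500)
        fit_pinned = fit_linear_mixed(
            frame_d,
            priors=Priors(coef_sd_overrides=(("previous_hb", 1e-8),)),
            mcmc=mc, seed=21,
        )
        fit_static = fit_linear_mixed(frame_s, mcmc=mc, seed=22)
        j = fit_pinned.variable_list.index("previous_hb")
        assert np.abs(fit_pinned.coef_draws[:, j]).max() < 1e-6
        for v in ("intercept", "x0"):
            a = fit_pinned.coef_draws[:, fit_pinned.variable_list.index(v)]
            b = fit_static.coef_draws[:, fit_static.variable_list.index(v)]
            se = np.sqrt(a.var() / len(a) + b.var() / len(b))
            assert abs(a.mean() - b.mean()) < 6 * se + 1e-3

    def test_save_writes_draws_table_and_sidecar(self, tmp_path):
        import json

        df, names = simulate_lmm(20, 4, np.array([140.0, 1.0]), 2.0, 3.0, seed=31)
        frame = build_frame(df, df.groupby("donor_id").tail(1), names)
        fit = fit_linear_mixed(frame, mcmc=MCMCConfig(chains=2, draws=50, warmup=25))
        draws_path, meta_path = fit.save(tmp_path / "fit")
        table = pd.read_csv(draws_path)
        assert set(table.columns) == {"chain", "draw", "parameter", "value"}
        assert set(table["parameter"]) == {
            "intercept", "x0", "sigma_b", "sigma_eps"
        }
        assert len(table) == 4 * 2 * 50  # params x chains x draws
        meta = json.loads(meta_path.read_text())
        assert meta["variable_list"] == ["intercept", "x0"]

    def test_diagnostics_reported_per_parameter(self):
        df, names = simulate_lmm(50, 5, np.array([140.0, 1.0]), 2.0, 3.0, seed=8)
        frame = build_frame(df, df.groupby("donor_id").tail(1), names)
        fit = fit_linear_mixed(frame, mcmc=MCMCConfig(chains=2, draws=200, warmup=150))
        assert set(fit.diagnostics["parameter"]) == {
            "intercept", "x0", "sigma_b", "sigma_eps"
        }
        assert fit.converged


def toy_fit(mu_draws, sigma_eps_draws, donor="dA"):
    """Hand-assembled single-donor LinearFit: intercept carries mu."""
    n = len(mu_draws)
    return LinearFit(
        variable_list=["intercept"],
        donor_ids=[donor],
        coef_draws=np.asarray(mu_draws, dtype=float)[:, None],
        b_draws=np.zeros((n, 1)),
        sigma_b_draws=np.ones(n),
        sigma_eps_draws=np.asarray(sigma_eps_draws, dtype=float),
        n_chains=1,
        scaling=Scaling(mean={}, std={}, binary={}),
        diagnostics=pd.DataFrame({"parameter": ["intercept"], "rhat": [1.0]}),
        dynamic=False,
        sex_stratum="female",
    )


def toy_test_frame(donor="dA", sex="female", hb=120.0):
    test = pd.DataFrame(
        {"donor_id": [donor], "sex": [sex], "hb": [hb], "deferred": [hb < 125]}
    )
    return build_frame(test.copy(), test, [])


class TestPosteriorPredict:
    def test_mu_at_limit_gives_half(self):
        fit = toy_fit([125.0, 125.0, 125.0], [5.0, 2.0, 9.0])
        pred = posterior_predict_last(fit, toy_test_frame())
        assert pred.frame["deferral_probability"].iloc[0] == pytest.approx(0.5)

    def test_vanishing_noise_far_above_limit(self):
        fit = toy_fit([135.0] * 3, [1e-9] * 3)
        pred = posterior_predict_last(fit, toy_test_frame())
        assert pred.frame["deferral_probability"].iloc[0] == pytest.approx(0.0)

    def test_three_draw_hand_average(self):
        mus, sds = [123.0, 126.0, 131.0], [4.0, 3.0, 5.0]
        fit = toy_fit(mus, sds)
        pred = posterior_predict_last(fit, toy_test_frame())
        hand = np.mean(
            [stats.norm.cdf((125.0 - m) / s) for m, s in zip(mus, sds)]
        )
        assert pred.frame["deferral_probability"].iloc[0] == pytest.approx(
            hand, abs=1e-12
        )
        assert pred.frame["predicted_hb"].iloc[0] == pytest.approx(np.mean(mus))

    def test_unknown_donor_rejected_unless_marginal(self):
        fit = toy_fit([125.0] * 3, [5.0] * 3)
        frame = toy_test_frame(donor="stranger")
        with pytest.raises(ValueError, match="without fitted intercepts"):
            posterior_predict_last(fit, frame)
        pred = posterior_predict_last(fit, frame, marginal_for_unseen=True)
        assert 0.0 < pred.frame["deferral_probability"].iloc[0] < 1.0


class TestBaseline:
    def test_slope_negative_on_simulated_cohort(self, filtered_cohort):
        frame = make_model_frame(
            filtered_cohort, ["previous_hb"], sex_stratum="female", dynamic=True
        )
        fit = fit_baseline_logistic(frame)
        assert fit.slope < 0

    def test_probabilities_monotone_decreasing(self):
        fit = BaselineFit(intercept=20.0, slope=-0.15, sex_stratum="both")
        x = np.array([110.0, 125.0, 140.0, 155.0])
        p = fit.probability(x)
        assert (np.diff(p) < 0).all()

    def test_logistic_midpoint(self):
        fit = BaselineFit(intercept=20.0, slope=-0.15, sex_stratum="both")
        assert fit.probability(np.array([20.0 / 0.15]))[0] == pytest.approx(0.5)

    def test_hand_evaluated_logistic(self):
        fit = BaselineFit(intercept=18.0, slope=-0.14, sex_stratum="both")
        x = np.array([120.0, 130.0, 140.0, 150.0])
        expected = 1.0 / (1.0 + np.exp(-(18.0 - 0.14 * x)))
        test = pd.DataFrame(
            {
                "donor_id": list("abcd"),
                "sex": ["female"] * 4,
                "hb": [130.0] * 4,
                "deferred": [False] * 4,
                "previous_hb": x,
            }
        )
        frame = build_frame(test.copy(), test, ["previous_hb"], dynamic=True)
        pred = predict_baseline(fit, frame)
        assert np.allclose(pred.frame["deferral_probability"], expected, atol=1e-9)
        assert pred.frame["predicted_hb"].isna().all()

    def test_all_accepted_labels_warn(self):
        df = pd.DataFrame(
            {
                "donor_id": list("aabb"),
                "sex": ["male"] * 4,
                "hb": [150.0] * 4,
                "deferred": [False] * 4,
                "previous_hb": [148.0, 149.0, 151.0, 150.0],
            }
        )
        frame = build_frame(df, df.groupby("donor_id").tail(1),
                            ["previous_hb"], dynamic=True)
        with pytest.warns(UserWarning, match="separation|degenerate"):
            fit = fit_baseline_logistic(frame)
        assert fit.separation_warning

    def test_missing_previous_hb_rejected(self):
        fit = BaselineFit(intercept=18.0, slope=-0.14, sex_stratum="both")
        test = pd.DataFrame(
            {
                "donor_id": ["a"],
                "sex": ["female"],
                "hb": [130.0],
                "deferred": [False],
                "previous_hb": [np.nan],
            }
        )
        frame = build_frame(test.copy(), test, ["previous_hb"], dynamic=True)
        with pytest.raises(ValueError):
            predict_baseline(fit, frame)


class TestEffectSizes:
    def test_binary_left_as_is_continuous_scaled(self):
        rng = np.random.default_rng(0)
        draws = np.column_stack(
            [np.full(1000, 1.7), np.full(1000, 1.0)]
        ) + rng.normal(0, 1e-9, (1000, 2))
        table = two_sd_effect_sizes(
            ["smoker", "weight"],
            draws,
            raw_sd={"smoker": 1.0, "weight": 2.0},
            binary={"smoker": True, "weight": False},
        )
        assert table.set_index("variable").loc["smoker", "mean"] == pytest.approx(
            1.7, abs=1e-6
        )
        assert table.set_index("variable").loc["weight", "mean"] == pytest.approx(
            4.0, abs=1e-6
        )

    def test_hpdi_matches_equal_tail_for_gaussian(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(3.0, 1.0, (20000, 1))
        table = two_sd_effect_sizes(
            ["x"], draws, raw_sd={"x": 0.5}, binary={"x": True}
        )
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert table["hpdi_low"].iloc[0] == pytest.approx(lo, abs=0.08)
        assert table["hpdi_high"].iloc[0] == pytest.approx(hi, abs=0.08)

    def test_fitted_model_effect_table(self, filtered_cohort):
        frame = make_model_frame(
            filtered_cohort, ["age", "warm_season"], sex_stratum="female",
            dynamic=True,
        )
        fit = fit_linear_mixed(
            frame, mcmc=MCMCConfig(chains=2, draws=300, warmup=200), seed=1
        )
        table = effect_sizes_2sd(fit)
        assert set(table["variable"]) == {"age", "warm_season", "previous_hb"}
        assert (table["hpdi_low"] <= table["mean"]).all()
        assert (table["mean"] <= table["hpdi_high"]).all()
        # the generator puts a -1.5 g/L warm-season effect in the data
        warm = table.set_index("variable").loc["warm_season"]
        assert warm["hpdi_high"] < 0.5
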