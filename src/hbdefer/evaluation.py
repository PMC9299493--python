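"""Metric suite with bootstrap uncertainty, and the savings-driven cutoff scan.

Hb prediction accuracy is measured with RMSE and MAE; deferral
classification with AUROC (Mann-Whitney formulation, tie midranks), AUPR
(precision-recall step integration) and F1 on the deferral class.
Confidence intervals are percentile bootstrap over donors.  The threshold
scan walks a probability-cutoff grid (default 0.02, 0.04, ..., 0.98),
converts each cutoff into a realized interval adjustment and avoided
deferral rate, and picks the cutoff minimizing the per-donation economic
effect E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import economics
from .economics import EconomicParams

__all__ = [
    "MetricReport",
    "ThresholdScan",
    "regression_metrics",
    "ranking_metrics",
    "f1_at_threshold",
    "bootstrap_ci",
    "threshold_scan",
    "default_grid",
    "metric_report",
]


def default_grid() -> np.ndarray:
    """Probability-cutoff candidates 0.02, 0.04, ..., 0.98."""
    return np.round(np.arange(0.02, 0.99, 0.02), 2)


@dataclass
class MetricReport:
    auroc: float
    aupr: float
    f1: float
    rmse: float | None
    mae: float | None
    ci: dict[str, tuple[float, float]]
    n_test: int
    sex_stratum: str
    threshold_used: float

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "f1": self.f1,
            "rmse": self.rmse,
            "mae": self.mae,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_test": self.n_test,
            "sex_stratum": self.sex_stratum,
            "threshold_used": self.threshold_used,
        }


@dataclass
class ThresholdScan:
    table: pd.DataFrame  # threshold, q, a_tot, E
    optimal_threshold: float
    optimal_E: float
    prolongation_days: int


def _frame(pred) -> pd.DataFrame:
    return pred.frame if hasattr(pred, "frame") else pred


def regression_metrics(pred) -> tuple[float, float]:
    """(RMSE, MAE) of predicted vs observed Hb over test rows."""
    df = _frame(pred)
    if len(df) == 0:
        raise ValueError("empty prediction set")
    if df["predicted_hb"].isna().all():
        raise ValueError("no Hb predictions (classifier-only prediction set)")
    err = df["predicted_hb"].to_numpy() - df["observed_hb"].to_numpy()
    return float(np.sqrt(np.mean(err**2))), float(np.mean(np.abs(err)))


def ranking_metrics(pred) -> tuple[float, float]:
    """(AUROC, AUPR) of the deferral probabilities.

    AUROC equals the Mann-Whitney pair statistic with ties counted half;
    AUPR is the step-integrated area under the precision-recall curve.
    """
    df = _frame(pred)
    y = df["observed_deferral"].to_numpy(dtype=int)
    s = df["deferral_probability"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes required for ranking metrics")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def f1_at_threshold(pred, threshold: float) -> float:
    """F1 of the deferral class at a probability cutoff.

    No predicted positives gives F1 = 0 with a warning.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    df = _frame(pred)
    y = df["observed_deferral"].to_numpy(dtype=bool)
    yhat = df["deferral_probability"].to_numpy() >= threshold
    tp = int((y & yhat).sum())
    fp = int((~y & yhat).sum())
    fn = int((y & ~yhat).sum())
    if tp + fp == 0:
        warnings.warn("no predicted positives; F1 reported as 0", stacklevel=2)
        return 0.0
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def bootstrap_ci(
    metric,
    pred,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric(pred)`` resampling donors.

    Replicates where the metric is undefined (e.g. a single-class resample
    for a ranking metric) are skipped; more than 20% skips is an error.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    df = _frame(pred).reset_index(drop=True)
    codes, _ = pd.factorize(df["donor_id"])
    row_lists = [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]
    n_donors = len(row_lists)
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(n_boot):
        sample = rng.integers(0, n_donors, size=n_donors)
        rows = np.concatenate([row_lists[c] for c in sample])
        boot = df.iloc[rows].reset_index(drop=True)
        try:
            vals.append(metric(boot))
        except ValueError:
            skipped += 1
    if skipped > 0.2 * n_boot:
        raise ValueError(
            f"{skipped}/{n_boot} bootstrap replicates undefined; "
            "metric not estimable on this prediction set"
        )
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def metric_report(
    pred,
    threshold: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
    sex_stratum: str = "both",
) -> MetricReport:
    """Full metric suite with 95% bootstrap CIs for one prediction set."""
    df = _frame(pred)
    auroc, aupr = ranking_metrics(df)
    f1 = f1_at_threshold(df, threshold)
    has_hb = not df["predicted_hb"].isna().all()
    rmse, mae = regression_metrics(df) if has_hb else (None, None)
    ci = {}
    specs = {
        "auroc": lambda d: ranking_metrics(d)[0],
        "aupr": lambda d: ranking_metrics(d)[1],
        "f1": lambda d: f1_at_threshold(d, threshold),
    }
    if has_hb:
        specs["rmse"] = lambda d: regression_metrics(d)[0]
        specs["mae"] = lambda d: regression_metrics(d)[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, (name, fn) in enumerate(specs.items()):
            ci[name] = bootstrap_ci(fn, df, n_boot=n_boot, seed=seed + i)
    return MetricReport(
        auroc=auroc,
        aupr=aupr,
        f1=f1,
        rmse=rmse,
        mae=mae,
        ci=ci,
        n_test=len(df),
        sex_stratum=sex_stratum,
        threshold_used=threshold,
    )


def threshold_scan(
    pred,
    histories: pd.DataFrame,
    econ: EconomicParams | None = None,
    prolongation_days: int = 183,
    grid: np.ndarray | None = None,
) -> ThresholdScan:
    """Scan probability cutoffs for the savings-optimal operating point.

    At each cutoff the flagged donors (predicted positive or observed
    deferred) receive the interval prolongation; the realized (a_tot, q)
    feed the economic model and the cutoff with minimal per-donation effect
    E wins, ties going to the smallest cutoff (flags more donors, the
    donor-health-conservative choice).
    """
    p = econ if econ is not None else EconomicParams()
    g = np.asarray(grid if grid is not None else default_grid(), dtype=float)
    if g.size == 0:
        raise ValueError("empty cutoff grid")
    if ((g <= 0) | (g >= 1)).any():
        raise ValueError("grid cutoffs must lie strictly inside (0, 1)")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for thr in g:
            a_tot, q = economics.realized_adjustment_and_avoidance(
                pred, histories, thr, prolongation_days
            )
            e = economics.economic_effect(p.with_operating_point(a_tot, q))
            rows.append((float(thr), q, a_tot, e))
    table = pd.DataFrame(rows, columns=["threshold", "q", "a_tot", "E"])
    best = int(np.argmin(table["E"].to_numpy()))  # argmin takes first = smallest
    return ThresholdScan(
        table=table,
        optimal_threshold=float(table["threshold"].iloc[best]),
        optimal_E=float(table["E"].iloc[best]),
        prolongation_days=prolongation_days,
    )
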