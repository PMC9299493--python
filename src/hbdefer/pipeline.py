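"""End-to-end experiment orchestration.

One call simulates a cohort, cleans and derives variables, fits the
previous-Hb logistic baseline, the LMM, the DLMM (sex-stratified) and the
joint random forest, evaluates every model on the identical held-out last
donations, runs the probability-cutoff scan for both 6- and 12-month
prolongations, and reports the per-donation economic effect at each model's
optimal operating point.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import economics, evaluation, forest, linear, preprocessing
from .economics import EconomicParams
from .linear import MCMCConfig, Priors
from .preprocessing import ModelFrame
from .synthetic import Dataset, SimConfig, simulate_population, write_dataset

__all__ = [
    "ExperimentConfig",
    "RunReport",
    "run_full_pipeline",
    "series_length_experiment",
    "enrichment_experiment",
    "prepare_dataset",
]

log = logging.getLogger("hbdefer")

LMM_VARIABLES = ["age", "warm_season", "days_to_previous", "lifetime_donations"]
DONOR_VARIABLES = ["height", "weight", "smoking", "snp_dosage", "polygenic_score"]


@dataclass
class ExperimentConfig:
    """Every tunable of the full pipeline, with defaults."""

    sim: SimConfig = field(default_factory=lambda: SimConfig(n_donors=2000))
    min_series_length: int = 7
    enrichment_fraction: float | None = None  # None: no enrichment (default)
    use_exploration_split: bool = False
    split_seed: int = 0
    lmm_variables: list[str] = field(default_factory=lambda: list(LMM_VARIABLES))
    donor_variables: list[str] = field(default_factory=lambda: list(DONOR_VARIABLES))
    include_donor_covariates: bool = True
    priors: Priors = field(default_factory=Priors)
    mcmc: MCMCConfig = field(default_factory=lambda: MCMCConfig(chains=2, draws=400, warmup=300))
    forest_grid: list[dict] | None = None
    forest_trees: int = 300
    n_boot: int = 200
    cutoff_grid: list[float] | None = None
    econ: EconomicParams = field(default_factory=EconomicParams)
    prolongations: tuple[int, ...] = (183, 365)
    models: tuple[str, ...] = ("baseline", "lmm", "dlmm", "forest")
    seed: int = 0

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    metrics: dict[str, evaluation.MetricReport]
    scans: dict[str, dict[int, evaluation.ThresholdScan]]  # model -> days -> scan
    econ_results: dict[str, dict[int, economics.EconomicResult]]
    cleaning: preprocessing.CleaningReport
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "metrics": {m: r.to_dict() for m, r in self.metrics.items()},
            "scans": {
                m: {
                    str(d): {
                        "optimal_threshold": s.optimal_threshold,
                        "optimal_E": s.optimal_E,
                        "table": s.table.to_dict(orient="list"),
                    }
                    for d, s in per.items()
                }
                for m, per in self.scans.items()
            },
            "economics": {
                m: {
                    str(d): {
                        "a_tot": r.params.a_tot,
                        "q": r.params.q,
                        "E": r.E,
                        "break_even_q": r.break_even_q,
                    }
                    for d, r in per.items()
                }
                for m, per in self.econ_results.items()
            },
            "cleaning": asdict(self.cleaning),
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def prepare_dataset(
    config: ExperimentConfig,
) -> tuple[Dataset, preprocessing.CleaningReport]:
    """Simulate, clean, derive, label and series-length-filter a cohort."""
    ds = simulate_population(config.sim)
    log.info("simulated %d records from %d donors", ds.n_records, ds.n_donors)
    ds, report = preprocessing.validate_and_clean(ds)
    ds = preprocessing.derive_variables(ds)
    ds = preprocessing.label_deferrals(ds)
    ds = preprocessing.filter_min_series_length(ds, config.min_series_length)
    log.info(
        "after series-length filter (k=%d): %d records, %d donors",
        config.min_series_length, ds.n_records, ds.n_donors,
    )
    if config.use_exploration_split:
        _, ds = preprocessing.split_exploration_final(ds, seed=config.split_seed)
    if config.enrichment_fraction is not None:
        ds = preprocessing.enrich_deferral_donors(
            ds, config.enrichment_fraction, seed=config.split_seed
        )
    return ds, report


def _linear_predictions(
    ds: Dataset, config: ExperimentConfig, dynamic: bool, seed: int
) -> tuple[linear.PredictionSet, dict[str, linear.LinearFit]]:
    """Sex-stratified (D)LMM fits; concatenated test predictions."""
    variables = list(config.lmm_variables)
    if config.include_donor_covariates:
        variables += config.donor_variables
    preds, fits = [], {}
    for i, sex in enumerate(("female", "male")):
        frame = preprocessing.make_model_frame(
            ds, variables, sex_stratum=sex, dynamic=dynamic
        )
        fit = linear.fit_linear_mixed(
            frame,
            priors=config.priors,
            mcmc=config.mcmc,
            seed=seed + i,
            donor_constant_vars=[
                v for v in config.donor_variables if v in frame.variable_list
            ],
        )
        fits[sex] = fit
        preds.append(linear.posterior_predict_last(fit, frame).frame)
    return linear.PredictionSet(pd.concat(preds, ignore_index=True)), fits


def _baseline_predictions(ds: Dataset, config: ExperimentConfig) -> linear.PredictionSet:
    preds = []
    for sex in ("female", "male"):
        frame = preprocessing.make_model_frame(
            ds, ["previous_hb"], sex_stratum=sex, dynamic=True
        )
        fit = linear.fit_baseline_logistic(frame)
        preds.append(linear.predict_baseline(fit, frame).frame)
    return linear.PredictionSet(pd.concat(preds, ignore_index=True))


def _forest_predictions(
    ds: Dataset, config: ExperimentConfig, seed: int
) -> tuple[linear.PredictionSet, forest.ForestFit]:
    df = ds.donations.sort_values(["donor_id", "date"], kind="stable")
    is_last = df.groupby("donor_id").cumcount(ascending=False) == 0
    train = df[~is_last].reset_index(drop=True)
    test = df[is_last].reset_index(drop=True)
    table = forest.build_event_table(train)
    grid = config.forest_grid if config.forest_grid is not None else forest.DEFAULT_GRID
    fit = forest.fit_random_forest_oversampled(
        table, grid=grid, seed=seed, n_estimators=config.forest_trees
    )
    return forest.predict_forest(fit, test), fit


def run_full_pipeline(config: ExperimentConfig | None = None) -> RunReport:
    """Simulate -> preprocess -> fit all models -> evaluate -> economics.

    All models are scored on the identical test rows (each donor's last
    donation); deterministic given ``config.seed``.
    """
    config = config or ExperimentConfig()
    rng = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(4)]

    ds, cleaning = prepare_dataset(config)
    histories = ds.donations

    predictions: dict[str, linear.PredictionSet] = {}
    for model in config.models:
        log.info("fitting model: %s", model)
        if model == "baseline":
            predictions[model] = _baseline_predictions(ds, config)
        elif model == "lmm":
            predictions[model], _ = _linear_predictions(
                ds, config, dynamic=False, seed=seeds[0]
            )
        elif model == "dlmm":
            predictions[model], _ = _linear_predictions(
                ds, config, dynamic=True, seed=seeds[1]
            )
        elif model == "forest":
            predictions[model], _ = _forest_predictions(ds, config, seed=seeds[2])
        else:
            raise ValueError(f"unknown model {model!r}")

    grid = (
        np.asarray(config.cutoff_grid, dtype=float)
        if config.cutoff_grid is not None
        else evaluation.default_grid()
    )
    metrics, scans, econ_results = {}, {}, {}
    for model, pred in predictions.items():
        scans[model] = {}
        econ_results[model] = {}
        for days in config.prolongations:
            scan = evaluation.threshold_scan(
                pred, histories, config.econ, prolongation_days=days, grid=grid
            )
            scans[model][days] = scan
            row = scan.table[scan.table["threshold"] == scan.optimal_threshold].iloc[0]
            econ_results[model][days] = economics.evaluate(
                config.econ.with_operating_point(float(row["a_tot"]), float(row["q"]))
            )
        thr = scans[model][config.prolongations[0]].optimal_threshold
        metrics[model] = evaluation.metric_report(
            pred, threshold=thr, n_boot=config.n_boot, seed=seeds[3]
        )
        log.info(
            "%s: AUROC %.3f, optimal cutoff %.2f, E %.4f eur/donation",
            model, metrics[model].auroc, thr,
            scans[model][config.prolongations[0]].optimal_E,
        )

    test_hashes = {}
    for model, pred in predictions.items():
        key = pred.frame[["donor_id", "observed_hb", "observed_deferral"]]
        key = key.sort_values("donor_id").reset_index(drop=True)
        test_hashes[model] = hashlib.sha256(
            pd.util.hash_pandas_object(key, index=False).to_numpy().tobytes()
        ).hexdigest()

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": _package_version(),
        "n_test_donors": int(next(iter(predictions.values())).frame.shape[0]),
        "test_hashes": test_hashes,
    }
    return RunReport(
        metrics=metrics,
        scans=scans,
        econ_results=econ_results,
        cleaning=cleaning,
        provenance=provenance,
    )


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("hbdefer")
    except Exception:
        return "unknown"


def series_length_experiment(
    ds: Dataset,
    lengths: list[int],
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """DLMM last-event prediction per exact time-series length.

    Each subset holds only donors with exactly that many attempts.  Subsets
    too small (or single-class) to fit or score are recorded as missing
    rows, never fatal.
    """
    config = config or ExperimentConfig()
    rows = []
    counts = ds.donations.groupby("donor_id").size()
    variables = list(config.lmm_variables)
    for L in lengths:
        if L < 3:
            raise ValueError(f"series length must be >= 3, got {L}")
        donors = counts[counts == L].index
        sub = ds.donations[ds.donations["donor_id"].isin(donors)]
        row = {"length": L, "n_donors": len(donors), "rmse": np.nan,
               "mae": np.nan, "auroc": np.nan}
        if len(donors) >= 10:
            try:
                frame = preprocessing.make_model_frame(
                    Dataset(sub, ds.donors), variables, dynamic=True
                )
                fit = linear.fit_linear_mixed(
                    frame, priors=config.priors, mcmc=config.mcmc, seed=config.seed
                )
                pred = linear.posterior_predict_last(fit, frame)
                row["rmse"], row["mae"] = evaluation.regression_metrics(pred)
                try:
                    row["auroc"], _ = evaluation.ranking_metrics(pred)
                except ValueError:
                    pass
            except ValueError as err:
                log.warning("length %d subset not fittable: %s", L, err)
        rows.append(row)
    return pd.DataFrame(rows)


def enrichment_experiment(
    ds: Dataset,
    fractions: list[float | None],
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """DLMM metrics per deferral-donor enrichment level of the training set.

    ``None`` in ``fractions`` is the natural (unenriched) control.  The test
    rows — every donor's last donation — are identical across levels; only
    the training rows are restricted to the enriched donor subset, and test
    donors dropped from training are predicted marginally (random intercept
    integrated out).
    """
    config = config or ExperimentConfig()
    variables = list(config.lmm_variables)
    base_frame = preprocessing.make_model_frame(ds, variables, dynamic=True)
    test_hash = hashlib.sha256(
        pd.util.hash_pandas_object(
            base_frame.test_rows[["donor_id", "hb"]], index=False
        ).to_numpy().tobytes()
    ).hexdigest()

    rows = []
    for frac in fractions:
        frame = preprocessing.make_model_frame(ds, variables, dynamic=True)
        if frac is not None:
            enriched = preprocessing.enrich_deferral_donors(
                ds, frac, seed=config.split_seed
            )
            keep = set(enriched.donations["donor_id"].unique())
            frame.train_rows = frame.train_rows[
                frame.train_rows["donor_id"].isin(keep)
            ].reset_index(drop=True)
        fit = linear.fit_linear_mixed(
            frame, priors=config.priors, mcmc=config.mcmc, seed=config.seed
        )
        pred = linear.posterior_predict_last(fit, frame, marginal_for_unseen=True)
        rmse, mae = evaluation.regression_metrics(pred)
        try:
            auroc, aupr = evaluation.ranking_metrics(pred)
        except ValueError:
            auroc, aupr = np.nan, np.nan
        train_def_frac = (
            frame.train_rows.groupby("donor_id")["deferred"].any().mean()
        )
        rows.append(
            {
                "fraction": np.nan if frac is None else frac,
                "train_deferral_donor_fraction": float(train_def_frac),
                "rmse": rmse,
                "mae": mae,
                "auroc": auroc,
                "aupr": aupr,
                "test_hash": test_hash,
            }
        )
    return pd.DataFrame(rows)


def save_report(report: RunReport, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "run_report.json"
    path.write_text(report.to_json())
    for model, per in report.scans.items():
        for days, scan in per.items():
            scan.table.to_csv(
                outdir / f"threshold_scan_{model}_{days}d.csv", index=False
            )
    return path
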