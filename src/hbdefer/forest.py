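"""Random-forest deferral classifier with donor-level deferral oversampling.

Deferrals are rare (~3% of attempts), so training data for the forest are
rebalanced at the *donor* level: donors whose last donation was a deferral
are oversampled until they make up a target fraction (default 50%) of the
bootstrap, with each sampled donor contributing all of their usable events.
The forest itself cannot model a time series, so each donation event is
augmented with the previous Hb and the lifetime donation count.

One joint model covers both sexes, with sex as a predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold

from .synthetic import Dataset

__all__ = [
    "EventTable",
    "ForestFit",
    "build_event_table",
    "oversample_donor_balanced",
    "fit_random_forest_oversampled",
    "predict_forest",
    "DEFAULT_GRID",
]

DEFAULT_FEATURES = [
    "sex",
    "age",
    "previous_hb",
    "days_to_previous",
    "warm_season",
    "lifetime_donations",
    "hour",
]

# small default search grid: features per split x minimum node size
DEFAULT_GRID = [
    {"max_features": mf, "min_samples_leaf": msl}
    for mf in ("sqrt", 0.5, 1.0)
    for msl in (1, 5, 25)
]


@dataclass
class EventTable:
    """Flat per-event table for the forest: features + deferral label.

    First events per donor are excluded (no previous Hb); ``donor_id`` is
    retained for donor-level sampling and grouped cross-validation.
    """

    frame: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.frame["previous_hb"].isna().any():
            raise ValueError("event table rows must have previous_hb")

    @property
    def n_rows(self) -> int:
        return len(self.frame)


@dataclass
class ForestFit:
    model: RandomForestClassifier
    feature_names: list[str]
    hyperparameters: dict
    importances: pd.DataFrame  # variable, importance
    oversample_fraction: float
    cv_results: pd.DataFrame | None = None
    category_levels: dict[str, list] = field(default_factory=dict)


def build_event_table(
    data: Dataset | pd.DataFrame, variables: list[str] | None = None
) -> EventTable:
    """Flatten a derived dataset into per-event classifier rows.

    Each usable event carries the configured features plus the previous Hb
    and lifetime donation index; the first event of every donor is dropped.
    """
    df = data.donations if isinstance(data, Dataset) else data
    feats = list(variables) if variables is not None else list(DEFAULT_FEATURES)
    for required in ("previous_hb", "lifetime_donations"):
        if required not in feats:
            feats.append(required)
    missing = [v for v in feats if v not in df.columns]
    if missing:
        raise ValueError(f"missing derived column(s): {missing}")
    keep = df[df["previous_hb"].notna()].copy()
    table = keep[["donor_id", "deferred"] + feats].reset_index(drop=True)
    return EventTable(frame=table, feature_names=feats)


def _donor_last_label(frame: pd.DataFrame) -> pd.Series:
    """Per donor: whether the last (usable) event is a deferral."""
    last = frame.groupby("donor_id").tail(1)
    return last.set_index("donor_id")["deferred"].astype(bool)


def oversample_donor_balanced(
    table: EventTable, target_fraction: float = 0.5, seed: int = 0
) -> EventTable:
    """Donor-level bootstrap balancing last-event deferral status.

    Draws donors with replacement so that in expectation ``target_fraction``
    of sampled donors have a deferral as their last event; every event of a
    sampled donor enters together.  Field values are never modified.
    """
    labels = _donor_last_label(table.frame)
    pos = labels[labels].index.to_numpy()
    neg = labels[~labels].index.to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            "both donor classes (last event deferred / accepted) required"
        )
    n_total = len(labels)
    rng = np.random.default_rng(seed)
    n_pos = rng.binomial(n_total, target_fraction)
    sampled = np.concatenate(
        [
            rng.choice(pos, size=n_pos, replace=True),
            rng.choice(neg, size=n_total - n_pos, replace=True),
        ]
    )
    groups = {d: g for d, g in table.frame.groupby("donor_id")}
    out = pd.concat([groups[d] for d in sampled], ignore_index=True)
    return EventTable(frame=out, feature_names=table.feature_names)


def _encode(frame: pd.DataFrame, feats: list[str],
            levels: dict[str, list] | None = None) -> tuple[np.ndarray, dict]:
    """Categorical features to integer codes; unseen levels map to -1."""
    out_levels = {} if levels is None else levels
    cols = []
    for v in feats:
        col = frame[v]
        if col.dtype == object or col.dtype.name in ("category", "string"):
            if levels is None:
                lv = sorted(col.dropna().unique().tolist())
                out_levels[v] = lv
            else:
                lv = levels.get(v, [])
            mapping = {x: i for i, x in enumerate(lv)}
            cols.append(col.map(mapping).fillna(-1).to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols), out_levels


def fit_random_forest_oversampled(
    table: EventTable,
    grid: list[dict] | None = None,
    n_folds: int = 4,
    seed: int = 0,
    n_estimators: int = 300,
    oversample_fraction: float = 0.5,
) -> ForestFit:
    """Tune and fit the forest on a donor-balanced bootstrap.

    Hyperparameters are selected by donor-grouped ``n_folds``-fold
    cross-validation maximizing AUROC on the *natural* (un-oversampled)
    held-out fold; the final model is refit on an oversampled bootstrap of
    the full table.  No donor's rows are ever split across folds.
    """
    grid = grid if grid is not None else DEFAULT_GRID
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    frame = table.frame
    X, levels = _encode(frame, table.feature_names)
    y = frame["deferred"].to_numpy(dtype=int)
    donors = frame["donor_id"].to_numpy()

    cv_rows = []
    if len(grid) == 1:
        best = grid[0]
        cv_results = None
    else:
        gkf = GroupKFold(n_splits=n_folds)
        folds = list(gkf.split(X, y, groups=donors))
        for fi, (_, te) in enumerate(folds):
            if y[te].sum() == 0 or y[te].sum() == len(te):
                raise ValueError(
                    f"cross-validation fold {fi} has a single class; "
                    "more data (or fewer folds) needed"
                )
        for gi, params in enumerate(grid):
            aucs = []
            for fi, (tr, te) in enumerate(folds):
                sub = EventTable(
                    frame.iloc[tr].reset_index(drop=True), table.feature_names
                )
                samp = oversample_donor_balanced(
                    sub, oversample_fraction, seed=seed * 1009 + gi * 31 + fi
                )
                Xs, _ = _encode(samp.frame, table.feature_names, levels)
                ys = samp.frame["deferred"].to_numpy(dtype=int)
                rf = RandomForestClassifier(
                    n_estimators=n_estimators,
                    random_state=seed + gi,
                    n_jobs=1,
                    **params,
                ).fit(Xs, ys)
                aucs.append(roc_auc_score(y[te], rf.predict_proba(X[te])[:, 1]))
            cv_rows.append({**params, "cv_auroc": float(np.mean(aucs))})
        cv_results = pd.DataFrame(cv_rows)
        best = grid[int(cv_results["cv_auroc"].idxmax())]

    sampled = oversample_donor_balanced(table, oversample_fraction, seed=seed)
    Xs, _ = _encode(sampled.frame, table.feature_names, levels)
    ys = sampled.frame["deferred"].to_numpy(dtype=int)
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, **best
    ).fit(Xs, ys)
    importances = pd.DataFrame(
        {"variable": table.feature_names, "importance": model.feature_importances_}
    ).sort_values("importance", ascending=False, ignore_index=True)
    return ForestFit(
        model=model,
        feature_names=table.feature_names,
        hyperparameters=dict(best),
        importances=importances,
        oversample_fraction=oversample_fraction,
        cv_results=cv_results,
        category_levels=levels,
    )


def predict_forest(fit: ForestFit, test: pd.DataFrame):
    """Per-row deferral probability = ensemble vote fraction.

    Unseen categorical levels are mapped to a designated out-of-vocabulary
    code with a warning.
    """
    import warnings

    from .linear import PredictionSet

    missing = [v for v in fit.feature_names if v not in test.columns]
    if missing:
        raise ValueError(f"test rows lack trained feature(s): {missing}")
    for v, lv in fit.category_levels.items():
        unseen = set(test[v].dropna().unique()) - set(lv)
        if unseen:
            warnings.warn(
                f"unseen level(s) in {v!r} mapped to 'other': {sorted(unseen)}",
                stacklevel=2,
            )
    X, _ = _encode(test, fit.feature_names, fit.category_levels)
    prob = fit.model.predict_proba(X)[:, 1]
    out = pd.DataFrame(
        {
            "donor_id": test["donor_id"].to_numpy(),
            "sex": test["sex"].to_numpy(),
            "observed_hb": test["hb"].to_numpy(dtype=float)
            if "hb" in test
            else np.nan,
            "observed_deferral": test["deferred"].to_numpy(dtype=bool),
            "predicted_hb": np.nan,
            "deferral_probability": prob,
        }
    )
    return PredictionSet(out)
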