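"""Cleaning, derived variables and cohort construction for donation tables.

Philosophy: drop, never impute.  Rows with missing haemoglobin, sex or date,
implausible haemoglobin, or out-of-order within-donor dates are removed and
tallied in a :class:`CleaningReport`.  Derived variables (previous Hb, days
to previous attempt, warm season, lifetime donation index, age at donation)
are exact functions of the retained rows.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .synthetic import Dataset

__all__ = [
    "CleaningReport",
    "ModelFrame",
    "validate_and_clean",
    "derive_variables",
    "label_deferrals",
    "filter_min_series_length",
    "enrich_deferral_donors",
    "split_exploration_final",
    "subsample_donors",
    "make_model_frame",
    "DEFERRAL_LIMITS",
]

DEFERRAL_LIMITS = {"male": 135.0, "female": 125.0}
DEFAULT_HB_RANGE = (25.0, 250.0)


@dataclass(frozen=True)
class CleaningReport:
    n_input_records: int
    n_dropped_missing: int
    n_dropped_outlier: int
    n_dropped_other: int
    n_output_records: int
    n_output_donors: int

    def __post_init__(self) -> None:
        dropped = self.n_dropped_missing + self.n_dropped_outlier + self.n_dropped_other
        assert self.n_output_records == self.n_input_records - dropped

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class Scaling:
    """Per-variable centring/scaling computed on training rows only."""

    mean: dict[str, float]
    std: dict[str, float]
    binary: dict[str, bool]

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for v, m in self.mean.items():
            s = self.std[v]
            out[v] = (out[v] - m) / (s if s > 0 else 1.0)
        return out

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for v, m in self.mean.items():
            s = self.std[v]
            out[v] = out[v] * (s if s > 0 else 1.0) + m
        return out


@dataclass
class ModelFrame:
    """Design frame for last-event prediction.

    Each donor's final attempt forms the single test row; the remaining
    attempts are training rows.  With ``dynamic=True`` the previous Hb is a
    design variable, so each donor's first attempt (which has no lag) is
    unusable for training.  Continuous design variables are standardized
    with training-row statistics stored in ``scaling``.
    """

    train_rows: pd.DataFrame
    test_rows: pd.DataFrame
    variable_list: list[str]
    sex_stratum: str
    dynamic: bool
    scaling: Scaling

    def __post_init__(self) -> None:
        train_ids = set(self.train_rows["donor_id"])
        missing = set(self.test_rows["donor_id"]) - train_ids
        if missing:
            raise ValueError(
                f"test donors without training rows: {sorted(missing)[:5]}"
            )


def _donations(data: Dataset | pd.DataFrame) -> pd.DataFrame:
    return data.donations if isinstance(data, Dataset) else data


def _wrap(data: Dataset | pd.DataFrame, donations: pd.DataFrame):
    if isinstance(data, Dataset):
        keep = donations["donor_id"].unique()
        donors = data.donors[data.donors["donor_id"].isin(keep)]
        return Dataset(donations, donors)
    return donations.reset_index(drop=True)


def validate_and_clean(
    raw: Dataset | pd.DataFrame,
    plausibility_range: tuple[float, float] = DEFAULT_HB_RANGE,
) -> tuple[Dataset | pd.DataFrame, CleaningReport]:
    """Drop (never impute) problematic rows and tally each cause.

    Causes, applied in order: missing Hb/sex/date; Hb outside the
    plausibility range; rows breaking strictly increasing within-donor date
    order (later duplicate/backward rows are dropped, counted as 'other').
    """
    df = _donations(raw).copy()
    n_in = len(df)
    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    df["hb"] = pd.to_numeric(df["hb"], errors="coerce")

    missing = df["hb"].isna() | df["sex"].isna() | df["date"].isna()
    if "sex" in df:
        missing |= ~df["sex"].isin(["male", "female"]) & df["sex"].notna()
    n_missing = int(missing.sum())
    df = df[~missing]

    lo, hi = plausibility_range
    outlier = (df["hb"] < lo) | (df["hb"] > hi)
    n_outlier = int(outlier.sum())
    df = df[~outlier]

    # enforce strictly increasing dates within donor, keeping earliest rows
    df = df.sort_values(["donor_id", "date"], kind="stable")
    prev = df.groupby("donor_id")["date"].shift()
    bad_order = prev.notna() & (df["date"] <= prev)
    # iterate: dropping a row can repair later comparisons, never break them
    n_other = 0
    while bad_order.any():
        n_other += int(bad_order.sum())
        df = df[~bad_order]
        prev = df.groupby("donor_id")["date"].shift()
        bad_order = prev.notna() & (df["date"] <= prev)

    df = df.reset_index(drop=True)
    report = CleaningReport(
        n_input_records=n_in,
        n_dropped_missing=n_missing,
        n_dropped_outlier=n_outlier,
        n_dropped_other=n_other,
        n_output_records=len(df),
        n_output_donors=df["donor_id"].nunique(),
    )
    return _wrap(raw, df), report


def derive_variables(data: Dataset | pd.DataFrame) -> Dataset | pd.DataFrame:
    """Fill previous_hb, days_to_previous, warm_season, lifetime_donations.

    First event per donor has absent lags.  warm_season is April-September.
    Existing values of these columns are recomputed from scratch.
    """
    df = _donations(data).copy()
    df = df.sort_values(["donor_id", "date"], kind="stable").reset_index(drop=True)
    g = df.groupby("donor_id", sort=False)
    df["previous_hb"] = g["hb"].shift()
    df["days_to_previous"] = (df["date"] - g["date"].shift()).dt.days.astype(float)
    df["warm_season"] = df["date"].dt.month.between(4, 9)
    df["lifetime_donations"] = g.cumcount() + 1
    return _wrap(data, df)


def label_deferrals(
    data: Dataset | pd.DataFrame, limits: dict[str, float] | None = None
) -> Dataset | pd.DataFrame:
    """Label deferred := hb strictly below the sex-specific limit.

    A measured Hb exactly at the limit is an acceptance (the limits are
    phrased as acceptance thresholds).
    """
    lims = limits if limits is not None else DEFERRAL_LIMITS
    df = _donations(data).copy()
    unknown = set(df["sex"].unique()) - set(lims)
    if unknown:
        raise ValueError(f"unknown sex code(s): {sorted(unknown)}")
    df["deferred"] = df["hb"] < df["sex"].map(lims)
    return _wrap(data, df)


def filter_min_series_length(
    data: Dataset | pd.DataFrame, k: int
) -> Dataset | pd.DataFrame:
    """Keep only donors with at least ``k`` attempts (all attempts kept).

    k must be >= 3: predicting the last event of a series needs at least two
    prior events, so three is the minimum usable series length.
    """
    if k < 3:
        raise ValueError(f"minimum series length must be >= 3, got {k}")
    df = _donations(data)
    counts = df.groupby("donor_id")["donor_id"].transform("size")
    return _wrap(data, df[counts >= k].reset_index(drop=True))


def enrich_deferral_donors(
    data: Dataset | pd.DataFrame, target_fraction: float, seed: int = 0
) -> Dataset | pd.DataFrame:
    """Raise the fraction of donors with >=1 deferral by dropping others.

    All donors with at least one deferral are kept; zero-deferral donors are
    randomly subsampled so the deferral-donor fraction lands as close as
    possible to ``target_fraction`` (never above by dropping deferral
    donors).  Event sequences of kept donors are untouched.
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError(f"target_fraction must be in (0, 1], got {target_fraction}")
    df = _donations(data)
    has_def = df.groupby("donor_id")["deferred"].any()
    def_donors = has_def[has_def].index.to_numpy()
    other_donors = has_def[~has_def].index.to_numpy()
    if len(def_donors) == 0:
        raise ValueError("no donors with a deferral; cannot enrich")
    n_def = len(def_donors)
    # choose n_other so n_def / (n_def + n_other) ~= target_fraction
    n_other = min(int(round(n_def * (1.0 - target_fraction) / target_fraction)),
                  len(other_donors))
    rng = np.random.default_rng(seed)
    kept_other = rng.choice(other_donors, size=n_other, replace=False)
    keep = set(def_donors) | set(kept_other)
    return _wrap(data, df[df["donor_id"].isin(keep)].reset_index(drop=True))


def split_exploration_final(
    data: Dataset | pd.DataFrame, seed: int = 0
) -> tuple[Dataset | pd.DataFrame, Dataset | pd.DataFrame]:
    """Donor-level partition into two equal halves (sizes differ by <= 1)."""
    df = _donations(data)
    donors = np.sort(df["donor_id"].unique())
    if len(donors) < 2:
        raise ValueError("need at least 2 donors to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(donors)
    half = (len(donors) + 1) // 2
    first = set(perm[:half])
    a = df[df["donor_id"].isin(first)].reset_index(drop=True)
    b = df[~df["donor_id"].isin(first)].reset_index(drop=True)
    return _wrap(data, a), _wrap(data, b)


def subsample_donors(
    data: Dataset | pd.DataFrame, n: int, seed: int = 0
) -> Dataset | pd.DataFrame:
    """Uniform seeded sample of ``n`` donors; all their events are kept."""
    df = _donations(data)
    donors = np.sort(df["donor_id"].unique())
    if n > len(donors):
        raise ValueError(f"requested {n} donors, only {len(donors)} available")
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(donors, size=n, replace=False))
    return _wrap(data, df[df["donor_id"].isin(keep)].reset_index(drop=True))


BINARY_VARIABLES = {"warm_season", "smoking", "sex_female"}


def make_model_frame(
    data: Dataset | pd.DataFrame,
    variables: list[str],
    sex_stratum: str = "both",
    dynamic: bool = False,
    donor_covariates: pd.DataFrame | None = None,
) -> ModelFrame:
    """Build the last-event-prediction design frame.

    Per donor the final attempt becomes the test row and the remaining
    attempts training rows; with ``dynamic`` the previous Hb joins the
    design, making each donor's first attempt unusable for training.
    Continuous variables are standardized using training-row mean/SD only
    (no test leakage); binary variables are left on their 0/1 scale.
    """
    df = _donations(data)
    if donor_covariates is None and isinstance(data, Dataset):
        donor_covariates = data.donors
    if donor_covariates is not None:
        df = df.merge(donor_covariates, on="donor_id", how="left")
    if sex_stratum in ("male", "female"):
        df = df[df["sex"] == sex_stratum]
    elif sex_stratum != "both":
        raise ValueError(f"sex_stratum must be male/female/both, got {sex_stratum!r}")
    df = df.copy()
    df["sex_female"] = (df["sex"] == "female").astype(float)

    design_vars = list(variables)
    if dynamic and "previous_hb" not in design_vars:
        design_vars.append("previous_hb")
    missing = [v for v in design_vars if v not in df.columns]
    if missing:
        raise ValueError(f"requested variable(s) absent: {missing}")

    df = df.sort_values(["donor_id", "date"], kind="stable")
    counts = df.groupby("donor_id")["donor_id"].transform("size")
    df = df[counts >= 3]
    is_last = df.groupby("donor_id").cumcount(ascending=False) == 0
    test = df[is_last]
    train = df[~is_last]
    # drop-not-impute: training rows with any missing design value (e.g. the
    # lag-free first event) are excluded
    train = train[train[design_vars].notna().all(axis=1)]
    if test[design_vars].isna().any().any():
        bad = test[design_vars].isna().any()
        raise ValueError(
            f"missing values in test-row design variables: {list(bad[bad].index)}"
        )

    # a constant column is collinear with the intercept and cannot be
    # standardized; drop it rather than failing downstream
    constant = [v for v in design_vars if train[v].nunique() <= 1]
    if constant:
        import warnings

        warnings.warn(
            f"dropping constant design variable(s): {constant}", stacklevel=2
        )
        design_vars = [v for v in design_vars if v not in constant]

    mean, std, binary = {}, {}, {}
    for v in design_vars:
        if v in BINARY_VARIABLES or set(train[v].unique()) <= {0, 1, 0.0, 1.0, True, False}:
            binary[v] = True
        else:
            binary[v] = False
            mean[v] = float(train[v].mean())
            std[v] = float(train[v].std(ddof=0))
    scaling = Scaling(mean=mean, std=std, binary=binary)

    train_scaled = scaling.transform(train.reset_index(drop=True))
    test_scaled = scaling.transform(test.reset_index(drop=True))
    for part in (train_scaled, test_scaled):
        for v in design_vars:
            part[v] = part[v].astype(float)
    return ModelFrame(
        train_rows=train_scaled,
        test_rows=test_scaled,
        variable_list=design_vars,
        sex_stratum=sex_stratum,
        dynamic=dynamic,
        scaling=scaling,
    )
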