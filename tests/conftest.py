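import numpy as np
import pandas as pd
import pytest

from hbdefer import preprocessing as pp
from hbdefer.synthetic import Dataset, SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_cohort() -> Dataset:
    """800-donor simulated cohort, cleaned, derived and labelled."""
    ds = simulate_population(SimConfig(n_donors=800, seed=20260923))
    ds, _ = pp.validate_and_clean(ds)
    ds = pp.derive_variables(ds)
    ds = pp.label_deferrals(ds)
    return ds


@pytest.fixture(scope="session")
def filtered_cohort(small_cohort) -> Dataset:
    """Donors with at least 7 attempts (last-event prediction ready)."""
    return pp.filter_min_series_length(small_cohort, 7)


@pytest.fixture()
def toy_donations() -> pd.DataFrame:
    """Hand-written three-donor donation table (raw schema)."""
    rows = [
        # donor, sex, date, hb
        ("A", "female", "2020-01-01", 140.0),
        ("A", "female", "2020-04-01", 138.0),
        ("A", "female", "2020-08-01", 124.0),
        ("B", "male", "2020-02-10", 150.0),
        ("B", "male", "2020-06-15", 148.0),
        ("B", "male", "2020-11-20", 134.0),
        ("B", "male", "2021-03-01", 152.0),
        ("C", "female", "2019-03-05", 131.0),
        ("C", "female", "2019-07-09", 128.0),
        ("C", "female", "2019-12-22", 135.0),
    ]
    df = pd.DataFrame(rows, columns=["donor_id", "sex", "date", "hb"])
    df["date"] = pd.to_datetime(df["date"])
    return df


@pytest.fixture()
def toy_predictions() -> pd.DataFrame:
    """Six test donors with known scores: one tied positive/negative pair."""
    return pd.DataFrame(
        {
            "donor_id": list("PQRSTU"),
            "sex": ["female"] * 6,
            "observed_hb": [120.0, 130.0, 124.0, 140.0, 138.0, 150.0],
            "observed_deferral": [True, False, True, False, True, False],
            "predicted_hb": [np.nan] * 6,
            "deferral_probability": [0.9, 0.1, 0.4, 0.4, 0.7, 0.2],
        }
    )
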