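import dataclasses

import numpy as np
import pandas as pd
import pytest

from ursatox import synthetic_data as sd
from ursatox.bear_ibm import Params
from ursatox.seal_model import N_AGE_CLASSES, SealGrowthParams


@pytest.fixture(scope="session")
def seal_growth():
    return SealGrowthParams()


@pytest.fixture(scope="session")
def trend_spec():
    return sd.default_seal_trend_spec()


@pytest.fixture(scope="session")
def trend_model(trend_spec):
    """Exact trend model implied by the default generator spec."""
    return sd.trend_model_from_spec(trend_spec)


@pytest.fixture(scope="session")
def small_params():
    """Reference parameters scaled to a 100-bear starting population."""
    return dataclasses.replace(Params(), init_n=100)


@pytest.fixture(scope="session")
def noiseless_spec(trend_spec):
    return dataclasses.replace(
        trend_spec, residual_sd=0.0, weight_noise_sd=0.0, n_per_year_age=1
    )


def make_trend_table(
    intercept: float,
    slope: float,
    years,
    n_per_year: int,
    sd: float,
    rng: np.random.Generator,
    group: str = "older",
) -> pd.DataFrame:
    """Observation-table rows from a single ln-scale linear trend."""
    centre = (min(years) + max(years)) / 2.0
    rows = []
    for year in years:
        ln_c = intercept + slope * (year - centre) + rng.normal(0, sd, n_per_year)
        for v in ln_c:
            rows.append(
                {
                    "year": year,
                    "age": 1 if group == "yearling" else 10,
                    "sex": "M",
                    "group": group,
                    "cb153_ng_g_lw": float(np.exp(v)),
                }
            )
    return pd.DataFrame(rows)
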