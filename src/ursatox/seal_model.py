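"""Ringed seal contamination trend, growth and blubber sub-models.

Ringed seals (*Phoca hispida*) are the dominant prey of East Greenland
polar bears, and the CB153 concentration in their blubber is the only
environmental driver of the bear bioaccumulation model.  This module
fits the age-class-specific time trend of log10 CB153 blubber
concentrations, evaluates it for any simulation year, and provides a
von Bertalanffy weight-at-age curve from which the blubber mass of a
caught seal of a given age class is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "N_AGE_CLASSES",
    "SIM_YEAR_MIN",
    "SIM_YEAR_MAX",
    "TREND_CLAMP_YEAR",
    "VonBertalanffy",
    "SealGrowthParams",
    "SealTrendModel",
    "seal_age_class",
    "fit_seal_trend",
    "predict_seal_concentration",
    "seal_weight",
    "seal_blubber_mass",
    "prediction_table",
]

#: Seals are pooled into age classes 0, 1, ..., 10 and 11+ (few older animals).
N_AGE_CLASSES = 12

#: Simulation horizon: burn-in starts in 1950, output ends in 2009.
SIM_YEAR_MIN = 1950
SIM_YEAR_MAX = 2009

#: No seal monitoring exists before 1986; earlier years reuse the 1986 level.
TREND_CLAMP_YEAR = 1986


def seal_age_class(age: int | float | np.ndarray) -> int | np.ndarray:
    """Map a seal age in years to its age class (ages >= 11 pool into class 11)."""
    return np.minimum(np.asarray(age, dtype=int), N_AGE_CLASSES - 1)[()]


@dataclass(frozen=True)
class VonBertalanffy:
    """Weight-at-age curve W(a) = W_inf * (1 - exp(-k * (a - a0)))**b.

    The cubic default for ``b`` reflects the mass ~ length**3 convention.
    Ages at or below ``a0`` give zero weight (the curve is floored at 0).
    """

    w_inf: float
    k: float
    a0: float
    b: float = 3.0

    def __post_init__(self) -> None:
        if self.w_inf <= 0:
            raise ValueError(f"asymptotic weight must be positive, got {self.w_inf}")
        if self.k <= 0:
            raise ValueError(f"growth rate must be positive, got {self.k}")

    def weight(self, age: float | np.ndarray) -> float | np.ndarray:
        base = 1.0 - np.exp(-self.k * (np.asarray(age, dtype=float) - self.a0))
        return (self.w_inf * np.maximum(base, 0.0) ** self.b)[()]


@dataclass(frozen=True)
class SealGrowthParams:
    """Seal growth curve plus per-age-class blubber fractions.

    ``blubber_fraction`` is the proportion of total body mass that is
    blubber, one value per age class; ringed seals carry roughly 40% of
    their mass as blubber, so a flat 0.4 is the default.
    ``plus_class_age`` is the representative age used for the open-ended
    11+ class.
    """

    curve: VonBertalanffy = field(
        default_factory=lambda: VonBertalanffy(w_inf=60.0, k=0.4, a0=-2.0, b=3.0)
    )
    blubber_fraction: tuple[float, ...] = (0.4,) * N_AGE_CLASSES
    plus_class_age: float = 11.0

    def __post_init__(self) -> None:
        if len(self.blubber_fraction) != N_AGE_CLASSES:
            raise ValueError(
                f"blubber_fraction needs {N_AGE_CLASSES} values, "
                f"got {len(self.blubber_fraction)}"
            )
        for frac in self.blubber_fraction:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"blubber fraction {frac} outside [0, 1]")

    def representative_age(self, age_class: int) -> float:
        return float(self.plus_class_age if age_class >= N_AGE_CLASSES - 1 else age_class)


@dataclass(frozen=True)
class SealTrendModel:
    """Fitted log10 CB153 ~ year * age-class trend, one line per age class.

    ``intercepts[c]`` is the log10 concentration of class ``c`` at
    ``reference_year``; ``slopes[c]`` is its annual change.  The
    full-interaction OLS fit is exactly equivalent to this per-class
    representation, which is what prediction needs.
    """

    intercepts: np.ndarray
    slopes: np.ndarray
    reference_year: float

    def __post_init__(self) -> None:
        if len(self.intercepts) != N_AGE_CLASSES or len(self.slopes) != N_AGE_CLASSES:
            raise ValueError(f"trend model requires {N_AGE_CLASSES} age classes")

    def log10_prediction(self, year: float, age_class: int) -> float:
        year_eff = max(float(year), float(TREND_CLAMP_YEAR))
        return float(
            self.intercepts[age_class]
            + self.slopes[age_class] * (year_eff - self.reference_year)
        )

    def concentration_matrix(self, years: np.ndarray) -> np.ndarray:
        """ng/g lw concentrations, shape (len(years), n_classes); years clamped."""
        yr = np.maximum(np.asarray(years, dtype=float), TREND_CLAMP_YEAR)
        log10c = self.intercepts[None, :] + self.slopes[None, :] * (
            yr[:, None] - self.reference_year
        )
        return 10.0**log10c


def fit_seal_trend(records: pd.DataFrame) -> SealTrendModel:
    """OLS fit of log10 concentration on year, age-class factor and interaction.

    ``records`` must carry columns ``year``, ``age`` and ``cb153_ng_g_lw``.
    Year is centred at the midpoint of the observed years before fitting;
    predictions are invariant to the centring constant.

    Raises
    ------
    ValueError
        If any of the 12 age classes is absent or observed in fewer than
        two distinct years (its slope would be inestimable).
    """
    df = records[["year", "age", "cb153_ng_g_lw"]].copy()
    if (df["cb153_ng_g_lw"] <= 0).any():
        raise ValueError("all CB153 concentrations must be strictly positive")
    df["age_class"] = seal_age_class(df["age"].to_numpy())
    for cls in range(N_AGE_CLASSES):
        n_years = df.loc[df["age_class"] == cls, "year"].nunique()
        if n_years < 2:
            raise ValueError(
                f"seal age class {cls} observed in {n_years} year(s); "
                "at least 2 distinct years are required to fit a trend"
            )
    reference_year = (df["year"].min() + df["year"].max()) / 2.0
    df["year_c"] = df["year"] - reference_year
    df["log10c"] = np.log10(df["cb153_ng_g_lw"])

    fit = smf.ols("log10c ~ year_c * C(age_class)", data=df).fit()
    params = fit.params

    intercepts = np.empty(N_AGE_CLASSES)
    slopes = np.empty(N_AGE_CLASSES)
    intercepts[0] = params["Intercept"]
    slopes[0] = params["year_c"]
    for cls in range(1, N_AGE_CLASSES):
        intercepts[cls] = params["Intercept"] + params[f"C(age_class)[T.{cls}]"]
        slopes[cls] = params["year_c"] + params[f"year_c:C(age_class)[T.{cls}]"]
    return SealTrendModel(
        intercepts=intercepts, slopes=slopes, reference_year=reference_year
    )


def predict_seal_concentration(
    model: SealTrendModel, year: int, age_class: int
) -> float:
    """CB153 concentration (ng/g lw) for a year and age class.

    Years before 1986 return the 1986 prediction, because no seal
    monitoring exists for the burn-in period.
    """
    if not SIM_YEAR_MIN <= year <= SIM_YEAR_MAX:
        raise ValueError(
            f"year {year} outside the simulation horizon "
            f"[{SIM_YEAR_MIN}, {SIM_YEAR_MAX}]"
        )
    if not 0 <= age_class < N_AGE_CLASSES:
        raise ValueError(f"age class {age_class} outside [0, {N_AGE_CLASSES - 1}]")
    return 10.0 ** model.log10_prediction(year, age_class)


def seal_weight(age: float, growth: SealGrowthParams) -> float:
    """Seal body weight (kg) at a given age from the von Bertalanffy curve."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return float(growth.curve.weight(age))


def seal_blubber_mass(age_class: int, growth: SealGrowthParams) -> float:
    """Blubber mass (kg) of a representative seal of the given age class."""
    if not 0 <= age_class < N_AGE_CLASSES:
        raise ValueError(f"age class {age_class} outside [0, {N_AGE_CLASSES - 1}]")
    rep_age = growth.representative_age(age_class)
    return seal_weight(rep_age, growth) * growth.blubber_fraction[age_class]


def prediction_table(
    model: SealTrendModel, years: list[int] | np.ndarray
) -> pd.DataFrame:
    """Per-(year, age class) concentration predictions as a tidy table."""
    years = np.asarray(sorted(years), dtype=int)
    conc = model.concentration_matrix(years)
    rows = [
        {"year": int(y), "age_class": c, "pred_ng_g_lw": conc[i, c]}
        for i, y in enumerate(years)
        for c in range(N_AGE_CLASSES)
    ]
    return pd.DataFrame(rows)
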