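"""Calibration of field metabolic factors and deposition efficiencies.

The four focal parameters (f_a, f_y for older bears and yearlings; a_a,
a_y the corresponding CB153 deposition efficiencies) are swept over a
full factorial grid.  Each simulated combination is compared to the
field observations by ANCOVA on ln concentration against centred year:
a combination is accepted only when neither the slope nor the intercept
differs significantly (p > 0.1) for both yearlings and older bears.
Accepted combinations are screened for biological relevance (f_a > 1
and a per-unit-weight energy requirement of yearlings at least that of
older bears, f_y >= f_a), and the accepted (A, f) pairs are summarised
by the one-parameter inverse law A = omega / f, whose least-squares
solution is closed form.  The product omega = A * f is the only
quantity the trend matching identifies.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import bear_ibm
from .bear_ibm import Params
from .seal_model import SealGrowthParams, SealTrendModel
from .synthetic_data import FieldSamplingScheme

__all__ = [
    "GridSpec",
    "CalibrationResult",
    "OmegaFit",
    "build_design",
    "ancova_match",
    "select_combinations",
    "relevance_filter",
    "fit_omega",
    "sweep",
    "load_table1",
    "ALPHA",
    "GROUP_WINDOWS",
]

#: Acceptance significance level: a combination passes only if all four
#: p-values exceed this.
ALPHA = 0.1

#: Comparison windows per group; yearling field data exist only for 1987-2000.
GROUP_WINDOWS = {"older": (1986, 2009), "yearling": (1987, 2000)}

#: Only individuals younger than 26 years enter the trend comparison.
MAX_COMPARISON_AGE = 25


@dataclass(frozen=True)
class GridSpec:
    """Factorial sweep grid; the default enumerates 13,000 combinations."""

    f_a_values: tuple[float, ...] = tuple(range(1, 11))
    f_y_values: tuple[float, ...] = tuple(range(1, 14))
    a_a_values: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))
    a_y_values: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))

    def __post_init__(self) -> None:
        for name in ("f_a_values", "f_y_values", "a_a_values", "a_y_values"):
            vals = getattr(self, name)
            if not vals:
                raise ValueError(f"{name} must be non-empty")
        for name in ("a_a_values", "a_y_values"):
            if any(not 0 <= v <= 1 for v in getattr(self, name)):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def size(self) -> int:
        return (
            len(self.f_a_values)
            * len(self.f_y_values)
            * len(self.a_a_values)
            * len(self.a_y_values)
        )


@dataclass(frozen=True)
class CalibrationResult:
    """One grid point: the four p-values, acceptance and relevance flags."""

    f_a: float
    f_y: float
    a_a: float
    a_y: float
    p_slope_older: float
    p_int_older: float
    p_slope_yearling: float
    p_int_yearling: float
    accepted: bool
    relevant: bool

    @property
    def omega_a(self) -> float:
        return self.f_a * self.a_a

    @property
    def omega_y(self) -> float:
        return self.f_y * self.a_y


@dataclass(frozen=True)
class OmegaFit:
    """Least-squares fit of the inverse proportionality A = omega / f."""

    omega: float
    residuals: tuple[float, ...]
    n_pairs: int


def build_design(grid: GridSpec) -> list[tuple[float, float, float, float]]:
    """Full Cartesian product (f_a outermost, a_y innermost), fixed order."""
    return [
        (f_a, f_y, a_a, a_y)
        for f_a in grid.f_a_values
        for f_y in grid.f_y_values
        for a_a in grid.a_a_values
        for a_y in grid.a_y_values
    ]


def _subsample_to_field_counts(
    sim: pd.DataFrame, field: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Match the simulated rows to the field per-year sample sizes.

    Sampling is without replacement; a year where the simulation has
    fewer rows than the field contributes all its rows.
    """
    pieces = []
    field_counts = field.groupby("year").size()
    for year, n_field in field_counts.items():
        candidates = sim[sim["year"] == year]
        if candidates.empty:
            continue
        n = min(n_field, len(candidates))
        idx = rng.choice(len(candidates), size=n, replace=False)
        pieces.append(candidates.iloc[np.sort(idx)])
    if not pieces:
        raise ValueError("no simulated rows fall in the field sampling years")
    return pd.concat(pieces, ignore_index=True)


def ancova_match(
    sim_obs: pd.DataFrame,
    field_obs: pd.DataFrame,
    group: str,
    seed: int = 0,
    window: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Test whether simulated and field ln-concentration trends coincide.

    Fits ln(CB153) ~ centred year * source(sim vs field) on the pooled
    rows of ``group`` and returns ``(p_slope, p_intercept)``: the
    p-values of the year-by-source interaction (slope difference) and of
    the source indicator (level difference at the centre of the window).
    Simulated rows are first subsampled (seeded) to the field per-year
    counts so both sources carry equal leverage.
    """
    if group not in GROUP_WINDOWS:
        raise ValueError(f"group must be one of {sorted(GROUP_WINDOWS)}, got {group!r}")
    lo, hi = window if window is not None else GROUP_WINDOWS[group]

    def prepare(df: pd.DataFrame) -> pd.DataFrame:
        out = df[(df["group"] == group) & df["year"].between(lo, hi)]
        if "age" in out.columns:
            out = out[out["age"] <= MAX_COMPARISON_AGE]
        return out

    sim = prepare(sim_obs)
    fld = prepare(field_obs)
    if sim.empty or fld.empty:
        raise ValueError(f"no {group} rows inside the {lo}-{hi} window")
    if (sim["cb153_ng_g_lw"] <= 0).any() or (fld["cb153_ng_g_lw"] <= 0).any():
        raise ValueError(
            "concentrations must be strictly positive for the ln-scale ANCOVA"
        )
    rng = np.random.default_rng(seed)
    sim = _subsample_to_field_counts(sim, fld, rng)

    centre = (lo + hi) / 2.0
    year_c = np.concatenate(
        [sim["year"].to_numpy(float), fld["year"].to_numpy(float)]
    ) - centre
    if len(np.unique(year_c)) < 2:
        raise ValueError("ANCOVA needs at least two distinct years")
    source = np.concatenate([np.ones(len(sim)), np.zeros(len(fld))])
    ln_c = np.log(
        np.concatenate(
            [sim["cb153_ng_g_lw"].to_numpy(float), fld["cb153_ng_g_lw"].to_numpy(float)]
        )
    )
    X = sm.add_constant(
        np.column_stack([year_c, source, year_c * source]), has_constant="add"
    )
    fit = sm.OLS(ln_c, X).fit()
    p_intercept = float(fit.pvalues[2])
    p_slope = float(fit.pvalues[3])
    return p_slope, p_intercept


def select_combinations(
    results: list[CalibrationResult] | pd.DataFrame, alpha: float = ALPHA
) -> list[CalibrationResult] | pd.DataFrame:
    """Accepted subset: every one of the four p-values exceeds ``alpha``."""
    if isinstance(results, pd.DataFrame):
        yr_slope = "p_slope_yr" if "p_slope_yr" in results.columns else "p_slope_yearling"
        yr_int = "p_int_yr" if "p_int_yr" in results.columns else "p_int_yearling"
        mask = (
            (results["p_slope_older"] > alpha)
            & (results["p_int_older"] > alpha)
            & (results[yr_slope] > alpha)
            & (results[yr_int] > alpha)
        )
        return results[mask]
    return [
        r
        for r in results
        if min(
            r.p_slope_older, r.p_int_older, r.p_slope_yearling, r.p_int_yearling
        )
        > alpha
    ]


def relevance_filter(combos: pd.DataFrame) -> pd.DataFrame:
    """Biological-relevance screen: f_a > 1 and f_y >= f_a.

    Combinations with the field metabolic rate equal to basal metabolism
    (f_a = 1), or where yearlings would need less energy per unit body
    weight than older bears (f_y < f_a), are discarded as implausible.
    """
    return combos[(combos["f_a"] > 1) & (combos["f_y"] >= combos["f_a"])]


def fit_omega(pairs: list[tuple[float, float]] | np.ndarray) -> OmegaFit:
    """Least squares for A = omega / f over (A, f) pairs, closed form.

    Minimising sum_i (A_i - omega/f_i)^2 gives
    omega = sum(A_i/f_i) / sum(1/f_i^2).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("fit_omega requires at least one (A, f) pair")
    A, f = arr[:, 0], arr[:, 1]
    if np.any(f <= 0):
        raise ValueError("all field metabolic factors must be positive")
    omega = float(np.sum(A / f) / np.sum(1.0 / f**2))
    residuals = tuple((A - omega / f).tolist())
    return OmegaFit(omega=omega, residuals=residuals, n_pairs=len(A))


def load_table1() -> pd.DataFrame:
    """The 24 published ANCOVA-accepted parameter combinations.

    Columns ``a_y, a_a, f_y, f_a`` plus ``biologically_relevant`` (1 for
    the combinations satisfying the relevance screen).
    """
    path = importlib.resources.files("ursatox.data").joinpath("table1.csv")
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p)


def sweep(
    grid: GridSpec,
    field_obs: pd.DataFrame,
    trend: SealTrendModel,
    growth: SealGrowthParams,
    base_params: Params,
    seed: int,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Run one simulation per grid point and ANCOVA-match it to the field.

    Returns a results table with one row per combination: the four
    p-values, acceptance and relevance flags and the omega products.
    Sub-seeds for the per-combination simulations and subsampling are
    derived deterministically from ``seed``.
    """
    combos = build_design(grid)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(combos))
    rows = []
    for (f_a, f_y, a_a, a_y), child in zip(combos, children):
        params = bear_ibm.with_focal_params(base_params, f_a, f_y, a_a, a_y)
        sub = child.generate_state(2)
        sim_obs = bear_ibm.run_simulation(
            params, trend, growth, seed=int(sub[0] % 2**31)
        )
        p_slope_o, p_int_o = ancova_match(
            sim_obs, field_obs, "older", seed=int(sub[1] % 2**31)
        )
        p_slope_y, p_int_y = ancova_match(
            sim_obs, field_obs, "yearling", seed=int(sub[1] % 2**31)
        )
        accepted = min(p_slope_o, p_int_o, p_slope_y, p_int_y) > alpha
        relevant = f_a > 1 and f_y >= f_a
        rows.append(
            {
                "f_a": f_a,
                "f_y": f_y,
                "a_a": a_a,
                "a_y": a_y,
                "p_slope_older": p_slope_o,
                "p_int_older": p_int_o,
                "p_slope_yr": p_slope_y,
                "p_int_yr": p_int_y,
                "accepted": accepted,
                "relevant": relevant,
                "omega_a": f_a * a_a,
                "omega_y": f_y * a_y,
            }
        )
    return pd.DataFrame(rows)
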