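"""Yearly-step individual-based model of CB153 bioaccumulation in polar bears.

Agents are bears aged 2-30.  Each simulated year a bear grows along a
sex-specific von Bertalanffy curve, computes its annual energy
requirement as 365 * f * BMR (Kleiber allometry, f the field metabolic
factor), satisfies that requirement by eating ringed seal blubber caught
seal by seal according to age-specific hunting preferences, and deposits
a fraction A (the deposition efficiency) of the ingested CB153 into its
storage blubber.  Lactating females additionally produce milk whose
lipids carry contaminant to their cubs and yearlings; cubs and yearlings
are not agents but state attached to their mother until weaned yearlings
recruit as new 2-year-old agents carrying their accumulated burden.

Units are fixed throughout: body burden in ug CB153, blubber mass in kg,
concentration in ng/g lipid weight (1 ug/kg == 1 ng/g), energy in kJ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .seal_model import (
    N_AGE_CLASSES,
    SealGrowthParams,
    SealTrendModel,
    VonBertalanffy,
    seal_blubber_mass,
)

__all__ = [
    "MilkModel",
    "Params",
    "Bear",
    "FeedingResult",
    "SealEnvironment",
    "YearAccounts",
    "bmr_kj_per_day",
    "bear_weight",
    "storage_blubber_mass",
    "milk_energy_annual",
    "annual_energy_requirement",
    "yearling_energy_requirement",
    "feed_bear",
    "lactation_transfer",
    "step_year",
    "run_simulation",
    "concentration",
    "initialize_population",
]

#: Kleiber's allometric constant: BMR = 70 * W^0.75 kcal/day.
KLEIBER_COEF = 70.0
KLEIBER_EXP = 0.75

DAYS_PER_YEAR = 365

REPRO_STATUSES = ("single", "pregnant", "with_cubs", "with_yearlings")


@dataclass(frozen=True)
class MilkModel:
    """Milk production and composition.

    Daily milk output per offspring is held constant over the year at the
    level measured during the summer ice-free period; cubs receive more
    milk than yearlings, which already eat seal blubber as well.
    """

    daily_milk_g_cub: float = 600.0
    daily_milk_g_yearling: float = 400.0
    lipid_fraction: float = 0.33
    energy_density_kj_g: float = 15.9

    def __post_init__(self) -> None:
        if self.daily_milk_g_cub < 0 or self.daily_milk_g_yearling < 0:
            raise ValueError("daily milk amounts must be non-negative")
        if not 0.0 <= self.lipid_fraction <= 1.0:
            raise ValueError(f"milk lipid fraction {self.lipid_fraction} outside [0, 1]")
        if self.energy_density_kj_g < 0:
            raise ValueError("milk energy density must be non-negative")

    def daily_grams(self, offspring_status: str) -> float:
        return (
            self.daily_milk_g_cub
            if offspring_status == "with_cubs"
            else self.daily_milk_g_yearling
        )


@dataclass(frozen=True)
class Params:
    """All constants of the bear model.

    The four focal parameters are the field metabolic factors ``f_a``
    (older bears, i.e. agents aged 2+) and ``f_y`` (yearlings) and the
    deposition efficiencies ``a_a`` and ``a_y``; the cub deposition
    efficiency ``a_c`` is fixed from literature at 0.23.  ``kappa``
    converts kcal to kJ and ``e_s`` is the energy density of seal
    blubber (assumed pure, fully digestible lipid).
    """

    # focal parameters (reference values of the sensitivity analysis)
    f_a: float = 6.0
    f_y: float = 11.0
    a_a: float = 0.1
    a_y: float = 0.3
    a_c: float = 0.23

    # energetics
    kappa: float = 4.2  # kJ per kcal
    e_s: float = 37.8  # kJ per g seal blubber

    # demography (annual survival probabilities per stage)
    cub_survival: float = 0.55
    yearling_survival: float = 0.91  # sigma_y
    subadult_survival: float = 0.93
    adult_survival: float = 0.95
    breeding_prob: float = 0.6
    litter_probs: tuple[float, ...] = (0.3, 0.6, 0.1)  # P(litter size = 1, 2, 3)
    mature_age: int = 5
    max_age: int = 30

    # growth and body composition
    male_growth: VonBertalanffy = field(
        default_factory=lambda: VonBertalanffy(w_inf=480.0, k=0.27, a0=-1.0, b=3.0)
    )
    female_growth: VonBertalanffy = field(
        default_factory=lambda: VonBertalanffy(w_inf=290.0, k=0.40, a0=-0.8, b=3.0)
    )
    yearling_weight: float = 115.0  # kg, literature value (no EG field weights)
    blubber_prop_male: float = 0.20
    blubber_prop_female: float = 0.25
    blubber_prop_yearling: float = 0.20
    # multiplicative weight adjustment by female reproductive status
    weight_factor_pregnant: float = 1.0
    weight_factor_with_cubs: float = 1.0
    weight_factor_with_yearlings: float = 1.0

    # hunting preference weights over seal prey categories
    hunt_pref: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)  # pup, 1-2 yr, 3-19 yr
    prey_age_ranges: tuple[tuple[int, int], ...] = ((0, 0), (1, 2), (3, 19))

    milk: MilkModel = field(default_factory=MilkModel)

    # simulation schedule
    init_n: int = 2000
    init_age_range: tuple[int, int] = (2, 20)
    burnin_start: int = 1950
    output_start: int = 1986
    output_end: int = 2009

    def __post_init__(self) -> None:
        for name in ("a_a", "a_y", "a_c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"deposition efficiency {name}={v} outside [0, 1]")
        for name in (
            "cub_survival",
            "yearling_survival",
            "subadult_survival",
            "adult_survival",
            "breeding_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability {name}={v} outside [0, 1]")
        if self.f_a < 0 or self.f_y < 0:
            raise ValueError("field metabolic factors must be non-negative")
        if self.e_s <= 0:
            raise ValueError(f"seal blubber energy density must be positive, got {self.e_s}")
        if self.kappa <= 0:
            raise ValueError(f"kcal->kJ constant must be positive, got {self.kappa}")
        if len(self.hunt_pref) != len(self.prey_age_ranges):
            raise ValueError("hunt_pref and prey_age_ranges must align")
        if any(w < 0 for w in self.hunt_pref) or sum(self.hunt_pref) <= 0:
            raise ValueError("hunting preference weights must be non-negative, not all zero")
        if abs(sum(self.hunt_pref) - 1.0) > 1e-9:
            raise ValueError("hunting preference weights must sum to 1")
        if abs(sum(self.litter_probs) - 1.0) > 1e-9:
            raise ValueError("litter size probabilities must sum to 1")

    def survival_prob(self, age: int) -> float:
        return self.adult_survival if age >= self.mature_age else self.subadult_survival

    def growth_curve(self, sex: str) -> VonBertalanffy:
        return self.male_growth if sex == "M" else self.female_growth

    def weight_factor(self, status: str) -> float:
        return {
            "single": 1.0,
            "pregnant": self.weight_factor_pregnant,
            "with_cubs": self.weight_factor_with_cubs,
            "with_yearlings": self.weight_factor_with_yearlings,
        }[status]


@dataclass
class Bear:
    """One simulated agent (age 2-30).

    Offspring (cubs or yearlings) are not agents; their burdens (ug),
    survival days within the current year and energy needs live on the
    mother.  Males never carry offspring state.
    """

    id: int
    age: int
    sex: str  # 'M' or 'F'
    weight: float = 0.0  # kg
    blubber_mass: float = 0.0  # kg storage blubber
    burden: float = 0.0  # ug CB153
    # female-only reproductive state
    pregnant: bool = False
    repro_status: str = "single"
    litter_size: int = 0
    offspring_burdens: list[float] = field(default_factory=list)
    offspring_days: list[int] = field(default_factory=list)
    offspring_energy_need: float = 0.0  # kJ per surviving yearling, informational
    # transient per-year quantities
    energy_requirement: float = 0.0  # kJ/yr incl. milk production
    milk_energy: float = 0.0  # kJ/yr contained in produced milk
    _conceived: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.sex == "M" and (
            self.pregnant or self.repro_status != "single" or self.offspring_burdens
        ):
            raise ValueError("males cannot carry reproductive state")
        if self.burden < 0:
            raise ValueError("body burden cannot be negative")

    @property
    def lactating(self) -> bool:
        return self.repro_status in ("with_cubs", "with_yearlings") and bool(
            self.offspring_burdens
        )


@dataclass(frozen=True)
class FeedingResult:
    """Outcome of one bear-year of feeding; the final seal is fractional."""

    seals_caught: float
    blubber_g: float
    contaminant_intake_ug: float
    contaminant_deposited_ug: float


@dataclass
class YearAccounts:
    """Per-year bookkeeping used by the mass/energy-balance invariant checks."""

    year: int
    deposited_agents: float = 0.0  # ug deposited into agents by feeding
    deposited_offspring: float = 0.0  # ug deposited into yearlings by their own feeding
    lactation_loss: float = 0.0  # ug leaving mothers via milk
    offspring_retained: float = 0.0  # ug of milk contaminant retained by offspring
    agent_burden_delta: float = 0.0  # sum of agent burden changes (pre pop. dynamics)
    offspring_burden_delta: float = 0.0
    max_energy_error_kj: float = 0.0  # |consumed blubber energy - requirement|
    population_size: int = 0


def bmr_kj_per_day(weight: float, kappa: float = 4.2) -> float:
    """Basal metabolic rate, Kleiber's allometry: kappa * 70 * W^0.75 kJ/day."""
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    return kappa * KLEIBER_COEF * weight**KLEIBER_EXP


def bear_weight(age: int, sex: str, status: str, params: Params) -> float:
    """Body weight (kg) from the sex-specific growth curve, status-adjusted."""
    w = float(params.growth_curve(sex).weight(age))
    if sex == "F":
        w *= params.weight_factor(status)
    return w


def storage_blubber_mass(bear: Bear, params: Params) -> float:
    prop = params.blubber_prop_male if bear.sex == "M" else params.blubber_prop_female
    return bear.weight * prop


def milk_energy_annual(female: Bear, milk: MilkModel) -> float:
    """Energy (kJ) in the milk a female produces over the year.

    Each offspring nurses for the days it survives within the year, at
    the status-specific daily amount.
    """
    if not female.lactating:
        return 0.0
    daily = milk.daily_grams(female.repro_status)
    total_days = sum(female.offspring_days)
    return daily * total_days * milk.energy_density_kj_g


def annual_energy_requirement(bear: Bear, params: Params) -> tuple[float, float]:
    """(annual energy requirement kJ, daily field metabolic rate kJ/day).

    Agents are all older than yearlings, so the older-bear factor f_a
    applies; lactating females add the energy content of the milk they
    produce.  The requirement only determines food (and hence
    contaminant) intake -- it does not affect survival or breeding.
    """
    daily_fmr = params.f_a * bmr_kj_per_day(bear.weight, params.kappa)
    annual = DAYS_PER_YEAR * daily_fmr
    annual += milk_energy_annual(bear, params.milk)
    return annual, daily_fmr


def yearling_energy_requirement(params: Params, days: int = DAYS_PER_YEAR) -> float:
    """Annual energy need (kJ) of a yearling alive for ``days`` of the year."""
    full_year = DAYS_PER_YEAR * params.f_y * bmr_kj_per_day(
        params.yearling_weight, params.kappa
    )
    return full_year * days / DAYS_PER_YEAR


class SealEnvironment:
    """Pre-computed seal prey field: blubber masses and yearly concentrations.

    Caching the per-class blubber energy and the year-by-class
    concentration matrix keeps the iterative seal-catching loop cheap.
    """

    def __init__(
        self,
        trend: SealTrendModel,
        growth: SealGrowthParams,
        params: Params,
        years: np.ndarray,
    ) -> None:
        self.years = np.asarray(years, dtype=int)
        self.year_index = {int(y): i for i, y in enumerate(self.years)}
        self.blubber_g = np.array(
            [seal_blubber_mass(c, growth) * 1000.0 for c in range(N_AGE_CLASSES)]
        )
        self.energy_per_seal = self.blubber_g * params.e_s  # kJ
        self.conc = trend.concentration_matrix(self.years)  # ng/g lw
        w = np.asarray(params.hunt_pref, dtype=float)
        self.cum_pref = np.cumsum(w / w.sum())
        self.cat_lo = np.array([lo for lo, _ in params.prey_age_ranges])
        self.cat_n = np.array([hi - lo + 1 for lo, hi in params.prey_age_ranges])
        # expected energy per caught seal, for batch sizing only
        per_cat = np.array(
            [
                self.energy_per_seal[
                    np.minimum(np.arange(lo, hi + 1), N_AGE_CLASSES - 1)
                ].mean()
                for lo, hi in params.prey_age_ranges
            ]
        )
        self.mean_energy = float((w / w.sum()) @ per_cat)

    def draw_seal_classes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        cat = np.searchsorted(self.cum_pref, rng.random(n), side="right")
        ages = self.cat_lo[cat] + (rng.random(n) * self.cat_n[cat]).astype(int)
        return np.minimum(ages, N_AGE_CLASSES - 1)


def _satisfy_energy(
    requirement_kj: float,
    conc_by_class: np.ndarray,
    env: SealEnvironment,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Catch seals until ``requirement_kj`` is met exactly.

    Prey are drawn one category at a time from the hunting preferences
    with a uniform age inside the category; the final seal is consumed
    fractionally so consumed blubber energy equals the requirement.

    Returns (seals caught, blubber grams, contaminant intake ug).
    """
    if requirement_kj < 0:
        raise ValueError(f"energy requirement must be non-negative, got {requirement_kj}")
    if requirement_kj == 0:
        return 0.0, 0.0, 0.0
    seals = grams = intake_ng = 0.0
    remaining = requirement_kj
    while True:
        n = max(4, int(remaining / env.mean_energy * 1.2) + 4)
        cls = env.draw_seal_classes(n, rng)
        energies = env.energy_per_seal[cls]
        csum = np.cumsum(energies)
        stop = int(np.searchsorted(csum, remaining))
        if stop >= n:  # batch too small; consume it whole and draw again
            seals += n
            grams += float(env.blubber_g[cls].sum())
            intake_ng += float(env.blubber_g[cls] @ conc_by_class[cls])
            remaining -= float(csum[-1])
            continue
        prev = float(csum[stop - 1]) if stop > 0 else 0.0
        frac = (remaining - prev) / float(energies[stop])
        head = cls[:stop]
        seals += stop + frac
        grams += float(env.blubber_g[head].sum()) + frac * float(env.blubber_g[cls[stop]])
        intake_ng += float(env.blubber_g[head] @ conc_by_class[head]) + frac * float(
            env.blubber_g[cls[stop]] * conc_by_class[cls[stop]]
        )
        break
    return seals, grams, intake_ng / 1000.0  # ng -> ug


def feed_bear(
    bear: Bear,
    year: int,
    trend: SealTrendModel,
    growth: SealGrowthParams,
    params: Params,
    rng: np.random.Generator,
    env: SealEnvironment | None = None,
) -> FeedingResult:
    """Satisfy one agent's annual energy requirement from seal blubber.

    Increases the bear's body burden by a_a times the CB153 intake and
    returns the feeding bookkeeping.  ``env`` may be passed to reuse the
    pre-computed prey field across many calls.
    """
    if env is None:
        env = SealEnvironment(trend, growth, params, np.array([year]))
    conc = env.conc[env.year_index[int(year)]]
    seals, grams, intake = _satisfy_energy(bear.energy_requirement, conc, env, rng)
    deposited = params.a_a * intake
    bear.burden += deposited
    return FeedingResult(seals, grams, intake, deposited)


def lactation_transfer(female: Bear, params: Params) -> tuple[float, float]:
    """Move contaminant from a lactating mother's blubber into her offspring.

    The lipophilic burden is assumed to distribute over the mother's
    total annual lipid pool -- storage blubber plus the milk lipid she
    produces -- so the fraction leaving with the milk is
    ``milk_lipid / (blubber + milk_lipid)``.  For small milk volumes
    this reduces to milk lipid carrying contaminant at the adipose
    concentration; it can never overdraw the burden, which therefore
    stays non-negative without an explicit cap.  Each offspring retains
    the cub (a_c) or yearling (a_y) deposition efficiency times its
    share (proportional to its days of nursing); the remainder of the
    milk contaminant is excreted or biotransformed by the offspring.

    Returns (mother loss ug, total offspring retention ug).
    """
    if not female.lactating:
        return 0.0, 0.0
    if female.blubber_mass <= 0:
        raise ValueError("lactating female must have positive blubber mass")
    daily = params.milk.daily_grams(female.repro_status)
    lipid_g = np.array(
        [daily * params.milk.lipid_fraction * d for d in female.offspring_days],
        dtype=float,
    )
    total_lipid_kg = float(lipid_g.sum()) / 1000.0
    if total_lipid_kg == 0.0 or female.burden == 0.0:
        return 0.0, 0.0
    total = female.burden * total_lipid_kg / (female.blubber_mass + total_lipid_kg)
    transfer = total * lipid_g / lipid_g.sum()  # ug per offspring
    eff = params.a_c if female.repro_status == "with_cubs" else params.a_y
    retained = 0.0
    for i, t in enumerate(transfer):
        female.offspring_burdens[i] += eff * float(t)
        retained += eff * float(t)
    female.burden -= total
    return total, retained


def _update_body(bear: Bear, params: Params) -> None:
    bear.weight = bear_weight(bear.age, bear.sex, bear.repro_status, params)
    bear.blubber_mass = storage_blubber_mass(bear, params)


def _draw_litter_size(params: Params, rng: np.random.Generator) -> int:
    u = rng.random()
    cum = np.cumsum(params.litter_probs)
    return int(np.searchsorted(cum, u, side="right")) + 1


def concentration(bear: Bear) -> float:
    """Adipose CB153 concentration (ng/g lw) = burden / storage blubber mass."""
    if bear.blubber_mass <= 0:
        raise ValueError(f"bear {bear.id} has non-positive blubber mass")
    return bear.burden / bear.blubber_mass


def step_year(
    population: list[Bear],
    year: int,
    trend: SealTrendModel,
    growth: SealGrowthParams,
    params: Params,
    rng: np.random.Generator,
    env: SealEnvironment | None = None,
    observations: list[dict] | None = None,
    accounts: YearAccounts | None = None,
    feed_rng: np.random.Generator | None = None,
) -> list[Bear]:
    """Advance the population by one year.

    Sub-steps run in a fixed order: offspring survival & pregnancy ->
    weight/blubber update -> energy requirements -> feeding -> lactation
    transfer -> population dynamics (death, weaning/recruitment,
    reproductive-status update) -> age/weight/blubber update.  If
    ``observations`` is given, one row per agent and surviving yearling
    is appended after lactation (the state field data would sample).

    ``rng`` drives the demographic draws; seal catches use ``feed_rng``
    when given (a separate feeding stream keeps the demographic
    trajectory identical across runs that differ only in energetics, so
    parameter contrasts are paired on the same population histories).
    """
    if feed_rng is None:
        feed_rng = rng
    if not population:
        warnings.warn(f"population empty at year {year}", stacklevel=2)
        return []
    if env is None:
        env = SealEnvironment(trend, growth, params, np.array([year]))
    conc_year = env.conc[env.year_index[int(year)]]
    burden_before = {b.id: b.burden for b in population}
    offspring_before = {
        b.id: sum(b.offspring_burdens) for b in population if b.sex == "F"
    }

    # 1. offspring survival and pregnancy
    for b in population:
        if b.sex != "F":
            continue
        b._conceived = False
        if b.repro_status == "with_cubs":
            p = params.cub_survival
        elif b.repro_status == "with_yearlings":
            p = params.yearling_survival
        else:
            if (
                b.repro_status == "single"
                and not b.pregnant
                and b.age >= params.mature_age
            ):
                b._conceived = rng.random() < params.breeding_prob
            continue
        b.offspring_days = [
            DAYS_PER_YEAR
            if rng.random() < p
            else int(rng.integers(1, DAYS_PER_YEAR + 1))
            for _ in b.offspring_burdens
        ]

    # 2. weight and blubber content
    for b in population:
        _update_body(b, params)

    # 3. energy requirements
    for b in population:
        b.milk_energy = milk_energy_annual(b, params.milk)
        b.energy_requirement, _ = annual_energy_requirement(b, params)
        if b.sex == "F" and b.repro_status == "with_yearlings":
            b.offspring_energy_need = yearling_energy_requirement(params)

    # 4. feeding (agents, then the seal share of yearlings)
    for b in population:
        result = feed_bear(b, year, trend, growth, params, feed_rng, env=env)
        if accounts is not None:
            accounts.deposited_agents += result.contaminant_deposited_ug
            accounts.max_energy_error_kj = max(
                accounts.max_energy_error_kj,
                abs(result.blubber_g * params.e_s - b.energy_requirement),
            )
        if b.sex == "F" and b.repro_status == "with_yearlings":
            daily = params.milk.daily_grams(b.repro_status)
            for i, days in enumerate(b.offspring_days):
                milk_kj = daily * days * params.milk.energy_density_kj_g
                seal_req = max(yearling_energy_requirement(params, days) - milk_kj, 0.0)
                _, _, intake = _satisfy_energy(seal_req, conc_year, env, feed_rng)
                b.offspring_burdens[i] += params.a_y * intake
                if accounts is not None:
                    accounts.deposited_offspring += params.a_y * intake

    # 5. lactation transfer
    for b in population:
        if b.sex == "F" and b.lactating:
            loss, retained = lactation_transfer(b, params)
            if accounts is not None:
                accounts.lactation_loss += loss
                accounts.offspring_retained += retained

    if accounts is not None:
        accounts.agent_burden_delta = sum(
            b.burden - burden_before[b.id] for b in population
        )
        accounts.offspring_burden_delta = sum(
            sum(b.offspring_burdens) - offspring_before[b.id]
            for b in population
            if b.sex == "F"
        )
        accounts.population_size = len(population)

    # observation snapshot (post feeding and lactation, pre mortality)
    if observations is not None:
        for b in population:
            observations.append(
                {
                    "year": int(year),
                    "id": b.id,
                    "age": b.age,
                    "sex": b.sex,
                    "group": "older",
                    "cb153_ng_g_lw": concentration(b),
                    "burden_ug": b.burden,
                }
            )
            if b.sex == "F" and b.repro_status == "with_yearlings":
                yearling_blubber = params.yearling_weight * params.blubber_prop_yearling
                for q, days in zip(b.offspring_burdens, b.offspring_days):
                    if days == DAYS_PER_YEAR:
                        observations.append(
                            {
                                "year": int(year),
                                "id": b.id,
                                "age": 1,
                                "sex": "U",
                                "group": "yearling",
                                "cb153_ng_g_lw": q / yearling_blubber,
                                "burden_ug": q,
                            }
                        )

    # 6. population dynamics: mortality, weaning/recruitment, status updates
    next_id = max(b.id for b in population) + 1
    survivors: list[Bear] = []
    for b in population:
        if b.age >= params.max_age:
            continue
        if rng.random() < params.survival_prob(b.age):
            survivors.append(b)
    recruits: list[Bear] = []
    for b in survivors:
        if b.sex != "F":
            continue
        if b.repro_status == "with_yearlings":
            for q, days in zip(b.offspring_burdens, b.offspring_days):
                if days == DAYS_PER_YEAR:
                    sex = "M" if rng.random() < 0.5 else "F"
                    recruits.append(
                        Bear(id=next_id, age=2, sex=sex, burden=max(q, 0.0))
                    )
                    next_id += 1
            b.offspring_burdens = []
            b.offspring_days = []
            b.litter_size = 0
            b.repro_status = "single"
        elif b.repro_status == "with_cubs":
            kept = [
                q
                for q, days in zip(b.offspring_burdens, b.offspring_days)
                if days == DAYS_PER_YEAR
            ]
            if kept:
                b.repro_status = "with_yearlings"
                b.offspring_burdens = kept
                b.offspring_days = [DAYS_PER_YEAR] * len(kept)
                b.litter_size = len(kept)
            else:
                b.repro_status = "single"
                b.offspring_burdens = []
                b.offspring_days = []
                b.litter_size = 0
        elif b.pregnant:
            size = _draw_litter_size(params, rng)
            b.pregnant = False
            b.repro_status = "with_cubs"
            b.litter_size = size
            b.offspring_burdens = [0.0] * size  # no trans-placental transfer
            b.offspring_days = [DAYS_PER_YEAR] * size
        elif b._conceived:
            b.pregnant = True
            b._conceived = False

    # 7. update age, weight and blubber
    for b in survivors:
        b.age += 1
        _update_body(b, params)
    for b in recruits:
        _update_body(b, params)
    survivors.extend(recruits)
    if not survivors:
        warnings.warn(f"population went extinct during year {year}", stacklevel=2)
    return survivors


def initialize_population(params: Params, rng: np.random.Generator) -> list[Bear]:
    """Starting population: zero burdens, random ages 2-20, random sex and
    (for mature females) random reproductive state."""
    lo, hi = params.init_age_range
    bears: list[Bear] = []
    for i in range(params.init_n):
        age = int(rng.integers(lo, hi + 1))
        sex = "M" if rng.random() < 0.5 else "F"
        b = Bear(id=i, age=age, sex=sex)
        if sex == "F" and age >= params.mature_age:
            status = REPRO_STATUSES[int(rng.integers(0, len(REPRO_STATUSES)))]
            if status == "pregnant":
                b.pregnant = True
            elif status in ("with_cubs", "with_yearlings"):
                size = _draw_litter_size(params, rng)
                b.repro_status = status
                b.litter_size = size
                b.offspring_burdens = [0.0] * size
                b.offspring_days = [DAYS_PER_YEAR] * size
        _update_body(b, params)
        bears.append(b)
    return bears


def run_simulation(
    params: Params,
    trend: SealTrendModel,
    growth: SealGrowthParams,
    seed: int,
    collect_accounts: list[YearAccounts] | None = None,
) -> pd.DataFrame:
    """Run the model from burn-in start to the last output year.

    Burdens start at zero in ``burnin_start`` (1950) and build up to the
    1986 level before any output is recorded.  Returns one row per agent
    (group ``older``) and per surviving yearling (group ``yearling``)
    for each output year, with adipose concentrations in ng/g lw.
    """
    demo_ss, feed_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(demo_ss)
    feed_rng = np.random.default_rng(feed_ss)
    years = np.arange(params.burnin_start, params.output_end + 1)
    env = SealEnvironment(trend, growth, params, years)
    population = initialize_population(params, rng)
    observations: list[dict] = []
    for year in years:
        collect = observations if year >= params.output_start else None
        accounts = YearAccounts(year=int(year)) if collect_accounts is not None else None
        population = step_year(
            population,
            int(year),
            trend,
            growth,
            params,
            rng,
            env=env,
            observations=collect,
            accounts=accounts,
            feed_rng=feed_rng,
        )
        if accounts is not None:
            collect_accounts.append(accounts)
        if not population:
            break
    columns = ["year", "id", "age", "sex", "group", "cb153_ng_g_lw", "burden_ug"]
    return pd.DataFrame(observations, columns=columns)


def with_focal_params(
    params: Params, f_a: float, f_y: float, a_a: float, a_y: float
) -> Params:
    """Copy of ``params`` with the four calibrated parameters replaced."""
    return replace(params, f_a=f_a, f_y=f_y, a_a=a_a, a_y=a_y)
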