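import dataclasses

import numpy as np
import pandas as pd
import pytest

from ursatox import bear_ibm
from ursatox.bear_ibm import (
    Bear,
    MilkModel,
    Params,
    annual_energy_requirement,
    bmr_kj_per_day,
    concentration,
    feed_bear,
    lactation_transfer,
    milk_energy_annual,
    run_simulation,
    step_year,
)
from ursatox.seal_model import SealTrendModel


def make_bear(age=10, sex="M", params=None, **kwargs) -> Bear:
    params = params or Params()
    b = Bear(id=0, age=age, sex=sex, **kwargs)
    b.weight = bear_ibm.bear_weight(age, sex, b.repro_status, params)
    b.blubber_mass = bear_ibm.storage_blubber_mass(b, params)
    return b


def flat_trend(conc_ng_g: float) -> SealTrendModel:
    """Seal field with the same constant concentration in every class/year."""
    return SealTrendModel(
        intercepts=np.full(12, np.log10(conc_ng_g)),
        slopes=np.zeros(12),
        reference_year=1998.0,
    )


class TestEnergetics:
    def test_kleiber_bmr_unit_weight(self):
        assert bmr_kj_per_day(1.0) == pytest.approx(294.0)

    def test_kleiber_bmr_200kg_oracle(self):
        assert bmr_kj_per_day(200.0) == pytest.approx(4.2 * 70 * 200**0.75, abs=1e-9)
        assert abs(bmr_kj_per_day(200.0) - 15636) < 1

    def test_power_law_scaling(self):
        assert bmr_kj_per_day(100.0) * 2**0.75 == pytest.approx(bmr_kj_per_day(200.0))

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            bmr_kj_per_day(0.0)

    def test_200kg_bear_at_f6_spends_93800_kj_per_day(self):
        params = dataclasses.replace(Params(), f_a=6.0)
        bear = make_bear(params=params)
        bear.weight = 200.0
        _, daily_fmr = annual_energy_requirement(bear, params)
        assert round(daily_fmr / 100) * 100 == 93800

    def test_zero_factor_means_zero_requirement(self):
        params = dataclasses.replace(Params(), f_a=0.0)
        bear = make_bear(params=params)
        annual, _ = annual_energy_requirement(bear, params)
        assert annual == 0.0

    def test_lactating_female_adds_exactly_the_milk_energy(self):
        params = Params()
        single = make_bear(age=10, sex="F", params=params)
        mother = make_bear(
            age=10,
            sex="F",
            params=params,
            repro_status="with_cubs",
            litter_size=2,
            offspring_burdens=[0.0, 0.0],
            offspring_days=[365, 365],
        )
        mother.weight = single.weight  # same body, same BMR
        e_single, _ = annual_energy_requirement(single, params)
        e_mother, _ = annual_energy_requirement(mother, params)
        assert e_mother - e_single == pytest.approx(
            milk_energy_annual(mother, params.milk)
        )


class TestMilkEnergy:
    def test_no_offspring_means_zero(self):
        assert milk_energy_annual(make_bear(sex="F"), MilkModel()) == 0.0

    def test_linear_in_litter_size(self):
        one = make_bear(
            sex="F",
            repro_status="with_cubs",
            litter_size=1,
            offspring_burdens=[0.0],
            offspring_days=[365],
        )
        two = make_bear(
            sex="F",
            repro_status="with_cubs",
            litter_size=2,
            offspring_burdens=[0.0, 0.0],
            offspring_days=[365, 365],
        )
        milk = MilkModel()
        assert milk_energy_annual(two, milk) == pytest.approx(
            2 * milk_energy_annual(one, milk)
        )

    def test_proportional_to_survival_days(self):
        full = make_bear(
            sex="F",
            repro_status="with_yearlings",
            litter_size=1,
            offspring_burdens=[0.0],
            offspring_days=[365],
        )
        partial = make_bear(
            sex="F",
            repro_status="with_yearlings",
            litter_size=1,
            offspring_burdens=[0.0],
            offspring_days=[100],
        )
        milk = MilkModel()
        assert milk_energy_annual(partial, milk) == pytest.approx(
            100 / 365 * milk_energy_annual(full, milk)
        )


class TestFeeding:
    def test_zero_requirement_zero_intake(self, seal_growth):
        params = Params()
        bear = make_bear(params=params)
        bear.energy_requirement = 0.0
        res = feed_bear(
            bear, 1990, flat_trend(100.0), seal_growth, params,
            np.random.default_rng(0),
        )
        assert res.seals_caught == 0
        assert res.contaminant_intake_ug == 0
        assert bear.burden == 0

    def test_zero_efficiency_ingests_but_deposits_nothing(self, seal_growth):
        params = dataclasses.replace(Params(), a_a=0.0)
        bear = make_bear(params=params)
        bear.energy_requirement, _ = annual_energy_requirement(bear, params)
        res = feed_bear(
            bear, 1990, flat_trend(100.0), seal_growth, params,
            np.random.default_rng(0),
        )
        assert res.contaminant_intake_ug > 0
        assert res.contaminant_deposited_ug == 0
        assert bear.burden == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_homogeneous_prey_gives_closed_form_intake(self, seal_growth, seed):
        """With one prey category and constant seal concentration c, the
        intake is (requirement / E_s) * c regardless of the random draws."""
        conc = 250.0
        params = dataclasses.replace(
            Params(), hunt_pref=(1.0,), prey_age_ranges=((5, 5),)
        )
        bear = make_bear(params=params)
        bear.energy_requirement, _ = annual_energy_requirement(bear, params)
        res = feed_bear(
            bear, 1990, flat_trend(conc), seal_growth, params,
            np.random.default_rng(seed),
        )
        expected_ug = (bear.energy_requirement / params.e_s) * conc / 1000.0
        assert res.contaminant_intake_ug == pytest.approx(expected_ug, rel=1e-9)
        assert res.blubber_g * params.e_s == pytest.approx(
            bear.energy_requirement, rel=1e-9
        )

    def test_energy_met_exactly_with_fractional_final_seal(self, seal_growth):
        params = Params()
        bear = make_bear(params=params)
        bear.energy_requirement, _ = annual_energy_requirement(bear, params)
        res = feed_bear(
            bear, 1990, flat_trend(100.0), seal_growth, params,
            np.random.default_rng(3),
        )
        assert res.blubber_g * params.e_s == pytest.approx(
            bear.energy_requirement, rel=1e-9
        )
        assert res.seals_caught % 1 != 0  # final seal consumed partially


class TestLactationTransfer:
    def make_mother(self, burden, status="with_cubs", days=(365, 365)):
        return make_bear(
            age=10,
            sex="F",
            repro_status=status,
            litter_size=len(days),
            offspring_burdens=[0.0] * len(days),
            offspring_days=list(days),
            burden=burden,
        )

    def test_zero_burden_transfers_nothing(self):
        mother = self.make_mother(0.0)
        loss, retained = lactation_transfer(mother, Params())
        assert loss == 0.0 and retained == 0.0
        assert mother.offspring_burdens == [0.0, 0.0]

    def test_mother_loss_bounds_offspring_gain(self):
        params = Params()
        mother = self.make_mother(5000.0)
        loss, retained = lactation_transfer(mother, params)
        assert 0 < retained < loss <= 5000.0
        assert retained == pytest.approx(params.a_c * loss)
        assert mother.burden == pytest.approx(5000.0 - loss)

    def test_full_retention_conserves_mass(self):
        params = dataclasses.replace(Params(), a_y=1.0)
        mother = self.make_mother(5000.0, status="with_yearlings")
        loss, retained = lactation_transfer(mother, params)
        assert retained == pytest.approx(loss)

    def test_equal_survival_days_receive_equal_shares(self):
        mother = self.make_mother(4000.0, days=(200, 200))
        lactation_transfer(mother, Params())
        assert mother.offspring_burdens[0] == pytest.approx(
            mother.offspring_burdens[1]
        )

    def test_unequal_days_split_proportionally(self):
        mother = self.make_mother(4000.0, days=(100, 300))
        lactation_transfer(mother, Params())
        assert mother.offspring_burdens[1] == pytest.approx(
            3 * mother.offspring_burdens[0]
        )

    def test_burden_never_negative_even_with_huge_milk_output(self):
        milk = MilkModel(daily_milk_g_cub=5000.0)
        params = dataclasses.replace(Params(), milk=milk)
        mother = self.make_mother(1000.0)
        loss, _ = lactation_transfer(mother, params)
        assert 0 <= mother.burden < 1000.0
        assert loss < 1000.0


class TestStepYear:
    def test_all_male_population_changes_burdens_only_by_feeding(
        self, trend_model, seal_growth
    ):
        params = Params()
        pop = [make_bear(age=a, sex="M", params=params) for a in (3, 10, 20)]
        for i, b in enumerate(pop):
            b.id = i
        accounts = bear_ibm.YearAccounts(year=1990)
        step_year(
            pop, 1990, trend_model, seal_growth, params,
            np.random.default_rng(0), accounts=accounts,
        )
        assert accounts.lactation_loss == 0.0
        assert accounts.offspring_retained == 0.0
        assert accounts.agent_burden_delta == pytest.approx(
            accounts.deposited_agents
        )

    def test_no_agent_exceeds_max_age_after_step(self, trend_model, seal_growth):
        params = Params()
        pop = [make_bear(age=a, sex="M", params=params) for a in (28, 29, 30)]
        for i, b in enumerate(pop):
            b.id = i
        out = step_year(
            pop, 1990, trend_model, seal_growth, params, np.random.default_rng(0)
        )
        assert all(2 <= b.age <= 30 for b in out)

    def test_step_is_deterministic_given_seed(self, trend_model, seal_growth):
        params = dataclasses.replace(Params(), init_n=40)

        def run_once():
            rng = np.random.default_rng(123)
            pop = bear_ibm.initialize_population(params, rng)
            pop = step_year(pop, 1990, trend_model, seal_growth, params, rng)
            return [(b.id, b.age, b.sex, b.burden, b.repro_status) for b in pop]

        assert run_once() == run_once()


class TestRunSimulation:
    def test_zero_deposition_everywhere_gives_zero_concentrations(
        self, trend_model, seal_growth
    ):
        params = dataclasses.replace(
            Params(), init_n=60, a_a=0.0, a_y=0.0, a_c=0.0
        )
        obs = run_simulation(params, trend_model, seal_growth, seed=0)
        assert (obs["cb153_ng_g_lw"] == 0).all()

    def test_identical_seed_reproduces_the_observation_table(
        self, trend_model, seal_growth
    ):
        params = dataclasses.replace(Params(), init_n=60)
        a = run_simulation(params, trend_model, seal_growth, seed=11)
        b = run_simulation(params, trend_model, seal_growth, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_output_restricted_to_output_years_with_valid_ages(
        self, trend_model, seal_growth
    ):
        params = dataclasses.replace(Params(), init_n=60)
        obs = run_simulation(params, trend_model, seal_growth, seed=4)
        assert obs["year"].between(1986, 2009).all()
        older = obs[obs["group"] == "older"]
        assert older["age"].between(2, 30).all()
        assert (obs[obs["group"] == "yearling"]["age"] == 1).all()


class TestConcentration:
    def test_unit_arithmetic(self):
        bear = make_bear()
        bear.burden = 1000.0
        bear.blubber_mass = 100.0
        assert concentration(bear) == pytest.approx(10.0)
        bear.blubber_mass = 50.0
        assert concentration(bear) == pytest.approx(20.0)
        bear.burden = 0.0
        assert concentration(bear) == 0.0

    def test_zero_blubber_rejected(self):
        bear = make_bear()
        bear.blubber_mass = 0.0
        with pytest.raises(ValueError):
            concentration(bear)
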