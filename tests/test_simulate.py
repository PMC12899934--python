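import numpy as np
import pandas as pd
import pytest

from dietsim.simulate import (CONSUMPTION_COLUMNS, ConfigError, PatternSpec,
                              PopulationTable, compute_footprints,
                              compute_intakes, derive_all, plant_animal_ratio,
                              sample_demographics, sample_shares,
                              simulate_population)


@pytest.fixture(scope="module")
def med_spec(specs):
    return specs["Mediterranean"]


class TestShares:
    def test_draws_live_on_simplex(self, med_spec, rng):
        draws = sample_shares(med_spec, rng, size=500)
        assert (draws >= 0).all()
        assert np.allclose(draws.sum(axis=1), 1.0)

    def test_mean_converges_to_base_shares(self, med_spec, rng):
        n = 10_000
        draws = sample_shares(med_spec, rng, size=n)
        base = np.asarray(med_spec.base_shares)
        mc_se = draws.std(axis=0) / np.sqrt(n)
        assert (np.abs(draws.mean(axis=0) - base) < 3 * mc_se + 1e-4).all()

    def test_higher_concentration_shrinks_variance(self, med_spec, rng):
        import dataclasses
        tight = dataclasses.replace(med_spec, concentration=med_spec.concentration * 10)
        a = sample_shares(med_spec, np.random.default_rng(0), size=4000).var(axis=0)
        b = sample_shares(tight, np.random.default_rng(0), size=4000).var(axis=0)
        assert (b < a).all()

    def test_zero_concentration_rejected(self, med_spec):
        import dataclasses
        with pytest.raises(ConfigError):
            dataclasses.replace(med_spec, concentration=0.0)


class TestDemographics:
    def test_plant_based_mean_age(self, specs, rng):
        # truncation to [18, 80] shifts the mean by ~+0.2 years at most
        demo = sample_demographics(specs["Plant-based"], rng, 10_000)
        assert abs(demo["age_years"].mean() - 45.8) < 0.5

    def test_western_mean_bmi(self, specs, rng):
        demo = sample_demographics(specs["Western"], rng, 10_000)
        assert abs(demo["bmi_kg_m2"].mean() - 27.3) < 0.25

    def test_zero_female_fraction_gives_all_males(self, med_spec, rng):
        import dataclasses
        spec = dataclasses.replace(med_spec, female_fraction=0.0)
        demo = sample_demographics(spec, rng, 200)
        assert (demo["sex"] == "male").all()

    def test_income_quintile_bounded(self, specs, rng):
        demo = sample_demographics(specs["Western"], rng, 2000)
        assert demo["income_quintile"].between(1, 5).all()
        assert demo["season"].between(1, 4).all()


class TestIntakesAndFootprints:
    def test_one_kg_animal(self, db):
        cons = np.zeros(8)
        cons[0] = 1.0  # Animal
        intakes = compute_intakes(cons, db)
        assert intakes["protein_g"][0] == pytest.approx(242.0)
        fp = compute_footprints(cons, db)
        assert fp["ghg_kgco2e"][0] == pytest.approx(10.58)
        assert fp["water_l"][0] == pytest.approx(6678.0)
        assert fp["cost_usd"][0] == pytest.approx(11.50)

    def test_weighted_mix_of_vegetable_and_legume(self, db):
        cons = np.zeros(8)
        cons[7] = 0.5  # Vegetable
        cons[4] = 0.2  # Legume
        intakes = compute_intakes(cons, db)
        assert intakes["energy_kcal"][0] == pytest.approx(589.0)
        assert intakes["iron_mg"][0] == pytest.approx(14.73)
        fp = compute_footprints(cons, db)
        assert fp["ghg_kgco2e"][0] == pytest.approx(0.763)
        assert fp["water_l"][0] == pytest.approx(1030.0)
        assert fp["cost_usd"][0] == pytest.approx(2.206)

    def test_zero_vector_gives_zero(self, db):
        assert (derive_all(np.zeros(8), db).to_numpy() == 0).all()

    def test_negative_consumption_rejected(self, db):
        cons = np.zeros(8)
        cons[1] = -0.1
        with pytest.raises(ValueError, match="non-negative"):
            compute_intakes(cons, db)

    def test_order_independence(self, db, rng):
        cons = rng.random((5, 8))
        a = derive_all(cons, db)
        b = derive_all(cons[::-1], db)
        assert np.allclose(a.to_numpy(), b.to_numpy()[::-1])


class TestPlantAnimalRatio:
    def test_all_plant_hits_cap(self):
        cons = np.zeros(8)
        cons[3] = 1.0
        assert plant_animal_ratio(cons, cap=50.0) == 50.0

    def test_balanced(self):
        cons = np.zeros(8)
        cons[0] = 0.5  # Animal
        cons[3] = 1.0  # Grain
        assert plant_animal_ratio(cons) == pytest.approx(2.0)


class TestSimulatePopulation:
    def test_default_counts(self, default_pop):
        assert len(default_pop.df) == 1500
        assert set(default_pop.pattern_counts()) == {375}

    def test_same_seed_identical(self, db):
        a = simulate_population(db, n_per_pattern=30, seed=11)
        b = simulate_population(db, n_per_pattern=30, seed=11)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_indivisible_total_rejected(self, db):
        with pytest.raises(ConfigError, match="divisible"):
            simulate_population(db, n_total=1502)

    def test_derived_fields_recompute_exactly(self, small_pop, db):
        cons = small_pop.consumption_matrix()
        derived = derive_all(cons, db)
        for col in derived.columns:
            stored = small_pop.df[col].to_numpy()
            assert np.allclose(stored, derived[col].to_numpy(), rtol=1e-9)

    def test_person_days(self, db):
        pop = simulate_population(db, n_per_pattern=10, days_per_person=3, seed=3)
        assert len(pop.df) == 120
        assert pop.df.groupby("person_id").size().eq(3).all()
        # demographics shared across a person's days, consumption varies
        g = pop.df.groupby("person_id")
        assert g["age_years"].nunique().eq(1).all()
        assert g[CONSUMPTION_COLUMNS[0]].nunique().gt(1).any()

    def test_pooled_energy_matches_calibration_target(self, default_pop):
        energy = default_pop.df["energy_kcal"]
        assert energy.mean() == pytest.approx(3311, rel=0.05)
        assert energy.std() == pytest.approx(1361, rel=0.10)


class TestPopulationIO:
    def test_round_trip(self, small_pop, tmp_path):
        path = tmp_path / "pop.csv"
        small_pop.write(path)
        back = PopulationTable.read(path)
        pd.testing.assert_frame_equal(
            small_pop.df, back.df, check_dtype=False, rtol=1e-12)
        assert back.meta["seed"] == small_pop.meta["seed"]

    def test_missing_column_named(self, small_pop, tmp_path):
        path = tmp_path / "pop.csv"
        small_pop.df.drop(columns=["ghg_kgco2e"]).to_csv(path, index=False)
        with pytest.raises(ConfigError, match="ghg_kgco2e"):
            PopulationTable.read(path)

    def test_empty_file_rejected(self, small_pop, tmp_path):
        path = tmp_path / "pop.csv"
        small_pop.df.iloc[:0].to_csv(path, index=False)
        with pytest.raises(ConfigError, match="empty"):
            PopulationTable.read(path)
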