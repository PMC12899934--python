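import numpy as np
import pytest

from dietsim.food_db import FOOD_GROUPS, RequirementSet
from dietsim.optimize import (WEIGHTING_SCHEMES, DietVector, ObjectiveTriple,
                              OptimizationNorms, ParetoSet, check_constraints,
                              evaluate_objectives, grid_oracle, nsga2,
                              nsga2_search, norms_from_population,
                              repair_shares, weighted_scenario_select,
                              weighted_score)


def _diet(shares, mass, cap=0.4):
    return DietVector(shares=tuple(shares), total_mass_kg=mass, share_cap=cap)


@pytest.fixture(scope="module")
def norms():
    return OptimizationNorms(cost_max=25.0)


class TestDietVector:
    def test_valid(self):
        d = _diet([0.125] * 8, 2.0)
        assert np.allclose(d.consumption_kg(), 0.25)

    def test_cap_enforced(self):
        shares = [0.5, 0.5, 0, 0, 0, 0, 0, 0]
        with pytest.raises(ValueError, match="0.4"):
            _diet(shares, 2.0)

    def test_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            _diet([0.1] * 8, 2.0)


class TestObjectives:
    def test_unit_adequacy_ratios_give_f1_one(self, db):
        d = _diet([0.125] * 8, 2.0)
        intake = d.consumption_kg() @ np.array(
            [[p.iron_mg_per_100g * 10, p.calcium_mg_per_100g * 10,
              p.zinc_mg_per_100g * 10, p.protein_g_per_100g * 10] for p in db])
        req = RequirementSet(thresholds={
            "iron_mg": {"male": intake[0], "female": intake[0]},
            "calcium_mg": {"male": intake[1], "female": intake[1]},
            "zinc_mg": {"male": intake[2], "female": intake[2]},
            "protein_g_per_kg": {"male": intake[3] / 70.0,
                                 "female": intake[3] / 70.0},
            "vitd_ug": {"male": 20.0, "female": 20.0},
            "b12_ug": {"male": 6.0, "female": 6.0},
        })
        obj = evaluate_objectives(d, db, requirements=req)
        assert obj.f1_adequacy == pytest.approx(1.0)

    def test_f2_is_one_at_observed_maxima(self, db):
        # animal + oil mix solving GHG = 3.96 and water = 4175 exactly
        c_animal, c_oil = np.linalg.solve(
            np.array([[10.58, 3.44], [6678.0, 6348.0]]), np.array([3.96, 4175.0]))
        mass = c_animal + c_oil
        shares = np.zeros(8)
        shares[FOOD_GROUPS.index("Animal")] = c_animal / mass
        shares[FOOD_GROUPS.index("Oil")] = c_oil / mass
        d = _diet(shares, mass, cap=1.0)
        assert evaluate_objectives(d, db).f2_environment == pytest.approx(1.0)
        half = _diet(shares, mass / 2, cap=1.0)
        assert evaluate_objectives(half, db).f2_environment == pytest.approx(0.5)

    def test_price_scaling_only_affects_cost(self, db):
        import dataclasses
        d = _diet([0.125] * 8, 2.0)
        base = evaluate_objectives(d, db)
        db2 = [dataclasses.replace(p, price_usd_per_kg=p.price_usd_per_kg * 3)
               for p in db]
        scaled = evaluate_objectives(d, db2)
        assert scaled.f3_cost == pytest.approx(3 * base.f3_cost)
        assert scaled.f1_adequacy == pytest.approx(base.f1_adequacy)
        assert scaled.f2_environment == pytest.approx(base.f2_environment)


class TestConstraints:
    def test_feasible_diet(self, db):
        # grain-heavy diet inside all windows
        shares = np.array([0.1, 0.05, 0.05, 0.4, 0.15, 0.05, 0.05, 0.15])
        d = _diet(shares, 1.2)
        rec = check_constraints(d, db)
        assert rec.energy_ok and rec.protein_ratio_ok and rec.shares_ok
        assert rec.feasible

    def test_low_energy_flagged(self, db):
        d = _diet([0.125] * 8, 0.6)
        rec = check_constraints(d, db)
        assert not rec.energy_ok
        assert not rec.feasible

    def test_share_above_cap_flagged(self, db):
        shares = np.zeros(8)
        shares[3] = 0.5
        shares[7] = 0.5
        d = _diet(shares, 1.5, cap=1.0)
        assert not check_constraints(d, db).shares_ok


class TestRepair:
    def test_projects_onto_capped_simplex(self, rng):
        raw = rng.random((200, 8)) ** 4  # sparse draws stress the cap
        repaired = repair_shares(raw)
        assert np.allclose(repaired.sum(axis=1), 1.0)
        assert (repaired <= 0.4 + 1e-12).all()
        assert (repaired >= 0).all()

    def test_leaves_valid_vectors_unchanged(self):
        x = np.array([0.2, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        assert np.allclose(repair_shares(x), x)


class TestEngine:
    def test_toy_biobjective_front(self):
        """Minimize (x^2, (1-x)^2): the front is the segment x in [0, 1]."""
        def evaluate(g):
            x = g[:, 0]
            return np.column_stack([x**2, (1 - x) ** 2])

        genomes, F = nsga2(evaluate, n_var=1, pop_size=100, generations=60, seed=4)
        x = np.sort(genomes[:, 0])
        # on-front: sqrt(f1) + sqrt(f2) == 1
        assert np.all(np.abs(np.sqrt(F[:, 0]) + np.sqrt(F[:, 1]) - 1) < 1e-3)
        # dense coverage of [0, 1]
        assert x[0] < 0.02 and x[-1] > 0.98
        assert np.max(np.diff(x)) < 0.1
        # hypervolume against the analytic front (reference point (1.1, 1.1))
        t = np.linspace(0, 1, 20001)
        def hv(f):
            order = np.argsort(f[:, 0])
            f = f[order]
            prev_f2 = 1.1
            total = 0.0
            for f1, f2 in f:
                if f2 < prev_f2:
                    total += (1.1 - f1) * (prev_f2 - f2)
                    prev_f2 = f2
            return total
        analytic = hv(np.column_stack([t**2, (1 - t) ** 2]))
        assert hv(F) > 0.95 * analytic

    def test_front_is_mutually_nondominated(self):
        def evaluate(g):
            return np.column_stack([g[:, 0], 1 - g[:, 0]])
        _, F = nsga2(evaluate, n_var=1, pop_size=50, generations=10, seed=0)
        for i in range(len(F)):
            dominates = ((F <= F[i]).all(axis=1) & (F < F[i]).any(axis=1))
            assert not dominates.any()


@pytest.fixture(scope="module")
def pareto(db, norms):
    return nsga2_search(db, norms=norms, seed=42, pop_size=100, generations=40)


class TestDietSearch:
    def test_all_solutions_feasible(self, db, pareto):
        for diet, _ in pareto.entries:
            assert check_constraints(diet, db).feasible

    def test_front_nondominated(self, pareto):
        F = pareto.objectives_array() * np.array([-1.0, 1.0, 1.0])
        for i in range(len(F)):
            dominates = ((F <= F[i]).all(axis=1) & (F < F[i]).any(axis=1))
            assert not dominates.any()

    def test_deterministic(self, db, norms):
        a = nsga2_search(db, norms=norms, seed=5, pop_size=60, generations=10)
        b = nsga2_search(db, norms=norms, seed=5, pop_size=60, generations=10)
        assert a.objectives_array().tolist() == b.objectives_array().tolist()


class TestWeightedSelection:
    def _pareto(self, objectives):
        entries = [(_diet([0.125] * 8, 2.0), ObjectiveTriple(*o))
                   for o in objectives]
        return ParetoSet(entries=entries)

    def test_pure_adequacy_weight(self):
        ps = self._pareto([(1.0, 0.9, 0.9), (0.8, 0.1, 0.1)])
        _, obj = weighted_scenario_select(ps, (1.0, 0.0, 0.0))
        assert obj.f1_adequacy == 1.0

    def test_pure_environment_weight(self):
        ps = self._pareto([(1.0, 0.9, 0.9), (0.8, 0.1, 0.2)])
        _, obj = weighted_scenario_select(ps, (0.0, 1.0, 0.0))
        assert obj.f2_environment == 0.1

    def test_balanced_weights_with_tie_break(self):
        ps = self._pareto([(1.0, 0.9, 0.9), (0.8, 0.4, 0.6), (0.6, 0.2, 0.2)])
        _, obj = weighted_scenario_select(ps, (0.33, 0.33, 0.33))
        assert obj.as_array().tolist() == [0.6, 0.2, 0.2]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            weighted_scenario_select(ParetoSet(entries=[]), (0.33, 0.33, 0.33))


class TestGridOracle:
    def test_two_group_toy_matches_manual_enumeration(self, db, norms):
        """step 0.5 over 2 groups: candidate shares are (0,1), (.5,.5), (1,0)."""
        res = grid_oracle(db, norms=norms, weights=(0.0, 0.0, 1.0),
                          grid_step=0.5, n_groups=2, share_cap=1.0,
                          mass_grid=np.array([1.0, 1.5]))
        manual = []
        per_kg = {
            "energy": np.array([1894.0, 2750.0]),
            "protein": np.array([242.0, 105.0]),
            "cost": np.array([11.50, 6.14]),
        }
        for shares in ([0.0, 1.0], [0.5, 0.5], [1.0, 0.0]):
            for mass in (1.0, 1.5):
                c = np.array(shares) * mass
                e = c @ per_kg["energy"]
                ratio = c @ per_kg["protein"] * 4 / e
                if 2000 <= e <= 3500 and 0.10 <= ratio <= 0.35:
                    manual.append((-(c @ per_kg["cost"]) / norms.cost_max,
                                   tuple(shares), mass))
        best = max(manual)
        assert res.score == pytest.approx(best[0])
        assert res.diet.total_mass_kg == best[2]

    def test_infeasible_region_flagged(self, db, norms):
        res = grid_oracle(db, norms=norms, grid_step=0.5, n_groups=1,
                          share_cap=1.0, mass_grid=np.array([0.1]))
        assert res.feasible_region_empty
        assert res.diet is None

    def test_nsga_selection_close_to_oracle(self, db, norms):
        pareto = nsga2_search(db, norms=norms, seed=42)
        for scheme, weights in WEIGHTING_SCHEMES.items():
            _, obj = weighted_scenario_select(pareto, weights)
            oracle = grid_oracle(db, norms=norms, weights=weights)
            assert weighted_score(obj, weights) >= oracle.score - 0.02, scheme
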