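import numpy as np
import pytest

from oracles import grid_oracle_between, grid_oracle_within, random_small_system

from dietopt.food_system_io import (
    Classification,
    Diet,
    FoodItem,
    FoodSystem,
    NutrientDef,
)
from dietopt.guidelines import GuidelineSet, MicroRef, relax_guidelines
from dietopt.optimizer import (
    MODE_BETWEEN,
    MODE_BOTH,
    MODE_WITHIN,
    OptimizerError,
    ScenarioConfig,
    solve_experiment1,
    solve_experiment2,
    solve_experiment3,
)
from dietopt.synthetic_data import (
    GeneratorParams,
    generate_food_system,
    generate_known_optimum_instance,
)


def cfg_within(**kw):
    kw.setdefault("classification_id", "groups")
    kw.setdefault("mode", MODE_WITHIN)
    return ScenarioConfig(**kw)


class TestConfigValidation:
    def test_epsilon_ordering(self):
        with pytest.raises(OptimizerError):
            ScenarioConfig(classification_id="c", epsilon1=1e-6, epsilon2=1e-3)

    def test_change_range(self):
        with pytest.raises(OptimizerError):
            ScenarioConfig(classification_id="c", allowed_change_pct=120.0)

    def test_mode_names(self):
        with pytest.raises(OptimizerError):
            ScenarioConfig(classification_id="c", mode="sideways")


class TestZeroChangeIdentity:
    def test_returns_observed_diet(self, tiny_system):
        diet = tiny_system.diets["obs"]
        result = solve_experiment1(
            tiny_system, diet, tiny_system.guidelines["obs"],
            cfg_within(allowed_change_pct=0.0),
        )
        assert result.status == "optimal"
        for iid, q in diet.quantities.items():
            assert result.diet.get(iid) == pytest.approx(q, abs=1e-6)
        assert result.c_total == pytest.approx(0.0, abs=1e-6)
        assert result.ghge_reduction == pytest.approx(0.0, abs=1e-6)

    def test_generated_system_all_classifications(self, generated_system):
        diet = generated_system.diets["female"]
        gl = generated_system.guidelines["female"]
        for cid in generated_system.classifications:
            result = solve_experiment1(
                generated_system, diet, gl,
                cfg_within(classification_id=cid, allowed_change_pct=0.0),
            )
            assert result.status == "optimal"
            assert result.c_total == pytest.approx(0.0, abs=1e-5)
            assert result.ghge == pytest.approx(result.ghge_observed, rel=1e-6)


class TestWithinGroupConstraints:
    def _one_group_system(self):
        defs = {
            "protein": NutrientDef("protein", "P", "g", "macro_energy", 4.0),
            "carbohydrate": NutrientDef("carbohydrate", "C", "g",
                                        "macro_energy", 4.0),
            "iron": NutrientDef("iron", "Fe", "mg", "micro"),
        }
        items = {
            "a": FoodItem("a", "A", 100.0,
                          {"protein": 5.0, "carbohydrate": 15.0, "iron": 2.0},
                          ghge=2.0),
            "b": FoodItem("b", "B", 100.0,
                          {"protein": 5.0, "carbohydrate": 15.0, "iron": 2.0},
                          ghge=1.0),
        }
        system = FoodSystem(
            items=items, nutrient_defs=defs,
            classifications={"groups": Classification(
                "groups", {"g": "G"}, {"a": "g", "b": "g"})},
            diets={"obs": Diet("obs", {"a": 10.0, "b": 0.0})},
            guidelines={"obs": GuidelineSet(
                macro_energy_bounds={"protein": (1.0, 90.0),
                                     "carbohydrate": (1.0, 95.0)},
                macro_mass_bounds={},
                micro_refs={"iron": MicroRef(rda=0.1, ear=0.08)},
            )},
        )
        system.validate()
        return system

    def test_full_swap_feasible_at_100(self):
        system = self._one_group_system()
        result = solve_experiment1(
            system, system.diets["obs"], system.guidelines["obs"],
            cfg_within(allowed_change_pct=100.0),
        )
        # b has lower ghge: all mass moves there (sum(p+n) = 20 = 2*mass)
        assert result.diet.get("a") == pytest.approx(0.0, abs=1e-3)
        assert result.diet.get("b") == pytest.approx(10.0, abs=1e-3)

    def test_half_budget_moves_at_most_5g(self):
        system = self._one_group_system()
        result = solve_experiment1(
            system, system.diets["obs"], system.guidelines["obs"],
            cfg_within(allowed_change_pct=50.0),
        )
        assert result.diet.get("b") == pytest.approx(5.0, abs=1e-3)
        assert result.diet.get("a") == pytest.approx(5.0, abs=1e-3)

    def test_item_cap_blocks_exceeding_group_max(self):
        system = self._one_group_system()
        # cap = max observed in group = 10; with o = {a:10, b:0} nothing may
        # exceed 10, so the full swap is still allowed but no growth beyond
        system.diets["obs"] = Diet("obs", {"a": 10.0, "b": 4.0})
        result = solve_experiment1(
            system, system.diets["obs"], system.guidelines["obs"],
            cfg_within(allowed_change_pct=100.0, item_cap_enabled=True),
        )
        assert result.diet.get("b") <= 10.0 + 1e-6
        assert result.diet.get("b") == pytest.approx(10.0, abs=1e-3)

    def test_fixed_item_never_moves(self, tiny_system):
        tiny_system.items["a1"].fixed = True
        diet = tiny_system.diets["obs"]
        result = solve_experiment1(
            tiny_system, diet, tiny_system.guidelines["obs"],
            cfg_within(allowed_change_pct=100.0),
        )
        assert result.diet.get("a1") == pytest.approx(diet.get("a1"), abs=1e-9)

    def test_group_totals_conserved(self, generated_system):
        diet = generated_system.diets["female"]
        gl = generated_system.guidelines["female"]
        cls = generated_system.classifications["medium"]
        result = solve_experiment1(
            generated_system, diet, gl,
            cfg_within(classification_id="medium", allowed_change_pct=75.0,
                       item_cap_enabled=True),
        )
        assert result.status == "optimal"
        by_group = {}
        for iid, gid in cls.assignment.items():
            if not generated_system.items[iid].fixed:
                by_group.setdefault(gid, []).append(iid)
        for gid, members in by_group.items():
            before = sum(diet.get(i) for i in members)
            after = sum(result.diet.get(i) for i in members)
            assert after == pytest.approx(before, rel=1e-6, abs=1e-6)

    def test_change_bounded_by_twice_budget(self, generated_system):
        diet = generated_system.diets["male"]
        gl = generated_system.guidelines["male"]
        for level in (25.0, 50.0, 75.0):
            result = solve_experiment1(
                generated_system, diet, gl,
                cfg_within(classification_id="fine",
                           allowed_change_pct=level),
            )
            assert result.c_total <= 2 * level + 1e-6


class TestKnownOptima:
    def test_within_swap_exact(self):
        system, expected = generate_known_optimum_instance("within_swap")
        result = solve_experiment1(
            system, system.diets["obs"], system.guidelines["obs"],
            cfg_within(allowed_change_pct=expected["allowed_change_pct"]),
        )
        assert result.status == "optimal"
        for iid, q in expected["diet"].items():
            assert result.diet.get(iid) == pytest.approx(q, abs=5e-3)
        assert result.ghge_reduction == pytest.approx(
            expected["ghge_reduction"], abs=1e-5
        )
        assert result.d_macro == pytest.approx(0.0, abs=1e-9)
        assert result.d_micro == pytest.approx(0.0, abs=1e-9)

    def test_adequacy_raises_ghge(self):
        system, expected = generate_known_optimum_instance("adequacy_vs_ghge")
        result = solve_experiment1(
            system, system.diets["obs"], system.guidelines["obs"],
            cfg_within(allowed_change_pct=100.0),
        )
        assert result.status == "optimal"
        assert result.d_micro == pytest.approx(0.0, abs=1e-5)
        assert result.ghge == pytest.approx(expected["ghge"], rel=1e-4)
        assert result.ghge > result.ghge_observed

    def test_between_removal_strict_nesting(self):
        system, expected = generate_known_optimum_instance("between_removal")
        results = {}
        for mode in (MODE_BETWEEN, MODE_BOTH):
            config = ScenarioConfig(
                classification_id="groups", mode=mode,
                ghge_reduction_target=expected["ghge_reduction_target"],
            )
            results[mode] = solve_experiment3(
                system, system.diets["obs"], system.guidelines["obs"], config
            )
        assert results[MODE_BETWEEN].c_total == pytest.approx(
            expected["between_c_total"], rel=1e-4
        )
        assert results[MODE_BOTH].c_total == pytest.approx(
            expected["both_c_total"], rel=1e-4
        )
        assert results[MODE_BOTH].c_total < results[MODE_BETWEEN].c_total

    def test_infeasible_cap_reported(self):
        system, expected = generate_known_optimum_instance("infeasible_cap")
        for mode in (MODE_BETWEEN, MODE_BOTH):
            config = ScenarioConfig(
                classification_id="groups", mode=mode,
                ghge_reduction_target=expected["ghge_reduction_target"],
            )
            result = solve_experiment3(
                system, system.diets["obs"], system.guidelines["obs"], config
            )
            assert result.status == "infeasible"
            assert "ghge_cap" in result.binding_blocks


class TestExperiment2:
    def test_preconditions(self, tiny_system):
        with pytest.raises(OptimizerError):
            solve_experiment2(
                tiny_system, tiny_system.diets["obs"],
                tiny_system.guidelines["obs"], cfg_within(goal_level="full"),
            )

    def test_stage1_no_worse_than_experiment1(self, generated_system):
        diet = generated_system.diets["female"]
        gl = generated_system.guidelines["female"]
        for level in (25.0, 100.0):
            r1 = solve_experiment1(
                generated_system, diet, gl,
                cfg_within(classification_id="fine", allowed_change_pct=level),
            )
            r2 = solve_experiment2(
                generated_system, diet, gl,
                cfg_within(classification_id="fine", allowed_change_pct=level,
                           goal_level="lowered"),
            )
            assert (
                r2.objective_stages[0].optimum
                <= r1.objective_stages[0].optimum + 1e-7
            )

    def test_zero_change_identity_any_goal_level(self, generated_system):
        diet = generated_system.diets["female"]
        gl = generated_system.guidelines["female"]
        r = solve_experiment2(
            generated_system, diet, gl,
            cfg_within(classification_id="fine", allowed_change_pct=0.0,
                       goal_level="lowered"),
        )
        assert r.c_total == pytest.approx(0.0, abs=1e-5)

    def test_lowered_goals_free_ghge_reduction(self, generated_system):
        diet = generated_system.diets["female"]
        gl = generated_system.guidelines["female"]
        r1 = solve_experiment1(
            generated_system, diet, gl,
            cfg_within(classification_id="fine", allowed_change_pct=100.0),
        )
        r2 = solve_experiment2(
            generated_system, diet, gl,
            cfg_within(classification_id="fine", allowed_change_pct=100.0,
                       goal_level="lowered"),
        )
        assert r2.ghge_reduction >= r1.ghge_reduction - 1e-6

    def test_accepts_prerelaxed_guidelines(self, generated_system):
        diet = generated_system.diets["female"]
        relaxed = relax_guidelines(generated_system.guidelines["female"])
        r = solve_experiment2(
            generated_system, diet, relaxed,
            cfg_within(classification_id="fine", allowed_change_pct=50.0,
                       goal_level="lowered"),
        )
        assert r.status == "optimal"


class TestExperiment3:
    def test_requires_target(self, tiny_system):
        with pytest.raises(OptimizerError):
            solve_experiment3(
                tiny_system, tiny_system.diets["obs"],
                tiny_system.guidelines["obs"],
                ScenarioConfig(classification_id="groups", mode=MODE_BETWEEN),
            )

    def test_compliant_diet_with_slack_needs_no_change(self, compliant_system):
        diet = compliant_system.diets["female"]
        gl = compliant_system.guidelines["female"]
        config = ScenarioConfig(
            classification_id="fine", mode=MODE_BOTH,
            ghge_reduction_target=-0.5,  # cap 50% above observed: slack
        )
        result = solve_experiment3(compliant_system, diet, gl, config)
        assert result.status == "optimal"
        assert result.c_total == pytest.approx(0.0, abs=1e-5)

    def test_nesting_on_generated_systems(self):
        for seed in (21, 22, 23):
            system = generate_food_system(GeneratorParams(seed=seed))
            diet = system.diets["female"]
            gl = system.guidelines["female"]
            results = {}
            for mode in (MODE_BETWEEN, MODE_BOTH):
                config = ScenarioConfig(
                    classification_id="coarse", mode=mode,
                    ghge_reduction_target=0.30,
                )
                results[mode] = solve_experiment3(system, diet, gl, config)
            if results[MODE_BETWEEN].status == "optimal":
                assert results[MODE_BOTH].status == "optimal"
                assert (
                    results[MODE_BOTH].c_total
                    <= results[MODE_BETWEEN].c_total + 1e-5
                )

    def test_hard_constraints_hold_at_optimum(self, generated_system):
        diet = generated_system.diets["female"]
        gl = generated_system.guidelines["female"]
        config = ScenarioConfig(
            classification_id="fine", mode=MODE_BOTH,
            ghge_reduction_target=0.30,
        )
        result = solve_experiment3(generated_system, diet, gl, config)
        assert result.status == "optimal"
        assert result.d_macro <= 1e-5
        assert result.d_micro <= 1e-5
        assert result.ghge <= 0.70 * result.ghge_observed * (1 + 1e-6)


class TestLexicographicVsWeighted:
    def test_agreement_on_tiny_instance(self):
        system, _ = generate_known_optimum_instance("within_swap")
        diet = system.diets["obs"]
        gl = system.guidelines["obs"]
        lex = solve_experiment1(system, diet, gl,
                                cfg_within(allowed_change_pct=100.0))
        weighted = solve_experiment1(
            system, diet, gl,
            cfg_within(allowed_change_pct=100.0, lexicographic=False,
                       epsilon1=1e-6, epsilon2=1e-9),
        )
        assert weighted.ghge == pytest.approx(lex.ghge, rel=1e-3)
        assert weighted.d_macro + weighted.d_micro == pytest.approx(
            lex.d_macro + lex.d_micro, abs=1e-5
        )

    def test_agreement_on_generated_system(self, generated_system):
        diet = generated_system.diets["female"]
        gl = generated_system.guidelines["female"]
        lex = solve_experiment1(
            generated_system, diet, gl,
            cfg_within(classification_id="coarse", allowed_change_pct=100.0),
        )
        weighted = solve_experiment1(
            generated_system, diet, gl,
            cfg_within(classification_id="coarse", allowed_change_pct=100.0,
                       lexicographic=False),
        )
        assert weighted.d_macro + weighted.d_micro == pytest.approx(
            lex.d_macro + lex.d_micro, abs=1e-3
        )


class TestGridOracleSpotChecks:
    def test_within_oracle_two_groups(self):
        rng = np.random.default_rng(123)
        system = random_small_system(rng, n_groups=2, items_per_group=[2, 2])
        diet = system.diets["obs"]
        gl = system.guidelines["obs"]
        result = solve_experiment1(system, diet, gl,
                                   cfg_within(allowed_change_pct=100.0))
        oracle = grid_oracle_within(
            system, diet, system.classifications["groups"], gl,
            allowed_pct=100.0, step_frac=0.01,
        )
        d_lp = result.d_macro + result.d_micro
        assert d_lp <= oracle["d_min"] + 1e-6
        assert oracle["d_min"] - d_lp <= oracle["tol_d"] + 1e-9

    def test_between_oracle_two_groups(self):
        rng = np.random.default_rng(321)
        system = random_small_system(rng, n_groups=2, items_per_group=[2, 2])
        diet = system.diets["obs"]
        gl = system.guidelines["obs"]
        probe = grid_oracle_between(
            system, diet, system.classifications["groups"], gl,
            ghge_cap=float("inf"),
        )
        obs_ghge = sum(
            diet.get(i) / 100.0 * system.items[i].ghge for i in system.items
        )
        if not probe["any_feasible"] or probe["min_feasible_ghge"] >= obs_ghge:
            pytest.skip("instance has no feasible reduction on the grid")
        cap = 0.5 * (probe["min_feasible_ghge"] + obs_ghge)
        oracle = grid_oracle_between(
            system, diet, system.classifications["groups"], gl, ghge_cap=cap
        )
        config = ScenarioConfig(
            classification_id="groups", mode=MODE_BETWEEN,
            ghge_reduction_target=1.0 - cap / obs_ghge,
        )
        result = solve_experiment3(system, diet, gl, config)
        assert result.status == "optimal"
        lp_change = result.c_total / 100.0 * sum(diet.quantities.values())
        assert lp_change <= oracle["change_min"] + 1e-6
        assert oracle["change_min"] - lp_change <= oracle["tol_change"] + 1e-9
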