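"""FBA core: model I/O, diet bounds, LP solve, sensitivities, flux ranges."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dietfba import (
    ModelError,
    ToyModelSpec,
    apply_diet_bounds,
    build_exchange_index,
    fixed_optimum_flux_range,
    make_toy_model,
    map_diet,
    read_model,
    solve_fba,
)
from dietfba.fixtures import toy_model_to_bigg_json

from conftest import diet_from
from oracles import brute_force_lp_max


def bounded_toy(spec: ToyModelSpec, concentrations: dict[str, float]):
    model, optimum = make_toy_model(spec)
    diet = diet_from(concentrations)
    maps = map_diet(diet, build_exchange_index(model), policy="surrogate-then-drop")
    return apply_diet_bounds(model, maps, diet), optimum, diet


class TestReadModel:
    def test_bigg_json_round_trip(self, tmp_path):
        model, _ = make_toy_model(ToyModelSpec(biomass_stoichiometry=(2.0, 3.0)))
        p = tmp_path / "toy.json"
        p.write_text(json.dumps(toy_model_to_bigg_json(model)))
        back = read_model(p)
        assert back.reaction_ids == model.reaction_ids
        assert back.metabolite_ids == model.metabolite_ids
        assert np.allclose(back.S.toarray(), model.S.toarray())
        assert np.allclose(back.lb, model.lb) and np.allclose(back.ub, model.ub)
        assert back.biomass_reaction == model.biomass_reaction
        assert sorted(back.exchange_reactions) == sorted(model.exchange_reactions)

    def test_truncated_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "broken.json"
        p.write_text('{"metabolites": [')
        with pytest.raises(ModelError):
            read_model(p)

    def test_missing_objective_rejected(self, tmp_path):
        model, _ = make_toy_model(ToyModelSpec())
        obj = toy_model_to_bigg_json(model)
        for rxn in obj["reactions"]:
            rxn["objective_coefficient"] = 0.0
        p = tmp_path / "noobj.json"
        p.write_text(json.dumps(obj))
        with pytest.raises(ModelError, match="objective"):
            read_model(p)


class TestApplyDietBounds:
    def test_uptake_bound_is_minus_concentration(self):
        model, _, _ = bounded_toy(ToyModelSpec(substrate_ids=("glc__D",)), {"glc__D": 10.0})
        assert model.lb[model.reaction_index("EX_glc__D(e)")] == -10.0

    def test_absent_compound_closed(self):
        spec = ToyModelSpec(biomass_stoichiometry=(1.0, 1.0))
        model, _, _ = bounded_toy(spec, {"sub1": 5.0})
        assert model.lb[model.reaction_index("EX_sub2(e)")] == 0.0

    def test_secretion_upper_bounds_untouched(self):
        spec = ToyModelSpec()
        raw, _ = make_toy_model(spec)
        model, _, _ = bounded_toy(spec, {"sub1": 5.0})
        assert np.allclose(model.ub, raw.ub)

    def test_dropped_mapping_warns_and_leaves_model_closed(self):
        spec = ToyModelSpec()
        model, _ = make_toy_model(spec)
        diet = diet_from({"sub1": 5.0, "unknown_cpd": 1.0})
        maps = map_diet(diet, build_exchange_index(model))
        with pytest.warns(UserWarning, match="unknown_cpd"):
            import warnings

            warnings.simplefilter("always")
            apply_diet_bounds(model, maps, diet)


class TestSolveFBA:
    def test_single_substrate_closed_form(self):
        model, optimum, _ = bounded_toy(ToyModelSpec(biomass_stoichiometry=(10.0,)), {"sub1": 10.0})
        res = solve_fba(model)
        assert res.optimal
        assert res.objective_value == pytest.approx(1.0, abs=1e-7)
        assert res.objective_value == pytest.approx(optimum({"sub1": 10.0}), abs=1e-7)

    def test_all_uptakes_closed_gives_zero(self):
        model, _, _ = bounded_toy(ToyModelSpec(), {})
        res = solve_fba(model)
        assert res.optimal and res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_doubling_the_bound_doubles_the_objective(self):
        spec = ToyModelSpec(biomass_stoichiometry=(10.0,))
        one, _, _ = bounded_toy(spec, {"sub1": 10.0})
        two, _, _ = bounded_toy(spec, {"sub1": 20.0})
        assert solve_fba(two).objective_value == pytest.approx(
            2 * solve_fba(one).objective_value, rel=1e-9
        )

    def test_infeasible_maintenance_reported_not_raised(self):
        model, optimum, _ = bounded_toy(
            ToyModelSpec(maintenance_demand=1.0), {}
        )
        res = solve_fba(model)
        assert res.status == "infeasible"
        assert optimum({}) is None

    def test_steady_state_and_bounds_hold_at_optimum(self):
        model, _, _ = bounded_toy(
            ToyModelSpec(biomass_stoichiometry=(1.0, 2.0)), {"sub1": 5.0, "sub2": 4.0}
        )
        res = solve_fba(model)
        v = res.fluxes.to_numpy()
        assert np.abs(model.S @ v).max() < 1e-9
        assert (v >= model.lb - 1e-9).all() and (v <= model.ub + 1e-9).all()

    def test_duality_gap_closes(self):
        model, _, _ = bounded_toy(
            ToyModelSpec(biomass_stoichiometry=(1.0, 2.0)), {"sub1": 5.0, "sub2": 4.0}
        )
        res = solve_fba(model)
        # strong duality: objective equals the bound-weighted multipliers
        finite_lb = np.isfinite(model.lb)
        finite_ub = np.isfinite(model.ub)
        dual_obj = float(
            res.reduced_costs_lower.to_numpy()[finite_lb] @ model.lb[finite_lb]
            + res.reduced_costs_upper.to_numpy()[finite_ub] @ model.ub[finite_ub]
        )
        assert dual_obj == pytest.approx(res.objective_value, rel=1e-6, abs=1e-9)

    def test_nonbinding_bound_has_zero_reduced_cost(self):
        model, _, _ = bounded_toy(
            ToyModelSpec(biomass_stoichiometry=(1.0, 2.0)), {"sub1": 5.0, "sub2": 4.0}
        )
        res = solve_fba(model)
        # sub1 is in excess (5/1 > 4/2): its uptake bound cannot be binding
        assert abs(res.reduced_costs["EX_sub1(e)"]) < 1e-8

    def test_limiting_bound_reduced_cost_is_marginal_yield(self):
        model, _, _ = bounded_toy(ToyModelSpec(biomass_stoichiometry=(10.0,)), {"sub1": 10.0})
        res = solve_fba(model)
        # d objective / d lb: lowering lb by 1 mmol/L buys 1/10 biomass
        assert res.reduced_costs_lower["EX_sub1(e)"] == pytest.approx(-0.1, abs=1e-9)


class TestAgainstBruteForce:
    @pytest.mark.parametrize(
        "spec,conc",
        [
            (ToyModelSpec(biomass_stoichiometry=(10.0,)), {"sub1": 10.0}),
            (ToyModelSpec(biomass_stoichiometry=(1.0, 2.0)), {"sub1": 5.0, "sub2": 4.0}),
            (ToyModelSpec(biomass_stoichiometry=(3.0,), maintenance_demand=1.0), {"sub1": 7.0}),
            (ToyModelSpec(biomass_stoichiometry=(2.0,), redundant_pathway=True), {"sub1": 8.0}),
        ],
    )
    def test_objective_matches_vertex_enumeration(self, spec, conc):
        model, optimum, _ = bounded_toy(spec, conc)
        res = solve_fba(model)
        brute, _ = brute_force_lp_max(model.S, model.lb, model.ub, model.c)
        assert res.objective_value == pytest.approx(brute, abs=1e-7)
        assert res.objective_value == pytest.approx(optimum(conc), abs=1e-7)

    def test_cobra_glpk_agrees(self):
        # independent solver route: same toy model through cobrapy/GLPK
        import cobra.io

        spec = ToyModelSpec(biomass_stoichiometry=(1.0, 2.0))
        model, _, _ = bounded_toy(spec, {"sub1": 5.0, "sub2": 4.0})
        obj = toy_model_to_bigg_json(model)
        import json as _json
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".json", delete=False) as fh:
            _json.dump(obj, fh)
            path = fh.name
        cm = cobra.io.load_json_model(path)
        sol = cm.optimize()
        ours = solve_fba(model)
        assert ours.objective_value == pytest.approx(sol.objective_value, abs=1e-7)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.lists(st.floats(0.5, 10.0), min_size=1, max_size=3),
        st.lists(st.floats(0.0, 20.0), min_size=3, max_size=3),
    )
    def test_monotone_in_bound_relaxation(self, stoichs, concs):
        spec = ToyModelSpec(biomass_stoichiometry=tuple(stoichs))
        conc = {f"sub{i+1}": concs[i] for i in range(len(stoichs))}
        model, _, _ = bounded_toy(spec, conc)
        base = solve_fba(model).objective_value
        for rxn in model.exchange_reactions:
            relaxed = model.copy()
            j = relaxed.reaction_index(rxn)
            relaxed.lb[j] -= 1.0
            assert solve_fba(relaxed).objective_value >= base - 1e-9


class TestFluxRange:
    def test_unique_optimum_collapses_range(self):
        model, _, _ = bounded_toy(ToyModelSpec(biomass_stoichiometry=(10.0,)), {"sub1": 10.0})
        res = solve_fba(model)
        lo, hi = fixed_optimum_flux_range(model, "T_sub1", res.objective_value)
        assert hi - lo < 1e-4
        assert lo <= res.fluxes["T_sub1"] + 1e-6 and hi >= res.fluxes["T_sub1"] - 1e-6

    def test_redundant_pathway_spans_both_alternatives(self):
        model, _, _ = bounded_toy(
            ToyModelSpec(biomass_stoichiometry=(2.0,), redundant_pathway=True), {"sub1": 8.0}
        )
        res = solve_fba(model)
        lo, hi = fixed_optimum_flux_range(model, "T_sub1", res.objective_value)
        # total transport is 8, split arbitrarily across the two routes
        assert lo == pytest.approx(0.0, abs=1e-4)
        assert hi == pytest.approx(8.0, abs=1e-4)
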