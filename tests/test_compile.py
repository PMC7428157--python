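"""Diet compiler: decomposition, unit conversion, speciation, environment."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from dietfba import (
    Compound,
    CompoundRegistry,
    ComponentComposition,
    CompositionEntry,
    MediumRecipe,
    MediumValidationError,
    RecipeItem,
    SpeciationError,
    SpeciationRule,
    apply_speciation,
    compile_diet,
    decompose_component,
    mass_to_molar,
    ph_to_proton,
)
from dietfba.compile import read_speciation_rules, write_speciation_rules
from dietfba.medium import WATER_MW

from conftest import diet_from


class TestMassToMolar:
    def test_pure_water_is_55_molar(self):
        # density 1 g/cm^3 -> 1000 g/L; 5.55e4 mmol/L at the printed precision
        water = Compound("h2o", molecular_weight=WATER_MW)
        assert mass_to_molar(1000.0, water) == pytest.approx(5.55e4, rel=5e-3)

    def test_glucose_hand_arithmetic(self):
        glc = Compound("glc__D", molecular_weight=180.16)
        assert mass_to_molar(1.8016, glc) == pytest.approx(10.0, rel=1e-12)

    def test_zero_mass_gives_zero(self):
        assert mass_to_molar(0.0, Compound("x", molecular_weight=42.0)) == 0.0

    def test_missing_molecular_weight_instructs_user(self):
        with pytest.raises(MediumValidationError, match="molecular weight"):
            mass_to_molar(1.0, Compound("x"))


class TestPhToProton:
    def test_neutral_ph_is_1e4_mmol_per_L(self):
        assert ph_to_proton(7.0) == pytest.approx(1e-4, rel=1e-12)

    @pytest.mark.parametrize("pH,expected", [(0.0, 1000.0), (14.0, 1e-11)])
    def test_range_endpoints(self, pH, expected):
        # 10^(-pH) mol/L x 1000: pH 0 -> 1 M = 1000 mmol/L; pH 14 -> 1e-11 mmol/L
        assert ph_to_proton(pH) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(MediumValidationError):
            ph_to_proton(-0.1)
        with pytest.raises(MediumValidationError):
            ph_to_proton(14.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 13.9), st.floats(1e-6, 0.1))
    def test_strictly_decreasing_in_ph(self, pH, eps):
        assert ph_to_proton(pH) > ph_to_proton(min(pH + eps, 14.0))


class TestDecompose:
    def test_mass_times_fraction(self):
        comp = ComponentComposition("tryptone", [CompositionEntry("glu__L", 0.05)])
        assert decompose_component(10.0, comp) == [("glu__L", pytest.approx(0.5))]

    def test_zero_amount_prunes_everything(self):
        comp = ComponentComposition("tryptone", [CompositionEntry("glu__L", 0.05)])
        assert decompose_component(0.0, comp) == []

    def test_mass_conserved_when_fractions_sum_to_one(self):
        comp = ComponentComposition(
            "casein",
            [CompositionEntry("a", 0.6), CompositionEntry("b", 0.4)],
        )
        out = decompose_component(5.0, comp)
        assert sum(m for _, m in out) == pytest.approx(5.0, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0.0, 100.0),
        st.lists(st.floats(0.0, 0.2), min_size=1, max_size=5),
    )
    def test_output_mass_never_exceeds_input(self, amount, fractions):
        comp = ComponentComposition(
            "c", [CompositionEntry(f"x{i}", f) for i, f in enumerate(fractions)]
        )
        out = decompose_component(amount, comp)
        assert sum(m for _, m in out) <= amount * (1 + 1e-9)

    def test_unknown_compound_named_in_error(self):
        reg = CompoundRegistry([Compound("gly", molecular_weight=75.07)])
        comp = ComponentComposition("c", [CompositionEntry("unobtainium", 0.1)])
        with pytest.raises(MediumValidationError, match="unobtainium"):
            decompose_component(1.0, comp, reg)


class TestSpeciation:
    def test_nacl_dissociation_one_to_one(self):
        diet = diet_from({"nacl": 171.0})
        rule = SpeciationRule("nacl", (("na1", 1.0), ("cl", 1.0)), "dissociation")
        out = apply_speciation(diet, [rule])
        assert out["na1"] == pytest.approx(171.0)
        assert out["cl"] == pytest.approx(171.0)
        assert "nacl" not in out

    def test_iron_oxidation_split_conserves_total(self):
        diet = diet_from({"fe": 0.10})
        rule = SpeciationRule("fe", (("fe2", 0.5), ("fe3", 0.5)), "oxidation_split")
        out = apply_speciation(diet, [rule])
        assert out["fe2"] == pytest.approx(0.05)
        assert out["fe3"] == pytest.approx(0.05)
        assert out["fe2"] + out["fe3"] == pytest.approx(diet["fe"])

    def test_no_matching_rule_is_identity(self):
        diet = diet_from({"glc__D": 10.0})
        rule = SpeciationRule("nacl", (("na1", 1.0), ("cl", 1.0)), "dissociation")
        assert apply_speciation(diet, [rule]) == diet

    def test_oxidation_fractions_must_sum_to_one(self):
        with pytest.raises(SpeciationError, match="sum"):
            SpeciationRule("fe", (("fe2", 0.5), ("fe3", 0.6)), "oxidation_split")

    def test_cyclic_rule_chain_rejected(self):
        rules = [
            SpeciationRule("a", (("b", 1.0),), "surrogate"),
            SpeciationRule("b", (("a", 1.0),), "surrogate"),
        ]
        with pytest.raises(SpeciationError, match="cyclic"):
            apply_speciation(diet_from({"a": 1.0}), rules)

    def test_chained_rules_apply_in_dependency_order(self):
        # salt dissociates, then one ion is surrogated to the model's form
        rules = [
            SpeciationRule("ion_raw", (("ion_model", 1.0),), "surrogate"),
            SpeciationRule("salt", (("ion_raw", 1.0), ("cl", 1.0)), "dissociation"),
        ]
        out = apply_speciation(diet_from({"salt": 2.0}), rules)
        assert out["ion_model"] == pytest.approx(2.0)
        assert "ion_raw" not in out

    def test_provenance_records_the_rule(self):
        diet = diet_from({"nacl": 1.0})
        out = apply_speciation(
            diet, [SpeciationRule("nacl", (("na1", 1.0), ("cl", 1.0)), "dissociation")]
        )
        assert any(r.rule == "dissociation" for r in out.provenance("na1"))

    def test_rule_file_round_trip(self, tmp_path):
        rules = [
            SpeciationRule("nacl", (("na1", 1.0), ("cl", 1.0)), "dissociation"),
            SpeciationRule("fe", (("fe2", 0.5), ("fe3", 0.5)), "oxidation_split"),
        ]
        p = tmp_path / "rules.csv"
        write_speciation_rules(rules, p)
        assert sorted(read_speciation_rules(p), key=lambda r: r.source) == sorted(
            rules, key=lambda r: r.source
        )


class TestCompileDiet:
    def test_empty_recipe_gives_environment_only(self):
        recipe = MediumRecipe(items=[], pH=7.0)
        diet = compile_diet(recipe, [], [], CompoundRegistry())
        assert diet.compounds == ["h", "h2o", "o2"]
        assert diet["h"] == pytest.approx(1e-4)
        assert diet["o2"] == pytest.approx(18.2)
        assert diet["h2o"] == pytest.approx(5.55e4, rel=5e-3)

    def test_anaerobic_non_aqueous_drops_oxygen_and_water(self):
        recipe = MediumRecipe(items=[], pH=7.0, oxygen_mmol_per_L=0.0, aqueous=False)
        diet = compile_diet(recipe, [], [], CompoundRegistry())
        assert diet.compounds == ["h"]

    def test_toy_bundle_full_pipeline(self, toy_bundle):
        recipe, compositions, rules, registry = toy_bundle
        diet = compile_diet(recipe, compositions, rules, registry)
        # 3 amino acids + 2 salt ions + 2 iron states + water/oxygen/protons
        assert len(diet) == 10
        assert diet["gly"] == pytest.approx(10 * 0.05 / 75.07 * 1000)
        assert diet["na1"] == pytest.approx(5.844 / 58.44 * 1000, rel=1e-6)
        assert diet["fe2"] == pytest.approx(0.05)
        assert all(diet.provenance(c) for c in diet.compounds)

    def test_same_compound_from_two_components_sums(self, toy_bundle):
        recipe, compositions, rules, registry = toy_bundle
        compositions = compositions + [
            ComponentComposition("extract", [CompositionEntry("gly", 0.02)])
        ]
        recipe.items.append(RecipeItem("extract", 5.0, "g/L"))
        diet = compile_diet(recipe, compositions, rules, registry)
        expected = (10 * 0.05 + 5 * 0.02) / 75.07 * 1000
        assert diet["gly"] == pytest.approx(expected, rel=1e-12)
        assert len(diet.provenance("gly")) == 2

    def test_order_independence(self, toy_bundle):
        recipe, compositions, rules, registry = toy_bundle
        forward = compile_diet(recipe, compositions, rules, registry)
        shuffled = MediumRecipe(
            items=list(reversed(recipe.items)),
            pH=recipe.pH,
            oxygen_mmol_per_L=recipe.oxygen_mmol_per_L,
            aqueous=recipe.aqueous,
        )
        backward = compile_diet(shuffled, list(reversed(compositions)), rules, registry)
        assert forward == backward

    def test_unresolvable_component_listed(self, toy_bundle):
        recipe, compositions, rules, registry = toy_bundle
        recipe.items.append(RecipeItem("dark_matter", 1.0, "g/L"))
        with pytest.raises(MediumValidationError, match="dark_matter"):
            compile_diet(recipe, compositions, rules, registry)

    def test_duplicate_environment_injection_rejected(self):
        registry = CompoundRegistry([Compound("o2", molecular_weight=31.998)])
        recipe = MediumRecipe(items=[RecipeItem("o2", 1.0, "mmol/L")])
        with pytest.raises(MediumValidationError, match="o2"):
            compile_diet(recipe, [], [], registry)

    def test_residue_mass_mode_divides_by_dehydrated_mw(self):
        registry = CompoundRegistry([Compound("gly", molecular_weight=75.07)])
        comp = [ComponentComposition("pep", [CompositionEntry("gly", 0.1)])]
        recipe = MediumRecipe(items=[RecipeItem("pep", 10.0, "g/L")])
        free = compile_diet(recipe, comp, [], registry)
        residue = compile_diet(recipe, comp, [], registry, residue_mass=True)
        assert residue["gly"] == pytest.approx(1.0 / (75.07 - WATER_MW) * 1000)
        assert residue["gly"] > free["gly"]
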