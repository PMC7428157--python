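"""Medium schema: domain invariants and tabular round-trips."""

import pytest

from dietfba import (
    Compound,
    CompoundRegistry,
    ComponentComposition,
    CompositionEntry,
    CompiledDiet,
    MediumParseError,
    MediumRecipe,
    MediumValidationError,
    ProvenanceRecord,
    RecipeItem,
    read_composition_table,
    read_recipe,
    write_recipe,
)
from dietfba.medium import read_compiled_diet, write_compiled_diet


class TestCompound:
    def test_rejects_nonpositive_molecular_weight(self):
        with pytest.raises(MediumValidationError):
            Compound("glc__D", molecular_weight=0.0)

    def test_registry_rejects_duplicate_ids(self):
        reg = CompoundRegistry([Compound("na1")])
        with pytest.raises(MediumValidationError):
            reg.add(Compound("na1"))

    def test_molar_mass_error_names_the_compound(self):
        reg = CompoundRegistry([Compound("mystery")])
        with pytest.raises(MediumValidationError, match="mystery"):
            reg.molar_mass("mystery")


class TestComposition:
    def test_mass_fractions_must_not_exceed_unity(self):
        with pytest.raises(MediumValidationError, match="more mass"):
            ComponentComposition(
                "tryptone",
                [CompositionEntry("glu__L", 0.7), CompositionEntry("ala__L", 0.5)],
            )

    def test_revalidates_after_edit(self):
        comp = ComponentComposition("tryptone", [CompositionEntry("glu__L", 0.5)])
        comp.entries.append(CompositionEntry("ala__L", 0.6))
        with pytest.raises(MediumValidationError):
            comp.validate()

    def test_negative_fraction_rejected(self):
        with pytest.raises(MediumValidationError):
            CompositionEntry("gly", -0.1)


class TestRecipe:
    def test_lb_formulation_reads_three_components(self, tmp_path):
        p = tmp_path / "lb.csv"
        p.write_text(
            "component,amount,unit,pH\n"
            "tryptone,10,g/L,7\n"
            "yeast_extract,5,g/L,7\n"
            "nacl,10,g/L,7\n"
        )
        recipe = read_recipe(p)
        assert len(recipe.items) == 3
        assert recipe.pH == 7.0
        assert {i.ingredient for i in recipe.items} == {"tryptone", "yeast_extract", "nacl"}

    def test_empty_component_table_gives_empty_recipe(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("component,amount,unit\n")
        recipe = read_recipe(p)
        assert recipe.items == [] and recipe.pH == 7.0

    def test_unknown_unit_is_a_parse_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("component,amount,unit\nflour,2,cups\n")
        with pytest.raises(MediumParseError, match="cups"):
            read_recipe(p)

    def test_negative_amount_is_a_validation_error(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text("component,amount,unit\nnacl,-1,g/L\n")
        with pytest.raises(MediumValidationError):
            read_recipe(p)

    def test_malformed_amount_names_the_row(self, tmp_path):
        p = tmp_path / "mal.csv"
        p.write_text("component,amount,unit\nnacl,ten,g/L\n")
        with pytest.raises(MediumParseError, match="row 0"):
            read_recipe(p)

    @pytest.mark.parametrize(
        "amount,unit,canonical_amount,canonical_unit",
        [(500, "mg/L", 0.5, "g/L"), (0.17, "mol/L", 170.0, "mmol/L"), (10, "g/L", 10.0, "g/L")],
    )
    def test_units_canonicalised_at_read(self, tmp_path, amount, unit, canonical_amount, canonical_unit):
        p = tmp_path / "r.csv"
        p.write_text(f"component,amount,unit\nx,{amount},{unit}\n")
        reg_item = read_recipe(p).items[0]
        assert reg_item.unit == canonical_unit
        assert reg_item.amount == pytest.approx(canonical_amount)

    def test_round_trip_identity(self, tmp_path):
        recipe = MediumRecipe(
            items=[RecipeItem("tryptone", 10.0, "g/L"), RecipeItem("fe", 0.1, "mmol/L")],
            pH=6.5,
            oxygen_mmol_per_L=0.0,
            aqueous=True,
        )
        p = tmp_path / "rt.csv"
        write_recipe(recipe, p)
        back = read_recipe(p)
        assert back.items == recipe.items
        assert back.pH == recipe.pH
        assert back.oxygen_mmol_per_L == recipe.oxygen_mmol_per_L
        assert back.aqueous == recipe.aqueous

    def test_ph_outside_range_rejected(self):
        with pytest.raises(MediumValidationError):
            MediumRecipe(pH=15.0)

    def test_sidecar_overrides_environment(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("component,amount,unit\nnacl,10,g/L\n")
        side = tmp_path / "env.yaml"
        side.write_text("pH: 6.0\noxygen_mmol_per_L: 0\n")
        recipe = read_recipe(p, sidecar=side)
        assert recipe.pH == 6.0 and recipe.oxygen_mmol_per_L == 0.0


class TestCompositionTable:
    def test_groups_rows_by_component(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "component,compound,mass_fraction,source\n"
            "tryptone,glu__L,0.05,manual\n"
            "tryptone,ala__L,0.03,manual\n"
        )
        comps = read_composition_table(p)
        assert len(comps) == 1
        assert len(comps[0].entries) == 2

    def test_fraction_sum_above_one_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "component,compound,mass_fraction,source\n"
            "tryptone,glu__L,0.7,m\n"
            "tryptone,ala__L,0.5,m\n"
        )
        with pytest.raises(MediumValidationError, match="tryptone"):
            read_composition_table(p)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("component,compound,mass_fraction,source\n")
        assert read_composition_table(p) == []


class TestCompiledDiet:
    def test_zero_entries_pruned_and_negative_rejected(self):
        prov = {c: [ProvenanceRecord("t", "direct")] for c in ("a", "b")}
        diet = CompiledDiet({"a": 1.0, "b": 0.0}, prov)
        assert "b" not in diet and len(diet) == 1
        with pytest.raises(MediumValidationError):
            CompiledDiet({"a": -1.0}, prov)

    def test_every_entry_requires_provenance(self):
        with pytest.raises(MediumValidationError, match="provenance"):
            CompiledDiet({"a": 1.0}, {})

    def test_tsv_round_trip(self, tmp_path):
        diet = CompiledDiet(
            {"glc__D": 10.0, "na1": 171.0},
            {c: [ProvenanceRecord("t", "direct", {"k": 1})] for c in ("glc__D", "na1")},
        )
        p = tmp_path / "diet.tsv"
        write_compiled_diet(diet, p)
        back = read_compiled_diet(p)
        assert back == diet
        assert back.provenance("na1")[0].rule == "direct"
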