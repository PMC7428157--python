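"""Compile a medium recipe into a molecular diet.

The compilation pipeline has a fixed order:

1. **decompose** — each complex component is split into constituent molecules
   by mass fractions (g constituent per g component);
2. **mass -> molar** — masses become concentrations via molar mass
   (mmol/L = g/L / (g/mol) x 1000);
3. **merge** — the same compound arriving from several components is summed;
4. **speciation** — salts dissociate to ions, polymers are substituted by a
   model-supported unit, redox-ambiguous metals are split across oxidation
   states, conjugate acid/base pairs collapse to the model's form;
5. **environment** — water (aqueous media), oxygen (aerobic regime) and
   protons (from pH) are injected.

Zero-concentration entries are pruned; a compound absent from the compiled
diet means its uptake will be closed when bounds are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .medium import (
    Compound,
    CompoundRegistry,
    ComponentComposition,
    CompiledDiet,
    MediumParseError,
    MediumRecipe,
    MediumValidationError,
    ProvenanceRecord,
    WATER_MW,
    _read_table,
    _sep_for,
)

__all__ = [
    "SpeciationRule",
    "EnvironmentSpec",
    "SpeciationError",
    "decompose_component",
    "mass_to_molar",
    "ph_to_proton",
    "apply_speciation",
    "compile_diet",
    "read_speciation_rules",
    "write_speciation_rules",
    "WATER_ID",
    "OXYGEN_ID",
    "PROTON_ID",
]

# BiGG-style ids used for the environmental compounds.
WATER_ID = "h2o"
OXYGEN_ID = "o2"
PROTON_ID = "h"

RULE_KINDS = ("dissociation", "polymer_substitution", "oxidation_split", "surrogate")

_FRACTION_SUM_TOL = 1e-9


class SpeciationError(ValueError):
    """A speciation rule set is invalid or inapplicable."""


@dataclass(frozen=True)
class SpeciationRule:
    """Replace one source compound by its model-representable species.

    ``products`` holds ``(compound_id, coefficient)`` pairs whose meaning
    depends on ``rule_kind``:

    * ``dissociation`` — stoichiometric coefficients (mol product per mol
      source), positive rationals; e.g. NaCl -> 1 Na+ + 1 Cl-.
    * ``oxidation_split`` — molar fractions that must sum to 1; e.g. total
      iron -> 0.5 Fe2+ + 0.5 Fe3+.
    * ``polymer_substitution`` — mol product per mol source such that product
      mass matches source mass within tolerance (checked against a registry
      when one is supplied to :func:`apply_speciation`).
    * ``surrogate`` — 1:1 replacement by a chemically related species the
      model does represent (e.g. butyric acid -> butyrate).
    """

    source: str
    products: tuple[tuple[str, float], ...]
    rule_kind: str

    def __post_init__(self) -> None:
        if self.rule_kind not in RULE_KINDS:
            raise SpeciationError(
                f"rule for {self.source!r}: unknown rule_kind {self.rule_kind!r}; "
                f"allowed {RULE_KINDS}"
            )
        if not self.products:
            raise SpeciationError(f"rule for {self.source!r} has no products")
        for cpd, coef in self.products:
            if coef < 0:
                raise SpeciationError(
                    f"rule for {self.source!r}: negative coefficient for {cpd!r}"
                )
        if self.rule_kind == "oxidation_split":
            total = sum(c for _, c in self.products)
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise SpeciationError(
                    f"oxidation_split for {self.source!r}: fractions sum to "
                    f"{total:.9g}, expected 1"
                )
        if self.rule_kind == "dissociation":
            for cpd, coef in self.products:
                # positive integers/rationals; reject e.g. 0 or irrational junk
                if coef <= 0 or Fraction(coef).limit_denominator(1000) == 0:
                    raise SpeciationError(
                        f"dissociation for {self.source!r}: coefficient for "
                        f"{cpd!r} must be a positive rational, got {coef}"
                    )
        if self.rule_kind == "surrogate" and len(self.products) != 1:
            raise SpeciationError(
                f"surrogate rule for {self.source!r} must have exactly one product"
            )


@dataclass(frozen=True)
class EnvironmentSpec:
    """Environmental compounds injected into every compiled diet.

    ``proton_mmol_per_L`` is exactly ``10**(-pH) * 1000``; oxygen 0 encodes
    anaerobic conditions; water is derived from density 1 g/cm^3 and the molar
    mass of water for aqueous media (zero otherwise).
    """

    water_mmol_per_L: float
    oxygen_mmol_per_L: float
    proton_mmol_per_L: float

    def __post_init__(self) -> None:
        for name in ("water_mmol_per_L", "oxygen_mmol_per_L", "proton_mmol_per_L"):
            if getattr(self, name) < 0:
                raise MediumValidationError(f"{name} must be >= 0")

    @classmethod
    def from_recipe(cls, recipe: MediumRecipe) -> "EnvironmentSpec":
        water = 1000.0 / WATER_MW * 1000.0 if recipe.aqueous else 0.0
        return cls(
            water_mmol_per_L=water,
            oxygen_mmol_per_L=recipe.oxygen_mmol_per_L,
            proton_mmol_per_L=ph_to_proton(recipe.pH),
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def ph_to_proton(pH: float) -> float:
    """Proton concentration in mmol/L for a given pH.

    pH 7 gives 1e-7 mol/L = 1e-4 mmol/L.
    """
    if not 0.0 <= pH <= 14.0:
        raise MediumValidationError(f"pH {pH} outside [0, 14]")
    return 10.0 ** (-pH) * 1000.0


def mass_to_molar(mass_g_per_L: float, compound: Compound) -> float:
    """Convert a mass concentration (g/L) to mmol/L via molar mass."""
    if compound.molecular_weight is None:
        raise MediumValidationError(
            f"compound {compound.id!r} has no molecular weight; supply one to "
            "convert its mass to a molar concentration"
        )
    if mass_g_per_L < 0:
        raise MediumValidationError(f"negative mass {mass_g_per_L} for {compound.id!r}")
    return mass_g_per_L / compound.molecular_weight * 1000.0


def decompose_component(
    component_amount_g_per_L: float,
    composition: ComponentComposition,
    registry: CompoundRegistry | None = None,
) -> list[tuple[str, float]]:
    """Split a complex component's mass across its molecular constituents.

    Returns ``(compound_id, mass g/L)`` pairs with zero masses pruned; total
    output mass never exceeds the input mass (fraction sums are validated on
    the composition).
    """
    if component_amount_g_per_L < 0:
        raise MediumValidationError(
            f"negative amount for component {composition.component_id!r}"
        )
    composition.validate()
    out: list[tuple[str, float]] = []
    for entry in composition.entries:
        if registry is not None and entry.compound_id not in registry:
            raise MediumValidationError(
                f"composition of {composition.component_id!r} references "
                f"unknown compound {entry.compound_id!r}"
            )
        mass = component_amount_g_per_L * entry.mass_fraction
        if mass > 0:
            out.append((entry.compound_id, mass))
    return out


def _toposort_rules(rules: Sequence[SpeciationRule]) -> list[SpeciationRule]:
    """Order rules so a rule's products are processed after it; reject cycles."""
    by_source = {r.source: r for r in rules}
    if len(by_source) != len(rules):
        dupes = [r.source for r in rules if sum(s.source == r.source for s in rules) > 1]
        raise SpeciationError(f"multiple rules for source(s) {sorted(set(dupes))}")
    ordered: list[SpeciationRule] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(src: str, chain: tuple[str, ...]) -> None:
        if state.get(src) == 1:
            return
        if state.get(src) == 0:
            cycle = chain[chain.index(src):] + (src,)
            raise SpeciationError(f"cyclic speciation rule chain: {' -> '.join(cycle)}")
        state[src] = 0
        for product, _ in by_source[src].products:
            if product in by_source and product != src:
                visit(product, chain + (src,))
        state[src] = 1
        ordered.append(by_source[src])

    for r in rules:
        visit(r.source, ())
    # reverse: a source whose product is another source must run first
    return list(reversed(ordered))


def apply_speciation(
    diet: CompiledDiet,
    rules: Sequence[SpeciationRule],
    registry: CompoundRegistry | None = None,
) -> CompiledDiet:
    """Replace diet entries by their speciated forms.

    Idempotent when no rule matches. 1:1 dissociations conserve the molar
    amount per product; oxidation splits conserve the total molar amount.
    Polymer substitutions are checked for mass conservation when molar masses
    are available in ``registry``.
    """
    ordered = _toposort_rules(rules)
    entries = {c: diet[c] for c in diet}
    prov: dict[str, list[ProvenanceRecord]] = {c: diet.provenance(c) for c in diet}

    for rule in ordered:
        if rule.source not in entries:
            continue
        conc = entries.pop(rule.source)
        source_trail = prov.pop(rule.source)
        if (
            rule.rule_kind == "polymer_substitution"
            and registry is not None
            and rule.source in registry
        ):
            src_mass = conc * registry.molar_mass(rule.source)
            prod_mass = sum(
                conc * coef * registry.molar_mass(p)
                for p, coef in rule.products
                if p in registry
            )
            if src_mass > 0 and abs(prod_mass - src_mass) / src_mass > 1e-3:
                raise SpeciationError(
                    f"polymer_substitution {rule.source!r}: product mass "
                    f"{prod_mass:.6g} g/L does not conserve source mass "
                    f"{src_mass:.6g} g/L"
                )
        for product, coef in rule.products:
            amount = conc * coef
            if amount <= 0:
                continue
            entries[product] = entries.get(product, 0.0) + amount
            record = ProvenanceRecord(
                source=rule.source,
                rule=rule.rule_kind,
                detail={"coefficient": coef, "source_mmol_per_L": conc},
            )
            prov.setdefault(product, [])
            prov[product] = prov[product] + source_trail + [record]
    return CompiledDiet(entries, prov)


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


def compile_diet(
    recipe: MediumRecipe,
    compositions: Iterable[ComponentComposition],
    rules: Sequence[SpeciationRule],
    registry: CompoundRegistry,
    residue_mass: bool = False,
) -> CompiledDiet:
    """Compile a recipe into a :class:`CompiledDiet` (mmol/L per compound).

    Pipeline order is fixed: decompose -> mass->molar -> merge duplicates by
    summation -> speciation -> environment injection. Every entry carries the
    full provenance of how its concentration was derived.

    ``residue_mass=True`` treats protein-hydrolysate amino-acid fractions as
    residue masses (peptide-bonded), dividing by (MW - MW_water) instead of
    the free amino-acid MW; the default follows manufacturer convention of
    free amino-acid equivalents.

    Raises if a recipe component is neither a registry compound nor covered
    by a composition table, or if an environmental compound (h2o/o2/h) is
    already present when the environment is injected.
    """
    comp_by_id = {c.component_id: c for c in compositions}
    molar: dict[str, float] = {}
    prov: dict[str, list[ProvenanceRecord]] = {}

    def add(cpd: str, mmol: float, records: list[ProvenanceRecord]) -> None:
        if mmol <= 0:
            return
        molar[cpd] = molar.get(cpd, 0.0) + mmol
        prov.setdefault(cpd, []).extend(records)

    for item in recipe.items:
        if item.ingredient in comp_by_id:
            if item.unit != "g/L":
                raise MediumValidationError(
                    f"component {item.ingredient!r} must be given in mass units "
                    f"to be decomposed, got {item.unit}"
                )
            parts = decompose_component(item.amount, comp_by_id[item.ingredient], registry)
            for cpd, mass in parts:
                mw = registry.molar_mass(cpd)
                divisor = mw - WATER_MW if residue_mass else mw
                if divisor <= 0:
                    raise MediumValidationError(
                        f"residue-mass conversion impossible for {cpd!r} (MW {mw})"
                    )
                mmol = mass / divisor * 1000.0
                add(
                    cpd,
                    mmol,
                    [
                        ProvenanceRecord(
                            source=item.ingredient,
                            rule="decompose+mass_to_molar",
                            detail={
                                "component_g_per_L": item.amount,
                                "mass_g_per_L": mass,
                                "molar_mass": mw,
                                "residue_mass": residue_mass,
                            },
                        )
                    ],
                )
        elif item.ingredient in registry:
            cpd = item.ingredient
            if item.unit == "g/L":
                mmol = mass_to_molar(item.amount, registry[cpd])
                rule = "mass_to_molar"
            else:
                mmol = item.amount
                rule = "direct"
            add(
                cpd,
                mmol,
                [
                    ProvenanceRecord(
                        source=cpd,
                        rule=rule,
                        detail={"amount": item.amount, "unit": item.unit},
                    )
                ],
            )
        else:
            raise MediumValidationError(
                f"recipe component {item.ingredient!r} is neither a registry "
                "compound nor covered by a composition table"
            )

    diet = CompiledDiet(molar, prov) if molar else CompiledDiet({}, {})
    diet = apply_speciation(diet, rules, registry)

    env = EnvironmentSpec.from_recipe(recipe)
    injections = [
        (WATER_ID, env.water_mmol_per_L, "aqueous solvent, density 1 g/cm^3"),
        (OXYGEN_ID, env.oxygen_mmol_per_L, "oxygen regime"),
        (PROTON_ID, env.proton_mmol_per_L, f"pH {recipe.pH}"),
    ]
    for cpd, conc, why in injections:
        if conc <= 0:
            continue
        if cpd in diet:
            raise MediumValidationError(
                f"environmental compound {cpd!r} already present in the diet; "
                "remove it from the recipe/composition to avoid double counting"
            )
        diet = diet.with_entry(
            cpd, conc, ProvenanceRecord(source="environment", rule="environment", detail={"why": why})
        )
    return diet


# ---------------------------------------------------------------------------
# rule file I/O: CSV/TSV `source,product,coefficient,rule_kind`
# ---------------------------------------------------------------------------


def read_speciation_rules(path: str | Path, dialect: str | None = None) -> list[SpeciationRule]:
    path = Path(path)
    df = _read_table(path, dialect, {"source", "product", "coefficient", "rule_kind"})
    grouped: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for i, row in df.iterrows():
        try:
            coef = float(row["coefficient"])
        except (TypeError, ValueError):
            raise MediumParseError(
                f"{path}, row {i}: bad coefficient {row['coefficient']!r}"
            ) from None
        key = (str(row["source"]).strip(), str(row["rule_kind"]).strip())
        grouped.setdefault(key, []).append((str(row["product"]).strip(), coef))
    return [
        SpeciationRule(source=src, products=tuple(products), rule_kind=kind)
        for (src, kind), products in grouped.items()
    ]


def write_speciation_rules(
    rules: Iterable[SpeciationRule], path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    rows = [
        {"source": r.source, "product": p, "coefficient": c, "rule_kind": r.rule_kind}
        for r in rules
        for p, c in r.products
    ]
    pd.DataFrame(rows, columns=["source", "product", "coefficient", "rule_kind"]).to_csv(
        path, sep=_sep_for(path, dialect), index=False
    )
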