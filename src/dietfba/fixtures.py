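"""Deterministic toy fixtures with analytically known optima.

Two families:

* :func:`make_toy_model` — a miniature metabolic model (per substrate: one
  exchange, one transport, one internal species; a single biomass reaction
  draining the internal species at fixed stoichiometry, optionally a
  maintenance demand and a redundant parallel transport). Its FBA optimum
  has the closed form ``min_i available_i / stoich_i``, returned alongside
  the model so tests can compare solver output against arithmetic.

* :func:`make_toy_recipe_bundle` — a miniature rich-medium bundle (one
  complex component decomposing to three amino acids, one salt with a
  dissociation rule, one redox-ambiguous metal with an oxidation split, plus
  the aqueous/aerobic environment), exercising every branch of the diet
  compiler.

Everything here is deterministic; fixtures are written in the same public
formats the real pipeline reads (BiGG-style JSON model, CSV recipe /
composition / rules / registry tables).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import scipy.sparse as sp

from .compile import SpeciationRule, write_speciation_rules
from .fba import MetabolicModel
from .medium import (
    Compound,
    CompoundRegistry,
    ComponentComposition,
    CompositionEntry,
    DEFAULT_AEROBIC_OXYGEN_MMOL_PER_L,
    MediumRecipe,
    RecipeItem,
    write_composition_table,
    write_recipe,
)

__all__ = [
    "ToyModelSpec",
    "make_toy_model",
    "make_toy_recipe_bundle",
    "toy_model_to_bigg_json",
    "write_toy_bundle",
]


@dataclass(frozen=True)
class ToyModelSpec:
    """Blueprint for a toy model with a closed-form optimum.

    ``biomass_stoichiometry[i]`` is the mmol of substrate i consumed per unit
    of biomass flux. ``maintenance_demand`` forces that many mmol/L of the
    first substrate through a maintenance drain before any biomass can form.
    ``redundant_pathway`` duplicates the first substrate's transporter,
    creating alternate optima in the flux space (the objective is unchanged).
    ``passive_compounds`` adds exchange-only metabolites the model cannot
    consume — useful to exercise identifier mapping on compounds the network
    ignores.
    """

    biomass_stoichiometry: tuple[float, ...] = (10.0,)
    maintenance_demand: float = 0.0
    redundant_pathway: bool = False
    substrate_ids: tuple[str, ...] | None = None
    passive_compounds: tuple[str, ...] = ()
    name: str = "toy"

    def __post_init__(self) -> None:
        if not self.biomass_stoichiometry:
            raise ValueError("need at least one substrate")
        if any(s <= 0 for s in self.biomass_stoichiometry):
            raise ValueError("biomass stoichiometries must be > 0")
        if self.maintenance_demand < 0:
            raise ValueError("maintenance_demand must be >= 0")
        if self.substrate_ids is not None and len(self.substrate_ids) != len(
            self.biomass_stoichiometry
        ):
            raise ValueError("substrate_ids length must match stoichiometry")

    @property
    def n_substrates(self) -> int:
        return len(self.biomass_stoichiometry)

    @property
    def substrates(self) -> tuple[str, ...]:
        if self.substrate_ids is not None:
            return self.substrate_ids
        return tuple(f"sub{i + 1}" for i in range(self.n_substrates))


_BIG = 1000.0


def make_toy_model(
    spec: ToyModelSpec,
) -> tuple[MetabolicModel, Callable[[Mapping[str, float]], float | None]]:
    """Build the toy model and its closed-form optimum function.

    The returned ``optimum(diet)`` takes compound id -> mmol/L and yields the
    analytic FBA optimum: ``min_i avail_i / stoich_i`` where ``avail_1`` is
    reduced by the maintenance demand; ``None`` marks an infeasible diet
    (maintenance unpayable).
    """
    subs = spec.substrates
    mets: list[str] = []
    rxns: list[str] = []
    entries: dict[tuple[int, int], float] = {}
    lb: list[float] = []
    ub: list[float] = []

    def met(mid: str) -> int:
        if mid not in mets:
            mets.append(mid)
        return mets.index(mid)

    def add_rxn(rid: str, stoich: dict[str, float], low: float, high: float) -> None:
        j = len(rxns)
        rxns.append(rid)
        for mid, coef in stoich.items():
            entries[(met(mid), j)] = coef
        lb.append(low)
        ub.append(high)

    for s in subs:
        add_rxn(f"EX_{s}(e)", {f"{s}_e": -1.0}, 0.0, _BIG)  # uptake closed by default
        add_rxn(f"T_{s}", {f"{s}_e": -1.0, f"{s}_c": 1.0}, 0.0, _BIG)
    if spec.redundant_pathway:
        s = subs[0]
        add_rxn(f"T_{s}_alt", {f"{s}_e": -1.0, f"{s}_c": 1.0}, 0.0, _BIG)
    add_rxn(
        f"BIOMASS_{spec.name}",
        {f"{s}_c": -coef for s, coef in zip(subs, spec.biomass_stoichiometry)},
        0.0,
        _BIG,
    )
    if spec.maintenance_demand > 0:
        add_rxn("MAINT", {f"{subs[0]}_c": -1.0}, spec.maintenance_demand, _BIG)
    for p in spec.passive_compounds:
        add_rxn(f"EX_{p}(e)", {f"{p}_e": -1.0}, 0.0, _BIG)

    S = sp.dok_matrix((len(mets), len(rxns)))
    for (i, j), coef in entries.items():
        S[i, j] = coef
    c = np.zeros(len(rxns))
    c[rxns.index(f"BIOMASS_{spec.name}")] = 1.0

    model = MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        S=sp.csr_matrix(S),
        lb=np.array(lb),
        ub=np.array(ub),
        c=c,
        exchange_reactions=[r for r in rxns if r.startswith("EX_")],
        biomass_reaction=f"BIOMASS_{spec.name}",
        compartment_dialect="(e)",
        name=spec.name,
    )

    stoich = dict(zip(subs, spec.biomass_stoichiometry))
    maintenance = spec.maintenance_demand
    first = subs[0]

    def optimum(diet: Mapping[str, float]) -> float | None:
        avail = {s: float(diet.get(s, 0.0)) for s in subs}
        avail[first] -= maintenance
        if avail[first] < 0:
            return None  # maintenance cannot be paid: LP infeasible
        return min(avail[s] / stoich[s] for s in subs)

    return model, optimum


# ---------------------------------------------------------------------------
# toy recipe bundle
# ---------------------------------------------------------------------------


def make_toy_recipe_bundle() -> tuple[
    MediumRecipe, list[ComponentComposition], list[SpeciationRule], CompoundRegistry
]:
    """A miniature rich-medium bundle exercising every compiler branch.

    One complex component ("peptone", 10 g/L) decomposing to three amino
    acids, one salt (NaCl, 5.844 g/L = 100 mmol/L) with a dissociation rule,
    one metal (iron, 0.1 mmol/L) with a 50/50 oxidation split, in an
    aqueous aerobic pH-7 environment. Compiling it yields exactly 10 diet
    entries: 3 amino acids + 2 salt ions + 2 iron oxidation states + water,
    oxygen and protons.
    """
    registry = CompoundRegistry(
        [
            Compound("gly", "glycine", 75.07, formula="C2H5NO2"),
            Compound("ala__L", "L-alanine", 89.09, formula="C3H7NO2"),
            Compound("glu__L", "L-glutamate", 147.13, formula="C5H9NO4"),
            Compound("nacl", "sodium chloride", 58.44, formula="NaCl"),
            Compound("na1", "sodium ion", 22.99, charge=1),
            Compound("cl", "chloride ion", 35.45, charge=-1),
            Compound("fe", "iron (total)", 55.845),
            Compound("fe2", "Fe2+", 55.845, charge=2),
            Compound("fe3", "Fe3+", 55.845, charge=3),
        ]
    )
    recipe = MediumRecipe(
        items=[
            RecipeItem("peptone", 10.0, "g/L"),
            RecipeItem("nacl", 5.844, "g/L"),
            RecipeItem("fe", 0.1, "mmol/L"),
        ],
        pH=7.0,
        oxygen_mmol_per_L=DEFAULT_AEROBIC_OXYGEN_MMOL_PER_L,
        aqueous=True,
        name="toy_lb_like",
    )
    compositions = [
        ComponentComposition(
            "peptone",
            [
                CompositionEntry("gly", 0.05, source="toy manufacturer sheet"),
                CompositionEntry("ala__L", 0.03, source="toy manufacturer sheet"),
                CompositionEntry("glu__L", 0.02, source="toy manufacturer sheet"),
            ],
        )
    ]
    rules = [
        SpeciationRule("nacl", (("na1", 1.0), ("cl", 1.0)), "dissociation"),
        SpeciationRule("fe", (("fe2", 0.5), ("fe3", 0.5)), "oxidation_split"),
    ]
    return recipe, compositions, rules, registry


# ---------------------------------------------------------------------------
# writing fixtures in public formats
# ---------------------------------------------------------------------------


def toy_model_to_bigg_json(model: MetabolicModel) -> dict:
    """Serialise a model container as a BiGG-style JSON dict."""
    Scsc = model.S.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rows = Scsc.indices[Scsc.indptr[j] : Scsc.indptr[j + 1]]
        coefs = Scsc.data[Scsc.indptr[j] : Scsc.indptr[j + 1]]
        reactions.append(
            {
                "id": rid,
                "name": rid,
                "metabolites": {model.metabolite_ids[i]: float(v) for i, v in zip(rows, coefs)},
                "lower_bound": float(model.lb[j]),
                "upper_bound": float(model.ub[j]),
                "gene_reaction_rule": "",
                "objective_coefficient": float(model.c[j]),
            }
        )
    metabolites = [
        {
            "id": mid,
            "name": mid,
            "compartment": "e" if mid.endswith("_e") else "c",
        }
        for mid in model.metabolite_ids
    ]
    return {
        "id": model.name or "toy",
        "version": "1",
        "metabolites": metabolites,
        "reactions": reactions,
        "genes": [],
        "compartments": {"e": "extracellular", "c": "cytosol"},
    }


def write_toy_bundle(directory: str | Path, spec: ToyModelSpec | None = None) -> dict[str, Path]:
    """Write the toy bundle + a matching toy model to ``directory``.

    The model consumes the bundle's three amino acids and passively exposes
    exchanges for the remaining diet compounds, so every compiled entry maps.
    Returns the paths written, keyed by role.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    recipe, compositions, rules, registry = make_toy_recipe_bundle()
    if spec is None:
        spec = ToyModelSpec(
            biomass_stoichiometry=(5.0, 3.0, 1.0),
            substrate_ids=("gly", "ala__L", "glu__L"),
            passive_compounds=("na1", "cl", "fe2", "fe3", "h2o", "o2", "h"),
            name="toy_lb_like",
        )
    model, _ = make_toy_model(spec)

    paths = {
        "recipe": directory / "recipe.csv",
        "compositions": directory / "compositions.csv",
        "rules": directory / "rules.csv",
        "registry": directory / "registry.csv",
        "model": directory / "model.json",
    }
    write_recipe(recipe, paths["recipe"])
    write_composition_table(compositions, paths["compositions"])
    write_speciation_rules(rules, paths["rules"])
    _write_registry(registry, paths["registry"])
    with open(paths["model"], "w") as fh:
        json.dump(toy_model_to_bigg_json(model), fh, indent=1, sort_keys=True)
    return paths


def _write_registry(registry: CompoundRegistry, path: Path) -> None:
    import pandas as pd

    rows = [
        {
            "id": cpd.id,
            "name": cpd.name,
            "molecular_weight": cpd.molecular_weight,
            "formula": cpd.formula or "",
            "charge": "" if cpd.charge is None else cpd.charge,
            "aliases": "|".join(cpd.aliases),
        }
        for cpd in registry
    ]
    pd.DataFrame(
        rows, columns=["id", "name", "molecular_weight", "formula", "charge", "aliases"]
    ).to_csv(path, index=False)
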