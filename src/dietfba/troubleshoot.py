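"""Diagnose zero or implausible growth via reduced costs on uptake bounds.

When a diet-constrained model refuses to grow, the LP's reduced costs on
exchange reactions point at the nutrients whose absence (closed uptake) or
scarcity (binding uptake bound) limits the objective. The classic example:
a rich-medium formulation missing a trace ion still required by the biomass
reaction — its closed exchange carries the largest absolute reduced cost,
and opening it at a trace concentration restores growth.

Note that a nil-growth solution can equally be caused by defects in the
model itself (missing reactions, wrong bounds, a broken biomass reaction);
this module only repairs the *diet* side and reports when it cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fba import (
    FBAResult,
    GROWTH_THRESHOLD,
    MetabolicModel,
    ModelError,
    OPTIMALITY_TOL,
    solve_fba,
)
from .medium import CompiledDiet, ProvenanceRecord

__all__ = [
    "RepairSuggestion",
    "RepairStep",
    "TroubleshootError",
    "rank_missing_nutrients",
    "repair_diet",
    "DEFAULT_SUGGESTED_BOUND",
]

#: Trace-level concentration (mmol/L) proposed when the user supplies no
#: candidate value; a placeholder that should be replaced by a literature
#: value before the result is taken at face value.
DEFAULT_SUGGESTED_BOUND = 1e-3


class TroubleshootError(RuntimeError):
    pass


@dataclass(frozen=True)
class RepairSuggestion:
    """One candidate nutrient addition, ranked by LP sensitivity."""

    exchange_reaction_id: str
    compound_id: str | None
    reduced_cost_magnitude: float
    suggested_bound: float  # negative lower bound, -mmol/L
    rationale: str


@dataclass
class RepairStep:
    iteration: int
    compound: str
    exchange_reaction_id: str
    bound_mmol_per_L: float
    objective_before: float
    objective_after: float

    def to_json_obj(self) -> dict:
        return {
            "iteration": self.iteration,
            "compound": self.compound,
            "exchange_reaction": self.exchange_reaction_id,
            "bound_mmol_per_L": self.bound_mmol_per_L,
            "objective_before": self.objective_before,
            "objective_after": self.objective_after,
        }


def _solve_with_relaxation(model: MetabolicModel) -> tuple[FBAResult, list[str]]:
    """Solve; if infeasible, relax positive internal lower bounds for diagnosis.

    Maintenance demands (e.g. a fixed ATP-hydrolysis flux) can make the LP
    infeasible outright when the diet supplies too little energy; reduced
    costs only exist for a solved LP, so those demands are temporarily
    relaxed to zero and the relaxation is reported back.
    """
    result = solve_fba(model)
    if result.optimal:
        return result, []
    exchange = set(model.exchange_reactions)
    relaxable = [
        r
        for j, r in enumerate(model.reaction_ids)
        if model.lb[j] > 0 and r not in exchange
    ]
    if result.status != "infeasible" or not relaxable:
        raise TroubleshootError(
            f"FBA is {result.status} and no maintenance-style lower bound can "
            "be relaxed; check the model itself (missing reactions, bounds, "
            "biomass definition) rather than the diet"
        )
    relaxed = model.copy()
    for r in relaxable:
        relaxed.lb[relaxed.reaction_index(r)] = 0.0
    result = solve_fba(relaxed)
    if not result.optimal:
        raise TroubleshootError(
            f"FBA remains {result.status} even with maintenance bounds "
            f"{sorted(relaxable)} relaxed; the model itself is inconsistent"
        )
    return result, sorted(relaxable)


def rank_missing_nutrients(
    model: MetabolicModel,
    reverse_mapping: Mapping[str, str] | None = None,
    suggested_bounds: Mapping[str, float] | None = None,
    min_magnitude: float = OPTIMALITY_TOL,
) -> list[RepairSuggestion]:
    """Rank closed/limiting uptake reactions by absolute reduced cost.

    Considers every exchange reaction whose lower bound is zero (closed
    uptake) or binding at the optimum, and reports those with
    ``|d objective / d lb| > min_magnitude``, sorted by descending magnitude
    with lexicographic tie-break on the reaction id.

    ``reverse_mapping`` (exchange reaction -> compound id) labels suggestions
    with the diet-side compound when known; ``suggested_bounds`` (compound ->
    mmol/L) overrides the trace-level default proposal.
    """
    result, relaxed = _solve_with_relaxation(model)
    suggested_bounds = dict(suggested_bounds or {})
    # infer exchange -> compound from the model's own nomenclature, then let
    # an explicit reverse mapping (e.g. from the diet mapper) override it
    try:
        from .mapping import build_exchange_index

        inferred = {rxn: cpd for cpd, rxn in build_exchange_index(model).items()}
    except Exception:
        inferred = {}
    reverse_mapping = {**inferred, **dict(reverse_mapping or {})}

    suggestions: list[RepairSuggestion] = []
    for rxn in model.exchange_reactions:
        j = model.reaction_index(rxn)
        lb = model.lb[j]
        flux = float(result.fluxes[rxn])
        binding = lb == 0.0 or abs(flux - lb) <= 1e-9 * max(1.0, abs(lb))
        if not binding:
            continue
        rc = float(result.reduced_costs_lower[rxn])
        if abs(rc) <= min_magnitude:
            continue
        compound = reverse_mapping.get(rxn)
        bound = suggested_bounds.get(compound or rxn, DEFAULT_SUGGESTED_BOUND)
        rationale = (
            f"relaxing the uptake bound of {rxn} improves the objective by "
            f"{abs(rc):.3g} per mmol/L"
        )
        if relaxed:
            rationale += f" (maintenance bounds relaxed for diagnosis: {relaxed})"
        if compound is None and bound == DEFAULT_SUGGESTED_BOUND:
            rationale += "; suggested bound is a trace-level placeholder"
        suggestions.append(
            RepairSuggestion(
                exchange_reaction_id=rxn,
                compound_id=compound,
                reduced_cost_magnitude=abs(rc),
                suggested_bound=-abs(bound),
                rationale=rationale,
            )
        )
    suggestions.sort(key=lambda s: (-s.reduced_cost_magnitude, s.exchange_reaction_id))
    return suggestions


def repair_diet(
    model: MetabolicModel,
    diet: CompiledDiet,
    candidate_bounds: Mapping[str, float] | None = None,
    max_iterations: int = 10,
    reverse_mapping: Mapping[str, str] | None = None,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> tuple[CompiledDiet, MetabolicModel, list[RepairStep]]:
    """Iteratively add top-ranked missing nutrients until the model grows.

    Each iteration opens the uptake of the highest-|reduced cost| suggestion
    at the candidate concentration (``candidate_bounds``, keyed by compound
    or exchange-reaction id; trace default otherwise), logs before/after
    objectives, and re-solves. Returns the repaired diet, the re-bounded
    model and the audit trail. An already-growing input returns unchanged
    with an empty trail.

    Raises :class:`TroubleshootError` when ``max_iterations`` additions do
    not restore growth — at that point model curation or gap-filling, not
    diet repair, is the likely fix.
    """
    candidate_bounds = dict(candidate_bounds or {})
    reverse_mapping = dict(reverse_mapping or {})
    work = model.copy()
    trail: list[RepairStep] = []

    for iteration in range(max_iterations + 1):
        result, _ = _solve_with_relaxation(work)
        objective = float(result.objective_value)
        # The relaxation is diagnostic only: growth is judged on the true model.
        true_result = solve_fba(work)
        true_objective = (
            float(true_result.objective_value) if true_result.optimal else 0.0
        )
        if true_result.optimal and true_objective > growth_threshold:
            return diet, work, trail
        if iteration == max_iterations:
            break
        suggestions = rank_missing_nutrients(
            work, reverse_mapping=reverse_mapping, suggested_bounds=candidate_bounds
        )
        if not suggestions:
            raise TroubleshootError(
                "no uptake reaction carries a nonzero reduced cost; the "
                "nil-growth solution points at the model itself — consider "
                "curation or gap-filling (out of scope here)"
            )
        top = suggestions[0]
        j = work.reaction_index(top.exchange_reaction_id)
        work.lb[j] = top.suggested_bound
        compound = top.compound_id or top.exchange_reaction_id
        diet = diet.with_entry(
            compound,
            abs(top.suggested_bound),
            ProvenanceRecord(
                source="troubleshooter",
                rule="repair",
                detail={
                    "exchange_reaction": top.exchange_reaction_id,
                    "reduced_cost_magnitude": top.reduced_cost_magnitude,
                },
            ),
        )
        after = solve_fba(work)
        trail.append(
            RepairStep(
                iteration=iteration + 1,
                compound=compound,
                exchange_reaction_id=top.exchange_reaction_id,
                bound_mmol_per_L=abs(top.suggested_bound),
                objective_before=true_objective,
                objective_after=float(after.objective_value) if after.optimal else 0.0,
            )
        )
    raise TroubleshootError(
        f"growth not restored after {max_iterations} additions "
        f"({[s.compound for s in trail]}); consider model curation or "
        "gap-filling instead of further diet repair"
    )
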