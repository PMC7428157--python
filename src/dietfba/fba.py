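"""Constraint-based model container, diet-to-bounds application, and FBA.

The model container is a plain stoichiometric view (matrix, bounds,
objective, exchange registry) detached from any solver. SBML (Level 3 FBC)
and BiGG-style JSON files are parsed through cobrapy, then converted; the LP
itself is solved through the minimal backend interface in :mod:`dietfba._lp`
so that solver choice stays pluggable and sensitivity conventions are under
our control.

Units. In *yield mode* exchange lower bounds carry concentrations (mmol per
litre of medium); because BiGG biomass reactions are normalised so that unit
flux corresponds to 1 gram dry weight, the optimal objective is then a
biomass yield in gDW per litre of medium. In *rate mode* the bounds carry
uptake fluxes (mmol/gDW/h) and the objective is a growth rate (1/h). The
mathematics is identical; results are labelled with the mode they came from.

Sensitivity conventions. Reduced costs are reported as the derivative of the
(maximised) objective with respect to the variable's own bound:
``reduced_cost_lower[j] = d objective / d lb_j``. An uptake bound that limits
growth therefore has a negative lower reduced cost, and its magnitude is the
growth gained per extra mmol/L of that nutrient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._lp import LPSolution, solve_lp
from .medium import CompiledDiet
from .mapping import MetaboliteMapping

__all__ = [
    "MetabolicModel",
    "FBAResult",
    "ModelError",
    "read_model",
    "from_cobra",
    "apply_diet_bounds",
    "solve_fba",
    "fixed_optimum_flux_range",
    "FEASIBILITY_TOL",
    "OPTIMALITY_TOL",
    "GROWTH_THRESHOLD",
]

#: Steady-state residual tolerance accepted on an optimal solution.
FEASIBILITY_TOL = 1e-9
#: Reduced costs below this magnitude are treated as zero.
OPTIMALITY_TOL = 1e-8
#: Objective above this counts as "the model grows".
GROWTH_THRESHOLD = 1e-6


class ModelError(ValueError):
    """A model violates the container invariants or cannot be read."""


@dataclass
class MetabolicModel:
    """Stoichiometric model: S (metabolites x reactions), bounds, objective.

    ``exchange_reactions`` are the boundary pseudo-reactions — exactly those
    with a single participating metabolite — through which the environment is
    expressed. Negative exchange flux is uptake, positive is secretion.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    exchange_reactions: list[str] = field(default_factory=list)
    biomass_reaction: str | None = None
    compartment_dialect: str = "_e"
    name: str = ""

    def __post_init__(self) -> None:
        m, n = self.S.shape
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != n:
            raise ModelError(
                f"dimension mismatch: S is {m}x{n} but "
                f"{len(self.metabolite_ids)} metabolites / "
                f"{len(self.reaction_ids)} reactions declared"
            )
        for arr, label in ((self.lb, "lb"), (self.ub, "ub"), (self.c, "c")):
            if len(arr) != n:
                raise ModelError(f"{label} has length {len(arr)}, expected {n}")
        if np.any(self.lb > self.ub + 1e-12):
            bad = [self.reaction_ids[j] for j in np.where(self.lb > self.ub + 1e-12)[0]]
            raise ModelError(f"lb > ub for reaction(s) {bad}")
        self._rxn_index = {r: j for j, r in enumerate(self.reaction_ids)}
        self._met_index = {m_: i for i, m_ in enumerate(self.metabolite_ids)}
        if len(self._rxn_index) != n:
            raise ModelError("reaction ids are not unique")

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            c=self.c.copy(),
            exchange_reactions=list(self.exchange_reactions),
            biomass_reaction=self.biomass_reaction,
            compartment_dialect=self.compartment_dialect,
            name=self.name,
        )

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)


@dataclass
class FBAResult:
    """Outcome of one FBA solve.

    ``reduced_costs`` combines the lower- and upper-bound sensitivities
    (at most one of the two binds per reaction):
    ``d objective / d lb`` where the lower bound binds, ``d objective / d ub``
    where the upper bound binds, ~0 elsewhere.
    """

    status: str  # optimal | infeasible | unbounded | ...
    objective_value: float | None
    fluxes: pd.Series | None
    reduced_costs: pd.Series | None
    reduced_costs_lower: pd.Series | None
    reduced_costs_upper: pd.Series | None
    duals: pd.Series | None  # per metabolite, d objective / d accumulation
    mode: str = "yield"
    non_unique: bool | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def objective_units(self) -> str:
        return "gDW/L" if self.mode == "yield" else "1/h"


# ---------------------------------------------------------------------------
# reading models
# ---------------------------------------------------------------------------


def _detect_exchanges(S: sp.spmatrix, reaction_ids: Sequence[str]) -> list[str]:
    """Exchange pseudo-reactions: exactly one participating metabolite."""
    nnz_per_col = np.diff(sp.csc_matrix(S).indptr)
    return [r for r, k in zip(reaction_ids, nnz_per_col) if k == 1]


def from_cobra(cobra_model) -> MetabolicModel:
    """Convert a cobrapy model into the plain stoichiometric container."""
    from cobra.util.array import create_stoichiometric_matrix

    S = sp.csr_matrix(create_stoichiometric_matrix(cobra_model, array_type="lil"))
    reaction_ids = [r.id for r in cobra_model.reactions]
    metabolite_ids = [m.id for m in cobra_model.metabolites]
    lb = np.array([r.lower_bound for r in cobra_model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cobra_model.reactions], dtype=float)
    c = np.array([r.objective_coefficient for r in cobra_model.reactions], dtype=float)
    if not np.any(c):
        raise ModelError(
            "model declares no objective; set an explicit biomass reaction "
            "as the objective before loading"
        )
    biomass = reaction_ids[int(np.flatnonzero(c)[0])]
    exchanges = _detect_exchanges(S, reaction_ids)
    dialect = "(e)" if any(r.endswith("(e)") for r in exchanges) else "_e"
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lb=lb,
        ub=ub,
        c=c,
        exchange_reactions=exchanges,
        biomass_reaction=biomass,
        compartment_dialect=dialect,
        name=getattr(cobra_model, "id", "") or "",
    )


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read an SBML (L3/FBC) or BiGG-style JSON model file.

    ``format`` is inferred from the extension when not given
    (``.xml``/``.sbml`` -> SBML, ``.json`` -> BiGG JSON).
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".xml", ".sbml"):
            format = "sbml"
        elif suffix == ".json":
            format = "json"
        else:
            raise ModelError(
                f"cannot infer model format from {path.name!r}; pass format="
                "'sbml' or 'json'"
            )
    try:
        if format == "sbml":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cobra_model = cobra.io.read_sbml_model(str(path))
        elif format == "json":
            cobra_model = cobra.io.load_json_model(str(path))
        else:
            raise ModelError(f"unknown model format {format!r}")
    except ModelError:
        raise
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ModelError(f"failed to parse {path}: {exc}") from exc
    return from_cobra(cobra_model)


# ---------------------------------------------------------------------------
# applying a diet
# ---------------------------------------------------------------------------


def apply_diet_bounds(
    model: MetabolicModel,
    mappings: Sequence[MetaboliteMapping],
    diet: CompiledDiet,
    mode: str = "yield",
) -> MetabolicModel:
    """Constrain exchange uptake bounds by a compiled diet.

    Every exchange reaction is first closed for uptake (lower bound 0);
    matched/surrogate mappings then open uptake at minus the diet value
    (a concentration in yield mode, an uptake flux in rate mode). Secretion
    upper bounds are never touched. Dropped mappings leave the model
    unchanged apart from the blanket closing, with a warning.
    """
    if mode not in ("yield", "rate"):
        raise ValueError(f"mode must be 'yield' or 'rate', got {mode!r}")
    out = model.copy()
    exchange_set = set(out.exchange_reactions)
    for rxn in out.exchange_reactions:
        j = out.reaction_index(rxn)
        out.lb[j] = 0.0  # compounds absent from the diet get no uptake
    for mp in mappings:
        if mp.status == "dropped":
            warnings.warn(
                f"diet compound {mp.compound_id!r} has no exchange reaction; "
                "its uptake stays closed",
                stacklevel=2,
            )
            continue
        if mp.exchange_reaction_id not in exchange_set:
            raise ModelError(
                f"mapping for {mp.compound_id!r} points at "
                f"{mp.exchange_reaction_id!r}, which is not an exchange reaction"
            )
        if mp.compound_id not in diet:
            continue
        j = out.reaction_index(mp.exchange_reaction_id)
        out.lb[j] = -float(diet[mp.compound_id])
    return out


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


def solve_fba(model: MetabolicModel, mode: str = "yield", backend: str = "scipy-highs") -> FBAResult:
    """Maximise the model objective: ``max c.v, S v = 0, lb <= v <= ub``.

    Infeasible/unbounded LPs are reported in ``status`` without raising.
    On an optimal solution the steady-state residual and bound violations are
    checked against :data:`FEASIBILITY_TOL` scaled by problem size.
    """
    if not np.any(model.c):
        raise ModelError("model has no objective coefficients")
    sol = solve_lp(model.c, model.S, np.zeros(model.n_metabolites), model.lb, model.ub, backend=backend)
    if not sol.optimal:
        return FBAResult(sol.status, None, None, None, None, None, None, mode=mode)

    v = sol.x
    residual = np.abs(model.S @ v)
    scale = max(1.0, float(np.abs(v).max()))
    if residual.size and residual.max() > 1e-6 * scale:
        raise ModelError(
            f"solver returned a solution violating steady state "
            f"(max |S.v| = {residual.max():.3g})"
        )

    idx = pd.Index(model.reaction_ids, name="reaction")
    rc_lower = pd.Series(sol.reduced_cost_lower, index=idx)
    rc_upper = pd.Series(sol.reduced_cost_upper, index=idx)
    return FBAResult(
        status="optimal",
        objective_value=float(sol.objective) + 0.0,  # normalise -0.0
        fluxes=pd.Series(v, index=idx),
        reduced_costs=rc_lower + rc_upper,
        reduced_costs_lower=rc_lower,
        reduced_costs_upper=rc_upper,
        duals=pd.Series(sol.eq_duals, index=pd.Index(model.metabolite_ids, name="metabolite")),
        mode=mode,
    )


def fixed_optimum_flux_range(
    model: MetabolicModel,
    reaction_id: str,
    optimum: float,
    rel_tol: float = 1e-6,
    backend: str = "scipy-highs",
) -> tuple[float, float]:
    """Min/max flux of one reaction with the objective held at its optimum.

    The objective is constrained to ``>= optimum * (1 - rel_tol)`` (absolute
    slack ``rel_tol`` when the optimum is ~0), i.e. flux variability analysis
    at the optimum; a range wider than ~0 flags alternate optima. Raises if
    fixing makes the LP infeasible (tolerance too tight for the solver).
    """
    j = model.reaction_index(reaction_id)
    slack = abs(optimum) * rel_tol if abs(optimum) > rel_tol else rel_tol
    A_ub = sp.csr_matrix(-model.c.reshape(1, -1))
    b_ub = np.array([-(optimum - slack)])
    b_eq = np.zeros(model.n_metabolites)

    out = []
    for sense in (-1.0, +1.0):  # minimise then maximise v_j
        c = np.zeros(model.n_reactions)
        c[j] = sense
        sol = solve_lp(c, model.S, b_eq, model.lb, model.ub, A_ub=A_ub, b_ub=b_ub, backend=backend)
        if not sol.optimal:
            raise ModelError(
                f"flux range for {reaction_id!r} at objective {optimum:.6g} is "
                f"{sol.status}; the optimum-fixing tolerance may be too tight"
            )
        out.append(sense * sol.objective)
    vmin, vmax = out
    return float(vmin), float(vmax)
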