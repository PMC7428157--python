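"""Minimal pluggable LP interface used by the FBA core.

The contract is deliberately small: a maximisation problem

    max  c.v
    s.t. A_eq.v = b_eq,  A_ub.v <= b_ub,  lb <= v <= ub

goes in; status, primal solution, equality duals and bound reduced costs come
out. Reduced costs follow the *maximisation* sensitivity convention:

    reduced_cost_lower[j] = d(optimal objective) / d(lb[j])
    reduced_cost_upper[j] = d(optimal objective) / d(ub[j])

so a beneficial nutrient whose uptake bound lb is binding has a *negative*
lower reduced cost (making lb more negative, i.e. allowing more uptake,
raises the objective). Backends register under a name in :data:`BACKENDS`;
the default is scipy's HiGHS interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = ["LPSolution", "solve_lp", "BACKENDS"]

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class LPSolution:
    status: str  # "optimal" | "infeasible" | "unbounded" | other solver states
    objective: float | None
    x: np.ndarray | None
    eq_duals: np.ndarray | None  # d(objective)/d(b_eq)
    reduced_cost_lower: np.ndarray | None  # d(objective)/d(lb)
    reduced_cost_upper: np.ndarray | None  # d(objective)/d(ub)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _solve_scipy_highs(
    c: np.ndarray,
    A_eq,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub=None,
    b_ub=None,
) -> LPSolution:
    # linprog minimises; negate the objective and flip sensitivities back.
    bounds = np.column_stack([lb, ub])
    res = linprog(
        -np.asarray(c, dtype=float),
        A_eq=sp.csr_matrix(A_eq) if A_eq is not None else None,
        b_eq=b_eq,
        A_ub=sp.csr_matrix(A_ub) if A_ub is not None else None,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, f"solver_status_{res.status}")
    if status != "optimal":
        return LPSolution(status, None, None, None, None, None)
    return LPSolution(
        status="optimal",
        objective=-float(res.fun),
        x=np.asarray(res.x, dtype=float),
        # min-problem marginals are d(min -c.v)/d(.): negate for the max problem
        eq_duals=-np.asarray(res.eqlin.marginals, dtype=float),
        reduced_cost_lower=-np.asarray(res.lower.marginals, dtype=float),
        reduced_cost_upper=-np.asarray(res.upper.marginals, dtype=float),
    )


BACKENDS: dict[str, Callable[..., LPSolution]] = {"scipy-highs": _solve_scipy_highs}


def solve_lp(
    c,
    A_eq,
    b_eq,
    lb,
    ub,
    A_ub=None,
    b_ub=None,
    backend: str = "scipy-highs",
) -> LPSolution:
    """Solve ``max c.v  s.t.  A_eq v = b_eq, A_ub v <= b_ub, lb <= v <= ub``."""
    try:
        fn = BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown LP backend {backend!r}; have {sorted(BACKENDS)}") from None
    return fn(
        np.asarray(c, dtype=float),
        A_eq,
        np.asarray(b_eq, dtype=float),
        np.asarray(lb, dtype=float),
        np.asarray(ub, dtype=float),
        A_ub,
        None if b_ub is None else np.asarray(b_ub, dtype=float),
    )
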