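"""Independent oracles used by the test suite.

These deliberately avoid the package's LP path: the vertex enumerator solves
small FBA problems by exhaustive basic-solution search, and the relaxation
oracle ranks missing nutrients by actually re-solving after each candidate
addition (using brute force again), so agreement with the implementation is
meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_lp_max(S, lb, ub, c, tol: float = 1e-9):
    """Maximise ``c.v`` s.t. ``S v = 0, lb <= v <= ub`` by vertex enumeration.

    Enumerates candidate vertices as solutions of the equality system with
    ``n - rank(S)`` bounds held active, keeps the feasible ones, and returns
    ``(best objective, best vertex)`` or ``(None, None)`` if no feasible
    vertex exists. Only sensible for a handful of reactions.
    """
    S = np.asarray(S.todense() if hasattr(S, "todense") else S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0
    k = n - rank
    bound_rows = [(j, lb[j]) for j in range(n) if np.isfinite(lb[j])] + [
        (j, ub[j]) for j in range(n) if np.isfinite(ub[j])
    ]
    best_obj, best_v = None, None
    for combo in itertools.combinations(bound_rows, k):
        A = np.vstack([S] + [np.eye(n)[j] for j, _ in combo]) if combo else S
        b = np.concatenate([np.zeros(m), [val for _, val in combo]])
        if np.linalg.matrix_rank(A) < n:
            continue
        v, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ v - b)) > tol:
            continue
        if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
            continue
        obj = float(c @ v)
        if best_obj is None or obj > best_obj:
            best_obj, best_v = obj, v
    return best_obj, best_v


def exhaustive_single_relaxation(model, amount: float = 1.0):
    """Objective gain from granting each exchange ``amount`` extra mmol/L.

    Relaxes every exchange uptake bound one at a time (closed bounds open at
    ``-amount``, finite bounds deepen by ``amount``), solves each relaxed LP
    by brute force, and returns a dict exchange-reaction -> gained objective;
    an infeasible baseline counts as objective 0.
    """
    base_obj, _ = brute_force_lp_max(model.S, model.lb, model.ub, model.c)
    base = base_obj if base_obj is not None else 0.0
    gains = {}
    for rxn in model.exchange_reactions:
        j = model.reaction_index(rxn)
        lb = model.lb.copy()
        lb[j] -= amount
        obj, _ = brute_force_lp_max(model.S, lb, model.ub, model.c)
        gains[rxn] = (obj if obj is not None else 0.0) - base
    return gains
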