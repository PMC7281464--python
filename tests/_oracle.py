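"""Brute-force LP oracle: exhaustive vertex enumeration for tiny FBA models.

Independent of the package's LP route (optlang/GLPK via cobrapy): builds the
stoichiometric matrix with plain numpy, enumerates every basic solution of
{v : S v = 0, L <= v <= U} by fixing n - rank(S) fluxes at a bound and
solving the remaining square-ish system, filters to feasible vertices and
takes the best objective value.  Only usable for models with ~10 reactions.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

FEAS_TOL = 1e-7


def stoichiometric_matrix(model) -> tuple[np.ndarray, list[str]]:
    mets = [m.id for m in model.metabolites]
    rxns = [r.id for r in model.reactions]
    S = np.zeros((len(mets), len(rxns)))
    mi = {m: i for i, m in enumerate(mets)}
    for j, r in enumerate(model.reactions):
        for met, coef in r.metabolites.items():
            S[mi[met.id], j] = coef
    return S, rxns


def enumerate_vertices(S: np.ndarray, L: np.ndarray, U: np.ndarray):
    """Yield all vertices of {v : S v = 0, L <= v <= U}."""
    m, n = S.shape
    rank = np.linalg.matrix_rank(S, tol=1e-10)
    n_fix = n - rank
    idx = range(n)
    for fixed in combinations(idx, n_fix):
        free = [j for j in idx if j not in fixed]
        S_free = S[:, free]
        if np.linalg.matrix_rank(S_free, tol=1e-10) < len(free):
            continue  # degenerate basis; any vertex here also appears elsewhere
        for choice in product((0, 1), repeat=n_fix):
            v = np.zeros(n)
            for j, c in zip(fixed, choice):
                v[j] = L[j] if c == 0 else U[j]
            rhs = -S[:, fixed] @ v[list(fixed)]
            sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            v[free] = sol
            if np.max(np.abs(S @ v)) > FEAS_TOL:
                continue
            if np.any(v < L - FEAS_TOL) or np.any(v > U + FEAS_TOL):
                continue
            yield v


def oracle_fba(model, objective: str, sense: str = "max",
               bound_overrides=None) -> tuple[str, float | None]:
    """Optimal objective value by exhaustive vertex enumeration.

    Returns ("optimal", value) or ("infeasible", None).  All toy-model bounds
    are finite, so the feasible set is a polytope and the optimum sits on a
    vertex.
    """
    S, rxns = stoichiometric_matrix(model)
    L = np.array([model.reactions.get_by_id(r).lower_bound for r in rxns])
    U = np.array([model.reactions.get_by_id(r).upper_bound for r in rxns])
    for rid, (lo, hi) in (bound_overrides or {}).items():
        j = rxns.index(rid)
        L[j], U[j] = lo, hi
    j_obj = rxns.index(objective)
    best = None
    for v in enumerate_vertices(S, L, U):
        val = v[j_obj]
        if best is None:
            best = val
        elif sense == "max":
            best = max(best, val)
        else:
            best = min(best, val)
    if best is None:
        return "infeasible", None
    return "optimal", float(best)
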