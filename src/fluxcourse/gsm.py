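"""Constraint-based model loading and single FBA solves.

Models are held as :class:`cobra.Model` objects (SBML Level 3 + FBC or the
community JSON dialect).  ``solve_fba`` runs one linear program — maximise or
minimise a reaction flux subject to S·v = 0 and bounds — and reports status as
data, never as an exception: an infeasible step of the dFBA relaxation loop is
an expected outcome, not an error.

Sign convention: exchange fluxes are negative for uptake and positive for
secretion.  User-facing uptake rates elsewhere in the package are nonnegative
magnitudes; the mapping onto exchange bounds happens in :mod:`fluxcourse.dfba`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import cobra
import cobra.io
from cobra.util.solver import OptimizationError

__all__ = ["FBAResult", "load_model", "solve_fba", "exchange_reaction_ids"]

#: default solver tolerances (feasibility, optimality)
FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-7


@dataclass(frozen=True)
class FBAResult:
    """Outcome of one FBA linear program."""

    status: str  # "optimal", "infeasible", "unbounded", ...
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def load_model(path, dialect: str | None = None) -> cobra.Model:
    """Load a genome-scale model from SBML (L3+FBC) or JSON.

    ``dialect`` is ``"sbml_fbc"`` or ``"json"``; inferred from the file
    extension when omitted (.xml/.sbml -> SBML, .json -> JSON).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if dialect is None:
        suffix = p.suffix.lower()
        if suffix in (".xml", ".sbml"):
            dialect = "sbml_fbc"
        elif suffix == ".json":
            dialect = "json"
        else:
            raise ValueError(
                f"cannot infer model dialect from extension {suffix!r}; "
                "pass dialect='sbml_fbc' or 'json'"
            )
    if dialect == "sbml_fbc":
        model = cobra.io.read_sbml_model(str(p))
    elif dialect == "json":
        model = cobra.io.load_json_model(str(p))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not model.boundary:
        raise ValueError(
            f"model {model.id or p.name!r} has no boundary (exchange) reactions"
        )
    _configure_solver(model)
    return model


def _configure_solver(
    model: cobra.Model,
    feasibility_tol: float = FEASIBILITY_TOL,
    optimality_tol: float = OPTIMALITY_TOL,
) -> None:
    model.tolerance = max(feasibility_tol, 1e-9)
    try:
        model.solver.configuration.tolerances.optimality = optimality_tol
    except (AttributeError, ValueError):
        pass  # not every optlang backend exposes an optimality knob


def exchange_reaction_ids(model: cobra.Model) -> list[str]:
    """Ids of boundary reactions (single-metabolite stoichiometry)."""
    return [r.id for r in model.exchanges]


def solve_fba(
    model: cobra.Model,
    objective: str,
    sense: str = "max",
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
    *,
    full_fluxes: bool = True,
) -> FBAResult:
    """Solve one FBA LP: optimise ``objective`` subject to S·v = 0 and bounds.

    ``bound_overrides`` maps reaction ids to (lower, upper) pairs applied for
    this solve only; the model's stored bounds are restored afterwards.
    Infeasible or unbounded problems are reported via ``FBAResult.status``.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    if objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    overrides = dict(bound_overrides or {})
    for rid, (lo, hi) in overrides.items():
        if rid not in model.reactions:
            raise KeyError(f"override reaction {rid!r} not in model")
        if lo > hi:
            raise ValueError(
                f"override for {rid!r} has lower {lo} > upper {hi}"
            )
    with model:
        for rid, (lo, hi) in overrides.items():
            model.reactions.get_by_id(rid).bounds = (lo, hi)
        model.objective = model.reactions.get_by_id(objective)
        model.objective_direction = sense
        try:
            if full_fluxes:
                with warnings.catch_warnings():
                    # infeasible is an expected outcome of the relaxation loop
                    warnings.filterwarnings(
                        "ignore", message="Solver status", category=UserWarning
                    )
                    sol = model.optimize(raise_error=False)
                status = sol.status
                obj = sol.objective_value
                fluxes = (
                    {r: float(v) for r, v in sol.fluxes.items()}
                    if status == "optimal"
                    else {}
                )
            else:
                obj = model.slim_optimize(error_value=float("nan"))
                status = model.solver.status
                fluxes = {}
        except OptimizationError as exc:  # pragma: no cover - defensive
            return FBAResult(status=str(exc), objective_value=None)
    if status != "optimal" or (obj is not None and not math.isfinite(obj)):
        return FBAResult(status=status if status != "optimal" else "unbounded",
                         objective_value=None)
    return FBAResult(status="optimal", objective_value=float(obj), fluxes=fluxes)
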