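"""Sequential two-step dFBA with iterative constraint relaxation.

At each node of a uniform time grid the driver:

1. evaluates the target specific glucose-uptake rate and specific growth rate
   from the fitted-polynomial profile (both already clamped at zero),
2. solves the *first-step* FBA — maximise growth — inside the multiplicative
   relaxation band target*(1 - d(n-1)) .. target*(1 + d(n-1)), starting from a
   zero-width band at n = 1 and widening by +/- d per repetition until the LP
   is optimal,
3. solves the *second-step* FBA — growth fixed at the first-step optimum,
   maximise the product exchange flux (held at zero during the induction
   phase),
4. extends the running Simpson integrals of substrate, product, biomass and
   medium amino acids, switching an amino acid's uptake off permanently once
   its integrated concentration reaches zero.

The uptake band is expressed on nonnegative uptake magnitudes and mapped to
exchange-flux bounds with the standard sign convention (uptake negative):
uptake in [lo, hi] corresponds to exchange flux in [-hi, -lo].  Relaxed lower
bounds are floored at zero so the band never permits secretion of the
substrate or biomass decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import cobra

from .gsm import FBAResult, solve_fba
from .integration import BiomassIntegral, RunningIntegral
from .timecourse import ConstraintProfile

__all__ = [
    "MediumComponent",
    "DfbaConfig",
    "StepResult",
    "DfbaTrajectory",
    "DfbaStepError",
    "relaxation_band",
    "relaxed_two_step_fba",
    "apply_depletion_rules",
    "run_dfba",
]

#: concentrations below this (mM) count as depleted
DEPLETION_TOL = 1e-9
#: relative slack applied when fixing step-2 growth at the step-1 optimum
GROWTH_FIX_SLACK = 1e-6


@dataclass(frozen=True)
class MediumComponent:
    """One supplemented medium species tracked for depletion switching."""

    exchange_id: str
    initial_mM: float
    max_uptake: float = 1000.0  # mmol/g DCW/h; effectively demand-limited

    def __post_init__(self) -> None:
        if self.initial_mM < 0:
            raise ValueError(f"{self.exchange_id}: initial concentration < 0")
        if self.max_uptake < 0:
            raise ValueError(f"{self.exchange_id}: max uptake < 0")


@dataclass(frozen=True)
class DfbaConfig:
    """Settings for one sequential dFBA run."""

    biomass_reaction: str
    substrate_exchange: str
    product_exchange: str
    t_start: float = 0.0
    t_end: float = 27.0
    step: float = 0.01  # h
    relax_increment: float = 0.01  # d in the multiplicative band
    n_max: int = 101  # band reaches +/-100% before the step fails
    induction_end: float = 2.0  # h; product export forced to 0 before this
    medium: tuple[MediumComponent, ...] = ()
    initial_substrate_mM: float = 0.0
    initial_biomass: float = 0.0  # g DCW/L
    track_exchanges: tuple[str, ...] = ()
    store_full_fluxes: bool = False

    @property
    def tracked_exchanges(self) -> list[str]:
        """Exchange ids whose concentrations are integrated during the run."""
        out = [self.substrate_exchange, self.product_exchange]
        out += [c.exchange_id for c in self.medium]
        out += [r for r in self.track_exchanges if r not in out]
        return out

    def __post_init__(self) -> None:
        if self.t_start > self.t_end:
            raise ValueError("t_start must be <= t_end")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.relax_increment <= 0:
            raise ValueError("relax_increment (d) must be > 0")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        object.__setattr__(self, "medium", tuple(self.medium))
        object.__setattr__(self, "track_exchanges", tuple(self.track_exchanges))

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.step))
        return self.t_start + self.step * np.arange(n + 1)


@dataclass(frozen=True)
class StepResult:
    """Flux snapshot from the two-step FBA at one grid node."""

    time: float
    relaxation_count: int  # n at which step 1 first became optimal
    growth_rate: float  # 1/h, step-1 optimum (held in step 2)
    uptake_rate: float  # mmol/g DCW/h, positive consumption magnitude
    product_flux: float  # mmol/g DCW/h
    status: str = "optimal"
    fluxes: dict = field(default_factory=dict)


class DfbaStepError(RuntimeError):
    """Raised when a grid node stays infeasible through n_max relaxations."""

    def __init__(self, time: float, n_max: int, last_status: str):
        self.time = time
        self.n_max = n_max
        self.last_status = last_status
        super().__init__(
            f"no optimal solution at t={time:.4f} h within {n_max} relaxations "
            f"(last solver status: {last_status})"
        )


@dataclass
class DfbaTrajectory:
    """Per-node flux snapshots plus integrated concentration time courses."""

    times: np.ndarray
    steps: list[StepResult]
    concentrations: dict[str, np.ndarray]  # mM, floored at 0 for reporting
    biomass: np.ndarray  # g DCW/L
    raw_concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    config: DfbaConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: time, n, mu, v_uptake, v_product, concentrations."""
        df = pd.DataFrame(
            {
                "time": self.times,
                "n": [s.relaxation_count for s in self.steps],
                "mu": [s.growth_rate for s in self.steps],
                "v_uptake": [s.uptake_rate for s in self.steps],
                "v_product": [s.product_flux for s in self.steps],
                "biomass": self.biomass,
            }
        )
        for rid, series in self.concentrations.items():
            df[rid] = series
        return df

    def final_concentration(self, exchange_id: str) -> float:
        return float(self.concentrations[exchange_id][-1])


def relaxation_band(target: float, n: int, d: float) -> tuple[float, float]:
    """Multiplicative relaxation band target*{1 -+ d(n-1)}, floored at zero.

    n = 1 gives the zero-width band [target, target]; a zero target stays the
    degenerate band {0} for every n, as the multiplicative formula dictates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    width = d * (n - 1)
    lo = max(0.0, target * (1.0 - width))
    hi = target * (1.0 + width)
    return lo, hi


def _uptake_overrides(exchange_id: str, lo: float, hi: float) -> dict:
    # uptake magnitude in [lo, hi]  <=>  exchange flux in [-hi, -lo]
    return {exchange_id: (-hi, -lo)}


def relaxed_two_step_fba(
    model: cobra.Model,
    t: float,
    uptake_target: float,
    growth_target: float,
    config: DfbaConfig,
    extra_overrides: dict | None = None,
) -> StepResult:
    """Two-step FBA at one time point with the iterative relaxation loop.

    Step 1 maximises growth inside the relaxation band around both targets,
    incrementing n until the LP is optimal.  Step 2 fixes growth at the
    step-1 optimum (with a small relative slack) and maximises the product
    exchange flux; during induction (t < induction_end) the product exchange
    upper bound is zero.
    """
    if uptake_target < 0 or growth_target < 0:
        raise ValueError("targets must be clamped nonnegative before the solve")
    base = dict(extra_overrides or {})
    if t < config.induction_end:
        rxn = model.reactions.get_by_id(config.product_exchange)
        base[config.product_exchange] = (min(rxn.lower_bound, 0.0), 0.0)

    last_status = "infeasible"
    for n in range(1, config.n_max + 1):
        up_lo, up_hi = relaxation_band(uptake_target, n, config.relax_increment)
        mu_lo, mu_hi = relaxation_band(growth_target, n, config.relax_increment)
        overrides = {
            **base,
            **_uptake_overrides(config.substrate_exchange, up_lo, up_hi),
            config.biomass_reaction: (mu_lo, mu_hi),
        }
        step1 = solve_fba(
            model, config.biomass_reaction, "max", overrides, full_fluxes=False
        )
        if step1.ok:
            break
        last_status = step1.status
    else:
        raise DfbaStepError(t, config.n_max, last_status)

    mu_opt = step1.objective_value
    slack = GROWTH_FIX_SLACK * max(abs(mu_opt), 1.0)
    overrides[config.biomass_reaction] = (max(0.0, mu_opt - slack), mu_opt + slack)
    step2 = solve_fba(
        model, config.product_exchange, "max", overrides, full_fluxes=True
    )
    if not step2.ok:
        # widen the growth fix slightly; degenerate boundary cases only
        overrides[config.biomass_reaction] = (
            max(0.0, mu_opt * (1 - 1e-4)),
            mu_opt * (1 + 1e-4) + 1e-12,
        )
        step2 = solve_fba(
            model, config.product_exchange, "max", overrides, full_fluxes=True
        )
    if not step2.ok:
        raise DfbaStepError(t, n, f"step 2 {step2.status}")

    fluxes = step2.fluxes
    if config.store_full_fluxes:
        kept = dict(fluxes)
    else:  # always keep the tracked subset: depletion switching reads it
        kept = {
            rid: fluxes.get(rid, 0.0)
            for rid in (*config.tracked_exchanges, config.biomass_reaction)
        }
    return StepResult(
        time=t,
        relaxation_count=n,
        growth_rate=float(fluxes[config.biomass_reaction]),
        uptake_rate=float(-fluxes[config.substrate_exchange]),
        product_flux=float(fluxes[config.product_exchange]),
        status="optimal",
        fluxes=kept,
    )


def apply_depletion_rules(
    medium_state: dict[str, float],
    depleted: set[str],
    medium: Sequence[MediumComponent],
) -> dict[str, tuple[float, float]]:
    """Exchange-bound overrides for supplemented medium components.

    A component whose running integrated concentration is <= 0 (within
    tolerance) joins ``depleted`` permanently and its uptake bound becomes 0;
    otherwise uptake is allowed up to its configured magnitude.  Secretion
    stays open.  ``depleted`` is updated in place.
    """
    overrides: dict[str, tuple[float, float]] = {}
    for comp in medium:
        if comp.exchange_id in depleted or (
            medium_state.get(comp.exchange_id, comp.initial_mM) <= DEPLETION_TOL
        ):
            depleted.add(comp.exchange_id)
            overrides[comp.exchange_id] = (0.0, 1000.0)
        else:
            overrides[comp.exchange_id] = (-comp.max_uptake, 1000.0)
    return overrides


def run_dfba(
    model: cobra.Model,
    profile: ConstraintProfile,
    config: DfbaConfig,
) -> DfbaTrajectory:
    """Run the sequential dFBA over the uniform grid of ``config``.

    Targets are evaluated at the left endpoint of each step interval (every
    grid node); concentration integrals advance concurrently with the solves
    so depletion switching sees up-to-date values.
    """
    times = config.times
    if config.substrate_exchange not in profile.uptake_targets:
        raise KeyError(
            f"profile has no uptake target for {config.substrate_exchange!r}"
        )
    tracked = config.tracked_exchanges

    initial = {rid: 0.0 for rid in tracked}
    initial[config.substrate_exchange] = config.initial_substrate_mM
    for comp in config.medium:
        initial[comp.exchange_id] = comp.initial_mM

    integrals = {
        rid: RunningIntegral(config.step, initial[rid]) for rid in tracked
    }
    biomass = BiomassIntegral(config.step, config.initial_biomass)
    depleted: set[str] = set()
    steps: list[StepResult] = []

    prev_flux: dict[str, float] = {}
    for i, t in enumerate(times):
        medium_state = {rid: integrals[rid].value for rid in integrals}
        medium_overrides = apply_depletion_rules(medium_state, depleted, config.medium)
        uptake_target = profile.uptake_targets[config.substrate_exchange](t)
        growth_target = profile.growth_target(t)
        step = relaxed_two_step_fba(
            model, t, uptake_target, growth_target, config, medium_overrides
        )
        steps.append(step)
        x_t = biomass.append(step.growth_rate)
        pair_done = i >= 2 and i % 2 == 0
        for rid in tracked:
            v = step.fluxes.get(rid, 0.0)
            if pair_done:
                # biomass midpoint was refined: re-sample the pair midpoint
                corrected = prev_flux[rid] * biomass.values[i - 1]
                integrals[rid].append(v * x_t, corrected_prev=corrected)
            else:
                integrals[rid].append(v * x_t)
            prev_flux[rid] = v

    raw = {rid: integrals[rid].series() for rid in tracked}
    concentrations = {rid: np.maximum(series, 0.0) for rid, series in raw.items()}
    return DfbaTrajectory(
        times=times,
        steps=steps,
        concentrations=concentrations,
        biomass=biomass.series(),
        raw_concentrations=raw,
        config=config,
    )
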