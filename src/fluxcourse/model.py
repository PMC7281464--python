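"""Model/Results front end for the kinetics-free dFBA workflow.

:class:`KineticsFreeDFBA` bundles the inputs of one analysis — a genome-scale
metabolic model, the experimental glucose and biomass time courses, and the
run settings — and its :meth:`~KineticsFreeDFBA.fit` performs the whole
pipeline: polynomial approximation of the time courses, conversion to
specific-rate constraint profiles, the sequential two-step FBA with
constraint relaxation, Simpson re-integration of fluxes into concentrations,
and (when an experimental product measurement is supplied) the
production-performance evaluation.  The returned :class:`DFBAResults` carries
the fitted polynomials, the trajectory, the performance report and a
``summary()`` table, with plotting attached.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import cobra

from . import timecourse as tc
from .dfba import DfbaConfig, DfbaTrajectory, MediumComponent, run_dfba
from .performance import PerformanceReport, report as performance_report

__all__ = ["KineticsFreeDFBA", "DFBAResults"]


class KineticsFreeDFBA:
    """Sequential dFBA analysis of one fermentation experiment.

    Parameters
    ----------
    gsm : cobra.Model
        Constraint-based metabolic model of the producing strain.
    glucose, biomass : TimeCourseSeries
        Experimental substrate and cell-concentration time courses in
        canonical units (mM and g DCW/L; use ``timecourse.convert_units``
        first for g/L or OD600 data).
    biomass_reaction, substrate_exchange, product_exchange : str
        Reaction ids in ``gsm``: the growth objective, the substrate exchange
        driven by the fitted uptake profile, and the product exchange
        maximised in the second FBA step.
    product : TimeCourseSeries, optional
        Experimental product concentrations (mM); enables the performance
        report on the fitted results.
    medium : sequence of MediumComponent, optional
        Supplemented species tracked for depletion switching.
    fit_order : int, default 5
        Polynomial order for both concentration fits.
    fit_segments : sequence of float, optional
        Interior breakpoints for segmented fits.
    t_end : float, optional
        Simulation horizon; defaults to the last biomass sample time.
    step, relax_increment, n_max, induction_end
        Passed through to :class:`~fluxcourse.dfba.DfbaConfig`.
    """

    def __init__(
        self,
        gsm: cobra.Model,
        glucose: tc.TimeCourseSeries,
        biomass: tc.TimeCourseSeries,
        *,
        biomass_reaction: str,
        substrate_exchange: str,
        product_exchange: str,
        product: tc.TimeCourseSeries | None = None,
        medium: Sequence[MediumComponent] = (),
        fit_order: int = 5,
        fit_segments: Sequence[float] | None = None,
        t_start: float | None = None,
        t_end: float | None = None,
        step: float = 0.01,
        relax_increment: float = 0.01,
        n_max: int = 101,
        induction_end: float = 2.0,
        store_full_fluxes: bool = False,
    ):
        for unit, series, name in (
            ("mM", glucose, "glucose"),
            ("gDCW_per_L", biomass, "biomass"),
        ):
            if series.unit != unit:
                raise ValueError(
                    f"{name} series must be in {unit} (got {series.unit!r}); "
                    "convert with timecourse.convert_units first"
                )
        for rid in (biomass_reaction, substrate_exchange, product_exchange):
            if rid not in gsm.reactions:
                raise KeyError(f"reaction {rid!r} not in model {gsm.id!r}")
        self.gsm = gsm
        self.glucose = glucose
        self.biomass = biomass
        self.product = product
        self.fit_order = fit_order
        self.fit_segments = tuple(fit_segments) if fit_segments else None
        self.config = DfbaConfig(
            biomass_reaction=biomass_reaction,
            substrate_exchange=substrate_exchange,
            product_exchange=product_exchange,
            t_start=glucose.times[0] if t_start is None else t_start,
            t_end=biomass.times[-1] if t_end is None else t_end,
            step=step,
            relax_increment=relax_increment,
            n_max=n_max,
            induction_end=induction_end,
            medium=tuple(medium),
            initial_substrate_mM=float(glucose.values[0]),
            initial_biomass=float(biomass.values[0]),
            store_full_fluxes=store_full_fluxes,
        )

    @classmethod
    def from_dataframe(
        cls,
        gsm: cobra.Model,
        data: pd.DataFrame,
        *,
        time_col: str = "time",
        glucose_col: str = "glucose",
        biomass_col: str = "biomass",
        product_col: str | None = None,
        glucose_unit: str = "mM",
        biomass_unit: str = "gDCW_per_L",
        glucose_molar_mass: float | None = None,
        od_factor: float | None = None,
        **kwargs,
    ) -> "KineticsFreeDFBA":
        """Build the model from a tidy DataFrame of measurements.

        Columns hold time (h) and concentrations; non-canonical units are
        converted on the way in (``glucose_molar_mass`` for g/L glucose,
        ``od_factor`` for OD600 biomass).
        """
        t = data[time_col].to_numpy(float)
        glucose = tc.convert_units(
            tc.TimeCourseSeries("glucose", t, data[glucose_col].to_numpy(float),
                                glucose_unit),
            molar_mass=glucose_molar_mass,
        )
        biomass = tc.convert_units(
            tc.TimeCourseSeries("biomass", t, data[biomass_col].to_numpy(float),
                                biomass_unit),
            od_factor=od_factor,
        )
        product = None
        if product_col is not None:
            mask = np.isfinite(data[product_col].to_numpy(float))
            product = tc.TimeCourseSeries(
                "product", t[mask], data[product_col].to_numpy(float)[mask], "mM"
            )
        return cls(gsm, glucose, biomass, product=product, **kwargs)

    def fit(self) -> "DFBAResults":
        """Run the full pipeline and return the results object."""
        glucose_fit = tc.fit_polynomial(self.glucose, self.fit_order, self.fit_segments)
        biomass_fit = tc.fit_polynomial(self.biomass, self.fit_order, self.fit_segments)
        profile = tc.ConstraintProfile.from_polynomials(
            {self.config.substrate_exchange: glucose_fit}, biomass_fit
        )
        trajectory = run_dfba(self.gsm, profile, self.config)
        performance = None
        if self.product is not None and len(self.product) > 0:
            performance = performance_report(
                trajectory, self.product, self.config.product_exchange
            )
        return DFBAResults(self, glucose_fit, biomass_fit, profile, trajectory,
                           performance)


class DFBAResults:
    """Results of a fitted :class:`KineticsFreeDFBA` analysis."""

    def __init__(
        self,
        model: KineticsFreeDFBA,
        glucose_fit,
        biomass_fit,
        profile: tc.ConstraintProfile,
        trajectory: DfbaTrajectory,
        performance: PerformanceReport | None,
    ):
        self.model = model
        self.glucose_fit = glucose_fit
        self.biomass_fit = biomass_fit
        self.profile = profile
        self.trajectory = trajectory
        self.performance = performance

    @property
    def final_product_mM(self) -> float:
        return self.trajectory.final_concentration(
            self.model.config.product_exchange
        )

    def to_frame(self) -> pd.DataFrame:
        return self.trajectory.to_frame()

    def summary(self) -> str:
        """Plain-text summary: fits, run settings, outcomes."""
        cfg = self.model.config
        traj = self.trajectory
        n_arr = np.array([s.relaxation_count for s in traj.steps])
        lines = [
            "Kinetics-free dynamic FBA results",
            "=================================",
            f"metabolic model        : {self.model.gsm.id or '<unnamed>'} "
            f"({len(self.model.gsm.reactions)} reactions)",
            f"grid                   : [{cfg.t_start:g}, {cfg.t_end:g}] h, "
            f"step {cfg.step:g} h ({len(traj.times)} nodes)",
            f"relaxation             : d = {cfg.relax_increment:g}, "
            f"n_max = {cfg.n_max}; median n = {int(np.median(n_arr))}, "
            f"max n = {int(n_arr.max())}",
            f"induction phase        : [{cfg.t_start:g}, {cfg.induction_end:g}) h",
            "",
            "Polynomial approximations (coefficients, ascending powers of t):",
            f"  glucose  (order {_order(self.glucose_fit)}, "
            f"RMS residual {self.glucose_fit.residual:.4g} mM): "
            f"{_coeff_str(self.glucose_fit)}",
            f"  biomass  (order {_order(self.biomass_fit)}, "
            f"RMS residual {self.biomass_fit.residual:.4g} g/L): "
            f"{_coeff_str(self.biomass_fit)}",
            "",
            "Final state at t = {:g} h:".format(cfg.t_end),
            f"  biomass                : {traj.biomass[-1]:.4f} g DCW/L",
            f"  substrate ({cfg.substrate_exchange:<12}): "
            f"{traj.final_concentration(cfg.substrate_exchange):.4f} mM",
            f"  product   ({cfg.product_exchange:<12}): "
            f"{self.final_product_mM:.4f} mM (simulated maximum)",
        ]
        for comp in cfg.medium:
            lines.append(
                f"  medium    ({comp.exchange_id:<12}): "
                f"{traj.final_concentration(comp.exchange_id):.4f} mM"
            )
        if self.performance is not None:
            lines += ["", self.performance.summary()]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Concentration time courses (substrate, product, biomass)."""
        import matplotlib.pyplot as plt

        cfg = self.model.config
        traj = self.trajectory
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        ax.plot(traj.times, traj.concentrations[cfg.substrate_exchange],
                label="substrate (mM)")
        ax.plot(traj.times, traj.concentrations[cfg.product_exchange],
                label="product (mM)")
        ax2 = ax.twinx()
        ax2.plot(traj.times, traj.biomass, "k--", label="biomass (g DCW/L)")
        ax.scatter(self.model.glucose.times, self.model.glucose.values,
                   marker="s", s=12, label="substrate data")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (mM)")
        ax2.set_ylabel("biomass (g DCW/L)")
        h1, l1 = ax.get_legend_handles_labels()
        h2, l2 = ax2.get_legend_handles_labels()
        ax.legend(h1 + h2, l1 + l2, loc="best", fontsize=8)
        return ax


def _order(fit) -> int:
    if isinstance(fit, tc.SegmentedPolynomial):
        return max(m.order for _, m in fit.segments)
    return fit.order


def _coeff_str(fit) -> str:
    if isinstance(fit, tc.SegmentedPolynomial):
        return "; ".join(
            f"[{a:g},{b:g}]: " + ", ".join(f"{c:.6g}" for c in m.coefficients)
            for (a, b), m in fit.segments
        )
    return ", ".join(f"{c:.6g}" for c in fit.coefficients)
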