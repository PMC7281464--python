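"""Strain production-performance evaluation.

The final integrated product concentration of a dFBA run — obtained under the
*same* substrate-consumption and growth constraints as the experiment — is the
simulated maximum attainable by the metabolic network.  Dividing the strain's
experimentally measured final product concentration by that maximum gives the
attainment (%), and 100 - attainment is the headroom left for strain or
process improvement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

from .dfba import DfbaTrajectory
from .timecourse import TimeCourseSeries, convert_units

__all__ = ["PerformanceReport", "production_ratio", "report"]


@dataclass(frozen=True)
class PerformanceReport:
    """Simulated-maximum vs. experimental product concentration."""

    simulated_max_mM: float
    experimental_final_mM: float
    attainment_percent: float
    headroom_percent: float
    time_of_max: float  # h; grid time of the simulated maximum
    simulated_max_g_per_L: float | None = None
    experimental_final_g_per_L: float | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        lines = [
            "Production performance",
            "----------------------",
            f"simulated maximum product : {self.simulated_max_mM:.4f} mM"
            + (
                f" ({self.simulated_max_g_per_L:.4f} g/L)"
                if self.simulated_max_g_per_L is not None
                else ""
            ),
            f"experimental final product: {self.experimental_final_mM:.4f} mM"
            + (
                f" ({self.experimental_final_g_per_L:.4f} g/L)"
                if self.experimental_final_g_per_L is not None
                else ""
            ),
            f"attainment                : {self.attainment_percent:.1f} %",
            f"headroom                  : {self.headroom_percent:.1f} %",
            f"time of simulated maximum : {self.time_of_max:.2f} h",
        ]
        return "\n".join(lines)


def production_ratio(experimental: float, simulated: float) -> float:
    """100 x experimental / simulated, both in the same concentration unit."""
    if simulated <= 0:
        raise ValueError(
            f"simulated maximum must be positive to define a ratio, got {simulated}"
        )
    if experimental < 0:
        raise ValueError("experimental concentration must be >= 0")
    return 100.0 * experimental / simulated


def report(
    trajectory: DfbaTrajectory,
    experimental_series: TimeCourseSeries,
    product_exchange: str,
    molar_mass: float | None = None,
) -> PerformanceReport:
    """Build a PerformanceReport from a run and the experimental product series.

    The simulated maximum is the integrated product concentration at the final
    grid time (the product objective can only accumulate).  The experimental
    value is the last measurement of the series, unit-harmonised to mM
    (``molar_mass`` required when the series is in g/L).
    """
    if len(experimental_series) == 0:
        raise ValueError("experimental series is empty")
    if experimental_series.times[-1] > trajectory.times[-1] + 1e-9:
        raise ValueError(
            "trajectory ends before the final experimental measurement "
            f"({trajectory.times[-1]} < {experimental_series.times[-1]} h)"
        )
    series_mM = convert_units(experimental_series, molar_mass=molar_mass)
    if series_mM.unit != "mM":
        raise ValueError(
            f"product series must be a metabolite concentration, got unit "
            f"{experimental_series.unit!r}"
        )
    sim_series = trajectory.concentrations[product_exchange]
    simulated = float(sim_series[-1])
    time_of_max = float(trajectory.times[int(sim_series.argmax())])
    experimental = float(series_mM.values[-1])
    attainment = production_ratio(experimental, simulated)
    to_gl = (lambda mm: mm * molar_mass / 1000.0) if molar_mass else (lambda mm: None)
    return PerformanceReport(
        simulated_max_mM=simulated,
        experimental_final_mM=experimental,
        attainment_percent=attainment,
        headroom_percent=100.0 - attainment,
        time_of_max=time_of_max,
        simulated_max_g_per_L=to_gl(simulated),
        experimental_final_g_per_L=to_gl(experimental),
    )
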