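"""Simpson's-rule integration of flux time courses into concentrations.

The dFBA driver needs concentrations *during* the stepping loop (amino-acid
uptake switches off when the integrated pool hits zero), so the integral is
maintained as a running series: each new sample extends the cumulative value
with a provisional trapezoid over the newest interval, and whenever an even
number of intervals completes a pair, that pair is finalised with Simpson's
rule.  A post-hoc pass over the full grid (``simpson_cumulative``) uses the
identical rule and therefore agrees with the running series to rounding.

Biomass is special because it appears inside its own integrand (dX/dt = mu X).
The forward sweep treats each update implicitly in the node being solved for:
a provisional implicit trapezoid at the newest node, then — when a pair
completes — a corrector pass that refines the pair midpoint with the
three-node left-interval rule  h/12 (5 g_{k-2} + 8 g_{k-1} - g_k)  (exact for
quadratics) and the pair endpoint with implicit Simpson, iterated twice.
With g_j = mu_j X_j this keeps the sweep single-pass and fourth-order in the
step at completed pairs.  Midpoint corrections are reported so that metabolite
integrands (flux x biomass) can be re-sampled consistently, keeping the
running series bit-identical to a post-hoc pass over the full grid.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RunningIntegral",
    "BiomassIntegral",
    "simpson_cumulative",
    "fluxes_to_concentrations",
]

_GRID_RTOL = 1e-8


def _check_uniform(times: np.ndarray) -> float:
    if times.ndim != 1 or len(times) < 1:
        raise ValueError("grid must be a 1-D array with at least one point")
    if len(times) == 1:
        return 0.0
    steps = np.diff(times)
    h = steps[0]
    if h <= 0 or not np.allclose(steps, h, rtol=_GRID_RTOL, atol=0):
        raise ValueError("grid must be uniform and increasing")
    return float(h)


class RunningIntegral:
    """Cumulative integral of sampled integrand values on a uniform grid.

    ``cumulative[0]`` is the initial value (e.g. the initial concentration);
    node k holds initial + integral of the integrand from node 0 to node k.
    """

    def __init__(self, step: float, initial: float = 0.0):
        if step <= 0:
            raise ValueError("step must be positive")
        self.step = float(step)
        self.samples: list[float] = []
        self.cumulative: list[float] = []
        self._initial = float(initial)

    def append(self, value: float, corrected_prev: float | None = None) -> float:
        """Add the integrand sample at the next grid node; return cumulative there.

        ``corrected_prev`` replaces the previous (midpoint) sample before the
        pair is finalised — used when the integrand depends on a concurrently
        integrated quantity whose midpoint value was just refined.
        """
        f = float(value)
        self.samples.append(f)
        k = len(self.samples) - 1
        h = self.step
        if k == 0:
            self.cumulative.append(self._initial)
            return self.cumulative[0]
        if corrected_prev is not None:
            if k % 2 != 0:
                raise ValueError("midpoint correction only applies at even nodes")
            self.samples[k - 1] = float(corrected_prev)
            self.cumulative[k - 1] = self.cumulative[k - 2] + h / 2.0 * (
                self.samples[k - 2] + self.samples[k - 1]
            )
        # provisional trapezoid over the newest interval
        self.cumulative.append(
            self.cumulative[k - 1] + h / 2.0 * (self.samples[k - 1] + f)
        )
        if k % 2 == 0:  # pair [k-2, k] complete: finalise with Simpson
            self.cumulative[k] = self.cumulative[k - 2] + h / 3.0 * (
                self.samples[k - 2] + 4.0 * self.samples[k - 1] + f
            )
        return self.cumulative[k]

    @property
    def value(self) -> float:
        """Cumulative value at the newest node."""
        return self.cumulative[-1] if self.cumulative else self._initial

    def series(self) -> np.ndarray:
        return np.asarray(self.cumulative)


class BiomassIntegral:
    """Self-consistent forward sweep of dX/dt = mu(t) X(t).

    Samples are specific growth rates mu_k (1/h); the integrand g_k = mu_k X_k
    uses the X value being solved for at the newest node (implicit update).
    """

    def __init__(self, step: float, initial: float):
        if step <= 0:
            raise ValueError("step must be positive")
        if initial < 0:
            raise ValueError("initial biomass must be >= 0")
        self.step = float(step)
        self.mu: list[float] = []
        self.values: list[float] = [float(initial)]
        self._initial = float(initial)

    def append(self, mu: float) -> float:
        """Add the growth-rate sample at the next node; return X there.

        Even nodes finalise a pair: the midpoint X is refined too (read it
        back from ``values[-2]`` for consistent re-sampling of integrands).
        """
        m = float(mu)
        self.mu.append(m)
        k = len(self.mu) - 1
        if k == 0:
            return self.values[0]
        h = self.step
        denom = 1.0 - h / 2.0 * m
        if denom <= 0:
            raise ValueError(f"step too large for growth rate {m} (h*mu >= 2)")
        g_prev = self.mu[k - 1] * self.values[k - 1]
        x = (self.values[k - 1] + h / 2.0 * g_prev) / denom
        if k % 2 == 0:
            x_mid = self.values[k - 1]
            m_mid, m_left = self.mu[k - 1], self.mu[k - 2]
            x_left = self.values[k - 2]
            g_left = m_left * x_left
            denom_mid = 1.0 - h * (8.0 / 12.0) * m_mid
            denom_end = 1.0 - h / 3.0 * m
            if denom_mid <= 0 or denom_end <= 0:
                raise ValueError(f"step too large for growth rate {m}")
            for _ in range(2):  # corrector iterations; contraction ~ (mu h)^2
                x_mid = (
                    x_left + h / 12.0 * (5.0 * g_left - m * x)
                ) / denom_mid
                x = (
                    x_left + h / 3.0 * (g_left + 4.0 * m_mid * x_mid)
                ) / denom_end
            self.values[k - 1] = x_mid
        if len(self.values) == k:
            self.values.append(x)
        else:  # pragma: no cover
            self.values[k] = x
        return x

    @property
    def value(self) -> float:
        return self.values[len(self.mu) - 1] if self.mu else self._initial

    def series(self) -> np.ndarray:
        return np.asarray(self.values)


def simpson_cumulative(
    times: np.ndarray, integrand: np.ndarray, initial: float = 0.0
) -> np.ndarray:
    """Cumulative composite-Simpson integral on a uniform grid.

    Even nodes close a Simpson pair; odd nodes carry a trapezoid over the
    trailing interval (so a grid with an odd number of intervals ends on a
    trapezoid).  ``initial`` offsets the whole series.
    """
    times = np.asarray(times, dtype=float)
    integrand = np.asarray(integrand, dtype=float)
    if times.shape != integrand.shape:
        raise ValueError("times and integrand must have identical shape")
    h = _check_uniform(times)
    out = RunningIntegral(step=h if h > 0 else 1.0, initial=initial)
    for f in integrand:
        out.append(f)
    return out.series()


def fluxes_to_concentrations(
    times: np.ndarray,
    exchange_fluxes: dict[str, np.ndarray],
    growth_rates: np.ndarray,
    initial_biomass: float,
    initial_concentrations: dict[str, float],
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Integrate specific fluxes into concentration time courses.

    For metabolite m with exchange flux v_m (mmol/g DCW/h, negative = uptake):
    C_m(t) = C_m(0) + integral of v_m(tau) * X(tau) dtau, so consumed species
    decrease.  Biomass X (g DCW/L) is integrated first by the self-consistent
    sweep and then feeds every metabolite integrand.

    Returns (concentrations by exchange id in mM, biomass series in g DCW/L).
    Concentrations here are the raw integrals; flooring at zero for reporting
    is the caller's choice.
    """
    times = np.asarray(times, dtype=float)
    growth_rates = np.asarray(growth_rates, dtype=float)
    if times.shape != growth_rates.shape:
        raise ValueError("growth_rates must share the time grid")
    h = _check_uniform(times)
    bio = BiomassIntegral(step=h if h > 0 else 1.0, initial=initial_biomass)
    for m in growth_rates:
        bio.append(m)
    X = bio.series()
    concentrations: dict[str, np.ndarray] = {}
    for rid, v in exchange_fluxes.items():
        v = np.asarray(v, dtype=float)
        if v.shape != times.shape:
            raise ValueError(f"flux series for {rid!r} does not share the grid")
        c0 = float(initial_concentrations.get(rid, 0.0))
        concentrations[rid] = simpson_cumulative(times, v * X, initial=c0)
    return concentrations, X
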