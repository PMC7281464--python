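"""Experimental time courses, polynomial approximation and specific-rate profiles.

Fermentation time courses (substrate and biomass concentrations sampled over a
batch culture) are approximated by least-squares polynomials in raw time.
Differentiating the fitted concentration polynomial and dividing by the fitted
biomass concentration yields the specific substrate-uptake rate (mmol/g DCW/h)
and the specific growth rate (1/h) that constrain each FBA solve of the
sequential dFBA driver.  Negative raw rates are clamped to zero: a polynomial
wiggle must not be read as substrate secretion or biomass decay.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourseSeries",
    "PolynomialModel",
    "SegmentedPolynomial",
    "ConstraintProfile",
    "convert_units",
    "fit_polynomial",
    "evaluate_poly",
    "differentiate_poly",
    "specific_rates",
    "read_timecourse_csv",
]

#: canonical unit for each series kind
CANONICAL_UNITS = ("mM", "gDCW_per_L")

_KNOWN_UNITS = ("mM", "g_per_L", "OD600", "gDCW_per_L")


@dataclass(frozen=True)
class TimeCourseSeries:
    """Timestamped concentration measurements for a single species.

    Parameters
    ----------
    species_id : str
        Identifier of the measured species (e.g. ``"glc__D"`` or ``"biomass"``).
    times : array-like of float
        Sampling times in hours, strictly increasing.
    values : array-like of float
        Concentrations: mM for metabolites, g DCW/L for biomass, or OD600
        before conversion.
    unit : {"mM", "g_per_L", "OD600", "gDCW_per_L"}
    """

    species_id: str
    times: np.ndarray
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.unit not in _KNOWN_UNITS:
            raise ValueError(
                f"unknown unit {self.unit!r}; expected one of {_KNOWN_UNITS}"
            )
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if len(times) != len(values):
            raise ValueError(
                f"length mismatch: {len(times)} times vs {len(values)} values"
            )
        if len(times) == 0:
            raise ValueError("series must contain at least one point")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise ValueError("times and values must be finite")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


def read_timecourse_csv(
    path, species_id: str, unit: str, *, time_col: str = "time", value_col: str = "value",
    sep: str | None = None,
) -> TimeCourseSeries:
    """Read a two-column delimited text file (CSV/TSV) into a series."""
    df = pd.read_csv(path, sep=sep, engine="python")
    if time_col not in df.columns or value_col not in df.columns:
        raise ValueError(
            f"expected columns {time_col!r} and {value_col!r}, found {list(df.columns)}"
        )
    return TimeCourseSeries(
        species_id=species_id,
        times=df[time_col].to_numpy(float),
        values=df[value_col].to_numpy(float),
        unit=unit,
    )


def convert_units(
    series: TimeCourseSeries,
    molar_mass: float | None = None,
    od_factor: float | None = None,
) -> TimeCourseSeries:
    """Convert a series to canonical units (mM for metabolites, g DCW/L for biomass).

    ``g/L -> mM`` requires ``molar_mass`` (g/mol): mM = g/L / molar_mass * 1000.
    ``OD600 -> g DCW/L`` requires ``od_factor`` (g DCW per OD600 unit; 0.33 for
    E. coli).  Series already in canonical units pass through unchanged.
    """
    if series.unit in CANONICAL_UNITS:
        return series
    if series.unit == "g_per_L":
        if molar_mass is None:
            raise ValueError("molar_mass required to convert g/L to mM")
        if molar_mass <= 0:
            raise ValueError(f"molar_mass must be positive, got {molar_mass}")
        return TimeCourseSeries(
            species_id=series.species_id,
            times=series.times,
            values=series.values / molar_mass * 1000.0,
            unit="mM",
        )
    if series.unit == "OD600":
        if od_factor is None:
            raise ValueError("od_factor required to convert OD600 to g DCW/L")
        if od_factor <= 0:
            raise ValueError(f"od_factor must be positive, got {od_factor}")
        return TimeCourseSeries(
            species_id=series.species_id,
            times=series.times,
            values=series.values * od_factor,
            unit="gDCW_per_L",
        )
    raise AssertionError(f"unhandled unit {series.unit!r}")  # pragma: no cover


@dataclass(frozen=True)
class PolynomialModel:
    """A least-squares polynomial c_0 + c_1 t + ... + c_k t^k over a time domain.

    Coefficients are in ascending power order and in raw (uncentred, unscaled)
    time, so they are directly comparable to published fit coefficients.
    ``residual`` is the root-mean-square deviation of the fit from the data
    (zero for an exact construction).
    """

    coefficients: np.ndarray
    domain: tuple[float, float]
    residual: float = 0.0

    def __post_init__(self) -> None:
        coeffs = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "domain", (float(self.domain[0]), float(self.domain[1])))
        if coeffs.ndim != 1 or len(coeffs) == 0:
            raise ValueError("coefficients must be a non-empty 1-D sequence")
        if self.domain[0] > self.domain[1]:
            raise ValueError(f"empty domain {self.domain}")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, t, *, extrapolate: bool = False):
        return evaluate_poly(self, t, extrapolate=extrapolate)

    def derivative(self) -> "PolynomialModel":
        return differentiate_poly(self)

    def antiderivative(self, constant: float = 0.0) -> "PolynomialModel":
        """Indefinite integral with the given constant term."""
        c = self.coefficients
        out = np.empty(len(c) + 1)
        out[0] = constant
        out[1:] = c / np.arange(1, len(c) + 1)
        return PolynomialModel(out, self.domain, 0.0)

    def to_dict(self) -> dict:
        return {
            "coefficients": [float(c) for c in self.coefficients],
            "order": self.order,
            "domain": [self.domain[0], self.domain[1]],
            "residual": float(self.residual),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PolynomialModel":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            domain=tuple(d["domain"]),
            residual=float(d.get("residual", 0.0)),
        )


@dataclass(frozen=True)
class SegmentedPolynomial:
    """Independent polynomial fits over contiguous, non-overlapping intervals.

    No continuity is enforced across breakpoints, so derived rates may jump
    there; a time on a shared breakpoint is resolved to the later segment.
    """

    segments: tuple

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("at least one segment required")
        for (lo, hi), model in segs:
            if lo > hi:
                raise ValueError(f"segment interval ({lo}, {hi}) is empty")
            if not isinstance(model, PolynomialModel):
                raise TypeError("each segment must carry a PolynomialModel")
        intervals = [iv for iv, _ in segs]
        for (a, b), (c, d) in zip(intervals, intervals[1:]):
            if not np.isclose(b, c):
                raise ValueError("segment intervals must be contiguous and sorted")

    @property
    def domain(self) -> tuple[float, float]:
        return (self.segments[0][0][0], self.segments[-1][0][1])

    @property
    def residual(self) -> float:
        return float(max(m.residual for _, m in self.segments))

    def segment_for(self, t: float) -> PolynomialModel:
        lo, hi = self.domain
        for (a, b), model in self.segments:
            if t < b or b == hi:
                return model
        return self.segments[-1][1]  # pragma: no cover

    def __call__(self, t, *, extrapolate: bool = False):
        return evaluate_poly(self, t, extrapolate=extrapolate)

    def derivative(self) -> "SegmentedPolynomial":
        return SegmentedPolynomial(
            tuple((iv, m.derivative()) for iv, m in self.segments)
        )

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"interval": [a, b], **m.to_dict()} for (a, b), m in self.segments
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SegmentedPolynomial":
        return cls(
            tuple(
                (tuple(s["interval"]), PolynomialModel.from_dict(s))
                for s in d["segments"]
            )
        )


def save_model_json(model: PolynomialModel | SegmentedPolynomial, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def load_model_json(path) -> PolynomialModel | SegmentedPolynomial:
    with open(path) as fh:
        d = json.load(fh)
    if "segments" in d:
        return SegmentedPolynomial.from_dict(d)
    return PolynomialModel.from_dict(d)


def _fit_one(times: np.ndarray, values: np.ndarray, order: int) -> PolynomialModel:
    if len(np.unique(times)) != len(times):
        raise ValueError("duplicate times in segment")
    if len(times) <= order:
        raise ValueError(
            f"under-determined fit: {len(times)} points for order {order}"
        )
    # raw-time Vandermonde: coefficients directly comparable to published fits
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            coeffs = np.polynomial.polynomial.polyfit(times, values, order)
        except np.exceptions.RankWarning:
            warnings.warn(
                "ill-conditioned design matrix for raw-time polynomial fit; "
                "consider a lower order or segmentation",
                stacklevel=3,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", np.exceptions.RankWarning)
                coeffs = np.polynomial.polynomial.polyfit(times, values, order)
    fitted = np.polynomial.polynomial.polyval(times, coeffs)
    residual = float(np.sqrt(np.mean((values - fitted) ** 2)))
    return PolynomialModel(coeffs, (float(times[0]), float(times[-1])), residual)


def fit_polynomial(
    series: TimeCourseSeries,
    order: int = 5,
    segments: Sequence[float] | None = None,
) -> PolynomialModel | SegmentedPolynomial:
    """Least-squares polynomial fit of a time course on raw time.

    Parameters
    ----------
    series : TimeCourseSeries
    order : int, default 5
        Polynomial order k; each (segment) fit needs more than ``order`` points.
    segments : sequence of float, optional
        Interior breakpoints.  When given, the data are split at these times
        and each section is fitted independently (no continuity constraint);
        a point lying exactly on a breakpoint belongs to the later section.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    t, y = series.times, series.values
    if not segments:
        return _fit_one(t, y, order)
    breaks = sorted(float(b) for b in segments)
    lo, hi = series.domain
    if breaks[0] <= lo or breaks[-1] >= hi:
        raise ValueError("breakpoints must lie strictly inside the data domain")
    edges = [lo, *breaks, hi]
    out = []
    for a, b in zip(edges, edges[1:]):
        mask = (t >= a) & (t < b) if b != hi else (t >= a) & (t <= b)
        model = _fit_one(t[mask], y[mask], order)
        out.append(((a, b), model))
    return SegmentedPolynomial(tuple(out))


def evaluate_poly(
    model: PolynomialModel | SegmentedPolynomial, t, *, extrapolate: bool = False
):
    """Evaluate a (segmented) polynomial at time(s) t, Horner style.

    Raises ``ValueError`` outside the fitted domain unless ``extrapolate`` is
    set (needed e.g. for the trailing half-step of an integration grid).
    """
    t_arr = np.asarray(t, dtype=float)
    lo, hi = model.domain
    if not extrapolate:
        tol = 1e-9 * max(1.0, abs(hi))
        if np.any(t_arr < lo - tol) or np.any(t_arr > hi + tol):
            raise ValueError(
                f"t={t} outside fitted domain [{lo}, {hi}]; "
                "pass extrapolate=True to override"
            )
    if isinstance(model, SegmentedPolynomial):
        if t_arr.ndim == 0:
            seg = model.segment_for(float(np.clip(t_arr, lo, hi)))
            return float(np.polynomial.polynomial.polyval(t_arr, seg.coefficients))
        out = np.empty_like(t_arr)
        for i, ti in np.ndenumerate(t_arr):
            seg = model.segment_for(float(np.clip(ti, lo, hi)))
            out[i] = np.polynomial.polynomial.polyval(ti, seg.coefficients)
        return out
    val = np.polynomial.polynomial.polyval(t_arr, model.coefficients)
    return float(val) if t_arr.ndim == 0 else val


def differentiate_poly(
    model: PolynomialModel | SegmentedPolynomial,
) -> PolynomialModel | SegmentedPolynomial:
    """d/dt of the polynomial; an order-0 model yields the zero polynomial."""
    if isinstance(model, SegmentedPolynomial):
        return model.derivative()
    c = model.coefficients
    if len(c) == 1:
        return PolynomialModel(np.zeros(1), model.domain, 0.0)
    dc = c[1:] * np.arange(1, len(c))
    return PolynomialModel(dc, model.domain, 0.0)


def specific_rates(
    conc_model: PolynomialModel | SegmentedPolynomial,
    biomass_model: PolynomialModel | SegmentedPolynomial,
    t: float,
    role: str,
    *,
    extrapolate: bool = False,
) -> float:
    """Specific rate at time t, clamped at zero.

    role ``"substrate_uptake"``: max(0, -(dC/dt)/X(t)) in mmol/g DCW/h —
    consumption is positive, so the concentration derivative enters negated.
    role ``"growth"``: max(0, (dX/dt)/X(t)) in 1/h (here ``conc_model`` is
    ignored; the biomass model supplies both numerator and denominator).
    """
    if role not in ("substrate_uptake", "growth"):
        raise ValueError(f"unknown role {role!r}")
    x = evaluate_poly(biomass_model, t, extrapolate=extrapolate)
    if x <= 0:
        raise ValueError(f"biomass concentration {x} <= 0 at t={t}")
    if role == "growth":
        dx = evaluate_poly(differentiate_poly(biomass_model), t, extrapolate=extrapolate)
        return max(0.0, dx / x)
    dc = evaluate_poly(differentiate_poly(conc_model), t, extrapolate=extrapolate)
    return max(0.0, -dc / x)


@dataclass
class ConstraintProfile:
    """Time-parameterised specific-rate targets for the dFBA driver.

    ``uptake_targets`` maps an exchange-reaction id to a callable t -> target
    specific uptake rate (mmol/g DCW/h, nonnegative magnitude);
    ``growth_target`` gives the target specific growth rate (1/h).
    """

    uptake_targets: dict[str, Callable[[float], float]]
    growth_target: Callable[[float], float]
    biomass_model: PolynomialModel | SegmentedPolynomial | None = None
    substrate_models: dict[str, PolynomialModel | SegmentedPolynomial] = field(
        default_factory=dict
    )

    @classmethod
    def from_polynomials(
        cls,
        substrate_models: Mapping[str, PolynomialModel | SegmentedPolynomial],
        biomass_model: PolynomialModel | SegmentedPolynomial,
        *,
        extrapolate: bool = True,
    ) -> "ConstraintProfile":
        """Build the profile from fitted concentration polynomials.

        ``substrate_models`` maps exchange-reaction ids to fitted substrate
        concentration models (mM).  Extrapolation defaults to on so the final
        half-step of an integration grid does not fall off the fitted domain.
        """

        def make_uptake(model):
            return lambda t: specific_rates(
                model, biomass_model, t, "substrate_uptake", extrapolate=extrapolate
            )

        return cls(
            uptake_targets={
                ex: make_uptake(m) for ex, m in substrate_models.items()
            },
            growth_target=lambda t: specific_rates(
                None, biomass_model, t, "growth", extrapolate=extrapolate
            ),
            biomass_model=biomass_model,
            substrate_models=dict(substrate_models),
        )
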