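"""Self-contained synthetic fixtures: toy GSMs and polynomial time courses.

Two kinds of fixture make the whole pipeline testable without any download:

* toy constraint-based models (``chain``, ``branch``, ``shikimate_toy``) with
  small rational stoichiometries whose LP optima can be computed by hand or by
  exhaustive vertex enumeration — test instruments, not biological models;
* synthetic glucose/biomass time courses generated by evaluating the
  case-study's published fifth-order concentration polynomials, with optional
  seeded Gaussian noise.

The shikimate toy mimics the *structure* of the case study: glucose uptake,
a biomass reaction requiring the three aromatic amino acids supplemented in
the medium, an overflow (respiration) sink for surplus carbon, and a product
export route.  Its numbers are small integers chosen for exactly rational
optima; it is a test instrument, not a biological reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import cobra
import cobra.io

from .timecourse import TimeCourseSeries

__all__ = [
    "GLUCOSE_POLY_COEFFS",
    "BIOMASS_POLY_COEFFS",
    "CASE_STUDY_DOMAIN",
    "AMINO_ACID_MOLAR_MASS",
    "AMINO_ACID_MEDIUM_G_PER_L",
    "OD600_TO_GDCW",
    "ToyModelSpec",
    "SyntheticSeriesSpec",
    "make_toy_model",
    "make_synthetic_timecourse",
    "write_toy_model",
]

#: case-study fifth-order fit of glucose concentration (mM), ascending powers of t (h)
GLUCOSE_POLY_COEFFS = (
    78.5035,
    1.89582,
    -1.21840,
    1.01057e-1,
    -3.43279e-3,
    4.24753e-5,
)

#: case-study fifth-order fit of biomass concentration (g DCW/L), ascending powers
BIOMASS_POLY_COEFFS = (
    0.173785,
    0.137275,
    6.43382e-2,
    -5.42057e-3,
    1.56060e-4,
    -1.51269e-6,
)

#: time span (h) of the case-study batch culture
CASE_STUDY_DOMAIN = (0.0, 27.0)

#: g/mol, for converting the supplemented-medium g/L values to mM
AMINO_ACID_MOLAR_MASS = {"phe": 165.19, "tyr": 181.19, "trp": 204.23}

#: supplemented aromatic amino acids in the case-study medium, g/L
AMINO_ACID_MEDIUM_G_PER_L = {"phe": 0.7, "tyr": 0.7, "trp": 0.35}

#: g DCW per OD600 unit for E. coli
OD600_TO_GDCW = 0.33


@dataclass(frozen=True)
class ToyModelSpec:
    """Recipe for a toy constraint-based model.

    ``product_yield`` and ``biomass_yield`` are mol product (resp. unit growth
    flux) per mol substrate consumed by the respective branch.
    """

    topology: str = "shikimate_toy"  # chain | branch | shikimate_toy
    substrate_uptake_bound: float = 10.0
    product_yield: float = 0.5
    biomass_yield: float = 0.2  # growth per substrate: growth costs 1/yield

    def __post_init__(self) -> None:
        if self.topology not in ("chain", "branch", "shikimate_toy"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.product_yield <= 0 or self.biomass_yield <= 0:
            raise ValueError("yields must be > 0")
        if self.substrate_uptake_bound < 0:
            raise ValueError("substrate uptake bound must be >= 0")


@dataclass(frozen=True)
class SyntheticSeriesSpec:
    """Recipe for synthetic glucose/biomass time courses."""

    glucose_coeffs: tuple = GLUCOSE_POLY_COEFFS
    biomass_coeffs: tuple = BIOMASS_POLY_COEFFS
    times: tuple = tuple(float(t) for t in range(28))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        t = np.asarray(self.times, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")


def _rxn(model, rid, mets, lb, ub):
    r = cobra.Reaction(rid)
    model.add_reactions([r])
    r.add_metabolites(mets)
    r.bounds = (lb, ub)
    return r


def make_toy_model(spec: ToyModelSpec = ToyModelSpec()) -> cobra.Model:
    """Build the toy model described by ``spec`` as a cobra.Model.

    chain (3 reactions): EX_S -> conversion -> EX_P (product yield per
        substrate); max product flux equals the uptake bound times the yield.
    branch (6 reactions): substrate splits between a growth branch
        (1/biomass_yield substrate per unit growth), a product branch
        (product_yield product per substrate) and a respiration overflow RESP
        that burns surplus substrate, so a two-sided uptake constraint stays
        feasible when neither growth nor export can absorb the carbon.
    shikimate_toy (10 reactions): branch plus three amino-acid exchanges
        (phe/tyr/trp) that growth requires 1:1:1 per unit flux, mimicking the
        aromatic-amino-acid requirement of a shikimate producer whose pathway
        is cut downstream of shikimate.  Only tryptophan has a (costly,
        2-substrate) synthesis bypass, so with the default uptake bound 10 and
        biomass_yield 0.2 the growth optimum is 10/5 = 2 with tryptophan
        uptake open and 10/7 without it, rather than dropping to zero.
    """
    m = cobra.Model(f"toy_{spec.topology}")
    ub = 1000.0
    if spec.topology == "chain":
        S = cobra.Metabolite("S_e", compartment="e")
        P = cobra.Metabolite("P_e", compartment="e")
        _rxn(m, "EX_S", {S: -1}, -spec.substrate_uptake_bound, 0.0)
        _rxn(m, "CONV", {S: -1, P: spec.product_yield}, 0.0, ub)
        _rxn(m, "EX_P", {P: -1}, 0.0, ub)
        m.objective = "EX_P"
        return m

    S_e = cobra.Metabolite("S_e", compartment="e")
    P_e = cobra.Metabolite("P_e", compartment="e")
    X_c = cobra.Metabolite("X_c", compartment="c")
    _rxn(m, "EX_glc", {S_e: -1}, -spec.substrate_uptake_bound, ub)
    growth_mets = {S_e: -1.0 / spec.biomass_yield, X_c: 1.0}
    _rxn(m, "PROD", {S_e: -1, P_e: spec.product_yield}, 0.0, ub)
    _rxn(m, "EX_prod", {P_e: -1}, 0.0, ub)
    _rxn(m, "RESP", {S_e: -1}, 0.0, ub)
    _rxn(m, "DM_X", {X_c: -1}, 0.0, ub)

    if spec.topology == "shikimate_toy":
        for aa in ("phe", "tyr", "trp"):
            e = cobra.Metabolite(f"{aa}_e", compartment="e")
            _rxn(m, f"EX_{aa}", {e: -1}, -ub, ub)
            growth_mets[e] = -1.0
        _rxn(m, "SYN_trp", {S_e: -2, m.metabolites.get_by_id("trp_e"): 1}, 0.0, ub)
    growth = _rxn(m, "GROWTH", growth_mets, 0.0, ub)
    m.objective = growth.id
    return m


def write_toy_model(model: cobra.Model, path) -> None:
    """Serialise a toy model to SBML (.xml/.sbml) or JSON (.json)."""
    p = str(path)
    if p.endswith(".json"):
        cobra.io.save_json_model(model, p)
    elif p.endswith((".xml", ".sbml")):
        cobra.io.write_sbml_model(model, p)
    else:
        raise ValueError(f"unsupported model extension for {p!r}")


def make_synthetic_timecourse(
    spec: SyntheticSeriesSpec = SyntheticSeriesSpec(),
) -> dict[str, TimeCourseSeries]:
    """Evaluate the generating polynomials at the sampling times (+ noise).

    Returns ``{"glucose": ..., "biomass": ...}``; glucose in mM, biomass in
    g DCW/L.  Noise is additive Gaussian with the spec's seed, so output is
    bit-reproducible for a fixed spec.
    """
    t = np.asarray(spec.times, dtype=float)
    rng = np.random.default_rng(spec.seed)
    glc = np.polynomial.polynomial.polyval(t, np.asarray(spec.glucose_coeffs))
    bio = np.polynomial.polynomial.polyval(t, np.asarray(spec.biomass_coeffs))
    if spec.noise_sd > 0:
        glc = glc + rng.normal(0.0, spec.noise_sd, size=t.shape)
        bio = bio + rng.normal(0.0, spec.noise_sd * 0.01, size=t.shape)
    return {
        "glucose": TimeCourseSeries("glucose", t, glc, "mM"),
        "biomass": TimeCourseSeries("biomass", t, bio, "gDCW_per_L"),
    }
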