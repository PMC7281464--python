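import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from fluxcourse.dfba import DfbaConfig, MediumComponent
from fluxcourse.fixtures import (
    BIOMASS_POLY_COEFFS,
    GLUCOSE_POLY_COEFFS,
    AMINO_ACID_MEDIUM_G_PER_L,
    AMINO_ACID_MOLAR_MASS,
    CASE_STUDY_DOMAIN,
    SyntheticSeriesSpec,
    ToyModelSpec,
    make_synthetic_timecourse,
    make_toy_model,
)
from fluxcourse.timecourse import ConstraintProfile, PolynomialModel


@pytest.fixture(scope="session")
def glc_poly() -> PolynomialModel:
    """Case-study fifth-order glucose concentration fit (mM)."""
    return PolynomialModel(GLUCOSE_POLY_COEFFS, CASE_STUDY_DOMAIN)


@pytest.fixture(scope="session")
def bio_poly() -> PolynomialModel:
    """Case-study fifth-order biomass concentration fit (g DCW/L)."""
    return PolynomialModel(BIOMASS_POLY_COEFFS, CASE_STUDY_DOMAIN)


@pytest.fixture(scope="session")
def case_profile(glc_poly, bio_poly) -> ConstraintProfile:
    return ConstraintProfile.from_polynomials({"EX_glc": glc_poly}, bio_poly)


@pytest.fixture()
def chain_model():
    return make_toy_model(ToyModelSpec("chain", 10.0, 1.0))


@pytest.fixture()
def branch_model():
    return make_toy_model(ToyModelSpec("branch", 10.0, 0.5, 0.1))


@pytest.fixture()
def shik_model():
    return make_toy_model(ToyModelSpec("shikimate_toy", 10.0, 0.5, 0.2))


@pytest.fixture(scope="session")
def noiseless_series():
    return make_synthetic_timecourse(SyntheticSeriesSpec())


@pytest.fixture()
def amino_acid_medium() -> tuple[MediumComponent, ...]:
    return tuple(
        MediumComponent(
            f"EX_{aa}",
            AMINO_ACID_MEDIUM_G_PER_L[aa] / AMINO_ACID_MOLAR_MASS[aa] * 1000.0,
        )
        for aa in ("phe", "tyr", "trp")
    )


@pytest.fixture()
def toy_case_config(amino_acid_medium, glc_poly, bio_poly) -> DfbaConfig:
    """Case-study run settings mapped onto the shikimate toy model."""
    return DfbaConfig(
        biomass_reaction="GROWTH",
        substrate_exchange="EX_glc",
        product_exchange="EX_prod",
        t_start=0.0,
        t_end=27.0,
        step=0.1,
        medium=amino_acid_medium,
        initial_substrate_mM=glc_poly(0.0),
        initial_biomass=bio_poly(0.0),
    )
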