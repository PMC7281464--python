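"""Structured run configuration for the command-line pipeline.

A run is described by a YAML (or JSON) file validated with pydantic, so every
invalid field is reported by name before any computation starts.  The medium
defaults mirror the case study: the three aromatic amino acids supplemented at
0.7 / 0.7 / 0.35 g/L (phenylalanine, tyrosine, tryptophan), converted to mM
with their standard molar masses.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .dfba import DfbaConfig, MediumComponent
from .fixtures import AMINO_ACID_MEDIUM_G_PER_L, AMINO_ACID_MOLAR_MASS

__all__ = ["SeriesConfig", "MediumEntry", "RunConfig", "load_config",
           "default_amino_acid_medium"]


class SeriesConfig(BaseModel):
    """One input time-course table (delimited text with time/value columns)."""

    path: Path
    unit: Literal["mM", "g_per_L", "OD600", "gDCW_per_L"]
    molar_mass: Optional[float] = Field(None, gt=0, description="g/mol, for g/L data")
    od_factor: Optional[float] = Field(None, gt=0, description="g DCW per OD600")
    time_col: str = "time"
    value_col: str = "value"

    @model_validator(mode="after")
    def _conversion_inputs(self):
        if self.unit == "g_per_L" and self.molar_mass is None:
            raise ValueError("molar_mass is required for g_per_L data")
        if self.unit == "OD600" and self.od_factor is None:
            raise ValueError("od_factor is required for OD600 data")
        return self


class MediumEntry(BaseModel):
    """A supplemented medium species subject to depletion switching."""

    exchange_id: str = Field(min_length=1)
    concentration: float = Field(ge=0)
    unit: Literal["mM", "g_per_L"] = "mM"
    molar_mass: Optional[float] = Field(None, gt=0)
    max_uptake: float = Field(1000.0, ge=0)

    @model_validator(mode="after")
    def _needs_molar_mass(self):
        if self.unit == "g_per_L" and self.molar_mass is None:
            raise ValueError("molar_mass is required for g_per_L medium entries")
        return self

    def to_component(self) -> MediumComponent:
        conc = self.concentration
        if self.unit == "g_per_L":
            conc = conc / self.molar_mass * 1000.0
        return MediumComponent(self.exchange_id, conc, self.max_uptake)


def default_amino_acid_medium() -> list[MediumEntry]:
    """Case-study supplement: Phe/Tyr/Trp at 0.7/0.7/0.35 g/L."""
    return [
        MediumEntry(
            exchange_id=f"EX_{aa}",
            concentration=AMINO_ACID_MEDIUM_G_PER_L[aa],
            unit="g_per_L",
            molar_mass=AMINO_ACID_MOLAR_MASS[aa],
        )
        for aa in ("phe", "tyr", "trp")
    ]


class RunConfig(BaseModel):
    """Everything needed for one end-to-end pipeline run."""

    model_config = ConfigDict(protected_namespaces=())

    model_path: Path
    model_dialect: Optional[Literal["sbml_fbc", "json"]] = None
    glucose: SeriesConfig
    biomass: SeriesConfig
    product: Optional[SeriesConfig] = None
    biomass_reaction: str = Field(min_length=1)
    substrate_exchange: str = Field(min_length=1)
    product_exchange: str = Field(min_length=1)
    medium: list[MediumEntry] = Field(default_factory=list)
    fit_order: int = Field(5, ge=0)
    fit_segments: Optional[list[float]] = None
    t_start: Optional[float] = None
    t_end: Optional[float] = None
    step: float = Field(0.01, gt=0)
    relax_increment: float = Field(0.01, gt=0)
    n_max: int = Field(101, ge=1)
    induction_end: float = 2.0
    seed: int = 0
    output_dir: Path = Path("fluxcourse_out")

    @field_validator("model_path")
    @classmethod
    def _model_exists(cls, v: Path) -> Path:
        if not v.exists():
            raise ValueError(f"model file {v} does not exist")
        return v

    def medium_components(self) -> tuple[MediumComponent, ...]:
        return tuple(entry.to_component() for entry in self.medium)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    p = Path(path)
    text = p.read_text()
    data = json.loads(text) if p.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration in {p} must be a mapping")
    # paths are relative to the config file's directory
    for key in ("model_path", "output_dir"):
        if key in data and data[key] is not None:
            data[key] = str((p.parent / data[key]).resolve())
    for key in ("glucose", "biomass", "product"):
        section = data.get(key)
        if isinstance(section, dict) and "path" in section:
            section["path"] = str((p.parent / section["path"]).resolve())
    return RunConfig(**data)
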