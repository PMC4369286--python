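"""Loaders for the bundled trans-cinnamic acid fixtures.

Everything ships as commented CSV under ``abrahamfit/data``: the McGowan
atomic volumes, the transcribed Abraham solvent-coefficient compilation,
the replicate-averaged saturation solubilities and direct log P values for
trans-cinnamic acid, solvent metadata (Kamlet-Taft beta, density, molar
mass), and the published fit tables used as reference expectations.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .data_prep import Measurement, read_measurements_csv, read_solvent_metadata_csv
from .model import CoefficientTable, SolventInfo

__all__ = [
    "data_path",
    "load_coefficient_table",
    "load_solubilities",
    "load_direct_logp",
    "load_solvent_metadata",
    "load_monomer_reference",
    "load_dimer_reference",
    "load_published_descriptors",
    "CINNAMIC_ACID_FORMULA",
    "CINNAMIC_ACID_MOLAR_MASS",
]

#: trans-cinnamic acid, C6H5-CH=CH-COOH
CINNAMIC_ACID_FORMULA = "C9H8O2"
CINNAMIC_ACID_MOLAR_MASS = 148.16  # g/mol


def data_path(name: str) -> Path:
    with resources.as_file(resources.files("abrahamfit.data") / name) as p:
        return Path(p)


def load_coefficient_table() -> CoefficientTable:
    return CoefficientTable.from_csv(data_path("abraham_coefficients.csv"))


def load_solubilities() -> list[Measurement]:
    return read_measurements_csv(data_path("cinnamic_acid_solubilities.csv"))


def load_direct_logp() -> list[Measurement]:
    return read_measurements_csv(data_path("cinnamic_acid_logp.csv"))


def load_solvent_metadata() -> dict[str, SolventInfo]:
    return read_solvent_metadata_csv(data_path("solvent_metadata.csv"))


def load_monomer_reference() -> pd.DataFrame:
    return pd.read_csv(data_path("monomer_fit_reference.csv"), comment="#")


def load_dimer_reference() -> pd.DataFrame:
    return pd.read_csv(data_path("dimer_fit_reference.csv"), comment="#")


def load_published_descriptors() -> pd.DataFrame:
    return pd.read_csv(data_path("published_descriptors.csv"), comment="#")
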