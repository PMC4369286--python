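"""Curation of raw measurements into fit-ready inputs.

Covers the preprocessing steps of the descriptor-determination workflow:
conversion of mole-fraction / mass-fraction / mass-ratio solubilities to
molarity, correction of off-25C measurements to 298.15 K with the
Buchowski lambda-h solid-liquid equilibrium relation, replicate averaging,
classification of saturation solubilities into monomer- or dimer-dominated
solvents by the Kamlet-Taft beta of the solvent, and exclusion of solvents
lacking Abraham coefficient records.

Unit conversions approximate the saturated-solution density by the pure
solvent density; this is a documented error source for very soluble
systems.  The Buchowski correction is applied in mole-fraction space with
lambda = 1, which makes h identifiable from a single measured point given
the boundary condition x = 1 at the melting temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import (
    SolventMetadataError,
    TemperatureRangeError,
    UnitError,
)
from .model import CoefficientTable, SolventInfo

__all__ = [
    "T_REFERENCE",
    "Measurement",
    "TemperatureCorrectionParams",
    "to_molarity",
    "buchowski_mole_fraction",
    "buchowski_adjust",
    "average_replicates",
    "classify_solvent_species",
    "filter_missing_coefficients",
    "read_measurements_csv",
    "write_measurements_csv",
    "read_solvent_metadata_csv",
]

T_REFERENCE = 298.15  # K

_SOLUBILITY_UNITS = ("molarity", "mole_fraction", "mass_fraction", "mass_ratio")
_UNITS = _SOLUBILITY_UNITS + ("log_p",)
_T_BAND = (270.0, 320.0)  # study temperatures span 19.5 C .. 28 C


@dataclass(frozen=True)
class Measurement:
    """One observation: a saturation solubility or a direct log P."""

    solvent: str
    kind: str  # solubility | direct_log_p
    value: float
    unit: str
    temperature: float = T_REFERENCE  # Kelvin
    species: str | None = None  # monomer | dimer | saturation_dependent
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("solubility", "direct_log_p"):
            raise ValueError(f"unknown measurement kind {self.kind!r}")
        if self.unit not in _UNITS:
            raise UnitError(f"unknown unit {self.unit!r}")
        if self.kind == "solubility" and self.unit == "log_p":
            raise UnitError("a solubility cannot carry unit log_p")
        if self.kind == "direct_log_p":
            if self.unit != "log_p":
                raise UnitError("a direct_log_p measurement must carry unit log_p")
            # dilute-regime determinations always probe the monomer
            object.__setattr__(self, "species", "monomer")
        if self.unit in _SOLUBILITY_UNITS and self.value < 0:
            raise ValueError(f"{self.solvent}: solubility must be non-negative")
        if not (_T_BAND[0] <= self.temperature <= _T_BAND[1]):
            raise TemperatureRangeError(
                f"{self.solvent}: temperature {self.temperature} K outside "
                f"[{_T_BAND[0]}, {_T_BAND[1]}] K"
            )


@dataclass(frozen=True)
class TemperatureCorrectionParams:
    """Buchowski lambda-h parameters for a solid solute."""

    tm: float  # melting temperature, K
    lam: float = 1.0
    h: float | None = None  # K; inferred per measurement when None

    def __post_init__(self) -> None:
        if self.tm <= T_REFERENCE:
            raise ValueError("melting temperature must exceed 298.15 K for a solid solute")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def _require_metadata(info: SolventInfo) -> None:
    if info.density is None or info.molar_mass is None:
        raise SolventMetadataError(
            f"insufficient solvent metadata for {info.name!r}: "
            "density and molar mass required"
        )


def to_molarity(
    m: Measurement, solvent_info: SolventInfo, solute_molar_mass: float
) -> Measurement:
    """Convert a solubility to mol/L, approximating solution by solvent density.

    mole fraction x:  C = 1000*rho*x / (x*M_solute + (1-x)*M_solvent)
    mass fraction w:  C = 1000*rho*w / M_solute
    mass ratio r:     via w = r / (1+r)
    """
    if m.unit == "log_p":
        raise UnitError(f"{m.solvent}: not a solubility")
    if m.unit == "molarity":
        return m
    _require_metadata(solvent_info)
    rho, m_solv = solvent_info.density, solvent_info.molar_mass
    if m.unit == "mole_fraction":
        x = m.value
        conc = 1000.0 * rho * x / (x * solute_molar_mass + (1 - x) * m_solv)
    else:
        w = m.value if m.unit == "mass_fraction" else m.value / (1 + m.value)
        conc = 1000.0 * rho * w / solute_molar_mass
    return replace(m, value=conc, unit="molarity")


def _molarity_to_mole_fraction(
    conc: float, solvent_info: SolventInfo, solute_molar_mass: float
) -> float:
    # exact inverse of the mole-fraction formula in to_molarity
    rho, m_solv = solvent_info.density, solvent_info.molar_mass
    return conc * m_solv / (1000.0 * rho + conc * (m_solv - solute_molar_mass))


def buchowski_mole_fraction(
    x: float, t: float, params: TemperatureCorrectionParams, t_out: float = T_REFERENCE
) -> float:
    """Correct a mole-fraction solubility from T to ``t_out``.

    The lambda-h relation ``ln[1 + lam*(1-x)/x] = lam*h*(1/T - 1/Tm)``
    holds at both temperatures with the same (lam, h); with the boundary
    condition x(Tm) = 1 built in, h follows from the single measured point
    unless supplied.
    """
    if x == 1.0 and t == params.tm:
        return 1.0  # miscibility boundary
    if t >= params.tm:
        raise TemperatureRangeError(f"above melting point: T={t} K >= Tm={params.tm} K")
    if x >= 1.0:
        raise ValueError("not a dilute solid solubility: mole fraction >= 1")
    if x <= 0.0:
        raise ValueError("mole fraction must be positive")
    lam = params.lam
    if params.h is None:
        h = math.log1p(lam * (1 - x) / x) / (lam * (1 / t - 1 / params.tm))
    else:
        h = params.h
    if t_out >= params.tm:
        raise TemperatureRangeError("output temperature at or above melting point")
    grow = math.exp(lam * h * (1 / t_out - 1 / params.tm))
    return lam / (grow - 1 + lam)


def buchowski_adjust(
    m: Measurement,
    params: TemperatureCorrectionParams,
    solvent_info: SolventInfo,
    solute_molar_mass: float,
) -> Measurement:
    """Correct a molarity measurement to 298.15 K (identity when already there).

    Works internally in mole-fraction space, so solvent density and molar
    mass are required except in the no-op case.
    """
    if m.unit != "molarity":
        raise UnitError(f"{m.solvent}: buchowski_adjust expects molarity input")
    if m.temperature == T_REFERENCE:
        return m
    _require_metadata(solvent_info)
    x = _molarity_to_mole_fraction(m.value, solvent_info, solute_molar_mass)
    x25 = buchowski_mole_fraction(x, m.temperature, params)
    rho, m_solv = solvent_info.density, solvent_info.molar_mass
    conc = 1000.0 * rho * x25 / (x25 * solute_molar_mass + (1 - x25) * m_solv)
    return replace(m, value=conc, temperature=T_REFERENCE)


def average_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and mean absolute deviation of replicate molarities."""
    if len(values) == 0:
        raise ValueError("no measurements to average")
    mean = sum(values) / len(values)
    mad = sum(abs(v - mean) for v in values) / len(values)
    return mean, mad


def classify_solvent_species(info: SolventInfo, threshold: float = 0.35) -> str:
    """Dominant solute species at saturation, from the solvent's beta.

    A hydrogen-bond-basic solvent (beta > threshold) breaks the carboxylic
    acid dimer apart: the monomer dominates.  Below the threshold the
    internally hydrogen-bonded dimer persists.  Missing beta, or beta
    exactly at the threshold, is returned as "unclassified" for the caller
    to assign manually.  Direct partition data is monomer regardless (it is
    measured in the dilute regime); this function addresses saturation
    solubilities only.
    """
    if info.beta is None or info.beta == threshold:
        return "unclassified"
    return "monomer" if info.beta > threshold else "dimer"


def filter_missing_coefficients(
    measurements: Iterable[Measurement], coeff_table: CoefficientTable
) -> tuple[list[Measurement], list[Measurement]]:
    """Partition measurements by coefficient availability of their solvent.

    A solvent is usable only with both its water->solvent and
    gas->solvent records present; the excluded list is preserved for
    reporting.
    """
    kept: list[Measurement] = []
    excluded: list[Measurement] = []
    for m in measurements:
        (kept if coeff_table.has_solvent_pair(m.solvent) else excluded).append(m)
    return kept, excluded


# -- CSV dialects ----------------------------------------------------------

def read_measurements_csv(path: str | Path) -> list[Measurement]:
    """Read measurements: solvent, kind, value, unit, temperature_C, source."""
    df = pd.read_csv(path, comment="#")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Measurement(
                solvent=row.solvent,
                kind=row.kind,
                value=float(row.value),
                unit=row.unit,
                temperature=float(row.temperature_C) + 273.15,
                source=str(getattr(row, "source", "")),
            )
        )
    return out


def write_measurements_csv(measurements: Iterable[Measurement], path: str | Path) -> None:
    rows = [
        {
            "solvent": m.solvent,
            "kind": m.kind,
            "value": m.value,
            "unit": m.unit,
            "temperature_C": m.temperature - 273.15,
            "source": m.source,
        }
        for m in measurements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_solvent_metadata_csv(path: str | Path) -> dict[str, SolventInfo]:
    """Read solvent metadata: name, beta, density_g_per_cm3, molar_mass."""
    df = pd.read_csv(path, comment="#")
    out = {}
    for row in df.itertuples(index=False):
        out[row.name] = SolventInfo(
            name=row.name,
            beta=None if pd.isna(row.beta) else float(row.beta),
            density=None if pd.isna(row.density_g_per_cm3) else float(row.density_g_per_cm3),
            molar_mass=None if pd.isna(row.molar_mass) else float(row.molar_mass),
        )
    return out
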