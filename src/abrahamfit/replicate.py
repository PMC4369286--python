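"""Replication driver for the trans-cinnamic acid case study.

Runs the full workflow on the bundled fixtures: curate the saturation
solubilities (exclude solvents without Abraham coefficients, split the
rest into monomer- and dimer-dominated sets by solvent beta), derive V and
E from structure, assemble the over-determined system for each species and
solve it, and emit a descriptor row, per-solvent observed/fitted tables
and AE/AAE/SD summaries.

The monomer fit frees S, A, L and log Kw, holding E (fragment estimate),
V (McGowan), B (user-fixed, default 0.50) and log Cw (the measured aqueous
solubility, default -2.40) fixed; it spans 16 solubilities, 5 direct
partitions, the two log Kw closures and one zero-weight placeholder for a
retention-data auxiliary equation (45 equations).  The dimer fit frees
S, A, B, L, log Kw and log Cw over 9 solubilities plus the closures
(20 equations), with E from the monomer->dimer affine relation and V of
the hydrogen-bonded dimer (three rings, the acid-bridge ring included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .data_prep import (
    Measurement,
    classify_solvent_species,
    filter_missing_coefficients,
)
from .exceptions import AbrahamFitError
from .fitting import (
    FitResult,
    FitSpec,
    assemble_equations,
    residual_stats,
    retention_placeholder,
    solve_least_squares,
)
from .model import CoefficientTable, SoluteDescriptors, predict_log_partition
from .structure import e_by_fragment_offset, e_dimer_from_monomer, mcgowan_volume

__all__ = ["ReplicationConfig", "SpeciesReport", "run_replication", "format_report"]

#: E values of the fragment-reference compounds (excess molar refractivity).
ANALOG_E = {"ethyl cinnamate": 1.102, "benzoic acid": 0.730, "ethyl benzoate": 0.689}


@dataclass(frozen=True)
class ReplicationConfig:
    """Inputs and fixed constants of the replication run."""

    which: str = "both"  # monomer | dimer | both
    solubilities_path: Path | None = None
    logp_path: Path | None = None
    coefficients_path: Path | None = None
    metadata_path: Path | None = None
    log_cw_monomer: float = -2.40
    b_monomer: float = 0.50
    beta_threshold: float = 0.35
    include_retention_placeholder: bool = True

    def __post_init__(self) -> None:
        if self.which not in ("monomer", "dimer", "both"):
            raise ValueError("which must be monomer, dimer or both")


@dataclass
class SpeciesReport:
    """One species' replication output."""

    species: str
    descriptors: dict[str, float]
    fit: FitResult
    table: pd.DataFrame  # solvent, calc/obs log Ps and log Cs
    ae: float
    aae: float
    sd: float
    n_equations: int
    n_solubilities: int
    excluded_solvents: list[str]


def _species_table(
    measurements: list[Measurement],
    coeff_table: CoefficientTable,
    desc: SoluteDescriptors,
    log_cw: float,
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        if m.kind != "solubility":
            continue
        obs_log_cs = float(np.log10(m.value))
        calc_log_ps = predict_log_partition(desc, coeff_table.get(m.solvent, "water_to_solvent"))
        rows.append(
            {
                "solvent": m.solvent,
                "calc_log_ps": calc_log_ps,
                "obs_log_ps": obs_log_cs - log_cw,
                "calc_log_cs": calc_log_ps + log_cw,
                "obs_log_cs": obs_log_cs,
            }
        )
    return pd.DataFrame(rows)


def _fit_species(
    species: str,
    solubilities: list[Measurement],
    direct: list[Measurement],
    coeff_table: CoefficientTable,
    spec: FitSpec,
    aux,
    excluded: list[str],
) -> SpeciesReport:
    constraints = assemble_equations(solubilities + direct, coeff_table, spec, aux=aux)
    fit = solve_least_squares(constraints, spec)
    descriptors = dict(spec.fixed_values)
    descriptors.update(fit.estimates)
    desc = SoluteDescriptors(
        **{k: v for k, v in descriptors.items() if k in ("E", "S", "A", "B", "V", "L")},
        fixed=frozenset(k for k in ("E", "S", "A", "B", "V", "L") if k in descriptors),
    )
    log_cw = descriptors["log_cw"]
    table = _species_table(solubilities, coeff_table, desc, log_cw)
    ae, aae, sd = residual_stats(table["obs_log_cs"], table["calc_log_cs"])
    return SpeciesReport(
        species=species,
        descriptors=descriptors,
        fit=fit,
        table=table,
        ae=ae,
        aae=aae,
        sd=sd,
        n_equations=fit.n_equations,
        n_solubilities=len(table),
        excluded_solvents=excluded,
    )


def run_replication(config: ReplicationConfig = ReplicationConfig()) -> dict[str, SpeciesReport]:
    """Execute the case-study pipeline; returns a report per species."""
    coeff_table = (
        CoefficientTable.from_csv(config.coefficients_path)
        if config.coefficients_path
        else datasets.load_coefficient_table()
    )
    from .data_prep import read_measurements_csv, read_solvent_metadata_csv

    solubilities = (
        read_measurements_csv(config.solubilities_path)
        if config.solubilities_path
        else datasets.load_solubilities()
    )
    direct = (
        read_measurements_csv(config.logp_path)
        if config.logp_path
        else datasets.load_direct_logp()
    )
    metadata = (
        read_solvent_metadata_csv(config.metadata_path)
        if config.metadata_path
        else datasets.load_solvent_metadata()
    )

    # water is the reference phase, not a fitted solvent
    organic = [m for m in solubilities if m.solvent != "water"]
    kept, excluded_ms = filter_missing_coefficients(organic, coeff_table)
    excluded = sorted({m.solvent for m in excluded_ms})

    split: dict[str, list[Measurement]] = {"monomer": [], "dimer": []}
    for m in kept:
        try:
            info = metadata[m.solvent]
        except KeyError:
            raise AbrahamFitError(f"no solvent metadata for {m.solvent!r}") from None
        species = classify_solvent_species(info, config.beta_threshold)
        if species == "unclassified":
            raise AbrahamFitError(
                f"solvent {m.solvent!r} unclassified (beta missing or at threshold); "
                "assign it manually"
            )
        split[species].append(m)

    e_monomer = round(
        e_by_fragment_offset(
            ANALOG_E["ethyl cinnamate"],
            (ANALOG_E["benzoic acid"], ANALOG_E["ethyl benzoate"]),
        ),
        2,
    )
    v_monomer = mcgowan_volume(datasets.CINNAMIC_ACID_FORMULA, rings=1)

    reports: dict[str, SpeciesReport] = {}
    if config.which in ("monomer", "both"):
        spec = FitSpec(
            free_unknowns=("S", "A", "L", "log_kw"),
            fixed_values={
                "E": e_monomer,
                "V": v_monomer,
                "B": config.b_monomer,
                "log_cw": config.log_cw_monomer,
            },
        )
        aux = [retention_placeholder()] if config.include_retention_placeholder else []
        reports["monomer"] = _fit_species(
            "monomer", split["monomer"], direct, coeff_table, spec, aux, excluded
        )
    if config.which in ("dimer", "both"):
        e_dimer = round(e_dimer_from_monomer(e_monomer), 2)
        v_dimer = mcgowan_volume("C18H16O4", rings=3)  # two aryl rings + acid bridge
        spec = FitSpec(
            free_unknowns=("S", "A", "B", "L", "log_kw", "log_cw"),
            fixed_values={"E": e_dimer, "V": v_dimer},
        )
        reports["dimer"] = _fit_species(
            "dimer", split["dimer"], [], coeff_table, spec, [], excluded
        )
    return reports


def format_report(reports: dict[str, SpeciesReport]) -> str:
    """Human-readable replication summary (values rounded to 3 decimals)."""
    lines: list[str] = []
    order = ("E", "S", "A", "B", "V", "L", "log_kw", "log_cw")
    for species, rep in reports.items():
        lines.append(f"== trans-cinnamic acid {species} ==")
        lines.append(
            "descriptors: "
            + "  ".join(
                f"{k}={rep.descriptors[k]:.4g}" for k in order if k in rep.descriptors
            )
        )
        lines.append(
            f"equations: {rep.n_equations}   solubilities: {rep.n_solubilities}   "
            f"excluded solvents: {', '.join(rep.excluded_solvents) or 'none'}"
        )
        lines.append(
            f"solubility residuals: AE={rep.ae:.3f}  AAE={rep.aae:.3f}  SD={rep.sd:.3f}"
        )
        tab = rep.table.copy()
        for col in ("calc_log_ps", "obs_log_ps", "calc_log_cs", "obs_log_cs"):
            tab[col] = tab[col].round(3)
        lines.append(tab.to_string(index=False))
        lines.append("")
    return "\n".join(lines)
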