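"""Synthetic solvent systems and measurements for pipeline validation.

The generator draws per-solvent Abraham coefficients uniformly from
realistic ranges, evaluates the forward model (the V- and L-form LFERs
plus the solubility and gas-partition bridges) at known true descriptors,
and perturbs the resulting log values with centred Gaussian noise.  Noise
lives in log units, matching the least-squares objective of the fit.  The
default scenario mirrors the hardest identifiability case of the
carboxylic-acid workflow: nine solvents, six free unknowns, twenty
equations.

Everything is deterministic under the scenario seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .data_prep import Measurement
from .exceptions import AbrahamFitError
from .fitting import FitSpec, assemble_equations, solve_least_squares
from .model import CoefficientTable, ProcessCoefficients, SoluteDescriptors, predict_log_partition

__all__ = [
    "DEFAULT_COEFFICIENT_RANGES",
    "DEFAULT_CLOSURE_RANGES",
    "SyntheticScenario",
    "gen_coefficient_table",
    "gen_measurements",
    "recovery_experiment",
]

#: Uniform draw bounds per coefficient, spanning realistic Abraham magnitudes.
DEFAULT_COEFFICIENT_RANGES: dict[str, tuple[float, float]] = {
    "c": (-1.0, 1.0),
    "e": (-1.0, 1.0),
    "s": (-2.0, 2.0),
    "a": (-4.0, 4.0),
    "b": (-5.0, 1.0),
    "v": (3.0, 4.7),
    "l": (0.6, 1.1),
}

#: Bounds for the gas->water closure records (water is a strong hydrogen-bond
#: acid and base, so s, a, b are large positive and v, l small negative).
DEFAULT_CLOSURE_RANGES: dict[str, tuple[float, float]] = {
    "c": (-1.5, -0.5),
    "e": (0.3, 1.0),
    "s": (2.0, 3.0),
    "a": (3.5, 4.2),
    "b": (4.5, 5.0),
    "v": (-1.0, -0.7),
    "l": (-0.25, -0.15),
}

_DIMER_LIKE_TRUTH = SoluteDescriptors(
    E=1.68, S=1.07, A=0.24, B=0.94, V=2.2098, L=10.30, log_kw=6.29, log_cw=-5.66,
    fixed=frozenset({"E", "V"}),
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study."""

    n_solvents: int = 9
    true_descriptors: SoluteDescriptors = _DIMER_LIKE_TRUTH
    free_unknowns: tuple[str, ...] = ("S", "A", "B", "L", "log_kw", "log_cw")
    coefficient_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENT_RANGES)
    )
    closure_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLOSURE_RANGES)
    )
    noise_sigma: float = 0.05
    seed: int = 0
    fraction_direct_logp: float = 0.0

    def __post_init__(self) -> None:
        if self.n_solvents < 1:
            raise ValueError("need at least one solvent")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0.0 <= self.fraction_direct_logp <= 1.0:
            raise ValueError("fraction_direct_logp must lie in [0, 1]")
        for rng_map in (self.coefficient_ranges, self.closure_ranges):
            for name, (lo, hi) in rng_map.items():
                if lo > hi:
                    raise ValueError(f"degenerate range for {name}: {lo} > {hi}")
        self.true_descriptors.require("E", "S", "A", "B", "V", "L", "log_kw", "log_cw")

    def spec(self) -> FitSpec:
        fixed = {
            n: getattr(self.true_descriptors, n)
            for n in ("E", "S", "A", "B", "V", "L", "log_kw", "log_cw")
            if n not in self.free_unknowns
        }
        return FitSpec(free_unknowns=self.free_unknowns, fixed_values=fixed)


def _draw(rng: np.random.Generator, ranges: Mapping[str, tuple[float, float]], name: str) -> float:
    lo, hi = ranges[name]
    return float(rng.uniform(lo, hi))


def _table_identifiable(table: CoefficientTable, scenario: SyntheticScenario) -> bool:
    """Cheap structural rank check of the design the table would induce."""
    from .fitting import _design  # local import to avoid a cycle at import time

    spec = scenario.spec()
    dummy = [
        Measurement(solvent=s, kind="solubility", value=1.0, unit="molarity")
        for s in table.systems("water_to_solvent")
    ]
    try:
        cons = assemble_equations(dummy, table, spec)
    except AbrahamFitError:
        return False
    X, _, w = _design(cons, spec.free_unknowns)
    X = X[w > 0]
    if X.shape[0] < len(spec.free_unknowns):
        return False
    return np.linalg.matrix_rank(X) == len(spec.free_unknowns)


def gen_coefficient_table(scenario: SyntheticScenario, max_retries: int = 5) -> CoefficientTable:
    """Draw a synthetic coefficient table (deterministic under seed).

    Each solvent gets one water->solvent and one gas->solvent record; two
    gas->water closure records are appended.  If the draw happens to yield
    a structurally rank-deficient design (possible with collapsed ranges),
    it is re-drawn with a warning, up to ``max_retries`` times.
    """
    rng = np.random.default_rng([int(scenario.seed), 0])
    truth = scenario.true_descriptors

    def _calibrated(draft: ProcessCoefficients, target: float) -> ProcessCoefficients:
        # shift the intercept so the record evaluates to `target` at the true
        # descriptors: keeps the thermodynamic cycle (Ps = Ks/Kw) exactly
        # consistent in the noiseless forward model
        from dataclasses import replace as _replace

        return _replace(draft, c=draft.c + target - predict_log_partition(truth, draft))

    for attempt in range(max_retries + 1):
        records = []
        for i in range(scenario.n_solvents):
            name = f"synthetic-{i:02d}"
            p_rec = ProcessCoefficients(
                system_id=name,
                process_kind="water_to_solvent",
                c=_draw(rng, scenario.coefficient_ranges, "c"),
                e=_draw(rng, scenario.coefficient_ranges, "e"),
                s=_draw(rng, scenario.coefficient_ranges, "s"),
                a=_draw(rng, scenario.coefficient_ranges, "a"),
                b=_draw(rng, scenario.coefficient_ranges, "b"),
                v=_draw(rng, scenario.coefficient_ranges, "v"),
            )
            k_draft = ProcessCoefficients(
                system_id=name,
                process_kind="gas_to_solvent",
                c=_draw(rng, scenario.coefficient_ranges, "c"),
                e=_draw(rng, scenario.coefficient_ranges, "e"),
                s=_draw(rng, scenario.coefficient_ranges, "s"),
                a=_draw(rng, scenario.coefficient_ranges, "a"),
                b=_draw(rng, scenario.coefficient_ranges, "b"),
                l=_draw(rng, scenario.coefficient_ranges, "l"),
            )
            log_ps = predict_log_partition(truth, p_rec)
            records.append(p_rec)
            records.append(_calibrated(k_draft, log_ps + truth.log_kw))
        v_draft = ProcessCoefficients(
            system_id="synthetic-water",
            process_kind="gas_to_water_V",
            c=_draw(rng, scenario.closure_ranges, "c"),
            e=_draw(rng, scenario.closure_ranges, "e"),
            s=_draw(rng, scenario.closure_ranges, "s"),
            a=_draw(rng, scenario.closure_ranges, "a"),
            b=_draw(rng, scenario.closure_ranges, "b"),
            v=_draw(rng, scenario.closure_ranges, "v"),
        )
        l_draft = ProcessCoefficients(
            system_id="synthetic-water",
            process_kind="gas_to_water_L",
            c=_draw(rng, scenario.closure_ranges, "c"),
            e=_draw(rng, scenario.closure_ranges, "e"),
            s=_draw(rng, scenario.closure_ranges, "s"),
            a=_draw(rng, scenario.closure_ranges, "a"),
            b=_draw(rng, scenario.closure_ranges, "b"),
            l=_draw(rng, scenario.closure_ranges, "l"),
        )
        records.append(_calibrated(v_draft, truth.log_kw))
        records.append(_calibrated(l_draft, truth.log_kw))
        table = CoefficientTable(records)
        if _table_identifiable(table, scenario):
            return table
        warnings.warn(
            f"synthetic coefficient draw {attempt + 1} rank-deficient; redrawing"
        )
    warnings.warn(
        f"no identifiable coefficient table in {max_retries + 1} draws; "
        "returning the last one (the solver will diagnose the deficiency)"
    )
    return table


def gen_measurements(
    scenario: SyntheticScenario, coeff_table: CoefficientTable
) -> list[Measurement]:
    """Forward-simulate one measurement per synthetic solvent.

    The first ``round(fraction_direct_logp * n)`` solvents yield direct
    log P values; the rest yield saturation molarities computed through
    log Cs = (water->solvent LFER) + log Cw, noise added in log units.
    """
    rng = np.random.default_rng([int(scenario.seed), 1])
    truth = scenario.true_descriptors
    n_direct = round(scenario.fraction_direct_logp * scenario.n_solvents)
    out: list[Measurement] = []
    for i, solvent in enumerate(coeff_table.systems("water_to_solvent")):
        if solvent.startswith("synthetic-water"):
            continue
        log_ps = predict_log_partition(truth, coeff_table.get(solvent, "water_to_solvent"))
        noise = float(rng.normal(0.0, scenario.noise_sigma)) if scenario.noise_sigma else 0.0
        if i < n_direct:
            out.append(
                Measurement(
                    solvent=solvent, kind="direct_log_p", value=log_ps + noise,
                    unit="log_p", source="synthetic",
                )
            )
        else:
            log_cs = log_ps + truth.log_cw + noise
            out.append(
                Measurement(
                    solvent=solvent, kind="solubility", value=10.0**log_cs,
                    unit="molarity", species="saturation_dependent", source="synthetic",
                )
            )
    return out


def recovery_experiment(
    scenario: SyntheticScenario, n_replicates: int = 50
) -> dict:
    """Generate -> assemble -> solve over seeded replicates.

    Returns per-unknown truth, bias and RMSE plus the count of replicates
    whose solve failed (errors are counted, never swallowed silently).
    """
    spec = scenario.spec()
    truth = {u: getattr(scenario.true_descriptors, u) for u in scenario.free_unknowns}
    estimates: dict[str, list[float]] = {u: [] for u in scenario.free_unknowns}
    failures: list[str] = []
    for r in range(n_replicates):
        sub = replace(scenario, seed=int(scenario.seed) + 7919 * (r + 1))
        try:
            table = gen_coefficient_table(sub)
            meas = gen_measurements(sub, table)
            cons = assemble_equations(meas, table, spec)
            result = solve_least_squares(cons, spec)
        except AbrahamFitError as err:
            failures.append(f"replicate {r}: {err}")
            continue
        for u in scenario.free_unknowns:
            estimates[u].append(result.estimates[u])
    report: dict = {"n_replicates": n_replicates, "n_failures": len(failures), "failures": failures, "unknowns": {}}
    for u in scenario.free_unknowns:
        est = np.asarray(estimates[u])
        if len(est) == 0:
            report["unknowns"][u] = {"truth": truth[u], "bias": float("nan"), "rmse": float("nan")}
            continue
        err = est - truth[u]
        report["unknowns"][u] = {
            "truth": truth[u],
            "bias": float(err.mean()),
            "rmse": float(np.sqrt((err**2).mean())),
            "se_of_bias": float(err.std(ddof=1) / np.sqrt(len(err))) if len(err) > 1 else float("nan"),
        }
    return report
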