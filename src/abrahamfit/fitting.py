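"""Assembly and solution of the over-determined descriptor system.

Every curated observation contributes two linear equations in the free
unknowns: a water->solvent form (the V-equation, through Ps = Cs/Cw for
solubilities) and a gas->solvent form (the L-equation, additionally
through Ps = Ks/Kw).  Two gas->water "closure" correlations, one written
in V and one in L, tie log Kw to the other descriptors, and auxiliary
constraints (e.g. a chromatographic retention correlation) can be appended
verbatim.  Contributions of fixed descriptors are folded into the response
so each equation is linear in the free-unknown vector; the stacked system
is solved by ordinary (optionally weighted) least squares.

Sign conventions for the solute-level unknowns, written with all unknowns
on the left: log Cw enters solubility constraints with coefficient +1;
log Kw enters every gas-form constraint with -1, including the closure
equations, whose response is 0.

The solver is exposed as a scikit-learn style estimator,
:class:`DescriptorRegression`, so it composes with sklearn tooling;
:func:`solve_least_squares` is the constraint-level wrapper around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    MissingCoefficientsError,
    UnderdeterminedError,
    UnidentifiableError,
)
from .model import CoefficientTable
from .data_prep import Measurement

__all__ = [
    "SOLVABLE_UNKNOWNS",
    "LinearConstraint",
    "FitSpec",
    "FitResult",
    "DescriptorRegression",
    "assemble_equations",
    "solve_least_squares",
    "residual_stats",
    "retention_placeholder",
]

#: Descriptors that may be left free and determined by regression.
SOLVABLE_UNKNOWNS = ("S", "A", "B", "L", "log_kw", "log_cw")


@dataclass(frozen=True)
class LinearConstraint:
    """One assembled equation: sum(coeff * unknown) = response.

    ``weight`` scales the equation's squared residual in the objective; a
    zero weight marks a placeholder that is counted but not solved on (used
    to carry an auxiliary equation whose coefficients are unavailable).
    """

    response: float
    unknown_coeffs: Mapping[str, float]
    weight: float = 1.0
    provenance: str = ""
    solvent: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.response):
            raise ValueError("constraint response must be finite")
        if self.weight < 0:
            raise ValueError("constraint weight must be non-negative")
        if not any(c != 0.0 for c in self.unknown_coeffs.values()):
            raise ValueError("constraint must reference at least one unknown")


@dataclass(frozen=True)
class FitSpec:
    """Which descriptors are free unknowns and which are held fixed.

    E and V are always fixed (both come from structure); the free set is
    drawn from :data:`SOLVABLE_UNKNOWNS`.
    """

    free_unknowns: tuple[str, ...]
    fixed_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.free_unknowns) - set(SOLVABLE_UNKNOWNS)
        if bad:
            raise ValueError(f"cannot free {sorted(bad)}; solvable: {SOLVABLE_UNKNOWNS}")
        overlap = set(self.free_unknowns) & set(self.fixed_values)
        if overlap:
            raise ValueError(f"unknowns both free and fixed: {sorted(overlap)}")
        for req in ("E", "V"):
            if req not in self.fixed_values:
                raise ValueError(f"{req} must be fixed (structure-derived) before fitting")


@dataclass
class FitResult:
    """Estimated unknowns plus per-equation fit and residual summaries.

    AE/AAE/SD are computed over the positively weighted constraints
    (observed - fitted, SD with the n-1 divisor).
    """

    estimates: dict[str, float]
    fitted: np.ndarray
    residuals: np.ndarray
    n_equations: int
    ae: float
    aae: float
    sd: float
    condition_number: float
    constraints: list[LinearConstraint] = field(default_factory=list)


def _constraint_terms(
    obs: float,
    coeffs,
    spec: FitSpec,
    solute_terms: Mapping[str, int],
) -> tuple[float, dict[str, float]]:
    """Fold fixed contributions into the response; collect free coefficients.

    ``solute_terms`` maps log_cw / log_kw to the sign with which they enter
    the unknown side of this equation form.
    """
    response = obs - coeffs.c
    unknown_coeffs: dict[str, float] = {}
    for name, coef in coeffs.active_terms().items():
        if name in spec.free_unknowns:
            unknown_coeffs[name] = unknown_coeffs.get(name, 0.0) + coef
        else:
            try:
                response -= coef * spec.fixed_values[name]
            except KeyError:
                raise UnidentifiableError(
                    f"descriptor {name} is neither free nor fixed"
                ) from None
    for name, sign in solute_terms.items():
        if name in spec.free_unknowns:
            unknown_coeffs[name] = unknown_coeffs.get(name, 0.0) + sign
        elif name in spec.fixed_values:
            response -= sign * spec.fixed_values[name]
        else:
            raise UnidentifiableError(f"{name} is neither free nor fixed")
    return response, unknown_coeffs


def retention_placeholder() -> LinearConstraint:
    """Zero-weight stand-in for a retention-data auxiliary equation.

    Keeps the equation count of a fit that historically included a
    gas-chromatographic retention correlation whose coefficients are not
    in the bundled table; carries no information (weight 0).
    """
    return LinearConstraint(
        response=0.0,
        unknown_coeffs={"L": 1.0},
        weight=0.0,
        provenance="auxiliary",
        solvent="(retention placeholder)",
    )


def assemble_equations(
    measurements: Sequence[Measurement],
    coeff_table: CoefficientTable,
    spec: FitSpec,
    aux: Iterable[LinearConstraint] = (),
    include_closures: bool = True,
) -> list[LinearConstraint]:
    """Build the stacked linear system from curated measurements.

    Each solubility (molarity) yields a water->solvent and a gas->solvent
    constraint; each direct log P likewise yields a P-form and a K-form
    constraint; two log Kw closures are appended when the table provides
    gas->water records; auxiliary constraints pass through verbatim.
    Solubilities must already be curated: a solvent without both
    coefficient records is a hard error here (filtering is data_prep's
    job).
    """
    constraints: list[LinearConstraint] = []
    for m in measurements:
        if not coeff_table.has_solvent_pair(m.solvent):
            raise MissingCoefficientsError(
                f"solvent {m.solvent!r} lacks coefficient records; "
                "run filter_missing_coefficients first"
            )
        p_rec = coeff_table.get(m.solvent, "water_to_solvent")
        k_rec = coeff_table.get(m.solvent, "gas_to_solvent")
        if m.kind == "solubility":
            if m.unit != "molarity":
                raise ValueError(f"{m.solvent}: solubility must be in molarity to assemble")
            if m.value <= 0:
                raise ValueError(f"{m.solvent}: solubility must be positive to take its log")
            log_cs = math.log10(m.value)
            # log Cs = P_RHS + log_cw
            resp, uc = _constraint_terms(log_cs, p_rec, spec, {"log_cw": +1})
            constraints.append(
                LinearConstraint(resp, uc, provenance="solubility_logP", solvent=m.solvent)
            )
            # log Cs = K_RHS + log_cw - log_kw
            resp, uc = _constraint_terms(log_cs, k_rec, spec, {"log_cw": +1, "log_kw": -1})
            constraints.append(
                LinearConstraint(resp, uc, provenance="solubility_logK", solvent=m.solvent)
            )
        else:  # direct_log_p
            resp, uc = _constraint_terms(m.value, p_rec, spec, {})
            constraints.append(
                LinearConstraint(resp, uc, provenance="direct_logP", solvent=m.solvent)
            )
            # log Ps = K_RHS - log_kw
            resp, uc = _constraint_terms(m.value, k_rec, spec, {"log_kw": -1})
            constraints.append(
                LinearConstraint(resp, uc, provenance="direct_logK", solvent=m.solvent)
            )
    if include_closures:
        for rec in coeff_table.closures():
            # 0 = closure_RHS - log_kw
            resp, uc = _constraint_terms(0.0, rec, spec, {"log_kw": -1})
            tag = "kw_closure_V" if rec.process_kind == "gas_to_water_V" else "kw_closure_L"
            constraints.append(
                LinearConstraint(resp, uc, provenance=tag, solvent=rec.system_id)
            )
    constraints.extend(aux)

    seen: set[str] = set()
    for con in constraints:
        if con.weight > 0:
            seen.update(n for n, c in con.unknown_coeffs.items() if c != 0.0)
    missing = [u for u in spec.free_unknowns if u not in seen]
    if missing and constraints:
        raise UnidentifiableError(
            f"unidentifiable unknown(s): {', '.join(missing)} appear in no constraint"
        )
    return constraints


class DescriptorRegression(RegressorMixin, BaseEstimator):
    """Least-squares estimator for the free solute descriptors.

    Parameters
    ----------
    unknowns : tuple of str
        Names of the free unknowns, in design-matrix column order.

    The design matrix ``X`` has one row per assembled equation and one
    column per unknown; ``y`` holds the responses.  The fit minimises
    ``sum(w * (y - X @ coef)**2)`` by a direct linear solve (no random
    initialisation, fully deterministic).  Exact collinearity aborts with
    the collinear unknowns named rather than silently pseudo-inverting.

    Attributes
    ----------
    coef_ : ndarray of shape (n_unknowns,)
    estimates_ : dict  -- unknown name -> value
    fitted_, residuals_ : ndarray over the training equations
    ae_, aae_, sd_ : residual summaries over positively weighted rows
    condition_number_ : of the weighted design matrix
    """

    def __init__(self, unknowns: tuple[str, ...] = ("S", "A", "L", "log_kw")):
        self.unknowns = unknowns

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.loc[:, list(self.unknowns)]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.unknowns):
            raise ValueError(
                f"X must have {len(self.unknowns)} columns ordered as {self.unknowns}"
            )
        return X

    def fit(self, X, y, sample_weight=None):
        X = self._as_matrix(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match the number of equations")
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        active = w > 0
        Xa, ya, wa = X[active], y[active], w[active]
        k = len(self.unknowns)
        if Xa.shape[0] < k:
            raise UnderdeterminedError(
                f"underdetermined: {Xa.shape[0]} informative equations for {k} unknowns"
            )
        sw = np.sqrt(wa)
        Xw, yw = Xa * sw[:, None], ya * sw
        rank = np.linalg.matrix_rank(Xw)
        if rank < k:
            _, _, vt = np.linalg.svd(Xw)
            null = vt[rank:]
            involved = sorted(
                {self.unknowns[j] for row in null for j in np.nonzero(np.abs(row) > 1e-8)[0]}
            )
            raise UnidentifiableError(
                f"unidentifiable system: collinear unknowns {', '.join(involved)}"
            )
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        self.coef_ = coef
        self.estimates_ = dict(zip(self.unknowns, coef.tolist()))
        self.fitted_ = X @ coef
        self.residuals_ = y - self.fitted_
        self.n_equations_ = len(y)
        ra = self.residuals_[active]
        self.ae_ = float(ra.mean())
        self.aae_ = float(np.abs(ra).mean())
        self.sd_ = (
            float(np.sqrt(np.sum(ra**2) / (len(ra) - 1))) if len(ra) > 1 else float("nan")
        )
        self.condition_number_ = float(np.linalg.cond(Xw))
        return self

    def predict(self, X) -> np.ndarray:
        return self._as_matrix(X) @ self.coef_


def _design(
    constraints: Sequence[LinearConstraint], unknowns: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.zeros((len(constraints), len(unknowns)))
    y = np.empty(len(constraints))
    w = np.empty(len(constraints))
    col = {u: j for j, u in enumerate(unknowns)}
    for i, con in enumerate(constraints):
        for name, coef in con.unknown_coeffs.items():
            if name not in col:
                raise UnidentifiableError(
                    f"constraint references {name!r}, not a free unknown of this fit"
                )
            X[i, col[name]] = coef
        y[i] = con.response
        w[i] = con.weight
    return X, y, w


def solve_least_squares(
    constraints: Sequence[LinearConstraint], spec: FitSpec
) -> FitResult:
    """Solve the assembled system for ``spec.free_unknowns``."""
    X, y, w = _design(constraints, spec.free_unknowns)
    est = DescriptorRegression(unknowns=tuple(spec.free_unknowns))
    est.fit(X, y, sample_weight=w)
    return FitResult(
        estimates=est.estimates_,
        fitted=est.fitted_,
        residuals=est.residuals_,
        n_equations=est.n_equations_,
        ae=est.ae_,
        aae=est.aae_,
        sd=est.sd_,
        condition_number=est.condition_number_,
        constraints=list(constraints),
    )


def residual_stats(
    observed: Sequence[float], fitted: Sequence[float]
) -> tuple[float, float, float]:
    """AE, AAE and SD (n-1 divisor) of observed - fitted."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.ndim != 1:
        raise ValueError("observed and fitted must be equal-length 1-D sequences")
    if len(obs) == 0:
        raise ValueError("empty residual set")
    if len(obs) < 2:
        raise ValueError("SD needs at least two residuals")
    r = obs - fit
    return (
        float(r.mean()),
        float(np.abs(r).mean()),
        float(np.sqrt(np.sum(r**2) / (len(r) - 1))),
    )
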