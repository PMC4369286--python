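"""Equation assembly, the least-squares estimator and residual statistics."""

import numpy as np
import pytest
from sklearn.base import clone

from abrahamfit import (
    DescriptorRegression,
    FitSpec,
    LinearConstraint,
    assemble_equations,
    residual_stats,
    solve_least_squares,
)
from abrahamfit.exceptions import (
    MissingCoefficientsError,
    UnderdeterminedError,
    UnidentifiableError,
)
from abrahamfit.fitting import retention_placeholder

MONOMER_SPEC = FitSpec(
    free_unknowns=("S", "A", "L", "log_kw"),
    fixed_values={"E": 1.14, "V": 1.1705, "B": 0.50, "log_cw": -2.40},
)
DIMER_SPEC = FitSpec(
    free_unknowns=("S", "A", "B", "L", "log_kw", "log_cw"),
    fixed_values={"E": 1.68, "V": 2.2098},
)


def grid_search_oracle(constraints, unknowns, lo=-8.0, hi=8.0, tol=1e-4):
    """Brute-force minimiser of the same weighted sum of squares.

    Dense coordinate grid over the unknown box, iteratively refined around
    the incumbent until the grid step falls below ``tol``.  Independent of
    the linear-algebra solve path.
    """
    centers = np.zeros(len(unknowns)) + (lo + hi) / 2
    half = (hi - lo) / 2

    def sse(point):
        total = 0.0
        for con in constraints:
            pred = sum(
                con.unknown_coeffs.get(u, 0.0) * point[j] for j, u in enumerate(unknowns)
            )
            total += con.weight * (con.response - pred) ** 2
        return total

    n_pts = 9
    while half * 2 / (n_pts - 1) > tol / 4:
        axes = [np.linspace(c - half, c + half, n_pts) for c in centers]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        vals = np.array([sse(p) for p in pts])
        centers = pts[np.argmin(vals)]
        half = half * 2 / (n_pts - 1)  # keep one old grid step on each side
    return dict(zip(unknowns, centers))


def _toy_constraints(rng, n, unknowns, truth, sigma=0.0):
    cons = []
    for _ in range(n):
        coeffs = {u: float(rng.uniform(-2, 2)) for u in unknowns}
        resp = sum(coeffs[u] * truth[u] for u in unknowns) + float(rng.normal(0, sigma)) if sigma else sum(
            coeffs[u] * truth[u] for u in unknowns
        )
        cons.append(LinearConstraint(response=resp, unknown_coeffs=coeffs))
    return cons


class TestAssembly:
    def test_monomer_counts_45(self, solubilities, direct_logp, coeff_table, solvent_metadata):
        from abrahamfit import classify_solvent_species, filter_missing_coefficients

        organic = [m for m in solubilities if m.solvent != "water"]
        kept, _ = filter_missing_coefficients(organic, coeff_table)
        monomer = [
            m for m in kept
            if classify_solvent_species(solvent_metadata[m.solvent]) == "monomer"
        ]
        cons = assemble_equations(
            monomer + direct_logp, coeff_table, MONOMER_SPEC, aux=[retention_placeholder()]
        )
        assert len(cons) == 45
        by_tag = {}
        for c in cons:
            by_tag[c.provenance] = by_tag.get(c.provenance, 0) + 1
        assert by_tag == {
            "solubility_logP": 16, "solubility_logK": 16,
            "direct_logP": 5, "direct_logK": 5,
            "kw_closure_V": 1, "kw_closure_L": 1, "auxiliary": 1,
        }

    def test_dimer_counts_20(self, solubilities, coeff_table, solvent_metadata):
        from abrahamfit import classify_solvent_species, filter_missing_coefficients

        organic = [m for m in solubilities if m.solvent != "water"]
        kept, _ = filter_missing_coefficients(organic, coeff_table)
        dimer = [
            m for m in kept
            if classify_solvent_species(solvent_metadata[m.solvent]) == "dimer"
        ]
        cons = assemble_equations(dimer, coeff_table, DIMER_SPEC)
        assert len(cons) == 20

    def test_empty_input_no_closures(self, coeff_table):
        assert assemble_equations([], coeff_table, MONOMER_SPEC, include_closures=False) == []

    def test_unfiltered_solvent_is_hard_error(self, solubilities, coeff_table):
        penta = [m for m in solubilities if m.solvent == "pentachloroethane"]
        with pytest.raises(MissingCoefficientsError, match="pentachloroethane"):
            assemble_equations(penta, coeff_table, MONOMER_SPEC)

    def test_equation_count_law(self, solubilities, direct_logp, coeff_table, solvent_metadata):
        """n = 2*(#solubilities + #direct) + #closures + #auxiliary."""
        from abrahamfit import classify_solvent_species, filter_missing_coefficients

        organic = [m for m in solubilities if m.solvent != "water"]
        kept, _ = filter_missing_coefficients(organic, coeff_table)
        for n_sol, n_dir, n_aux in [(3, 0, 0), (5, 2, 1), (9, 5, 0)]:
            ms = kept[:n_sol] + direct_logp[:n_dir]
            aux = [retention_placeholder()] * n_aux
            cons = assemble_equations(ms, coeff_table, DIMER_SPEC, aux=aux)
            assert len(cons) == 2 * (n_sol + n_dir) + 2 + n_aux

    def test_unidentifiable_unknown_reported(self, direct_logp, coeff_table):
        # log_cw never appears when only direct partitions are assembled
        spec = FitSpec(
            free_unknowns=("S", "A", "L", "log_kw", "log_cw"),
            fixed_values={"E": 1.14, "V": 1.1705, "B": 0.50},
        )
        with pytest.raises(UnidentifiableError, match="log_cw"):
            assemble_equations(direct_logp, coeff_table, spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="must be fixed"):
            FitSpec(free_unknowns=("S",), fixed_values={"E": 1.0})
        with pytest.raises(ValueError, match="both free and fixed"):
            FitSpec(free_unknowns=("S",), fixed_values={"E": 1, "V": 1, "S": 0.5})
        with pytest.raises(ValueError, match="cannot free"):
            FitSpec(free_unknowns=("E",), fixed_values={"E": 1, "V": 1})


class TestSolver:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(17)
        truth = {"S": 1.07, "A": 0.24, "B": 0.94}
        cons = _toy_constraints(rng, 12, ("S", "A", "B"), truth)
        spec = FitSpec(free_unknowns=("S", "A", "B"), fixed_values={"E": 1, "V": 1})
        result = solve_least_squares(cons, spec)
        for u, v in truth.items():
            assert result.estimates[u] == pytest.approx(v, abs=1e-8)
        assert np.max(np.abs(result.residuals)) < 1e-8

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        truth = {"S": 1.2, "A": -0.5, "L": 4.0}
        cons = _toy_constraints(rng, 10, ("S", "A", "L"), truth, sigma=0.3)
        spec = FitSpec(free_unknowns=("S", "A", "L"), fixed_values={"E": 1, "V": 1})
        result = solve_least_squares(cons, spec)
        oracle = grid_search_oracle(cons, ("S", "A", "L"))
        for u in truth:
            assert result.estimates[u] == pytest.approx(oracle[u], abs=1e-4)

    def test_normal_equations_hold(self):
        rng = np.random.default_rng(5)
        truth = {"S": 0.8, "A": 0.3, "L": 6.1, "log_kw": 5.5}
        cons = _toy_constraints(rng, 25, tuple(truth), truth, sigma=0.1)
        spec = FitSpec(free_unknowns=tuple(truth), fixed_values={"E": 1, "V": 1})
        result = solve_least_squares(cons, spec)
        from abrahamfit.fitting import _design

        X, y, w = _design(cons, spec.free_unknowns)
        grad = X.T @ (w * (y - X @ np.array([result.estimates[u] for u in truth])))
        assert np.max(np.abs(grad)) < 1e-8

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(11)
        truth = {"S": 1.0, "A": 0.5}
        cons = _toy_constraints(rng, 15, ("S", "A"), truth, sigma=0.2)
        spec = FitSpec(free_unknowns=("S", "A"), fixed_values={"E": 1, "V": 1})
        result = solve_least_squares(cons, spec)
        from abrahamfit.fitting import _design

        X, y, w = _design(cons, spec.free_unknowns)
        r = w * result.residuals
        for j in range(X.shape[1]):
            denom = np.linalg.norm(X[:, j]) * np.linalg.norm(r) + 1e-30
            assert abs(X[:, j] @ r) <= 1e-8 * max(denom, 1.0)

    def test_exactly_satisfied_constraint_changes_nothing(self):
        rng = np.random.default_rng(7)
        truth = {"S": 1.0, "A": 0.5}
        cons = _toy_constraints(rng, 12, ("S", "A"), truth, sigma=0.2)
        spec = FitSpec(free_unknowns=("S", "A"), fixed_values={"E": 1, "V": 1})
        base = solve_least_squares(cons, spec)
        extra = LinearConstraint(
            response=2.0 * base.estimates["S"] - 1.0 * base.estimates["A"],
            unknown_coeffs={"S": 2.0, "A": -1.0},
        )
        again = solve_least_squares(cons + [extra], spec)
        for u in truth:
            assert again.estimates[u] == pytest.approx(base.estimates[u], abs=1e-10)

    def test_duplicate_constraint_acts_as_weight(self):
        rng = np.random.default_rng(13)
        truth = {"S": 1.0, "A": 0.5}
        cons = _toy_constraints(rng, 8, ("S", "A"), truth, sigma=0.3)
        spec = FitSpec(free_unknowns=("S", "A"), fixed_values={"E": 1, "V": 1})
        duplicated = solve_least_squares(cons + [cons[0]], spec)
        import dataclasses

        reweighted = [dataclasses.replace(cons[0], weight=2.0)] + cons[1:]
        weighted = solve_least_squares(reweighted, spec)
        for u in truth:
            assert duplicated.estimates[u] == pytest.approx(weighted.estimates[u], abs=1e-10)

    def test_zero_weight_row_is_counted_but_ignored(self):
        rng = np.random.default_rng(19)
        truth = {"S": 1.0, "A": 0.5, "L": 4.0}
        cons = _toy_constraints(rng, 10, ("S", "A", "L"), truth, sigma=0.1)
        spec = FitSpec(free_unknowns=("S", "A", "L"), fixed_values={"E": 1, "V": 1})
        base = solve_least_squares(cons, spec)
        padded = solve_least_squares(cons + [retention_placeholder()], spec)
        assert padded.n_equations == base.n_equations + 1
        for u in truth:
            assert padded.estimates[u] == pytest.approx(base.estimates[u], abs=1e-12)
        assert padded.ae == pytest.approx(base.ae, abs=1e-12)

    def test_underdetermined(self):
        cons = [LinearConstraint(1.0, {"S": 1.0, "A": 1.0})]
        spec = FitSpec(free_unknowns=("S", "A"), fixed_values={"E": 1, "V": 1})
        with pytest.raises(UnderdeterminedError):
            solve_least_squares(cons, spec)

    def test_collinear_unknowns_named(self):
        cons = [
            LinearConstraint(float(i), {"S": 1.0 * i, "A": 2.0 * i}) for i in (1, 2, 3)
        ]
        spec = FitSpec(free_unknowns=("S", "A"), fixed_values={"E": 1, "V": 1})
        with pytest.raises(UnidentifiableError, match="S.*A|A.*S"):
            solve_least_squares(cons, spec)

    def test_estimator_sklearn_protocol(self):
        est = DescriptorRegression(unknowns=("S", "A"))
        assert clone(est).get_params()["unknowns"] == ("S", "A")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 2))
        beta = np.array([1.5, -0.5])
        est.fit(X, X @ beta)
        assert est.coef_ == pytest.approx(beta, abs=1e-10)
        assert est.predict(X[:3]) == pytest.approx(X[:3] @ beta, abs=1e-10)
        assert est.score(X, X @ beta) == pytest.approx(1.0)


class TestResidualStats:
    def test_monomer_reference_table(self, monomer_reference):
        ae, aae, sd = residual_stats(
            monomer_reference.obs_log_cs, monomer_reference.calc_log_cs
        )
        assert (round(ae, 3), round(aae, 3), round(sd, 3)) == (0.006, 0.055, 0.078)

    def test_dimer_reference_table(self, dimer_reference):
        ae, aae, sd = residual_stats(
            dimer_reference.obs_log_cs, dimer_reference.calc_log_cs
        )
        assert (round(ae, 3), round(aae, 3), round(sd, 3)) == (0.003, 0.053, 0.084)

    def test_sd_uses_n_minus_one(self, monomer_reference, dimer_reference):
        """The n divisor would give visibly different (wrong) values."""
        for df, with_n1, with_n in [
            (monomer_reference, 0.078, 0.075),
            (dimer_reference, 0.084, 0.079),
        ]:
            r = np.asarray(df.obs_log_cs) - np.asarray(df.calc_log_cs)
            assert round(float(np.sqrt((r**2).sum() / (len(r) - 1))), 3) == with_n1
            assert round(float(np.sqrt((r**2).mean())), 3) == with_n

    def test_perfect_fit(self):
        assert residual_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0)

    def test_aae_bounds_ae(self):
        ae, aae, _ = residual_stats([1.0, 2.0, 4.0], [1.1, 2.3, 3.0])
        assert aae >= abs(ae)

    def test_validation(self):
        with pytest.raises(ValueError):
            residual_stats([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            residual_stats([1.0], [1.0])


class TestConstraintValidation:
    def test_all_zero_coefficients_rejected(self):
        with pytest.raises(ValueError, match="at least one unknown"):
            LinearConstraint(1.0, {"S": 0.0})

    def test_non_finite_response_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            LinearConstraint(float("nan"), {"S": 1.0})

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            LinearConstraint(1.0, {"S": 1.0}, weight=-1.0)
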