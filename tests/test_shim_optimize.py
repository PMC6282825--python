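"""Localized and fat-constrained solvers against closed forms and the
grid-search oracle."""

import dataclasses

import numpy as np
import pytest

from fetalshim import (
    InfeasibleShimError,
    PhantomSpec,
    ShimBasis,
    ShimProblem,
    compute_fieldmap,
    generate_phantom,
    project_shim,
    qp_oracle,
    roi_sd,
    solve_constrained,
    solve_localized,
    unwrap_fieldmap,
)


@pytest.fixture
def toy_2c(rng):
    A = rng.normal(size=(10, 2))
    b = rng.normal(size=10) * 50
    return A, b


def _box(n, lim):
    return -np.full(n, float(lim)), np.full(n, float(lim))


class TestLocalized:
    def test_exact_representable_field(self, rng):
        A = rng.normal(size=(20, 8))
        s_true = rng.normal(scale=30, size=8)
        lb, ub = _box(8, 2000)
        p = ShimProblem(A=A, b=A @ s_true, lam=0.0, lb=lb, ub=ub)
        sol = solve_localized(p)
        assert np.allclose(sol.s, s_true, atol=1e-9)
        assert np.std(A @ sol.s - p.b) < 1e-9

    def test_ridge_matches_normal_equations(self, toy_2c):
        A, b = toy_2c
        lb, ub = _box(2, 1e6)
        p = ShimProblem(A=A, b=b, lam=0.03, lb=lb, ub=ub)
        sol = solve_localized(p)
        rms = p.column_rms()
        closed = np.linalg.solve(A.T @ A + 0.03 * np.diag(rms**2), A.T @ b)
        assert np.abs(sol.s - closed).max() < 1e-8

    def test_unconstrained_optimum_beyond_bound_clips(self):
        A = np.ones((5, 1))
        p = ShimProblem(A=A, b=np.full(5, 10.0), lam=0.0,
                        lb=np.array([-2.0]), ub=np.array([2.0]))
        sol = solve_localized(p)
        orc = qp_oracle(p, 1e-6)
        assert sol.s[0] == pytest.approx(2.0)
        assert np.abs(sol.s - orc.s).max() < 1e-6
        assert sol.active_bounds == ("c0",)

    def test_small_roi_warns(self, rng):
        A = rng.normal(size=(5, 8))
        lb, ub = _box(8, 2000)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            solve_localized(ShimProblem(A=A, b=rng.normal(size=5), lb=lb, ub=ub))

    def test_rank_deficient_with_ridge_still_unique(self, rng):
        col = rng.normal(size=10)
        A = np.stack([col, col], axis=1)  # rank 1
        lb, ub = _box(2, 1e6)
        p = ShimProblem(A=A, b=rng.normal(size=10), lam=0.03, lb=lb, ub=ub)
        sol = solve_localized(p)
        rms = p.column_rms()
        closed = np.linalg.solve(A.T @ A + 0.03 * np.diag(rms**2), A.T @ p.b)
        assert np.abs(sol.s - closed).max() < 1e-8

    def test_lambda_monotonically_shrinks_normalized_norm(self, toy_2c):
        A, b = toy_2c
        lb, ub = _box(2, 1e6)
        norms = []
        for lam in (0.0, 0.03, 0.3, 3.0):
            p = ShimProblem(A=A, b=b, lam=lam, lb=lb, ub=ub)
            norms.append(np.linalg.norm(p.column_rms() * solve_localized(p).s))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestConstrained:
    def test_inactive_constraints_equal_localized(self, toy_2c):
        A, b = toy_2c
        lb, ub = _box(2, 1e6)
        loc = solve_localized(ShimProblem(A=A, b=b, lam=0.03, lb=lb, ub=ub))
        C = np.eye(2)
        p = ShimProblem(A=A, b=b, lam=0.03, lb=lb, ub=ub,
                        C=C, b_fat=C @ loc.s, d1=-50.0, d2=50.0)
        con = solve_constrained(p)
        assert np.abs(con.s - loc.s).max() < 1e-8
        assert "inactive" in con.solver_report

    def test_two_coefficient_toy_matches_oracle(self, toy_2c):
        A, b = toy_2c
        lb, ub = _box(2, 60)
        C = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, -1.0]])
        loc = solve_localized(ShimProblem(A=A, b=b, lam=0.03, lb=lb, ub=ub))
        target = loc.s + np.array([3.0, -2.0])
        p = ShimProblem(A=A, b=b, lam=0.03, lb=lb, ub=ub,
                        C=C, b_fat=C @ target, d1=-1.0, d2=1.0)
        sol = solve_constrained(p)
        orc = qp_oracle(p, 1e-5)
        assert sol.feasible
        assert np.abs(sol.s - orc.s).max() < 1e-4
        assert sol.objective >= solve_localized(p).objective - 1e-9

    def test_three_coefficient_toy_matches_oracle(self, rng):
        A = rng.normal(size=(12, 3))
        b = rng.normal(size=12) * 30
        lb, ub = _box(3, 50)
        C = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0],
                      [1.0, 1.0, 0], [0, 1.0, -1.0]])
        loc = solve_localized(ShimProblem(A=A, b=b, lam=0.03, lb=lb, ub=ub))
        target = loc.s + np.array([2.0, -1.5, 1.0])
        p = ShimProblem(A=A, b=b, lam=0.03, lb=lb, ub=ub,
                        C=C, b_fat=C @ target, d1=-1.5, d2=1.5)
        sol = solve_constrained(p)
        orc = qp_oracle(p, 1e-5)
        assert np.abs(sol.s - orc.s).max() < 1e-4

    def test_feasibility_certificate_on_phantom(self, fat_conflict_phantom):
        d = fat_conflict_phantom
        f = unwrap_fieldmap(compute_fieldmap(d.echo1, d.echo2),
                            d.echo2.te - d.echo1.te)
        p = ShimProblem.from_fieldmap(f, d.brain_mask, d.fat_mask)
        sol = solve_constrained(p)
        assert sol.feasible
        assert p.fat_violation(sol.s).max() <= 1e-6

    def test_infeasible_strict_raises(self):
        A = np.ones((5, 1))
        C = np.array([[1.0], [-1.0]])
        kw = dict(A=A, b=np.full(5, 10.0), lam=0.0,
                  lb=np.array([-2.0]), ub=np.array([2.0]),
                  C=C, b_fat=np.array([1000.0, -1000.0]), d1=-10.0, d2=10.0)
        with pytest.raises(InfeasibleShimError):
            solve_constrained(ShimProblem(**kw, infeasible_policy="strict"))

    def test_infeasible_relax_widens_minimally(self):
        A = np.ones((5, 1))
        C = np.array([[1.0], [-1.0]])
        p = ShimProblem(A=A, b=np.full(5, 10.0), lam=0.0,
                        lb=np.array([-2.0]), ub=np.array([2.0]),
                        C=C, b_fat=np.array([1000.0, -1000.0]),
                        d1=-10.0, d2=10.0, infeasible_policy="relax")
        sol = solve_constrained(p)
        assert "relaxed" in sol.solver_report
        # minimal widening: resid at s=2 is 998 vs d2=10 -> eps = 988
        assert "988" in sol.solver_report
        assert not sol.feasible  # against the original band

    def test_no_fat_voxels_falls_back(self, toy_2c):
        A, b = toy_2c
        lb, ub = _box(2, 1e6)
        p = ShimProblem(A=A, b=b, lam=0.03, lb=lb, ub=ub)
        sol = solve_constrained(p)
        assert "fell back" in sol.solver_report


class TestOracle:
    def test_refuses_more_than_three_coefficients(self, rng):
        A = rng.normal(size=(10, 4))
        lb, ub = _box(4, 10)
        with pytest.raises(ValueError):
            qp_oracle(ShimProblem(A=A, b=rng.normal(size=10), lb=lb, ub=ub), 0.1)

    def test_reports_empty_feasible_set(self):
        A = np.ones((5, 1))
        C = np.array([[1.0], [-1.0]])
        p = ShimProblem(A=A, b=np.full(5, 10.0), lam=0.0,
                        lb=np.array([-2.0]), ub=np.array([2.0]),
                        C=C, b_fat=np.array([1000.0, -1000.0]),
                        d1=-10.0, d2=10.0)
        orc = qp_oracle(p, 0.01)
        assert not orc.feasible

    def test_convexity_never_beats_solver_beyond_grid_bound(self, toy_2c):
        A, b = toy_2c
        lb, ub = _box(2, 60)
        p = ShimProblem(A=A, b=b, lam=0.03, lb=lb, ub=ub)
        sol = solve_localized(p)
        orc = qp_oracle(p, 1e-4)
        assert orc.objective >= sol.objective - 1e-6


class TestParameterRecovery:
    def test_rmse_decreases_with_noise(self):
        """Recovered coefficients degrade in proportion to injected field
        noise and converge to truth at zero noise."""
        base = PhantomSpec()
        rmses = []
        for sd in (0.0, 1.0, 5.0):
            d = generate_phantom(dataclasses.replace(base, noise_sd=sd, seed=3))
            f = unwrap_fieldmap(compute_fieldmap(d.echo1, d.echo2),
                                d.echo2.te - d.echo1.te)
            p = ShimProblem.from_fieldmap(f, d.brain_mask, lam=0.0)
            sol = solve_localized(p)
            rms = p.column_rms()
            rmses.append(float(np.sqrt(np.mean((rms * (sol.s - d.coeffs)) ** 2))))
        assert rmses[0] < 1e-6
        assert rmses[0] < rmses[1] < rmses[2]
        # noise averaging over ~hundreds of ROI voxels: RMSE well below sigma
        assert rmses[2] < 5.0


def test_constrained_reduces_fat_excursions_on_phantom(fat_conflict_phantom):
    """The regime of the study: localized shim pushes fat residuals outside
    the saturation band, the constrained shim pulls every fat voxel back at
    a modest brain-homogeneity cost."""
    from fetalshim import fat_out_of_band

    d = fat_conflict_phantom
    f = unwrap_fieldmap(compute_fieldmap(d.echo1, d.echo2),
                        d.echo2.te - d.echo1.te)
    p = ShimProblem.from_fieldmap(f, d.brain_mask, d.fat_mask)
    sl, sc = solve_localized(p), solve_constrained(p)
    rl = project_shim(f, ShimBasis(), sl.s)
    rc = project_shim(f, ShimBasis(), sc.s)
    out_l = fat_out_of_band(rl, d.fat_mask)
    out_c = fat_out_of_band(rc, d.fat_mask)
    assert out_l > 0.0
    assert out_c == 0.0
    assert roi_sd(rc, d.brain_mask) <= 1.2 * roi_sd(rl, d.brain_mask)
    assert sc.objective >= sl.objective
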