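"""Localized and fat-constrained shim optimization.

Both solvers minimize the Tikhonov-regularized least-squares cost

    || A s - b ||^2  +  lambda || s_tilde ||^2,    lb <= s <= ub,

where A holds the shim basis sampled over the brain ROI, b the measured
off-resonance there (Hz), and s_tilde are the coefficients after scaling
each column of A to unit RMS over the ROI, which makes the default
lambda = 0.03 meaningful regardless of coefficient units.  The
fat-constrained variant adds a per-fat-voxel band on the residual field,

    d1 <= b_fat - C s <= d2        (d1 = -350 Hz, d2 = 100 Hz by default),

the effective range of the fat-saturation pulse expressed as fat-frequency
deviation.  Sign convention: the solver fits A s ~ b, so hardware must
apply the negated coefficients; the residual is always b - A s.

The bound-only problem is solved with an active-set bounded least squares
(BVLS); the fat-constrained convex QP with an interior-point/trust-region
iteration followed by an exact KKT polish on the identified active set.
A dense grid-search oracle (``qp_oracle``) is provided for cross-checking
small problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, lsq_linear, minimize

from .fieldmap import FieldMap, RegionMask
from .shim_model import (
    N_TERMS,
    SH_TERMS,
    ShimBasis,
    ShimLimits,
    build_design_matrix,
)

DEFAULT_LAMBDA = 0.03
DEFAULT_D1 = -350.0
DEFAULT_D2 = 100.0
FEAS_TOL = 1e-6  # Hz, feasibility certificate for returned solutions


class InfeasibleShimError(RuntimeError):
    """No coefficient vector satisfies bounds plus all fat constraints."""


@dataclass
class ShimProblem:
    """Data of one shim solve; ``C``/``b_fat`` are absent for L-IB."""

    A: np.ndarray
    b: np.ndarray
    lam: float = DEFAULT_LAMBDA
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None
    C: np.ndarray | None = None
    b_fat: np.ndarray | None = None
    d1: float = DEFAULT_D1
    d2: float = DEFAULT_D2
    terms: tuple[str, ...] | None = None
    infeasible_policy: str = "relax"   # or "strict"
    fat_subsample: int = 1

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        n = self.A.shape[1]
        if self.A.shape[0] != self.b.size:
            raise ValueError("A row count must match b")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.lb is None or self.ub is None:
            lim = ShimLimits()
            if n != N_TERMS:
                raise ValueError("explicit bounds required for non-standard bases")
            self.lb = lim.lb if self.lb is None else self.lb
            self.ub = lim.ub if self.ub is None else self.ub
        self.lb = np.asarray(self.lb, dtype=float).ravel()
        self.ub = np.asarray(self.ub, dtype=float).ravel()
        if self.lb.size != n or self.ub.size != n or np.any(self.lb > self.ub):
            raise ValueError("invalid coefficient bounds")
        if self.terms is None:
            self.terms = SH_TERMS if n == N_TERMS else tuple(
                f"c{i}" for i in range(n)
            )
        if self.C is not None:
            self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
            self.b_fat = np.asarray(self.b_fat, dtype=float).ravel()
            if self.C.shape[1] != n or self.C.shape[0] != self.b_fat.size:
                raise ValueError("C/b_fat dimensions inconsistent with A")
            if not self.d1 < self.d2:
                raise ValueError("need d1 < d2 for the fat band")
            if self.fat_subsample > 1:
                self.C = self.C[:: self.fat_subsample]
                self.b_fat = self.b_fat[:: self.fat_subsample]
        if self.infeasible_policy not in ("relax", "strict"):
            raise ValueError("infeasible_policy must be 'relax' or 'strict'")

    @classmethod
    def from_fieldmap(
        cls,
        fieldmap: FieldMap,
        brain: RegionMask,
        fat: RegionMask | None = None,
        basis: ShimBasis = ShimBasis(),
        limits: ShimLimits | None = None,
        lam: float = DEFAULT_LAMBDA,
        d1: float = DEFAULT_D1,
        d2: float = DEFAULT_D2,
        **kwargs,
    ) -> "ShimProblem":
        """Assemble the problem from an (unwrapped) field map and masks.

        Masks are intersected with the field map's valid-voxel mask before
        the design matrices are built.
        """
        fieldmap.grid.require_match(brain.grid, "field map and brain mask")
        limits = limits or ShimLimits()
        brain_eff = RegionMask(brain.mask & fieldmap.valid, fieldmap.grid, "brain")
        if brain_eff.count == 0:
            raise ValueError("brain ROI contains no valid field-map voxels")
        Ad = build_design_matrix(brain_eff, basis)
        b = fieldmap.freq[tuple(Ad.voxel_index.T)]
        C = b_fat = None
        if fat is not None and fat.count:
            fieldmap.grid.require_match(fat.grid, "field map and fat mask")
            fat_eff = RegionMask(fat.mask & fieldmap.valid, fieldmap.grid, "fat")
            if fat_eff.count:
                Cd = build_design_matrix(fat_eff, basis)
                C = Cd.values
                b_fat = fieldmap.freq[tuple(Cd.voxel_index.T)]
        return cls(
            A=Ad.values, b=b, lam=lam, lb=limits.lb, ub=limits.ub,
            C=C, b_fat=b_fat, d1=d1, d2=d2, **kwargs,
        )

    # -- shared pieces -----------------------------------------------------

    @property
    def n(self) -> int:
        return self.A.shape[1]

    def column_rms(self) -> np.ndarray:
        """Per-column RMS of A over the ROI (the Tikhonov normalization);
        all-zero columns fall back to the largest RMS so that the penalty
        still pins them."""
        rms = np.sqrt(np.mean(self.A**2, axis=0))
        fallback = rms.max() if rms.max() > 0 else 1.0
        return np.where(rms > 1e-12 * fallback, rms, fallback)

    def objective(self, s: np.ndarray) -> float:
        s = np.asarray(s, dtype=float)
        r = self.A @ s - self.b
        st = self.column_rms() * s
        return float(r @ r + self.lam * (st @ st))

    def fat_violation(self, s: np.ndarray) -> np.ndarray:
        """Per-fat-voxel violation of d1 <= b_fat - C s <= d2 (Hz, >= 0)."""
        if self.C is None:
            return np.zeros(0)
        resid = self.b_fat - self.C @ s
        return np.maximum(self.d1 - resid, 0) + np.maximum(resid - self.d2, 0)


@dataclass
class ShimSolution:
    s: np.ndarray
    objective: float
    feasible: bool
    active_bounds: tuple[str, ...] = ()
    active_fat_voxels: int = 0
    solver_report: str = ""
    f0_offset_hz: float = 0.0
    terms: tuple[str, ...] = dc_field(default_factory=lambda: SH_TERMS)

    def to_dict(self) -> dict:
        return {
            "coefficients": {t: float(v) for t, v in zip(self.terms, self.s)},
            "objective": self.objective,
            "feasible": self.feasible,
            "active_bounds": list(self.active_bounds),
            "active_fat_voxels": self.active_fat_voxels,
            "f0_offset_hz": self.f0_offset_hz,
            "solver_report": self.solver_report,
        }


def _finish(problem: ShimProblem, s: np.ndarray, report: str) -> ShimSolution:
    s = np.clip(s, problem.lb, problem.ub)
    span = np.maximum(problem.ub - problem.lb, 1e-30)
    at_lb = (s - problem.lb) <= 1e-9 * span
    at_ub = (problem.ub - s) <= 1e-9 * span
    active = tuple(
        t for t, a in zip(problem.terms, at_lb | at_ub) if a
    )
    viol = problem.fat_violation(s)
    n_active_fat = int(_at_band_edge(problem, s).sum()) if problem.C is not None else 0
    feasible = bool(viol.size == 0 or viol.max() <= FEAS_TOL)
    return ShimSolution(
        s=s,
        objective=problem.objective(s),
        feasible=feasible,
        active_bounds=active,
        active_fat_voxels=n_active_fat,
        solver_report=report,
        f0_offset_hz=float(np.mean(problem.b - problem.A @ s)),
        terms=problem.terms,
    )


def _at_band_edge(problem: ShimProblem, s: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    resid = problem.b_fat - problem.C @ s
    return (np.abs(resid - problem.d1) <= tol) | (np.abs(resid - problem.d2) <= tol)


def solve_localized(problem: ShimProblem) -> ShimSolution:
    """Bounded, Tikhonov-regularized least squares over the brain ROI (L-IB).

    Solved exactly with active-set bounded least squares on the stacked
    system [A; sqrt(lambda) diag(rms)].  Fat constraints, if present on the
    problem, are ignored here.
    """
    nb, n = problem.A.shape
    if nb < n:
        warnings.warn(
            f"only {nb} ROI voxels for {n} shim terms: ill-conditioned fit",
            stacklevel=2,
        )
    if problem.lam == 0 and np.linalg.matrix_rank(problem.A) < n:
        warnings.warn("rank-deficient design matrix with lambda = 0", stacklevel=2)
    rms = problem.column_rms()
    if problem.lam > 0:
        M = np.vstack([problem.A, np.sqrt(problem.lam) * np.diag(rms)])
        rhs = np.concatenate([problem.b, np.zeros(n)])
    else:
        M, rhs = problem.A, problem.b
    try:
        res = lsq_linear(M, rhs, bounds=(problem.lb, problem.ub),
                         method="bvls", tol=1e-14)
    except Exception:  # bvls can reject degenerate systems
        res = lsq_linear(M, rhs, bounds=(problem.lb, problem.ub),
                         method="trf", tol=1e-14)
    return _finish(problem, res.x, f"L-IB/bvls: {res.status} {res.message}")


def solve_constrained(problem: ShimProblem) -> ShimSolution:
    """Fat-constrained shim (FC-IB): same objective plus the residual band
    d1 <= b_fat - C s <= d2 at every fat voxel.

    If the localized optimum already satisfies the band the two solutions
    coincide (the constraints are inactive).  An infeasible constraint set
    is handled per ``problem.infeasible_policy``: 'strict' raises, 'relax'
    widens the band symmetrically by the smallest feasible epsilon (found
    by linear programming) and reports it.
    """
    loc = solve_localized(problem)
    if problem.C is None or problem.C.shape[0] == 0:
        loc.solver_report += " | no fat voxels: constrained solve fell back to L-IB"
        return loc
    if problem.fat_violation(loc.s).max() <= 1e-9:
        loc.solver_report += " | fat constraints inactive at localized optimum"
        return loc

    eps, worst = _min_band_widening(problem)
    d1, d2 = problem.d1, problem.d2
    report_extra = ""
    if eps > FEAS_TOL:
        if problem.infeasible_policy == "strict":
            raise InfeasibleShimError(
                f"fat band infeasible: minimal widening {eps:.3g} Hz; "
                f"most violated voxel rows: {worst}"
            )
        d1, d2 = d1 - eps, d2 + eps
        report_extra = f" | infeasible band relaxed symmetrically by {eps:.6g} Hz"

    s = _solve_qp(problem, d1, d2)
    return _finish(problem, s, "FC-IB/trust-constr+KKT-polish" + report_extra)


def _min_band_widening(problem: ShimProblem) -> tuple[float, list[int]]:
    """LP: smallest symmetric band widening epsilon that admits a feasible s."""
    n = problem.n
    C, bf = problem.C, problem.b_fat
    # variables (s, eps); constraints C s - eps <= bf - d1, -C s - eps <= d2 - bf
    G = np.vstack([np.hstack([C, -np.ones((C.shape[0], 1))]),
                   np.hstack([-C, -np.ones((C.shape[0], 1))])])
    h = np.concatenate([bf - problem.d1, problem.d2 - bf])
    cost = np.zeros(n + 1)
    cost[-1] = 1.0
    bounds = [(lo, hi) for lo, hi in zip(problem.lb, problem.ub)] + [(0, None)]
    res = linprog(cost, A_ub=G, b_ub=h, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"feasibility LP failed: {res.message}")
    eps = float(res.x[-1])
    viol = problem.fat_violation(res.x[:n])
    worst = list(np.argsort(viol)[::-1][:5]) if viol.size else []
    return eps, [int(i) for i in worst]


def _qp_matrices(problem: ShimProblem):
    rms = problem.column_rms()
    H = 2.0 * (problem.A.T @ problem.A + problem.lam * np.diag(rms**2))
    g = -2.0 * problem.A.T @ problem.b
    return H, g


def _solve_qp(problem: ShimProblem, d1: float, d2: float) -> np.ndarray:
    """Convex QP with band + box constraints.

    Outer constraint generation: solve with only the currently violated
    fat constraints in the working set (a tiny QP), then add any newly
    violated rows and repeat — exact for a convex QP once no constraint is
    violated.  Each inner solve uses a trust-region iteration with exact
    gradient/Hessian followed by a KKT polish on the active set.
    """
    H, g = _qp_matrices(problem)
    C, bf = problem.C, problem.b_fat
    G_all = np.vstack([C, -C])
    h_all = np.concatenate([bf - d1, d2 - bf])

    s = np.clip(np.linalg.solve(H, -g), problem.lb, problem.ub)
    working: set[int] = set()
    per_round = 20  # most-violated rows added per outer round
    for _ in range(200):
        viol = G_all @ s - h_all
        new = np.where(viol > 1e-9)[0]
        if new.size == 0:
            break
        new = new[np.argsort(viol[new])[::-1][:per_round]]
        working.update(int(i) for i in new)
        idx = np.array(sorted(working))
        s = _inner_qp(H, g, G_all[idx], h_all[idx], problem.lb, problem.ub, s)
    return s


def _inner_qp(H, g, G, h, lb, ub, x0) -> np.ndarray:
    def fun(s):
        return 0.5 * s @ H @ s + g @ s

    def jac(s):
        return H @ s + g

    res = minimize(
        fun, x0, jac=jac, hess=lambda s: H,
        method="trust-constr",
        bounds=Bounds(lb, ub),
        constraints=[LinearConstraint(G, -np.inf, h)],
        options={"gtol": 1e-9, "xtol": 1e-12, "maxiter": 300},
    )
    s = res.x
    # active-set identification from a point O(1e-4) off needs a loose
    # activity tolerance; try a ladder and keep the best valid polish
    best, best_f = s, fun(s)
    for tol in (1e-8, 1e-6, 1e-4, 1e-2):
        polished = _kkt_polish(H, g, G, h, lb, ub, s, tol=tol)
        if polished is not None and fun(polished) <= best_f + 1e-12:
            best, best_f = polished, fun(polished)
    return best


def _kkt_polish(H, g, G, h, lb, ub, s, tol=1e-6) -> np.ndarray | None:
    """Resolve the equality-constrained QP on the active set of ``s``.

    Returns the polished point when it is primal feasible with non-negative
    multipliers (then it is the exact optimum); None otherwise.
    """
    n = s.size
    act_ineq = np.where(h - G @ s <= tol)[0]
    act_lb = np.where(s - lb <= tol)[0]
    act_ub = np.where(ub - s <= tol)[0]
    rows = [G[act_ineq]]
    rhs = [h[act_ineq]]
    eye = np.eye(n)
    rows += [-eye[act_lb], eye[act_ub]]
    rhs += [-lb[act_lb], ub[act_ub]]
    Ga = np.vstack(rows) if rows else np.zeros((0, n))
    ha = np.concatenate(rhs) if rhs else np.zeros(0)
    m = Ga.shape[0]
    if m == 0:
        cand = np.linalg.solve(H, -g)
    else:
        K = np.block([[H, Ga.T], [Ga, np.zeros((m, m))]])
        try:
            sol = np.linalg.lstsq(K, np.concatenate([-g, ha]), rcond=None)[0]
        except np.linalg.LinAlgError:
            return None
        cand, mult = sol[:n], sol[n:]
        if np.any(mult < -1e-8):
            return None
    ok = (
        np.all(G @ cand <= h + 1e-8)
        and np.all(cand >= lb - 1e-8)
        and np.all(cand <= ub + 1e-8)
    )
    if not ok:
        return None
    # accept only if it does not worsen the objective
    f_new = 0.5 * cand @ H @ cand + g @ cand
    f_old = 0.5 * s @ H @ s + g @ s
    return cand if f_new <= f_old + 1e-12 * max(1.0, abs(f_old)) else None


def qp_oracle(problem: ShimProblem, resolution: float) -> ShimSolution:
    """Exhaustive grid minimizer of the same objective (test oracle).

    Dense grid search over the feasible box, refined multi-scale around the
    incumbent until the grid step reaches ``resolution`` (the zoom is valid
    because objective and feasible set are convex).  Grid points breaking
    the fat band are discarded; if none survives at the final resolution
    the empty feasible set is reported.  Refuses more than 3 free
    coefficients; used only for cross-checking the QP solvers.
    """
    n = problem.n
    if n > 3:
        raise ValueError("qp_oracle handles at most 3 free coefficients")
    if resolution <= 0:
        raise ValueError("resolution must be positive")

    def sweep(lo, hi, res):
        axes = [np.arange(lo[j], hi[j] + res / 2, res) for j in range(n)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        viol = np.zeros(pts.shape[0])
        if problem.C is not None:
            resid = problem.b_fat[None, :] - pts @ problem.C.T
            viol = np.maximum(problem.d1 - resid, 0).sum(axis=1) + np.maximum(
                resid - problem.d2, 0
            ).sum(axis=1)
        r = pts @ problem.A.T - problem.b[None, :]
        st = pts * problem.column_rms()[None, :]
        cost = np.sum(r**2, axis=1) + problem.lam * np.sum(st**2, axis=1)
        feas = viol <= 0
        if feas.any():
            k = int(np.argmin(np.where(feas, cost, np.inf)))
            return pts[k], float(cost[k]), True
        k = int(np.argmin(viol + 1e-12 * cost))  # least-violated fallback
        return pts[k], float(cost[k]), False

    lo, hi = problem.lb.copy(), problem.ub.copy()
    res = max(float(np.max(hi - lo)) / 40.0, resolution)
    while True:
        best, cost, feas_found = sweep(lo, hi, res)
        if res <= resolution:
            break
        res = max(resolution, res / 4.0)
        # window wide enough (10 previous cells) that an incumbent displaced
        # along an oblique active-constraint face is not zoomed out of view
        lo = np.maximum(problem.lb, best - 40 * res)
        hi = np.minimum(problem.ub, best + 40 * res)
    if not feas_found:
        return ShimSolution(
            s=np.full(n, np.nan), objective=np.inf, feasible=False,
            solver_report="oracle: empty feasible set on grid",
            terms=problem.terms,
        )
    return ShimSolution(
        s=best, objective=cost, feasible=True,
        solver_report=f"oracle: final grid step {res}",
        f0_offset_hz=float(np.mean(problem.b - problem.A @ best)),
        terms=problem.terms,
    )
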