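"""Inverse force balance: infer boundary loads from measured spindle shape.

The measured geometry constrains the model through three conditions:

1. reflection symmetry about the spindle midplane, y_b'(L/2) = 0;
2. the kinetochore height, y_k(x_k) = h_k;
3. the k-fibre angle at the kinetochore, |atan y_k'(x_k)| = theta_k.

The unknowns are the pole force F0, the kinetochore tension Fk and the
junction position x_j (the pole moment M0 is fixed, 0 by default, because it
trades off against F0). The three-residual system is solved by damped
multistart least squares. For model-consistent constraint targets (e.g.
targets read off a forward-generated shape) the solver converges to the
exact root; for generic measured targets the system is near rank-deficient
in Fk and an exact root need not exist, in which case the best-fit point is
returned with ``converged=False`` and full residual diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .beam import (
    BeamModelError,
    SpindleShape,
    forward_spindle_shape,
)
from .geometry import BoundaryLoads, FibreArchitecture, SpindleGeometry

_PENALTY = 1.0e3


class SolverError(RuntimeError):
    """Raised when the inverse solve fails structurally (not merely red residuals)."""


@dataclass(frozen=True)
class SolverConfig:
    """Tunables of the inverse solver.

    Tolerances follow the convention: positions in um, slopes in radians
    (slope residuals are small enough near convergence that slope ~ angle).
    The solver first runs damped least squares from the multistart grid
    (junction offsets measured back from x_k); if no start converges it
    escalates to a vectorized coarse scan of the (F0, Fk, x_j) box followed
    by chained local polishing, because the residual landscape develops
    narrow curved valleys for thick bridging fibres.
    """

    tol_position_um: float = 1.0e-3
    tol_slope: float = 1.0e-3
    n_steps: int = 50
    M0_pN_um: float = 0.0
    branch: str = "auto"  # sign of y_k'(x_k): "positive", "negative" or "auto"
    f0_starts: Sequence[float] = (10.0, 50.0, 100.0)
    fk_starts: Sequence[float] = (100.0, 300.0, 500.0)
    xj_offsets_um: Sequence[float] = (0.5, 1.0, 1.5)  # junction distance from x_k
    f0_bounds: Tuple[float, float] = (1.0e-3, 500.0)
    fk_bounds: Tuple[float, float] = (1.0e-3, 2000.0)
    max_nfev: int = 2000
    global_scan: bool = True  # escalate when the multistart grid fails
    scan_shape: Tuple[int, int, int] = (40, 32, 44)
    scan_candidates: int = 25  # polished starts kept per branch from the scan
    descent_rounds: int = 12  # null-direction descent rounds after the scan
    descent_magnitudes: Sequence[float] = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6)


@dataclass(frozen=True)
class ForceBalanceSolution:
    """Result of the inverse solve."""

    loads: BoundaryLoads
    xj_um: float
    shape: SpindleShape
    residuals: np.ndarray  # (symmetry slope, h_k mismatch um, theta_k slope mismatch)
    converged: bool
    branch: int  # sign of y_k'(x_k) imposed by the solved branch
    diagnostics: Dict[str, object] = field(default_factory=dict)

    @property
    def junction_distance_um(self) -> float:
        """Distance between the kinetochore and the junction along x."""
        return self.diagnostics["xk_um"] - self.xj_um  # type: ignore[operator]


def _residuals(
    params: np.ndarray,
    geometry: SpindleGeometry,
    architecture: FibreArchitecture,
    config: SolverConfig,
    branch: int,
) -> np.ndarray:
    F0, Fk, xj = params
    if not (0.0 < xj < min(geometry.xk_um, geometry.half_length_um)):
        return np.full(3, _PENALTY * (1.0 + abs(xj)))
    loads = BoundaryLoads(F0_pN=F0, Fk_pN=Fk, M0_pN_um=config.M0_pN_um)
    try:
        shape = forward_spindle_shape(
            geometry, architecture, loads, xj, n_steps=config.n_steps
        )
    except BeamModelError:
        return np.full(3, _PENALTY)
    target_slope = branch * math.tan(geometry.thetak_rad)
    return np.array(
        [
            shape.midpoint_slope,
            shape.hk_model_um - geometry.hk_um,
            shape.kinetochore_slope - target_slope,
        ]
    )


def _vector_scan(
    geometry: SpindleGeometry,
    architecture: FibreArchitecture,
    config: SolverConfig,
) -> Dict[int, np.ndarray]:
    """Vectorized coarse scan of the (F0, Fk, x_j) box.

    Integrates the three rods simultaneously for every grid point with the
    same fixed-step RK2 scheme and returns, per theta_k branch, candidate
    parameter triples ranked by residual cost.
    """
    nf0, nfk, nxj = config.scan_shape
    xj_hi = min(geometry.xk_um, geometry.half_length_um) - 1.0e-3
    f0g = np.geomspace(max(config.f0_bounds[0], 0.5), config.f0_bounds[1], nf0)
    fkg = np.linspace(max(config.fk_bounds[0], 5.0), min(config.fk_bounds[1], 1000.0), nfk)
    xjg = np.linspace(0.05, xj_hi, nxj)
    F0, FK, XJ = (a.ravel() for a in np.meshgrid(f0g, fkg, xjg, indexing="ij"))
    n = F0.size
    hk = geometry.hk_um
    M0 = config.M0_pN_um
    slope_limit = 11.0  # ~tan(85 deg); scan-only guard

    def run(kappa: float, moment, x0, x1, y0, s0):
        steps = config.n_steps
        h = (x1 - x0) / steps
        y = np.array(y0, dtype=float, copy=True)
        s = np.array(s0, dtype=float, copy=True)
        bad = np.zeros(n, dtype=bool)
        with np.errstate(all="ignore"):
            for _ in range(steps):
                a1 = -moment(y) * (1.0 + s * s) ** 1.5 / kappa
                ym = y + 0.5 * h * s
                sm = s + 0.5 * h * a1
                a2 = -moment(ym) * (1.0 + sm * sm) ** 1.5 / kappa
                y = y + h * sm
                s = s + h * a2
                bad |= (np.abs(s) > slope_limit) | ~np.isfinite(y)
                y = np.where(bad, 0.0, y)
                s = np.where(bad, 0.0, s)
        return y, s, bad

    y0 = np.zeros(n)
    s0 = np.full(n, math.tan(geometry.theta0_rad))
    hj, sj, b1 = run(architecture.kappa_p, lambda y: M0 + F0 * y, 0.0, XJ, y0, s0)
    yk, sk, b2 = run(
        architecture.kappa_k, lambda y: -FK * (y - hk), XJ,
        np.full(n, geometry.xk_um), hj, sj,
    )
    yb, sb, b3 = run(
        architecture.kappa_b, lambda y: (F0 + FK) * y - FK * hk + M0, XJ,
        np.full(n, geometry.half_length_um), hj, sj,
    )
    bad = b1 | b2 | b3
    out: Dict[int, np.ndarray] = {}
    for branch in (1, -1):
        r3 = sk - branch * math.tan(geometry.thetak_rad)
        cost = sb**2 + (yk - hk) ** 2 + r3**2
        cost = np.where(bad, np.inf, cost)
        # best candidate per junction slice (covers every basin along x_j)
        grid_cost = cost.reshape(nf0, nfk, nxj)
        picks = []
        for k in range(nxj):
            sl = grid_cost[:, :, k]
            ij = np.unravel_index(np.argmin(sl), sl.shape)
            if np.isfinite(sl[ij]):
                picks.append((sl[ij], f0g[ij[0]], fkg[ij[1]], xjg[k]))
        # plus the global best few
        order = np.argsort(cost)[:8]
        for idx in order:
            if np.isfinite(cost[idx]):
                picks.append((cost[idx], F0[idx], FK[idx], XJ[idx]))
        picks.sort(key=lambda t: t[0])
        picks = picks[: config.scan_candidates]
        out[branch] = np.array([[p[1], p[2], p[3]] for p in picks])
    return out


#: characteristic parameter magnitudes (F0 pN, Fk pN, x_j um) used to scale
#: steps along the numerical null direction of the residual Jacobian
_DESCENT_SCALE = np.array([10.0, 100.0, 0.5])


def _null_direction(
    x: np.ndarray,
    geometry: SpindleGeometry,
    architecture: FibreArchitecture,
    config: SolverConfig,
    branch: int,
) -> np.ndarray:
    """Unit right-singular vector of the smallest singular value of the
    finite-difference residual Jacobian (the locally least-constrained
    parameter direction)."""
    J = np.zeros((3, 3))
    for j in range(3):
        h = 1e-6 * max(1.0, abs(x[j]))
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] -= h
        J[:, j] = (
            _residuals(xp, geometry, architecture, config, branch)
            - _residuals(xm, geometry, architecture, config, branch)
        ) / (2 * h)
    return np.linalg.svd(J)[2][-1]


def _is_converged(res: np.ndarray, config: SolverConfig) -> bool:
    return bool(
        abs(res[0]) < config.tol_slope
        and abs(res[1]) < config.tol_position_um
        and abs(res[2]) < config.tol_slope
    )


def solve_force_balance(
    geometry: SpindleGeometry,
    architecture: FibreArchitecture,
    config: Optional[SolverConfig] = None,
) -> ForceBalanceSolution:
    """Solve for (F0, Fk, x_j) from the measured spindle geometry.

    Returns the best solution across the multistart grid and, when
    ``config.branch == "auto"``, across both signed branches of the
    kinetochore-angle constraint. ``converged`` reports whether every
    residual is below its tolerance; when False the returned point is the
    least-squares best fit and ``diagnostics['best_cost']`` carries the
    residual norm.
    """
    config = config or SolverConfig()
    branches = {"positive": (1,), "negative": (-1,), "auto": (1, -1)}.get(config.branch)
    if branches is None:
        raise ValueError(f"unknown branch {config.branch!r}")

    xj_hi = min(geometry.xk_um, geometry.half_length_um)
    lb = np.array([config.f0_bounds[0], config.fk_bounds[0], 1.0e-2])
    ub = np.array([config.f0_bounds[1], config.fk_bounds[1], xj_hi - 1.0e-3])

    best: Optional[Tuple[float, np.ndarray, np.ndarray, int]] = None
    converged_roots: List[Tuple[int, np.ndarray]] = []
    n_starts = 0
    total_nfev = 0
    used_global_scan = False

    def try_start(x0: np.ndarray, branch: int, max_nfev: Optional[int] = None) -> None:
        nonlocal best, n_starts, total_nfev
        n_starts += 1
        try:
            fit = optimize.least_squares(
                _residuals,
                np.clip(x0, lb, ub),
                args=(geometry, architecture, config, branch),
                bounds=(lb, ub),
                max_nfev=max_nfev or config.max_nfev,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            return
        total_nfev += fit.nfev
        res = _residuals(fit.x, geometry, architecture, config, branch)
        cost = float(np.sum(res**2))
        if _is_converged(res, config):
            converged_roots.append((branch, fit.x.copy()))
        if best is None or cost < best[0]:
            best = (cost, fit.x.copy(), res, branch)

    quick = min(300, config.max_nfev)
    for branch in branches:
        for f0 in config.f0_starts:
            for fk in config.fk_starts:
                for off in config.xj_offsets_um:
                    xj0 = geometry.xk_um - off
                    if lb[2] < xj0 < ub[2]:
                        try_start(np.array([f0, fk, xj0]), branch, quick)

    if not converged_roots and config.global_scan:
        # narrow curved valleys defeat the plain multistart grid: rank coarse
        # grid points by residual cost, polish the best, then follow the
        # valley by chained re-polishing from perturbed optima
        used_global_scan = True
        candidates = _vector_scan(geometry, architecture, config)
        for branch in branches:
            for x0 in candidates.get(branch, []):
                try_start(np.asarray(x0, dtype=float), branch)
        if not converged_roots and best is not None:
            # deterministic valley descent: the residual surface develops a
            # long, narrow valley along the least-constrained (near-null)
            # direction; step along it from the running best point and
            # re-polish until a root appears or progress stalls
            for _ in range(config.descent_rounds):
                prev_cost, x, _, branch = best
                v = _null_direction(np.asarray(x), geometry, architecture,
                                    config, branch)
                for mag in config.descent_magnitudes:
                    for sgn in (1.0, -1.0):
                        try_start(np.asarray(x) + sgn * mag * v * _DESCENT_SCALE,
                                  branch)
                        if converged_roots or best[0] < 0.5 * prev_cost:
                            break
                    if converged_roots or best[0] < 0.5 * prev_cost:
                        break
                if converged_roots or best[0] >= prev_cost:
                    break

    if best is None:
        raise SolverError("all multistart attempts failed to produce a model shape")

    # prefer converged roots over a lower-cost non-converged point; when the
    # measured kinetochore-to-bridge distance is available, use it to select
    # among materially distinct roots (the constraint set is near rank-
    # deficient, so distinct roots can coexist; d_bk discriminates them)
    if converged_roots:
        scored = []
        for branch, x in converged_roots:
            res = _residuals(x, geometry, architecture, config, branch)
            cost = float(np.sum(res**2))
            key = cost
            if geometry.dbk_um is not None:
                loads_r = BoundaryLoads(x[0], x[1], config.M0_pN_um)
                try:
                    shape_r = forward_spindle_shape(
                        geometry, architecture, loads_r, x[2], config.n_steps
                    )
                    key = abs(shape_r.dbk_model_um(geometry) - geometry.dbk_um)
                except BeamModelError:
                    pass
            scored.append((key, cost, x, res, branch))
        _, cost, x, res, branch = min(scored, key=lambda t: t[0])
        best = (cost, x, res, branch)

    cost, x, res, branch = best
    if cost >= _PENALTY**2:
        raise SolverError(
            "no integrable model shape found from any start "
            f"(best cost {cost:.3g})"
        )
    loads = BoundaryLoads(F0_pN=x[0], Fk_pN=x[1], M0_pN_um=config.M0_pN_um)
    try:
        shape = forward_spindle_shape(
            geometry, architecture, loads, x[2], n_steps=config.n_steps
        )
    except BeamModelError as exc:
        raise SolverError(f"best-fit point has no integrable shape: {exc}") from exc
    converged = _is_converged(res, config)

    # flag materially distinct converged roots (multi-root warning)
    distinct: List[List[float]] = []
    for _, xr in converged_roots:
        if not any(np.allclose(xr, np.array(d), rtol=1e-3, atol=1e-4) for d in distinct):
            distinct.append(list(xr))
    diagnostics: Dict[str, object] = {
        "n_starts": n_starts,
        "n_converged": len(converged_roots),
        "distinct_roots": distinct,
        "multiple_roots": len(distinct) > 1,
        "best_cost": cost,
        "total_nfev": total_nfev,
        "used_global_scan": used_global_scan,
        "xk_um": geometry.xk_um,
        "final_step_um": (x[2]) / config.n_steps,
    }
    return ForceBalanceSolution(
        loads=loads,
        xj_um=float(x[2]),
        shape=shape,
        residuals=res,
        converged=converged,
        branch=branch,
        diagnostics=diagnostics,
    )


def _symmetry_residual_of_F0(
    F0: float,
    geometry: SpindleGeometry,
    architecture: FibreArchitecture,
    Fk: float,
    M0: float,
    xj: float,
    n_steps: int,
) -> float:
    """Midpoint slope of the bridging fibre as a function of F0 (rods p and b
    only; rod k does not enter the symmetry condition)."""
    from .beam import integrate_rod

    loads = BoundaryLoads(F0_pN=F0, Fk_pN=Fk, M0_pN_um=M0)
    try:
        rod_p = integrate_rod(
            "p", 0.0, xj, 0.0, math.tan(geometry.theta0_rad),
            loads, architecture, geometry.hk_um, n_steps,
        )
        _, hj, sj = rod_p.end_state
        rod_b = integrate_rod(
            "b", xj, geometry.half_length_um, hj, sj,
            loads, architecture, geometry.hk_um, n_steps,
        )
    except BeamModelError:
        return math.nan
    return rod_b.end_state[2]


def _bracketed_roots(
    fun, lo: float, hi: float, n_scan: int = 240
) -> List[float]:
    """All sign-change roots of ``fun`` on [lo, hi] found by a uniform scan.

    The scanned functions have NaN pockets (integration blow-up regions), so
    only sign changes between finite neighbours are bisected.
    """
    grid = np.linspace(lo, hi, n_scan)
    vals = np.array([fun(g) for g in grid])
    roots = []
    for i in range(n_scan - 1):
        a, b = vals[i], vals[i + 1]
        if math.isfinite(a) and math.isfinite(b) and a * b < 0:
            try:
                roots.append(optimize.brentq(fun, grid[i], grid[i + 1], xtol=1e-10))
            except ValueError:
                # NaN pocket inside the bracket (integration blow-up region)
                continue
    return roots


def _bridge_mode_count(
    F0: float,
    geometry: SpindleGeometry,
    architecture: FibreArchitecture,
    Fk: float,
    M0: float,
    xj: float,
    n_steps: int,
) -> int:
    """Buckling-mode index of the bridging fibre: number of slope sign
    changes along rod b. The fundamental (stable) equilibrium has mode 0;
    thin compressed bridges admit additional oscillatory equilibria."""
    from .beam import integrate_rod

    loads = BoundaryLoads(F0_pN=F0, Fk_pN=Fk, M0_pN_um=M0)
    rod_p = integrate_rod(
        "p", 0.0, xj, 0.0, math.tan(geometry.theta0_rad),
        loads, architecture, geometry.hk_um, n_steps,
    )
    _, hj, sj = rod_p.end_state
    rod_b = integrate_rod(
        "b", xj, geometry.half_length_um, hj, sj,
        loads, architecture, geometry.hk_um, n_steps,
    )
    s = rod_b.slope
    s = s[np.abs(s) > 1e-12]
    return int(np.sum(np.diff(np.sign(s)) != 0))


def _strut_limit_F0(
    geometry: SpindleGeometry,
    architecture: FibreArchitecture,
    Fk: float,
    M0: float,
    xj: float,
    n_steps: int,
) -> float:
    """n_b = 0 limit: the rigidity-free bridge collapses onto its zero-moment
    line y* = (Fk*h_k - M0)/(F0 + Fk); solve F0 so rod p meets that line at
    the junction. (The kappa_b -> 0 limit is singular: the tangency condition
    is absorbed into a vanishing boundary layer, leaving position continuity.)
    """
    arch0 = FibreArchitecture(
        n_k=architecture.n_k, n_b=0, kappa0_pN_um2=architecture.kappa0_pN_um2,
        coupling=architecture.coupling,
    )

    def f(F0: float) -> float:
        loads = BoundaryLoads(F0_pN=F0, Fk_pN=Fk, M0_pN_um=M0)
        from .beam import integrate_rod

        try:
            rod = integrate_rod(
                "p", 0.0, xj, 0.0, math.tan(geometry.theta0_rad),
                loads, arch0, geometry.hk_um, n_steps,
            )
        except BeamModelError:
            return math.nan
        ystar = (Fk * geometry.hk_um - M0) / (F0 + Fk)
        return rod.end_state[1] - ystar

    roots = _bracketed_roots(f, 0.5, 500.0)
    if not roots:
        raise SolverError("no strut-limit root for n_b = 0")
    return roots[0]


def sweep_pole_force(
    n_b_values: Sequence[int],
    geometry: SpindleGeometry,
    n_k: int,
    kappa0_pN_um2: float,
    Fk_pN: float,
    xj_um: float,
    M0_pN_um: float = 0.0,
    n_steps: int = 50,
    f0_max: float = 500.0,
):
    """Pole force F0 as a function of bridging-fibre thickness n_b.

    For each n_b the single-unknown problem is solved: find F0 such that the
    midpoint symmetry condition y_b'(L/2) = 0 holds, with Fk, x_j and M0
    fixed. theta_k and h_k are outputs here, not constraints. Roots are
    tracked by continuation (the root nearest the previous n_b's solution)
    because the symmetry condition develops multiple roots for thin bridges.
    Returns a pandas DataFrame with columns n_b, F0_pN, hk_model_um,
    thetak_model_deg.
    """
    import pandas as pd

    # the symmetry condition admits several equilibria per n_b (higher
    # buckling modes of the compressed bridge); the physical branch is
    # tracked by continuation outward from an anchor thickness where the
    # fundamental mode is unique, preferring the mid-range
    idx_sorted = sorted(range(len(n_b_values)), key=lambda i: n_b_values[i])
    anchor_pos = len(idx_sorted) // 2
    for pos in sorted(
        range(len(idx_sorted)), key=lambda p: (abs(p - anchor_pos), p)
    ):
        nb_try = n_b_values[idx_sorted[pos]]
        if nb_try == 0:
            continue
        arch_try = FibreArchitecture(
            n_k=n_k, n_b=int(nb_try), kappa0_pN_um2=kappa0_pN_um2
        )
        roots_try = _bracketed_roots(
            lambda F0: _symmetry_residual_of_F0(
                F0, geometry, arch_try, Fk_pN, M0_pN_um, xj_um, n_steps
            ),
            0.5,
            f0_max,
            n_scan=1200,
        )
        modes_try = []
        for r in roots_try:
            try:
                modes_try.append(
                    _bridge_mode_count(r, geometry, arch_try, Fk_pN,
                                       M0_pN_um, xj_um, n_steps)
                )
            except BeamModelError:
                modes_try.append(10**6)
        if roots_try and sum(m == min(modes_try) for m in modes_try) == 1:
            anchor_pos = pos
            break
    order = idx_sorted[anchor_pos:] + idx_sorted[:anchor_pos][::-1]
    anchor_f0: Optional[float] = None
    rows_by_index: Dict[int, Dict[str, float]] = {}
    rows = []
    prev: Optional[float] = None
    for seq, idx in enumerate(order):
        nb = n_b_values[idx]
        if seq == len(idx_sorted) - anchor_pos:
            prev = anchor_f0  # restart downward continuation from the anchor
        if nb < 0:
            raise ValueError("n_b must be >= 0")
        if nb == 0:
            arch = FibreArchitecture(n_k=n_k, n_b=0, kappa0_pN_um2=kappa0_pN_um2)
            f0 = _strut_limit_F0(geometry, arch, Fk_pN, M0_pN_um, xj_um, n_steps)
            rows_by_index[idx] = {
                "n_b": nb, "F0_pN": f0, "hk_model_um": math.nan,
                "thetak_model_deg": math.nan,
            }
            continue
        arch = FibreArchitecture(n_k=n_k, n_b=int(nb), kappa0_pN_um2=kappa0_pN_um2)

        def f(F0: float) -> float:
            return _symmetry_residual_of_F0(
                F0, geometry, arch, Fk_pN, M0_pN_um, xj_um, n_steps
            )

        roots = _bracketed_roots(f, 0.5, f0_max, n_scan=1200)
        if not roots:
            raise SolverError(f"no symmetry root found for n_b={nb}")
        # keep the lowest buckling mode present (the stable equilibrium),
        # then track the branch by continuation from the previous n_b
        modes = []
        for r in roots:
            try:
                modes.append(
                    _bridge_mode_count(r, geometry, arch, Fk_pN, M0_pN_um,
                                       xj_um, n_steps)
                )
            except BeamModelError:
                modes.append(10**6)
        m_min = min(modes)
        fundamental = [r for r, m in zip(roots, modes) if m == m_min]
        if prev is None:
            f0 = min(fundamental)
        else:
            f0 = min(fundamental, key=lambda r: abs(r - prev))
        prev = f0
        if anchor_f0 is None:
            anchor_f0 = f0
        loads = BoundaryLoads(F0_pN=f0, Fk_pN=Fk_pN, M0_pN_um=M0_pN_um)
        try:
            shape = forward_spindle_shape(geometry, arch, loads, xj_um, n_steps)
            hk_model, thetak_model = shape.hk_model_um, shape.thetak_model_deg
        except BeamModelError:  # rod k may be unintegrable off the solution
            hk_model = thetak_model = math.nan
        rows_by_index[idx] = {
            "n_b": nb,
            "F0_pN": f0,
            "hk_model_um": hk_model,
            "thetak_model_deg": thetak_model,
        }
    rows = [rows_by_index[i] for i in range(len(n_b_values))]
    return pd.DataFrame(rows)


def forward_consistent_case(
    geometry: SpindleGeometry,
    architecture: FibreArchitecture,
    Fk_pN: float,
    xj_um: float,
    M0_pN_um: float = 0.0,
    n_steps: int = 50,
    max_iter: int = 60,
    tol: float = 1e-11,
) -> Tuple[SpindleGeometry, "BoundaryLoads", SpindleShape]:
    """Construct a self-consistent forward case with known loads and junction.

    Given (Fk, x_j), finds F0 from the midpoint symmetry condition and
    iterates the kinetochore height to its fixed point (h_k enters the
    bending moments as the height of the tension's line of action, so a
    consistent case requires the rod-k endpoint to land exactly on h_k).
    Returns the geometry whose (h_k, theta_k) constraint targets are exactly
    satisfied by the returned loads and shape — the ground truth for
    round-trip tests of the inverse solver.
    """
    from .geometry import SpindleGeometry as _SG

    f0_track: List[Optional[float]] = [None]

    def case_at(hk: float):
        geo = _SG(
            theta0_deg=geometry.theta0_deg,
            thetak_deg=geometry.thetak_deg,
            L_um=geometry.L_um,
            hk_um=hk,
            xk_um=geometry.xk_um,
            dk_um=geometry.dk_um,
            dbk_um=geometry.dbk_um,
        )
        roots = _bracketed_roots(
            lambda F0: _symmetry_residual_of_F0(
                F0, geo, architecture, Fk_pN, M0_pN_um, xj_um, n_steps
            ),
            0.5,
            500.0,
        )
        if not roots:
            return None
        F0 = (
            min(roots)
            if f0_track[0] is None
            else min(roots, key=lambda r: abs(r - f0_track[0]))
        )
        f0_track[0] = F0
        loads = BoundaryLoads(F0_pN=F0, Fk_pN=Fk_pN, M0_pN_um=M0_pN_um)
        try:
            shape = forward_spindle_shape(geo, architecture, loads, xj_um, n_steps)
        except BeamModelError:
            return None
        return geo, loads, shape

    def gap(hk: float) -> float:
        out = case_at(hk)
        return math.nan if out is None else out[2].hk_model_um - hk

    # the kinetochore tension's line of action passes through the rod-k
    # endpoint only when the endpoint height equals the h_k used in the
    # moments: bracket that fixed point in h_k and bisect
    lo, hi = 0.25 * geometry.hk_um, 1.6 * geometry.hk_um
    grid = np.linspace(lo, hi, max_iter)
    vals = [gap(h) for h in grid]
    hk_star: Optional[float] = None
    for i in range(len(grid) - 1):
        a_, b_ = vals[i], vals[i + 1]
        if math.isfinite(a_) and math.isfinite(b_) and a_ * b_ < 0:
            hk_star = optimize.brentq(gap, grid[i], grid[i + 1], xtol=tol)
            break
    if hk_star is None:
        raise SolverError(
            f"no self-consistent kinetochore height for Fk={Fk_pN}, xj={xj_um}"
        )
    geo, loads, shape = case_at(hk_star)
    out_geo = _SG(
        theta0_deg=geometry.theta0_deg,
        thetak_deg=shape.thetak_model_deg,
        L_um=geometry.L_um,
        hk_um=shape.hk_model_um,
        xk_um=geometry.xk_um,
        dk_um=geometry.dk_um,
        dbk_um=shape.dbk_model_um(geo),
    )
    return out_geo, loads, shape


def predict_cut_outcome(stub_length_um: float, junction_distance_um: float) -> str:
    """Outcome of severing a k-fibre at a given stub length.

    The interkinetochore tension is retained only when the remaining stub is
    strictly longer than the kinetochore-to-junction distance, so that the
    stub still reaches the bridging fibre; otherwise the connection to the
    bridge is lost and the tension relaxes. Ties count as lost (connection
    requires overlap strictly beyond the junction).
    """
    if stub_length_um < 0 or junction_distance_um < 0:
        raise ValueError("lengths must be non-negative")
    return (
        "tension_retained"
        if stub_length_um > junction_distance_um
        else "tension_lost"
    )
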