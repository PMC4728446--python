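"""Forward Euler–Bernoulli mechanics of the three-rod half-spindle.

The half-spindle is modelled as three slender elastic rods:

* rod ``p`` from the pole (0, 0) to the junction (x_j, h_j),
* rod ``k`` from the junction to the kinetochore (x_k, h_k),
* rod ``b`` from the junction to the system midpoint (L/2, h).

Bending moments (about a point at height y) generated by the horizontal
boundary forces are

    M_p(y) = M0 + F0 * y
    M_k(y) = -Fk * (y - h_k)
    M_b(y) = (F0 + Fk) * y - Fk * h_k + M0

which satisfy the junction balance M_p = M_k + M_b identically. With the
internal-moment sign convention fixed by the statics (inward pole force
+F0 x̂ through the pole, kinetochore tension +Fk x̂ through (x_k, h_k),
counter-clockwise positive), each rod's shape y(x) obeys

    kappa_i * y'' = -M_i(y) * (1 + y'^2)^(3/2)

The reference integrator is the fixed-step explicit midpoint (RK2) method
with 50 steps per rod, matching the numerical scheme of the original
analysis; tests compare it against an adaptive high-order solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .geometry import BoundaryLoads, FibreArchitecture, SpindleGeometry

ROD_IDS = ("p", "k", "b")

#: slopes beyond this magnitude (|angle| > 86 deg) abort the integration:
#: the graph parameterization y(x) breaks down for near-vertical rods
SLOPE_LIMIT = math.tan(math.radians(86.0))

DEFAULT_N_STEPS = 50


class BeamModelError(RuntimeError):
    """Base class for beam-model failures."""


class DegenerateRodError(BeamModelError):
    """A zero-rigidity rod was asked to carry a bending moment."""


class ParameterizationBreakdownError(BeamModelError):
    """The rod turned near-vertical and y(x) is no longer a graph."""


def bending_moment(
    rod_id: str, y_um: float, loads: BoundaryLoads, hk_um: float
) -> float:
    """Bending moment (pN·um) of rod ``rod_id`` at height ``y_um``."""
    F0, Fk, M0 = loads.F0_pN, loads.Fk_pN, loads.M0_pN_um
    if rod_id == "p":
        return M0 + F0 * y_um
    if rod_id == "k":
        return -Fk * (y_um - hk_um)
    if rod_id == "b":
        return (F0 + Fk) * y_um - Fk * hk_um + M0
    raise ValueError(f"unknown rod_id {rod_id!r}; expected one of {ROD_IDS}")


@dataclass(frozen=True)
class RodContour:
    """Sampled contour of one rod: y(x) and slope y'(x) on a uniform x grid."""

    rod_id: str
    x_um: np.ndarray
    y_um: np.ndarray
    slope: np.ndarray

    @property
    def end_state(self) -> Tuple[float, float, float]:
        return float(self.x_um[-1]), float(self.y_um[-1]), float(self.slope[-1])

    def arc_length(self) -> float:
        dx = np.diff(self.x_um)
        dy = np.diff(self.y_um)
        return float(np.sum(np.hypot(dx, dy)))


def integrate_rod(
    rod_id: str,
    x_start: float,
    x_end: float,
    y_start: float,
    slope_start: float,
    loads: BoundaryLoads,
    architecture: FibreArchitecture,
    hk_um: float,
    n_steps: int = DEFAULT_N_STEPS,
) -> RodContour:
    """Integrate one rod's Euler–Bernoulli equation with fixed-step RK2.

    The rod is integrated from ``x_start`` to ``x_end`` (either direction)
    starting at height ``y_start`` with slope ``slope_start``. Raises
    :class:`DegenerateRodError` for a zero-rigidity rod under load and
    :class:`ParameterizationBreakdownError` when the slope bound is exceeded.
    """
    if rod_id not in ROD_IDS:
        raise ValueError(f"unknown rod_id {rod_id!r}; expected one of {ROD_IDS}")
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2; got {n_steps}")
    if x_end == x_start:
        raise ValueError("x_end must differ from x_start")

    kappa = {"p": architecture.kappa_p, "k": architecture.kappa_k,
             "b": architecture.kappa_b}[rod_id]
    if kappa <= 0.0:
        # a massless string cannot carry a bending moment
        if abs(bending_moment(rod_id, y_start, loads, hk_um)) > 0.0:
            raise DegenerateRodError(
                f"rod {rod_id!r} has zero rigidity but a nonzero moment"
            )
        kappa = math.inf  # moment identically zero: straight line

    h = (x_end - x_start) / n_steps
    xs = x_start + h * np.arange(n_steps + 1)
    ys = np.empty(n_steps + 1)
    ss = np.empty(n_steps + 1)
    y, s = float(y_start), float(slope_start)
    ys[0], ss[0] = y, s

    def accel(yy: float, sl: float) -> float:
        m = bending_moment(rod_id, yy, loads, hk_um)
        return -m * (1.0 + sl * sl) ** 1.5 / kappa

    for i in range(n_steps):
        if abs(s) > SLOPE_LIMIT or not math.isfinite(y):
            raise ParameterizationBreakdownError(
                f"rod {rod_id!r} became near-vertical at x={xs[i]:.3f}"
            )
        a1 = accel(y, s)
        y_mid = y + 0.5 * h * s
        s_mid = s + 0.5 * h * a1
        a2 = accel(y_mid, s_mid)
        y = y + h * s_mid
        s = s + h * a2
        ys[i + 1], ss[i + 1] = y, s

    if abs(s) > SLOPE_LIMIT or not math.isfinite(y):
        raise ParameterizationBreakdownError(
            f"rod {rod_id!r} became near-vertical at x={xs[-1]:.3f}"
        )
    return RodContour(rod_id=rod_id, x_um=xs, y_um=ys, slope=ss)


@dataclass(frozen=True)
class SpindleShape:
    """Solved half-spindle shape: contours of rods p, k, b plus summaries."""

    rods: Dict[str, RodContour]
    xj_um: float
    hj_um: float
    junction_slope: float
    h_um: float  # bridging-fibre height at the midpoint L/2
    hk_model_um: float  # rod-k endpoint height at x_k
    thetak_model_deg: float  # |angle| of rod k at the kinetochore
    kinetochore_slope: float  # signed slope of rod k at x_k
    midpoint_slope: float  # bridging-fibre slope at L/2
    n_steps: int

    def dbk_model_um(self, geometry: SpindleGeometry) -> float:
        """Model kinetochore-to-bridge distance at x = x_k (positive when the
        kinetochore lies above the bridging fibre)."""
        b = self.rods["b"]
        yb = float(np.interp(geometry.xk_um, b.x_um, b.y_um))
        return geometry.hk_um - yb


def forward_spindle_shape(
    geometry: SpindleGeometry,
    architecture: FibreArchitecture,
    loads: BoundaryLoads,
    xj_um: float,
    n_steps: int = DEFAULT_N_STEPS,
) -> SpindleShape:
    """Forward model: integrate the three rods for given loads and junction.

    Rod p starts at the pole (0, 0) with slope tan(theta0); rods k and b
    continue from the junction with continuous position and slope (the rods
    are clamped and tangential to each other there).
    """
    if not (0.0 < xj_um < min(geometry.xk_um, geometry.half_length_um)):
        raise ValueError(
            f"xj_um must lie in (0, min(x_k, L/2)); got {xj_um}"
        )
    hk = geometry.hk_um
    rod_p = integrate_rod(
        "p", 0.0, xj_um, 0.0, math.tan(geometry.theta0_rad),
        loads, architecture, hk, n_steps,
    )
    _, hj, sj = rod_p.end_state
    rod_k = integrate_rod(
        "k", xj_um, geometry.xk_um, hj, sj, loads, architecture, hk, n_steps
    )
    rod_b = integrate_rod(
        "b", xj_um, geometry.half_length_um, hj, sj, loads, architecture, hk, n_steps
    )
    _, yk_end, sk_end = rod_k.end_state
    _, h_mid, s_mid = rod_b.end_state
    return SpindleShape(
        rods={"p": rod_p, "k": rod_k, "b": rod_b},
        xj_um=xj_um,
        hj_um=hj,
        junction_slope=sj,
        h_um=h_mid,
        hk_model_um=yk_end,
        thetak_model_deg=math.degrees(abs(math.atan(sk_end))),
        kinetochore_slope=sk_end,
        midpoint_slope=s_mid,
        n_steps=n_steps,
    )


def mirror_full_spindle(shape: SpindleShape, L_um: float) -> Dict[str, np.ndarray]:
    """Reflect a half-spindle shape about x = L/2 into a full contour.

    Returns per-rod arrays for the full spindle: rods ``p``, ``k``, ``b`` of
    the left half plus their mirror images ``p'``, ``k'``, and the bridging
    fibre joined across the midplane into a single contour ``b``.
    """
    out: Dict[str, np.ndarray] = {}
    for rid in ("p", "k"):
        rod = shape.rods[rid]
        out[rid] = np.column_stack([rod.x_um, rod.y_um])
        out[rid + "'"] = np.column_stack([L_um - rod.x_um[::-1], rod.y_um[::-1]])
    b = shape.rods["b"]
    xb = np.concatenate([b.x_um, (L_um - b.x_um[::-1])[1:]])
    yb = np.concatenate([b.y_um, b.y_um[::-1][1:]])
    out["b"] = np.column_stack([xb, yb])
    return out
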