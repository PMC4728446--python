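"""Domain types for the three-rod spindle model.

Geometry follows the convention used throughout the package: the spindle
long axis is the x axis, the left pole sits at the origin, heights y are
positive above the axis, and one half-spindle spans 0 <= x <= L/2. Angles
are degrees at the API surface and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


class InvalidGeometryError(ValueError):
    """Raised when a geometry violates its physical invariants."""


@dataclass(frozen=True)
class SpindleGeometry:
    """Measured shape parameters of one half-spindle.

    Parameters
    ----------
    theta0_deg
        Angle between the k-fibre and the spindle long axis near the pole.
    thetak_deg
        Angle between the k-fibre and the long axis near the kinetochore
        (unsigned magnitude, as measured).
    L_um
        Pole-to-pole spindle length.
    hk_um
        Spindle half-width: height of the outermost kinetochore pair above
        the long axis.
    xk_um
        Horizontal kinetochore position measured from the pole.
    dk_um
        Interkinetochore distance (optional; informational).
    dbk_um
        Kinetochore-to-bridging-fibre distance (optional). Positive when the
        kinetochore lies on the outer side of the bridging fibre.
    """

    theta0_deg: float
    thetak_deg: float
    L_um: float
    hk_um: float
    xk_um: float
    dk_um: Optional[float] = None
    dbk_um: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.theta0_deg < 90.0):
            raise InvalidGeometryError(
                f"theta0_deg must lie in (0, 90); got {self.theta0_deg}"
            )
        if not (0.0 <= self.thetak_deg < 90.0):
            raise InvalidGeometryError(
                f"thetak_deg must lie in [0, 90); got {self.thetak_deg}"
            )
        if self.L_um <= 0:
            raise InvalidGeometryError(f"L_um must be positive; got {self.L_um}")
        if self.hk_um <= 0:
            raise InvalidGeometryError(f"hk_um must be positive; got {self.hk_um}")
        if not (0.0 < self.xk_um <= self.L_um / 2):
            raise InvalidGeometryError(
                f"xk_um must lie in (0, L/2]; got {self.xk_um} with L={self.L_um}"
            )
        if self.dk_um is not None and self.dk_um <= 0:
            raise InvalidGeometryError(f"dk_um must be positive; got {self.dk_um}")

    @property
    def theta0_rad(self) -> float:
        return math.radians(self.theta0_deg)

    @property
    def thetak_rad(self) -> float:
        return math.radians(self.thetak_deg)

    @property
    def half_length_um(self) -> float:
        return self.L_um / 2


@dataclass(frozen=True)
class FibreArchitecture:
    """Microtubule counts and flexural rigidities of the three rods.

    Rigidity is additive over the microtubules of a bundle (MTs are free to
    slide as the bundle bends): kappa_i = n_i * kappa0. The pole-side rod p
    carries the merged bundle, n_p = n_k + n_b. A quadratic scaling
    (fully crosslinked bundle, kappa_i = n_i**2 * kappa0) is available via
    ``coupling="quadratic"`` but is not the default.
    """

    n_k: int
    n_b: int
    kappa0_pN_um2: float = 30.0
    coupling: str = "sliding"

    def __post_init__(self) -> None:
        if self.n_k <= 0:
            raise InvalidGeometryError(f"n_k must be positive; got {self.n_k}")
        if self.n_b < 0:
            raise InvalidGeometryError(f"n_b must be >= 0; got {self.n_b}")
        if self.kappa0_pN_um2 <= 0:
            raise InvalidGeometryError(
                f"kappa0_pN_um2 must be positive; got {self.kappa0_pN_um2}"
            )
        if self.coupling not in ("sliding", "quadratic"):
            raise InvalidGeometryError(
                f"coupling must be 'sliding' or 'quadratic'; got {self.coupling!r}"
            )

    def _kappa(self, n: float) -> float:
        if self.coupling == "quadratic":
            return float(n) ** 2 * self.kappa0_pN_um2
        return float(n) * self.kappa0_pN_um2

    @property
    def n_p(self) -> int:
        return self.n_k + self.n_b

    @property
    def kappa_k(self) -> float:
        return self._kappa(self.n_k)

    @property
    def kappa_b(self) -> float:
        return self._kappa(self.n_b)

    @property
    def kappa_p(self) -> float:
        if self.coupling == "sliding":
            # additive by construction: kappa_p = kappa_k + kappa_b
            return self._kappa(self.n_p)
        return self._kappa(self.n_p)


@dataclass(frozen=True)
class BoundaryLoads:
    """Boundary loads of the half-spindle.

    F0_pN is the inward horizontal force at the spindle pole, Fk_pN the
    horizontal interkinetochore tension applied at the kinetochore, and
    M0_pN_um the clamping bending moment at the pole.
    """

    F0_pN: float
    Fk_pN: float
    M0_pN_um: float = 0.0

    def replace(self, **kw) -> "BoundaryLoads":
        d = dict(F0_pN=self.F0_pN, Fk_pN=self.Fk_pN, M0_pN_um=self.M0_pN_um)
        d.update(kw)
        return BoundaryLoads(**d)


#: Fixed geometry used for the reference HeLa computation: the published
#: model-figure parameter set (theta0 = 64 deg, L = 11.1 um, x_k = 5.05 um)
#: with the measured HeLa constraint targets h_k = 5.0 um, theta_k = 13.7 deg.
HELA_REFERENCE_GEOMETRY = SpindleGeometry(
    theta0_deg=64.0,
    thetak_deg=13.7,
    L_um=11.1,
    hk_um=5.0,
    xk_um=5.05,
    dk_um=1.05,
    dbk_um=0.24,
)

#: Reference HeLa architecture: 17-MT k-fibres, 14-MT bridging fibre,
#: single-MT rigidity 30 pN um^2.
HELA_REFERENCE_ARCHITECTURE = FibreArchitecture(n_k=17, n_b=14, kappa0_pN_um2=30.0)
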