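"""Kinematics of forced penetration into a locally quadrilateral lattice.

A rigid sphere (or ellipsoid entering through its short axis) pressed into a
square cell of chains stretches the four chains in contact with it. The
normalized sink y/rho and the chain stretch lam are linked by

    y/rho = 1 - sqrt(1 - lam**2 * eta**2),

where eta = R / (rho * sqrt(2*(xi**2 + 1))) compares the inter-chain distance
R with the pertinent particle dimension (eta = R/(2*rho) for a sphere).
Full penetration — the particle equator reaching the network plane —
occurs at lam = 1/eta.

The rotating neighbor chains form trapezoids with base angle
alpha = arccos((lam - 1)/2): alpha = 90 deg in the reference state and 0 at
lam = 3, where the trapezoid collapses and further sink requires the
neighbors themselves to stretch (network stiffening). An ellipsoid of aspect
ratio xi distorts the square cell into a rhombus with vertex angle
gamma = 2*arctan(1/xi).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .chains import DomainError

__all__ = [
    "COLLAPSE_STRETCH",
    "LatticeState",
    "ParticleShape",
    "Regime",
    "classify_regime",
    "eta",
    "penetration_stretch",
    "rhombus_vertex_angle",
    "sink_from_stretch",
    "stretch_from_sink",
    "trapezoid_angle",
]

#: chain stretch at which the neighbor trapezoid collapses (alpha = 0)
COLLAPSE_STRETCH = 3.0


class Regime(str, enum.Enum):
    """Phase of the quasi-static penetration process."""

    SPONTANEOUS = "spontaneous"
    PRE_COLLAPSE = "pre_collapse"
    POST_COLLAPSE = "post_collapse"
    FULLY_PENETRATED = "fully_penetrated"


@dataclass(frozen=True)
class ParticleShape:
    """Rigid sphere or prolate ellipsoid with semi-axes (rho, rho, xi*rho).

    The ellipsoid penetrates through its short axis, long axis along the
    cell diagonal; xi = 1 recovers the sphere.
    """

    rho: float
    xi: float = 1.0

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise DomainError(f"rho must be positive, got {self.rho}")
        if not self.xi >= 1:
            raise DomainError(f"aspect ratio xi must be >= 1, got {self.xi}")

    @property
    def kind(self) -> str:
        return "sphere" if self.xi == 1.0 else "ellipsoid"

    @property
    def long_axis(self) -> float:
        """Full length of the longest axis, 2*xi*rho."""
        return 2.0 * self.xi * self.rho


@dataclass(frozen=True)
class LatticeState:
    """One quasi-static state of the particle-lattice system."""

    eta: float
    lam: float
    y_over_rho: float
    alpha_deg: float
    gamma_deg: float
    regime: Regime


def eta(shape: ParticleShape, R: float) -> float:
    """Inter-chain distance over particle dimension: R/(rho*sqrt(2*(xi^2+1)))."""
    if R <= 0:
        raise DomainError(f"R must be positive, got {R}")
    return R / (shape.rho * math.sqrt(2.0 * (shape.xi**2 + 1.0)))


def sink_from_stretch(lam: float, eta_value: float) -> float:
    """Normalized sink y/rho at chain stretch lam.

    y/rho = 1 - sqrt(1 - lam**2 * eta**2). Saturates at 1 (full penetration)
    for lam*eta >= 1 rather than erroring: the particle is already through.
    """
    if lam < 1:
        raise DomainError(f"stretch must be >= 1, got {lam}")
    if eta_value <= 0:
        raise DomainError(f"eta must be positive, got {eta_value}")
    x = lam * eta_value
    if x >= 1.0:
        return 1.0
    return 1.0 - math.sqrt(1.0 - x * x)


def stretch_from_sink(y_over_rho: float, eta_value: float) -> float:
    """Chain stretch at normalized sink y/rho (exact inverse of Eq. above).

    lam = sqrt(1 - (1 - y/rho)**2) / eta. Defined for sinks at or beyond the
    initial (lam = 1) sink; shallower sinks would require compression, which
    is not modelled.
    """
    if not 0.0 <= y_over_rho <= 1.0:
        raise DomainError(f"y/rho must lie in [0, 1], got {y_over_rho}")
    if eta_value <= 0:
        raise DomainError(f"eta must be positive, got {eta_value}")
    lam = math.sqrt(1.0 - (1.0 - y_over_rho) ** 2) / eta_value
    if lam < 1.0 - 1e-12:
        y0 = sink_from_stretch(1.0, eta_value)
        raise DomainError(
            f"sink {y_over_rho:.6g} is below the initial sink {y0:.6g} "
            "(compressive states are not modelled)"
        )
    return max(lam, 1.0)


def trapezoid_angle(lam: float, degrees: bool = True) -> float:
    """Base angle alpha of the neighbor trapezoids at stretch lam.

    alpha = arccos((lam - 1)/2); 90 deg in the reference state (lam = 1),
    0 at collapse (lam = 3). Stretches beyond collapse clamp to 0 — those
    are valid, stiffened states.
    """
    if lam < 1:
        raise DomainError(f"stretch must be >= 1, got {lam}")
    if lam >= COLLAPSE_STRETCH:
        alpha = 0.0
    else:
        alpha = math.acos((lam - 1.0) / 2.0)
    return math.degrees(alpha) if degrees else alpha


def rhombus_vertex_angle(xi: float, degrees: bool = True) -> float:
    """Vertex angle gamma = 2*arctan(1/xi) of the distorted (rhombus) cell.

    90 deg for a sphere (xi = 1), decreasing toward 0 as the ellipsoid
    elongates.
    """
    if xi < 1:
        raise DomainError(f"aspect ratio xi must be >= 1, got {xi}")
    gamma = 2.0 * math.atan(1.0 / xi)
    return math.degrees(gamma) if degrees else gamma


def penetration_stretch(eta_value: float) -> float:
    """Stretch at which penetration completes: lam_pen = 1/eta."""
    if eta_value <= 0:
        raise DomainError(f"eta must be positive, got {eta_value}")
    return 1.0 / eta_value


def classify_regime(lam: float, eta_value: float) -> Regime:
    """Phase of the penetration process at stretch lam.

    - ``spontaneous``: eta >= 1, the particle fits the mesh at lam = 1;
    - ``fully_penetrated``: lam >= 1/eta, the equator has passed the plane;
    - ``post_collapse``: lam > 3, neighbors stretch (stiffened network);
    - ``pre_collapse`` otherwise.

    Stiffened states occur before penetration iff 1/eta > 3, i.e. eta < 1/3.
    """
    if lam < 1:
        raise DomainError(f"stretch must be >= 1, got {lam}")
    if eta_value <= 0:
        raise DomainError(f"eta must be positive, got {eta_value}")
    if eta_value >= 1.0:
        return Regime.SPONTANEOUS
    if lam >= penetration_stretch(eta_value):
        return Regime.FULLY_PENETRATED
    if lam > COLLAPSE_STRETCH:
        return Regime.POST_COLLAPSE
    return Regime.PRE_COLLAPSE
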