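"""Forces and damage during quasi-static forced penetration.

As the particle sinks, four chains in direct contact stretch by lam while
12 neighbor chains (three per side) first rotate at constant length and,
once the trapezoid collapses at lam = 3, stretch in series with the contact
chains at lam/3. The module computes:

- the average dimensionless chain force over the 16 local chains,
- the resultant force on the two distinct cross-link sites of the (possibly
  rhombic) cell, from the in-plane vector sum of the four chain tensions
  meeting at each site,
- damage classification against critical chain-rupture and cross-link
  dissociation forces, and
- `simulate_penetration`, the quasi-static sweep driver producing a
  force-sink trajectory and an outcome.

All forces are dimensionless, f*l/(kB*T).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .chains import ChainSpec, DomainError, FiniteExtensibilityError, inverse_langevin
from .lattice import (
    COLLAPSE_STRETCH,
    ParticleShape,
    Regime,
    classify_regime,
    eta as eta_of,
    penetration_stretch,
    rhombus_vertex_angle,
    sink_from_stretch,
    trapezoid_angle,
)

__all__ = [
    "DamageEvent",
    "DamageThresholds",
    "Outcome",
    "PenetrationRecord",
    "Trajectory",
    "average_chain_force",
    "check_damage",
    "contributing_chain_stretches",
    "crosslink_resultant",
    "simulate_penetration",
]

logger = logging.getLogger(__name__)

#: chains contacted directly by the particle / rotating-then-stretching neighbors
N_CONTACT = 4
N_NEIGHBOR = 12

_LAMBDA_MAX_GUARD = 1e-6


class DamageEvent(str, enum.Enum):
    CHAIN_RUPTURE = "chain_rupture"
    CROSSLINK_DISSOCIATION = "crosslink_dissociation"


class Outcome(str, enum.Enum):
    """How the penetration attempt ends."""

    SPONTANEOUS = "spontaneous"
    ELASTIC_PENETRATION = "elastic_penetration"
    CHAIN_RUPTURE = "chain_rupture"
    CROSSLINK_DISSOCIATION = "crosslink_dissociation"
    JAMMED = "jammed"


@dataclass(frozen=True)
class DamageThresholds:
    """Critical forces for the two damage modes (dimensionless f*l/(kB*T)).

    Parameters
    ----------
    f_rup : float
        Chain-rupture force; a contact chain breaks when its tension
        exceeds this. ``inf`` disables rupture.
    f_dis : float
        Cross-link dissociation force, compared against the resultant on
        the critical site (cross-link 1). ``inf`` disables dissociation.
    k : int
        Chains per cross-link (>= 2); 4 for the quadrilateral lattice.
    prefer_on_tie : DamageEvent
        Mode reported when both thresholds are exceeded by the same relative
        amount. Defaults to cross-link dissociation, the more probable mode
        in physically cross-linked gels such as mucin.
    """

    f_rup: float = math.inf
    f_dis: float = math.inf
    k: int = 4
    prefer_on_tie: DamageEvent = DamageEvent.CROSSLINK_DISSOCIATION

    def __post_init__(self) -> None:
        if not self.f_rup > 0:
            raise DomainError(f"f_rup must be positive, got {self.f_rup}")
        if not self.f_dis > 0:
            raise DomainError(f"f_dis must be positive, got {self.f_dis}")
        if self.k < 2:
            raise DomainError(f"k must be >= 2, got {self.k}")


def contributing_chain_stretches(lam: float) -> list[tuple[float, int]]:
    """Stretch and multiplicity of each chain class at contact-chain stretch lam.

    Pre-collapse (lam <= 3) the 12 neighbors rotate without stretching and
    sit at their reference length. Post-collapse they stretch at lam/3:
    the collapsed trapezoid puts the far side and both legs (each of
    referential length R) in series with the near side of length lam*R, so
    equal neighbor stretch gives lam_nb = lam/3 — continuous at lam = 3.
    """
    if lam < 1:
        raise DomainError(f"stretch must be >= 1, got {lam}")
    if lam <= COLLAPSE_STRETCH:
        return [(lam, N_CONTACT), (1.0, N_NEIGHBOR)]
    return [(lam, N_CONTACT), (lam / COLLAPSE_STRETCH, N_NEIGHBOR)]


def _class_force(stretch: float, chain: ChainSpec, label: str) -> float:
    x = stretch * chain.kappa
    if x >= 1.0 - 1e-9:
        raise FiniteExtensibilityError(
            f"{label} chains reach full extension at stretch {stretch:.6g} "
            f"(kappa={chain.kappa:.6g})"
        )
    return inverse_langevin(x)


def average_chain_force(lam: float, chain: ChainSpec) -> float:
    """Average dimensionless force over the 16 local chains at stretch lam.

    <f> = sum(count * beta(kappa * stretch)) / 16 over the contributing
    chain classes. Continuous in lam, with an upward kink in slope at the
    collapse stretch lam = 3 where the neighbors start stretching — the
    local stiffening seen in force-sink curves.
    """
    classes = contributing_chain_stretches(lam)
    labels = ("contact", "neighbor")
    total = 0.0
    count_total = 0
    for (stretch, count), label in zip(classes, labels):
        total += count * _class_force(stretch, chain, label)
        count_total += count
    return total / count_total


def crosslink_resultant(
    lam: float, chain: ChainSpec, xi: float = 1.0
) -> tuple[float, float]:
    """Resultant force magnitudes on the two distinct cross-link sites.

    At each vertex of the (rhombic for xi > 1, square for xi = 1) cell, four
    chain tensions meet in plane: two stretched cell sides with tension
    f = beta(kappa*lam) along directions separated by the vertex angle, and
    the two adjacent trapezoid legs with tension f_leg, each directed at the
    base angle alpha below its own cell side (component cos(alpha) along the
    side, -sin(alpha) along the other side). The vector sum factorizes:

        f_CL_1 = 2*cos(gamma/2) * |f + f_leg*(cos(alpha) - sin(alpha))|
        f_CL_2 = 2*sin(gamma/2) * |f + f_leg*(cos(alpha) - sin(alpha))|

    with gamma = 2*arctan(1/xi). Cross-link 1 (acute vertex, on the long
    axis) always carries the larger load: f_CL_1 / f_CL_2 = xi. At lam = 1
    (alpha = 90 deg, f_leg = f) both vanish — reference-state equilibrium.

    The legs rotate at constant length pre-collapse (tension beta(kappa))
    and stretch at lam/3 post-collapse.
    """
    if lam < 1:
        raise DomainError(f"stretch must be >= 1, got {lam}")
    gamma = rhombus_vertex_angle(xi, degrees=False)
    alpha = trapezoid_angle(lam, degrees=False)
    f = _class_force(lam, chain, "contact")
    if lam <= COLLAPSE_STRETCH:
        f_leg = _class_force(1.0, chain, "neighbor")
    else:
        f_leg = _class_force(lam / COLLAPSE_STRETCH, chain, "neighbor")
    core = abs(f + f_leg * (math.cos(alpha) - math.sin(alpha)))
    return 2.0 * math.cos(gamma / 2.0) * core, 2.0 * math.sin(gamma / 2.0) * core


def check_damage(
    f_chain: float, f_cl_1: float, thresholds: DamageThresholds
) -> DamageEvent | None:
    """Classify the damage mode, if any, for the current force state.

    Compares the contact-chain tension with f_rup and the critical
    cross-link resultant with f_dis. When both are exceeded in the same
    step, the mode with the larger relative exceedance wins; an exact tie
    goes to ``thresholds.prefer_on_tie``.
    """
    if f_chain < 0 or f_cl_1 < 0:
        raise DomainError("forces must be non-negative")
    exceed_chain = f_chain / thresholds.f_rup if math.isfinite(thresholds.f_rup) else 0.0
    exceed_cl = f_cl_1 / thresholds.f_dis if math.isfinite(thresholds.f_dis) else 0.0
    if exceed_chain <= 1.0 and exceed_cl <= 1.0:
        return None
    if exceed_chain > exceed_cl:
        return DamageEvent.CHAIN_RUPTURE
    if exceed_cl > exceed_chain:
        return DamageEvent.CROSSLINK_DISSOCIATION
    return thresholds.prefer_on_tie


@dataclass(frozen=True)
class PenetrationRecord:
    """One quasi-static state along the penetration sweep."""

    lam: float
    y_over_rho: float
    alpha_deg: float
    regime: Regime
    avg_chain_force: float
    f_cl_1: float
    f_cl_2: float
    damage: DamageEvent | None = None


@dataclass
class Trajectory:
    """Quasi-static force-sink trajectory and its outcome."""

    records: list = field(default_factory=list)
    outcome: Outcome = Outcome.JAMMED
    params: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        columns = [
            "lambda",
            "y_over_rho",
            "alpha_deg",
            "regime",
            "avg_chain_force",
            "f_cl_1",
            "f_cl_2",
            "damage",
        ]
        rows = [
            {
                "lambda": r.lam,
                "y_over_rho": r.y_over_rho,
                "alpha_deg": r.alpha_deg,
                "regime": r.regime.value,
                "avg_chain_force": r.avg_chain_force,
                "f_cl_1": r.f_cl_1,
                "f_cl_2": r.f_cl_2,
                "damage": r.damage.value if r.damage else "",
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=columns)


def simulate_penetration(
    shape: ParticleShape,
    chain: ChainSpec,
    R: float,
    thresholds: DamageThresholds | None = None,
    steps: int = 400,
    subtract_reference: bool = False,
) -> Trajectory:
    """Sweep the chain stretch quasi-statically and record forces until the
    particle penetrates, the network is damaged, or the chains lock.

    The stretch runs uniformly from 1 to min(1/eta, lam_max*(1 - 1e-6)),
    where lam_max = 1/kappa is the chain-locking stretch. At each state the
    sink, trapezoid angle, regime, average chain force and cross-link
    resultants are recorded; damage terminates the sweep at the first state
    whose forces exceed a threshold.

    Parameters
    ----------
    shape : ParticleShape
    chain : ChainSpec
    R : float
        Referential end-to-end distance of the local chains (same length
        unit as shape.rho).
    thresholds : DamageThresholds, optional
        Damage criteria; omitted = indestructible network.
    steps : int, optional
        Number of quasi-static states (>= 2). Default 400.
    subtract_reference : bool, optional
        Report the average chain force relative to the reference tension
        beta(kappa), so curves start at zero. Default False (absolute).

    Returns
    -------
    Trajectory
        Deterministic; ``outcome`` is spontaneous, elastic_penetration,
        chain_rupture, crosslink_dissociation or jammed.
    """
    if steps < 2:
        raise DomainError(f"steps must be >= 2, got {steps}")
    if thresholds is None:
        thresholds = DamageThresholds()
    eta_value = eta_of(shape, R)
    params = {
        "rho": shape.rho,
        "xi": shape.xi,
        "R": R,
        "eta": eta_value,
        "kappa": chain.kappa,
        "f_rup": thresholds.f_rup,
        "f_dis": thresholds.f_dis,
        "steps": steps,
        "subtract_reference": subtract_reference,
    }

    if eta_value >= 1.0:
        logger.info("eta=%.4g >= 1: spontaneous penetration, no sweep", eta_value)
        return Trajectory(records=[], outcome=Outcome.SPONTANEOUS, params=params)

    lam_pen = penetration_stretch(eta_value)
    lam_lock = chain.max_stretch * (1.0 - _LAMBDA_MAX_GUARD)
    lam_end = min(lam_pen, lam_lock)
    baseline = inverse_langevin(chain.kappa) if subtract_reference else 0.0

    records: list[PenetrationRecord] = []
    outcome = Outcome.JAMMED
    prev_regime: Regime | None = None
    for i in range(steps):
        lam = 1.0 + (lam_end - 1.0) * i / (steps - 1)
        regime = classify_regime(lam, eta_value)
        if regime != prev_regime:
            logger.info("regime %s from lambda=%.6g", regime.value, lam)
            prev_regime = regime
        avg_force = average_chain_force(lam, chain)
        f_contact = _class_force(lam, chain, "contact")
        f_cl_1, f_cl_2 = crosslink_resultant(lam, chain, shape.xi)
        damage = check_damage(f_contact, f_cl_1, thresholds)
        records.append(
            PenetrationRecord(
                lam=lam,
                y_over_rho=sink_from_stretch(lam, eta_value),
                alpha_deg=trapezoid_angle(lam),
                regime=regime,
                avg_chain_force=avg_force - baseline,
                f_cl_1=f_cl_1,
                f_cl_2=f_cl_2,
                damage=damage,
            )
        )
        if damage is not None:
            outcome = Outcome(damage.value)
            logger.info("damage %s at lambda=%.6g", damage.value, lam)
            break
    else:
        if lam_end >= lam_pen:
            outcome = Outcome.ELASTIC_PENETRATION
        else:
            outcome = Outcome.JAMMED

    return Trajectory(records=records, outcome=outcome, params=params)
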