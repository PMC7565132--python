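"""Spontaneous (unforced) penetration and gel microstructure characterization.

A particle penetrates a bio-gel without external force when it fits through
the mesh. For a local arrangement of ``m`` chains around a spherical particle
of diameter ``2*rho``, geometry gives the criterion

    R > 2*rho * tan(pi/m)

on the average chain end-to-end distance R. Read in reverse, the largest
particle observed to penetrate spontaneously pins down the smallest
consistent R — and, combined with the gel's liquid content (-> swelling J)
and repeat-unit length l, the number of repeat units per chain
n = (R/(J^(1/3)*l))^2. That inverse pipeline is what `characterize_gel`
and `characterize_table` implement.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .chains import (
    DomainError,
    monomers_from_end_to_end,
    swelling_from_liquid_content,
)

__all__ = [
    "GelObservation",
    "MeshEstimate",
    "can_penetrate_spontaneously",
    "characterize_gel",
    "characterize_table",
    "max_spontaneous_diameter",
    "min_end_to_end",
    "round_sigfigs",
]

logger = logging.getLogger(__name__)

DEFAULT_SIGFIGS = 2


def round_sigfigs(x: float, sigfigs: int = DEFAULT_SIGFIGS) -> float:
    """Round to the given number of significant figures (half away from zero)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (exponent - sigfigs + 1)
    return round(x / factor) * factor


def _as_range(value) -> tuple[float, float]:
    """Normalize a scalar or (lo, hi) pair to a (lo, hi) tuple."""
    if isinstance(value, (tuple, list)):
        lo, hi = float(value[0]), float(value[1])
        if lo > hi:
            raise DomainError(f"range ({lo}, {hi}) has lo > hi")
        return lo, hi
    v = float(value)
    return v, v


@dataclass
class GelObservation:
    """One gel's spontaneous-penetration record from the literature.

    Parameters
    ----------
    name : str
        Gel label (e.g. "Respiratory mucus").
    d_min, d_max, d_avg : float
        Minimum, maximum and average diameters (nm) of particles reported
        to penetrate the gel spontaneously.
    cl : float or (float, float)
        Liquid volume fraction, scalar or (lo, hi) range.
    l : float or (float, float)
        Repeat-unit length in nm, scalar or (lo, hi) range.
    m_values : list of int
        Local chain coordinations to evaluate (each >= 3); m = 3 is a
        triangular, m = 4 a quadrilateral arrangement.
    """

    name: str
    d_min: float
    d_max: float
    d_avg: float
    cl: object
    l: object
    m_values: list = field(default_factory=lambda: [3, 4])

    def __post_init__(self) -> None:
        if not 0 < self.d_min <= self.d_avg <= self.d_max:
            raise DomainError(
                f"{self.name}: need 0 < d_min <= d_avg <= d_max, got "
                f"({self.d_min}, {self.d_avg}, {self.d_max})"
            )
        lo, hi = _as_range(self.cl)
        if not 0.0 <= lo <= hi < 1.0:
            raise DomainError(f"{self.name}: liquid content must lie in [0, 1)")
        lo, hi = _as_range(self.l)
        if lo <= 0:
            raise DomainError(f"{self.name}: repeat-unit length must be positive")
        self.m_values = [int(m) for m in self.m_values]
        if any(m < 3 for m in self.m_values):
            raise DomainError(f"{self.name}: every coordination m must be >= 3")

    @property
    def cl_mid(self) -> float:
        """Scalar liquid content: the value itself, or the range midpoint."""
        lo, hi = _as_range(self.cl)
        return 0.5 * (lo + hi)

    @property
    def l_mid(self) -> float:
        """Scalar repeat-unit length: the value itself, or the range midpoint."""
        lo, hi = _as_range(self.l)
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class MeshEstimate:
    """Microstructure inferred from one gel observation at one coordination m."""

    name: str
    m: int
    R: float  #: end-to-end estimate 2*rho*tan(pi/m), full precision (nm)
    R_reported: float  #: R rounded to the reporting precision (nm)
    n: int  #: repeat units per chain, from R_reported
    sub_monomer: bool = False  #: True when the raw n fell below 1


def min_end_to_end(diameter: float, m: int) -> float:
    """Smallest end-to-end distance R (nm) admitting spontaneous penetration.

    R = diameter * tan(pi/m) for a sphere of the given diameter in a local
    arrangement of m chains.
    """
    if diameter <= 0:
        raise DomainError(f"diameter must be positive, got {diameter}")
    if m < 3:
        raise DomainError(f"coordination m must be >= 3, got {m}")
    return diameter * math.tan(math.pi / m)


def max_spontaneous_diameter(R: float, m: int) -> float:
    """Largest sphere diameter that penetrates spontaneously: R/tan(pi/m)."""
    if R <= 0:
        raise DomainError(f"R must be positive, got {R}")
    if m < 3:
        raise DomainError(f"coordination m must be >= 3, got {m}")
    return R / math.tan(math.pi / m)


def can_penetrate_spontaneously(
    diameter: float, R: float, m: int = 4, xi: float = 1.0
) -> bool:
    """Whether a particle penetrates the gel without external force.

    For a sphere (xi = 1) the criterion is ``R > diameter * tan(pi/m)``
    (strict: the boundary case does not penetrate). An ellipsoid with aspect
    ratio xi > 1 must clear the mesh with its long axis ``xi * diameter``;
    that case is defined for the quadrilateral arrangement (m = 4), where
    tan(pi/4) = 1 reduces the criterion to ``R > xi * diameter``.
    """
    if diameter <= 0 or R <= 0:
        raise DomainError("diameter and R must be positive")
    if m < 3:
        raise DomainError(f"coordination m must be >= 3, got {m}")
    if xi < 1:
        raise DomainError(f"aspect ratio xi must be >= 1, got {xi}")
    if xi > 1 and m != 4:
        raise DomainError("ellipsoidal criterion is defined for m = 4 only")
    threshold = xi * diameter * math.tan(math.pi / m)
    # strict inequality; the relative tolerance absorbs rounding in tan(pi/m)
    return R > threshold * (1.0 + 1e-12)


def characterize_gel(
    obs: GelObservation,
    l: float | None = None,
    cl: float | None = None,
    sigfigs: int = DEFAULT_SIGFIGS,
) -> list[MeshEstimate]:
    """Infer (R, n) for one gel, one estimate per coordination in m_values.

    Pipeline, per m: R = d_avg * tan(pi/m); round R to `sigfigs` significant
    figures; convert the *rounded* R to n = round((R/(J^(1/3)*l))^2) with
    J = 1/(1 - cl). Rounding R before computing n is the reporting
    convention adopted throughout.

    Parameters
    ----------
    obs : GelObservation
    l, cl : float, optional
        Override the observation's repeat-unit length / liquid content
        (defaults: the observation's scalar value or range midpoint).
    sigfigs : int, optional
        Significant figures for the reported R. Default 2.
    """
    l_eff = obs.l_mid if l is None else float(l)
    cl_eff = obs.cl_mid if cl is None else float(cl)
    if l_eff <= 0:
        raise DomainError(f"{obs.name}: repeat-unit length must be positive")
    J = swelling_from_liquid_content(cl_eff)

    estimates = []
    for m in sorted(obs.m_values):
        R = min_end_to_end(obs.d_avg, m)
        R_reported = round_sigfigs(R, sigfigs)
        n_raw = monomers_from_end_to_end(R_reported, J, l_eff, rounded=False)
        sub_monomer = n_raw < 1.0
        if sub_monomer:
            warnings.warn(
                f"{obs.name} (m={m}): end-to-end {R_reported:.3g} nm is below "
                f"one swollen repeat unit (raw n={n_raw:.3g}); reporting n=1",
                stacklevel=2,
            )
        n = max(1, int(round(n_raw)))
        estimates.append(
            MeshEstimate(
                name=obs.name,
                m=m,
                R=R,
                R_reported=R_reported,
                n=n,
                sub_monomer=sub_monomer,
            )
        )
    return estimates


def characterize_table(
    observations: list,
    l: float | None = None,
    cl: float | None = None,
    sigfigs: int = DEFAULT_SIGFIGS,
) -> pd.DataFrame:
    """Characterize a batch of gels into a tidy table.

    Returns one row per (gel, m), in input order then ascending m, with
    columns ``name, m, R_nm, R_reported_nm, n``.
    """
    columns = ["name", "m", "R_nm", "R_reported_nm", "n"]
    if not observations:
        logger.warning("characterize_table called with no observations")
        return pd.DataFrame(columns=columns)
    rows = []
    for obs in observations:
        for est in characterize_gel(obs, l=l, cl=cl, sigfigs=sigfigs):
            rows.append(
                {
                    "name": est.name,
                    "m": est.m,
                    "R_nm": est.R,
                    "R_reported_nm": est.R_reported,
                    "n": est.n,
                }
            )
    return pd.DataFrame(rows, columns=columns)
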