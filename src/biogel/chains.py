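"""Freely jointed chain (FJC) entropic elasticity and swelling relations.

A bio-gel is idealized as a network of freely jointed chains: each chain
consists of ``n`` rigid repeat units of length ``l`` (nm) between two
cross-links. Swelling by a volumetric ratio ``J`` sets the referential
end-to-end length ``R = J**(1/3) * sqrt(n) * l``. The entropic tension of a
chain stretched by a factor ``lam`` relative to R is governed by the inverse
Langevin law; throughout the package forces are dimensionless, reported as
``f*l/(kB*T)``.

The key dimensionless group is the extensibility scale

    kappa = J**(1/3) / sqrt(n)

so that the inverse-Langevin argument at stretch ``lam`` is ``lam * kappa``
and the chain locks (force diverges) as ``lam -> 1/kappa``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BOLTZMANN_J_PER_K",
    "DEFAULT_TEMPERATURE_K",
    "ChainSpec",
    "DomainError",
    "FiniteExtensibilityError",
    "chain_force",
    "chain_force_si",
    "inverse_langevin",
    "liquid_content",
    "monomers_from_end_to_end",
    "referential_end_to_end",
    "swelling_from_liquid_content",
]

BOLTZMANN_J_PER_K = 1.380649e-23
DEFAULT_TEMPERATURE_K = 310.0

#: stretches with lam*kappa above this are treated as the locking singularity
_EXTENSIBILITY_GUARD = 1.0 - 1e-9


class DomainError(ValueError):
    """An input lies outside the physically meaningful domain."""


class FiniteExtensibilityError(DomainError):
    """A chain was asked to stretch at or beyond its contour length."""


def inverse_langevin(x):
    """Padé-type approximant of the inverse Langevin function.

    beta(x) = x * (3 - x**2) / (1 - x**2)

    Parameters
    ----------
    x : float or array_like
        Fractional chain extension r / (n*l), ``0 <= x < 1``.

    Returns
    -------
    float or ndarray
        Approximate beta such that ``L(beta) = coth(beta) - 1/beta ~ x``.

    Raises
    ------
    DomainError
        If any element is negative or >= 1 (non-physical extension).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0):
        raise DomainError("fractional extension must be non-negative")
    if np.any(arr >= 1.0):
        raise FiniteExtensibilityError(
            "fractional extension must be < 1 (chain fully extended)"
        )
    out = arr * (3.0 - arr**2) / (1.0 - arr**2)
    if np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ChainSpec:
    """A freely jointed chain between two cross-links of a swollen network.

    Parameters
    ----------
    n : float
        Repeat units per chain (> 0).
    l : float
        Repeat-unit length in nm (> 0).
    J : float, optional
        Volumetric swelling ratio, swollen/dry volume (>= 1). Default 1
        (dry network).
    """

    n: float
    l: float
    J: float = 1.0

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise DomainError(f"n must be > 0, got {self.n}")
        if not self.l > 0:
            raise DomainError(f"l must be > 0, got {self.l}")
        if not self.J >= 1:
            raise DomainError(f"J must be >= 1, got {self.J}")

    @property
    def kappa(self) -> float:
        """Extensibility scale J**(1/3)/sqrt(n); lam_max = 1/kappa."""
        return self.J ** (1.0 / 3.0) / math.sqrt(self.n)

    @property
    def R(self) -> float:
        """Referential end-to-end length J**(1/3)*sqrt(n)*l (nm)."""
        return self.J ** (1.0 / 3.0) * math.sqrt(self.n) * self.l

    @property
    def contour_length(self) -> float:
        """Fully extended chain length n*l (nm)."""
        return self.n * self.l

    @property
    def max_stretch(self) -> float:
        """Stretch at which the chain locks, 1/kappa."""
        return 1.0 / self.kappa

    @classmethod
    def from_kappa(cls, kappa: float, l: float = 1.0) -> "ChainSpec":
        """Build an unswollen chain (J=1) with the given extensibility scale.

        Useful when a simulation is parameterized directly by kappa rather
        than by (n, J): kappa = 1/sqrt(n) at J = 1.
        """
        if not 0.0 < kappa < 1.0:
            raise DomainError(f"kappa must lie in (0, 1), got {kappa}")
        return cls(n=1.0 / kappa**2, l=l, J=1.0)


def chain_force(lam: float, chain: ChainSpec) -> float:
    """Dimensionless entropic tension f*l/(kB*T) of a chain at stretch lam.

    The FJC force law evaluated at fractional extension
    ``lam * R / (n*l) = lam * kappa``.

    Raises
    ------
    FiniteExtensibilityError
        If ``lam * kappa`` reaches the locking singularity.
    DomainError
        If lam is negative.
    """
    if lam < 0:
        raise DomainError(f"stretch must be non-negative, got {lam}")
    x = lam * chain.kappa
    if x > _EXTENSIBILITY_GUARD:
        raise FiniteExtensibilityError(
            f"stretch {lam} reaches the contour length (lam*kappa={x:.6g}); "
            f"max stretch is {chain.max_stretch:.6g}"
        )
    return inverse_langevin(x)


def chain_force_si(
    lam: float,
    chain: ChainSpec,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Chain tension in newtons: chain_force * kB*T / l (l in nm)."""
    f_dimensionless = chain_force(lam, chain)
    l_m = chain.l * 1e-9
    return f_dimensionless * BOLTZMANN_J_PER_K * temperature_K / l_m


def swelling_from_liquid_content(cl: float) -> float:
    """Volumetric swelling ratio J from the liquid volume fraction.

    The liquid content of a gel is cl = (J - 1)/J, so J = 1/(1 - cl).

    Parameters
    ----------
    cl : float
        Liquid volume fraction, ``0 <= cl < 1`` (e.g. 0.95 for mucus).
    """
    if not 0.0 <= cl < 1.0:
        raise DomainError(f"liquid content must lie in [0, 1), got {cl}")
    return 1.0 / (1.0 - cl)


def liquid_content(J: float) -> float:
    """Liquid volume fraction (J - 1)/J of a network swollen by J."""
    if not J >= 1.0:
        raise DomainError(f"J must be >= 1, got {J}")
    return (J - 1.0) / J


def referential_end_to_end(chain: ChainSpec) -> float:
    """Referential (swollen, unloaded) end-to-end length R in nm."""
    return chain.R


def monomers_from_end_to_end(
    R: float, J: float, l: float, rounded: bool = True
):
    """Repeat units per chain from the end-to-end length: n = (R/(J^(1/3)*l))^2.

    This inverts ``R = J**(1/3)*sqrt(n)*l``, the route by which
    spontaneous-penetration observations yield chain lengths.

    Parameters
    ----------
    R, l : float
        End-to-end length and repeat-unit length (nm, > 0).
    J : float
        Volumetric swelling ratio (>= 1).
    rounded : bool, optional
        Round to the nearest integer (the reporting convention). Default True.
    """
    if R <= 0 or l <= 0:
        raise DomainError("R and l must be positive")
    if J < 1:
        raise DomainError(f"J must be >= 1, got {J}")
    n = (R / (J ** (1.0 / 3.0) * l)) ** 2
    if rounded:
        return int(round(n))
    return n
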