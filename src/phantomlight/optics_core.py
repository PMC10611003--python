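"""Shared domain types and Fresnel/Snell utilities for slab-phantom optics.

Conventions used throughout the package:

* lengths in mm, scattering/absorption coefficients in mm^-1,
* angles in radians, direction cosines measured against the slab normal,
* the slab occupies ``z in [0, d]`` with the illuminated face at ``z = 0``
  (top) and the detection face at ``z = d`` (bottom),
* all Fresnel coefficients are unpolarized power coefficients
  (average of the s and p polarizations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "OpticalSlab",
    "DetectionAperture",
    "DerivedCoefficients",
    "fresnel_reflectance",
    "fresnel_transmittance",
    "aperture_angle",
    "derive_coefficients",
]


def fresnel_reflectance(n_incident, n_transmitted, mu):
    """Unpolarized Fresnel power reflectance at a planar dielectric interface.

    Parameters
    ----------
    n_incident, n_transmitted
        Refractive indices of the incidence and transmission media.
    mu
        Cosine of the angle of incidence, in ``(0, 1]``.  Scalar or array.

    Returns
    -------
    Reflectance in ``[0, 1]``; exactly 1 beyond the critical angle
    (total internal reflection).
    """
    n1 = float(n_incident)
    n2 = float(n_transmitted)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("refractive indices must be positive")
    mu_arr = np.asarray(mu, dtype=float)
    scalar = mu_arr.ndim == 0
    mu_arr = np.atleast_1d(mu_arr)
    if np.any(mu_arr <= 0) or np.any(mu_arr > 1):
        raise ValueError("incidence cosine mu must lie in (0, 1]")

    sin_i2 = 1.0 - mu_arr**2
    sin_t2 = (n1 / n2) ** 2 * sin_i2
    tir = sin_t2 >= 1.0
    mu_t = np.sqrt(np.clip(1.0 - sin_t2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = (n1 * mu_arr - n2 * mu_t) / (n1 * mu_arr + n2 * mu_t)
        rp = (n2 * mu_arr - n1 * mu_t) / (n2 * mu_arr + n1 * mu_t)
    r = 0.5 * (rs**2 + rp**2)
    r = np.where(tir, 1.0, r)
    r = np.clip(r, 0.0, 1.0)
    return float(r[0]) if scalar else r


def fresnel_transmittance(n_incident, n_transmitted, mu):
    """Unpolarized Fresnel power transmittance, ``1 - R``."""
    r = fresnel_reflectance(n_incident, n_transmitted, mu)
    return 1.0 - r


def aperture_angle(na: float, n_ambient: float) -> float:
    """Half-angle (radians) of a detection cone of numerical aperture ``na``.

    ``theta_max = arcsin(na / n_ambient)``, defined in the medium of index
    ``n_ambient`` on the detection side.
    """
    if na <= 0:
        raise ValueError("numerical aperture must be positive")
    if n_ambient <= 0:
        raise ValueError("ambient refractive index must be positive")
    if na > n_ambient:
        raise ValueError(
            f"numerical aperture {na} exceeds ambient index {n_ambient}"
        )
    return math.asin(na / n_ambient)


class DerivedCoefficients(NamedTuple):
    """Coefficients derived from (mus_prime, g, mua, d)."""

    mus: float
    mut: float
    l_transport: float
    tau: float


def derive_coefficients(
    mus_prime: float, g: float, mua: float, d: float
) -> DerivedCoefficients:
    """Derive (mus, mut, transport mean free path, transport optical thickness).

    ``mus = mus_prime / (1 - g)``; ``mut = mus + mua``;
    ``l_transport = 1 / mus_prime`` (``inf`` for a non-scattering medium);
    ``tau = mus_prime * d``.
    """
    if not 0 <= g < 1:
        raise ValueError("anisotropy g must lie in [0, 1)")
    if mus_prime < 0 or mua < 0:
        raise ValueError("optical coefficients must be nonnegative")
    if d <= 0:
        raise ValueError("thickness d must be positive")
    mus = mus_prime / (1.0 - g)
    mut = mus + mua
    l_transport = math.inf if mus_prime == 0 else 1.0 / mus_prime
    tau = mus_prime * d
    return DerivedCoefficients(mus, mut, l_transport, tau)


@dataclass(frozen=True)
class OpticalSlab:
    """A homogeneous scattering/absorbing slab phantom.

    Parameters
    ----------
    d
        Thickness (mm).
    mus_prime
        Effective (reduced) scattering coefficient mus' = mus * (1 - g) (mm^-1).
    mua
        Absorption coefficient (mm^-1).
    g
        Henyey-Greenstein anisotropy factor, in ``[0, 1)``.
    n_slab, n_ambient
        Refractive indices of the slab medium and of its (identical)
        surroundings on both faces.
    sample_id
        Optional phantom label.
    """

    d: float
    mus_prime: float
    mua: float
    g: float = 0.6
    n_slab: float = 1.552
    n_ambient: float = 1.0
    sample_id: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("thickness d must be positive")
        if self.mus_prime < 0:
            raise ValueError("mus_prime must be nonnegative")
        if self.mua < 0:
            raise ValueError("mua must be nonnegative")
        if not 0 <= self.g < 1:
            raise ValueError("anisotropy g must lie in [0, 1)")
        if self.n_slab < 1 or self.n_ambient < 1:
            raise ValueError("refractive indices must be >= 1")

    @property
    def mus(self) -> float:
        """Scattering coefficient mus = mus' / (1 - g) (mm^-1)."""
        return self.mus_prime / (1.0 - self.g)

    @property
    def mut(self) -> float:
        """Total attenuation coefficient mus + mua (mm^-1)."""
        return self.mus + self.mua

    @property
    def l_transport(self) -> float:
        """Transport mean free path 1 / mus' (mm)."""
        return math.inf if self.mus_prime == 0 else 1.0 / self.mus_prime

    @property
    def tau(self) -> float:
        """Transport optical thickness mus' * d (dimensionless)."""
        return self.mus_prime * self.d

    def derived(self) -> DerivedCoefficients:
        return derive_coefficients(self.mus_prime, self.g, self.mua, self.d)


@dataclass(frozen=True)
class DetectionAperture:
    """Detection cone defined by a numerical aperture in the ambient medium."""

    na: float
    n_ambient: float = 1.0

    def __post_init__(self):
        # aperture_angle validates 0 < na <= n_ambient
        aperture_angle(self.na, self.n_ambient)

    @property
    def theta_max(self) -> float:
        """Maximum accepted polar angle in the ambient medium (radians)."""
        return aperture_angle(self.na, self.n_ambient)

    def mu_min_interior(self, n_slab: float) -> float:
        """Smallest interior direction cosine refracted into the aperture.

        The NA is invariant across the interface (``n sin(theta)`` is
        conserved), so the interior cutoff is ``sqrt(1 - (na/n_slab)^2)``.
        """
        s = self.na / n_slab
        if s >= 1.0:
            return 0.0
        return math.sqrt(1.0 - s * s)
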