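"""Photon-transport Monte Carlo in slab geometry.

Independent verification oracle for the P_N solver and optional forward
engine for the integrating-sphere look-up table.  A normally incident
pencil beam is launched at the top face (equivalent, for the integrated
quantities computed here, to plane-wave illumination with localized
detection); free paths are sampled at rate ``mut``, scattering angles from
the Henyey-Greenstein distribution, absorption via implicit capture
(weight times ``mus/mut`` per collision) with Russian roulette below a
weight threshold, and every boundary crossing draws against the
angle-dependent unpolarized Fresnel reflectance.

Weight bookkeeping is exact: the net weight created or destroyed by
roulette is folded into the absorption tally (a zero-mean correction), so
``t_total + r_total + a_total == 1`` holds to floating-point round-off for
every run.  Only the depth coordinate and the direction cosine are tracked;
for a laterally infinite homogeneous slab the transverse position never
enters any tally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .optics_core import DetectionAperture, OpticalSlab

__all__ = ["MCResult", "simulate", "hg_sample", "integrate_na"]

_ROULETTE_THRESHOLD = 1e-4
_ROULETTE_SURVIVAL = 0.1


def hg_sample(g: float, u):
    """Inverse-CDF sample of the Henyey-Greenstein scattering cosine.

    ``u`` is a uniform variate in ``[0, 1)``; for ``g = 0`` the cosine is
    ``2 u - 1`` (isotropic scattering).
    """
    if not 0 <= g < 1:
        raise ValueError("anisotropy g must lie in [0, 1)")
    u_arr = np.asarray(u, dtype=float)
    if g == 0.0:
        out = 2.0 * u_arr - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u_arr)
        out = (1.0 + g * g - frac * frac) / (2.0 * g)
    out = np.clip(out, -1.0, 1.0)
    return float(out) if np.asarray(u).ndim == 0 else out


@njit(cache=True, inline="always")
def _fresnel_r(n1, n2, mu):
    """Unpolarized Fresnel power reflectance (scalar, numba)."""
    if n1 == n2:
        return 0.0
    sin_t2 = (n1 / n2) ** 2 * (1.0 - mu * mu)
    if sin_t2 >= 1.0:
        return 1.0
    mu_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * mu - n2 * mu_t) / (n1 * mu + n2 * mu_t)
    rp = (n2 * mu - n1 * mu_t) / (n2 * mu + n1 * mu_t)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _transport_kernel(
    n_photons, seed, d, mus, mua, g, n_in, n_out, n_theta_bins, n_z_bins
):
    np.random.seed(seed)
    mut = mus + mua
    r_entry = _fresnel_r(n_out, n_in, 1.0)

    scalars = np.zeros(8)  # T, T2, R, R2, A, A2, BAL, BAL2
    ang = np.zeros(n_theta_bins)
    ang2 = np.zeros(n_theta_bins)
    flu = np.zeros(max(n_z_bins, 1))
    flu2 = np.zeros(max(n_z_bins, 1))
    flu_local = np.zeros(max(n_z_bins, 1))
    dz = d / n_z_bins if n_z_bins > 0 else d
    half_pi = 0.5 * math.pi

    for _ in range(n_photons):
        t_w = 0.0
        r_w = 0.0
        a_w = 0.0
        bal_w = 0.0
        if n_z_bins > 0:
            flu_local[:] = 0.0

        if np.random.random() < r_entry:
            r_w = 1.0  # specular reflection at the entry face
        else:
            z = 0.0
            uz = 1.0
            w = 1.0
            nsc = 0
            alive = True
            while alive:
                if mut > 0.0:
                    step = -math.log(1.0 - np.random.random()) / mut
                else:
                    step = 1e30
                zn = z + uz * step
                if zn < 0.0 or zn > d:
                    # boundary crossing
                    bottom = zn > d
                    z = d if bottom else 0.0
                    amu = abs(uz)
                    rf = _fresnel_r(n_in, n_out, amu)
                    if np.random.random() < rf:
                        uz = -uz
                        continue
                    if bottom:
                        t_w = w
                        if nsc == 0:
                            bal_w = w
                        else:
                            sin_i = math.sqrt(max(0.0, 1.0 - amu * amu))
                            sin_a = min(1.0, n_in * sin_i / n_out)
                            theta_a = math.asin(sin_a)
                            b = int(theta_a / half_pi * n_theta_bins)
                            if b >= n_theta_bins:
                                b = n_theta_bins - 1
                            ang[b] += w
                            ang2[b] += w * w
                    else:
                        r_w = w
                    alive = False
                else:
                    z = zn
                    # collision: implicit capture
                    if n_z_bins > 0:
                        bz = int(z / dz)
                        if bz >= n_z_bins:
                            bz = n_z_bins - 1
                        flu_local[bz] += w / mut
                    a_w += w * mua / mut
                    w *= mus / mut
                    nsc += 1
                    # Henyey-Greenstein polar cosine, uniform azimuth
                    u = np.random.random()
                    if g == 0.0:
                        ct = 2.0 * u - 1.0
                    else:
                        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                        ct = (1.0 + g * g - frac * frac) / (2.0 * g)
                        if ct > 1.0:
                            ct = 1.0
                        elif ct < -1.0:
                            ct = -1.0
                    st = math.sqrt(max(0.0, 1.0 - ct * ct))
                    phi = 2.0 * math.pi * np.random.random()
                    suz = math.sqrt(max(0.0, 1.0 - uz * uz))
                    uz = uz * ct + suz * st * math.cos(phi)
                    if uz > 1.0:
                        uz = 1.0
                    elif uz < -1.0:
                        uz = -1.0
                    # Russian roulette with conservation compensation
                    if w < _ROULETTE_THRESHOLD:
                        if np.random.random() < _ROULETTE_SURVIVAL:
                            boost = w / _ROULETTE_SURVIVAL - w
                            a_w -= boost
                            w = w / _ROULETTE_SURVIVAL
                        else:
                            a_w += w
                            alive = False

        scalars[0] += t_w
        scalars[1] += t_w * t_w
        scalars[2] += r_w
        scalars[3] += r_w * r_w
        scalars[4] += a_w
        scalars[5] += a_w * a_w
        scalars[6] += bal_w
        scalars[7] += bal_w * bal_w
        if n_z_bins > 0:
            for k in range(n_z_bins):
                flu[k] += flu_local[k]
                flu2[k] += flu_local[k] * flu_local[k]

    return scalars, ang, ang2, flu, flu2


def _mean_se(total, total_sq, n):
    mean = total / n
    var = max(total_sq / n - mean * mean, 0.0)
    return mean, math.sqrt(var / n)


@dataclass
class MCResult:
    """Tallies of a slab Monte Carlo run, normalized to unit incident power."""

    n_photons: int
    seed: int
    slab: OpticalSlab
    t_total: float
    r_total: float
    a_total: float
    t_ballistic: float
    se_t: float
    se_r: float
    se_a: float
    se_ballistic: float
    theta_edges: np.ndarray  # ambient exit-angle bin edges, [0, pi/2]
    t_angular: np.ndarray  # scattered transmitted weight fraction per bin
    se_angular: np.ndarray
    z_edges: np.ndarray | None = None
    fluence: np.ndarray | None = field(default=None, repr=False)
    se_fluence: np.ndarray | None = field(default=None, repr=False)


def simulate(
    slab: OpticalSlab,
    n_photons: int,
    seed: int,
    n_angle_bins: int = 90,
    n_z_bins: int = 0,
) -> MCResult:
    """Run the slab transport Monte Carlo.

    Parameters
    ----------
    slab
        Phantom description; illumination is a normally incident unit-power
        pencil beam at the top face.
    n_photons
        Number of photon packets (>= 1).
    seed
        Mandatory RNG seed; identical ``(seed, inputs)`` give bit-identical
        tallies.
    n_angle_bins
        Uniform-in-theta exit bins over ``[0, pi/2]`` (ambient angles) for
        scattered transmitted photons; the ballistic delta is kept separate.
    n_z_bins
        If positive, also tally the collision-estimator fluence (total,
        i.e. collimated plus diffuse) on this many uniform depth bins.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if n_angle_bins < 1:
        raise ValueError("n_angle_bins must be >= 1")
    seed = int(seed) & 0x7FFFFFFF
    scalars, ang, ang2, flu, flu2 = _transport_kernel(
        int(n_photons),
        seed,
        float(slab.d),
        float(slab.mus),
        float(slab.mua),
        float(slab.g),
        float(slab.n_slab),
        float(slab.n_ambient),
        int(n_angle_bins),
        int(n_z_bins),
    )
    n = n_photons
    t_total, se_t = _mean_se(scalars[0], scalars[1], n)
    r_total, se_r = _mean_se(scalars[2], scalars[3], n)
    a_total, se_a = _mean_se(scalars[4], scalars[5], n)
    t_bal, se_bal = _mean_se(scalars[6], scalars[7], n)
    ang_mean = ang / n
    ang_se = np.sqrt(np.maximum(ang2 / n - ang_mean**2, 0.0) / n)
    theta_edges = np.linspace(0.0, math.pi / 2, n_angle_bins + 1)
    z_edges = fluence = se_fluence = None
    if n_z_bins > 0:
        z_edges = np.linspace(0.0, slab.d, n_z_bins + 1)
        dz = slab.d / n_z_bins
        fl_mean = flu / n
        fl_se = np.sqrt(np.maximum(flu2 / n - fl_mean**2, 0.0) / n)
        fluence = fl_mean / dz
        se_fluence = fl_se / dz
    return MCResult(
        n_photons=n_photons,
        seed=seed,
        slab=slab,
        t_total=t_total,
        r_total=r_total,
        a_total=a_total,
        t_ballistic=t_bal,
        se_t=se_t,
        se_r=se_r,
        se_a=se_a,
        se_ballistic=se_bal,
        theta_edges=theta_edges,
        t_angular=ang_mean,
        se_angular=ang_se,
        z_edges=z_edges,
        fluence=fluence,
        se_fluence=se_fluence,
    )


def integrate_na(result: MCResult, aperture: DetectionAperture):
    """Sum the angular tallies inside a detection aperture.

    The cut angle rarely falls on a bin edge; the edge bin contributes the
    linear fraction of its width inside the aperture.  Returns
    ``(t_na_diffuse, t_na, se)`` where ``t_na`` includes the ballistic tally.
    """
    theta_max = aperture.theta_max
    edges = result.theta_edges
    widths = np.diff(edges)
    frac = np.clip((theta_max - edges[:-1]) / widths, 0.0, 1.0)
    t_na_diffuse = float(np.sum(frac * result.t_angular))
    var = float(np.sum((frac * result.se_angular) ** 2))
    t_na = t_na_diffuse + result.t_ballistic
    se = math.sqrt(var + result.se_ballistic**2)
    return t_na_diffuse, t_na, se
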