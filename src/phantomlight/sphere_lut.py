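"""Integrating-sphere forward model and look-up-table inversion.

An integrating sphere measures the total hemispherical transmittance and
reflectance ``(T, R)`` of a slab.  Given the fixed sample parameters
(anisotropy ``g``, refractive indices, thickness ``d``), the forward map
``(mus', mua) -> (T, R)`` is tabulated on a grid and the measurement is
inverted by continuous two-dimensional root finding on the bilinearly
interpolated surfaces (bilinear in ``(mus', log mua)``), recovering the
effective scattering and absorption coefficients.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .monte_carlo import simulate
from .optics_core import OpticalSlab
from .pn_solver import angular_transmittance

__all__ = [
    "LookupTable",
    "LUTRangeError",
    "LUTAmbiguityError",
    "forward_TR",
    "build_lut",
    "invert",
    "jacobian_singular_values",
]

_DEFAULT_PN_ORDER = 31
_DEFAULT_MC_PHOTONS = 10**6


class LUTRangeError(ValueError):
    """Target observables are outside the range spanned by the table."""


class LUTAmbiguityError(RuntimeError):
    """The interpolated forward map brackets the target non-uniquely."""


def forward_TR(
    slab: OpticalSlab,
    engine: str = "pn",
    budget: int | None = None,
    seed: int = 0,
):
    """Total hemispherical transmittance and reflectance of a slab.

    ``engine="pn"`` evaluates the deterministic P_N forward model
    (``budget`` = truncation order, default 31); ``engine="mc"`` runs the
    photon Monte Carlo (``budget`` = photon count, default 1e6) and is the
    stochastic counterpart of a sphere measurement.
    """
    if engine == "pn":
        order = budget if budget is not None else _DEFAULT_PN_ORDER
        table = angular_transmittance(slab, order=order, n_angles=2)
        return table.t_total, table.r_total
    if engine == "mc":
        n_photons = int(budget) if budget is not None else _DEFAULT_MC_PHOTONS
        res = simulate(slab, n_photons=n_photons, seed=seed, n_angle_bins=2)
        return res.t_total, res.r_total
    raise ValueError(f"unknown forward engine {engine!r}; use 'pn' or 'mc'")


@dataclass
class LookupTable:
    """Forward ``(T, R)`` tables over a ``(mus', mua)`` grid at fixed slab.

    ``table_t[i, j]`` and ``table_r[i, j]`` hold the forward observables at
    ``grid_mus_prime[i]``, ``grid_mua[j]``.
    """

    grid_mus_prime: np.ndarray
    grid_mua: np.ndarray
    g: float
    n_slab: float
    n_ambient: float
    d: float
    table_t: np.ndarray
    table_r: np.ndarray
    engine: str = "pn"
    budget: int | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("grid_mus_prime", "grid_mua"):
            axis = np.asarray(getattr(self, name), dtype=float)
            if axis.size < 2 or np.any(np.diff(axis) <= 0):
                raise ValueError(f"{name} must be strictly increasing, >= 2 nodes")
            setattr(self, name, axis)

    def interpolators(self):
        """Bilinear interpolants of T and R on ``(mus', log mua)``."""
        x = self.grid_mus_prime
        y = np.log(self.grid_mua)
        it = RegularGridInterpolator((x, y), self.table_t, method="linear")
        ir = RegularGridInterpolator((x, y), self.table_r, method="linear")
        return it, ir

    def to_csv(self, path) -> None:
        """Persist in long form (mus_prime, mua, T, R)."""
        mus, mua = np.meshgrid(self.grid_mus_prime, self.grid_mua, indexing="ij")
        df = pd.DataFrame(
            {
                "mus_prime": mus.ravel(),
                "mua": mua.ravel(),
                "T": self.table_t.ravel(),
                "R": self.table_r.ravel(),
            }
        )
        header = (
            f"# phantomlight LUT g={self.g} n_slab={self.n_slab} "
            f"n_ambient={self.n_ambient} d={self.d} engine={self.engine} "
            f"budget={self.budget} seed={self.seed}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "LookupTable":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# phantomlight LUT"):
                raise ValueError("not a phantomlight LUT CSV")
            meta = dict(
                item.split("=", 1) for item in header.split()[3:] if "=" in item
            )
            df = pd.read_csv(io.StringIO(fh.read()))
        x = np.unique(df["mus_prime"].to_numpy())
        y = np.unique(df["mua"].to_numpy())
        t = df["T"].to_numpy().reshape(x.size, y.size)
        r = df["R"].to_numpy().reshape(x.size, y.size)
        budget = meta.get("budget", "None")
        return cls(
            grid_mus_prime=x,
            grid_mua=y,
            g=float(meta["g"]),
            n_slab=float(meta["n_slab"]),
            n_ambient=float(meta["n_ambient"]),
            d=float(meta["d"]),
            table_t=t,
            table_r=r,
            engine=meta.get("engine", "pn"),
            budget=None if budget == "None" else int(budget),
            seed=int(meta.get("seed", 0)),
        )


def build_lut(
    mus_prime_axis,
    mua_axis,
    fixed: tuple[float, float, float, float],
    engine: str = "pn",
    budget: int | None = None,
    seed: int = 0,
) -> LookupTable:
    """Populate the forward tables node by node.

    Parameters
    ----------
    mus_prime_axis, mua_axis
        Strictly increasing grid axes (mm^-1), each with >= 2 nodes.
    fixed
        ``(g, n_slab, n_ambient, d)`` shared by every node.
    engine, budget, seed
        Forward engine as in :func:`forward_TR`.  With the ``mc`` engine
        node ``(i, j)`` uses seed ``seed + i * len(mua_axis) + j`` so that
        rebuilding with the same seed is bit-identical.
    """
    g, n_slab, n_ambient, d = fixed
    x = np.asarray(mus_prime_axis, dtype=float)
    y = np.asarray(mua_axis, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each LUT axis needs at least 2 nodes")
    table_t = np.zeros((x.size, y.size))
    table_r = np.zeros((x.size, y.size))
    for i, mus_prime in enumerate(x):
        for j, mua in enumerate(y):
            slab = OpticalSlab(
                d=d, mus_prime=mus_prime, mua=mua, g=g,
                n_slab=n_slab, n_ambient=n_ambient,
            )
            node_seed = seed + i * y.size + j
            table_t[i, j], table_r[i, j] = forward_TR(
                slab, engine=engine, budget=budget, seed=node_seed
            )
    return LookupTable(
        grid_mus_prime=x,
        grid_mua=y,
        g=g,
        n_slab=n_slab,
        n_ambient=n_ambient,
        d=d,
        table_t=table_t,
        table_r=table_r,
        engine=engine,
        budget=budget,
        seed=seed,
    )


def _newton_root(it, ir, target, p0, bounds, tol=1e-12, max_iter=200):
    """Damped Newton on the interpolated (T, R) map in (mus', log mua)."""

    def residual(p):
        return np.array(
            [it(p).item() - target[0], ir(p).item() - target[1]]
        )

    lo = np.array([bounds[0][0], bounds[1][0]])
    hi = np.array([bounds[0][1], bounds[1][1]])
    h = 1e-7 * (hi - lo)
    p = np.array(p0, dtype=float)
    f = residual(p)
    for _ in range(max_iter):
        norm = np.linalg.norm(f)
        if norm < tol:
            break
        jac = np.empty((2, 2))
        for k in range(2):
            pp = p.copy()
            pm = p.copy()
            pp[k] = min(pp[k] + h[k], hi[k])
            pm[k] = max(pm[k] - h[k], lo[k])
            jac[:, k] = (residual(pp) - residual(pm)) / (pp[k] - pm[k])
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        improved = False
        for _ in range(40):
            pn = np.clip(p + lam * step, lo, hi)
            fn = residual(pn)
            if np.linalg.norm(fn) < norm:
                p, f = pn, fn
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
    return p, np.linalg.norm(f)


def invert(T_meas: float, R_meas: float, lut: LookupTable):
    """Recover ``(mus', mua)`` from measured total hemispherical ``(T, R)``.

    Continuous 2D root finding (damped Newton with grid-scan
    initialization) on the bilinearly interpolated forward surfaces.

    Returns
    -------
    (mus_prime_hat, mua_hat, diagnostics)
        ``diagnostics`` holds the residual norm ``||(dT, dR)||``, iteration
        metadata and the bracketing cell indices.

    Raises
    ------
    LUTRangeError
        If ``(T, R)`` is unphysical or outside the table's range.
    LUTAmbiguityError
        If distinct starting cells converge to distinct solutions.
    """
    if not (0 <= T_meas <= 1 and 0 <= R_meas <= 1):
        raise LUTRangeError("T and R must lie in [0, 1]")
    if T_meas + R_meas > 1.0:
        raise LUTRangeError(
            f"infeasible pair: T + R = {T_meas + R_meas:.4f} > 1"
        )
    tt, rr = lut.table_t, lut.table_r
    if not (tt.min() <= T_meas <= tt.max()):
        raise LUTRangeError(
            f"T={T_meas:.4g} outside table range "
            f"[{tt.min():.4g}, {tt.max():.4g}] (mua/mus_prime axes too narrow)"
        )
    if not (rr.min() <= R_meas <= rr.max()):
        raise LUTRangeError(
            f"R={R_meas:.4g} outside table range "
            f"[{rr.min():.4g}, {rr.max():.4g}] (mus_prime axis too narrow)"
        )

    it, ir = lut.interpolators()
    x = lut.grid_mus_prime
    y = np.log(lut.grid_mua)
    bounds = ((x[0], x[-1]), (y[0], y[-1]))
    target = (T_meas, R_meas)

    # Grid scan for starting nodes, best three distinct cells.
    err = (tt - T_meas) ** 2 + (rr - R_meas) ** 2
    flat_order = np.argsort(err.ravel())
    starts = []
    for idx in flat_order:
        i, j = np.unravel_index(idx, err.shape)
        if all(abs(i - i0) > 1 or abs(j - j0) > 1 for i0, j0 in starts):
            starts.append((i, j))
        if len(starts) == 3:
            break

    solutions = []
    for i, j in starts:
        p0 = (x[i], y[j])
        p, res = _newton_root(it, ir, target, p0, bounds)
        solutions.append((p, res))

    tol_accept = 1e-8
    converged = [(p, r) for p, r in solutions if r < tol_accept]
    if not converged:
        best = min(solutions, key=lambda s: s[1])
        raise LUTRangeError(
            f"no interpolated forward state matches (T={T_meas:.4g}, "
            f"R={R_meas:.4g}); best residual {best[1]:.3g}"
        )
    p_best, res_best = min(converged, key=lambda s: s[1])
    span = np.array([x[-1] - x[0], y[-1] - y[0]])
    for p, _ in converged:
        if np.any(np.abs(p - p_best) > 0.02 * span):
            raise LUTAmbiguityError(
                "multiple distinct (mus', mua) states reproduce the "
                f"measurement: {p_best} vs {p}"
            )
    mus_prime_hat = float(p_best[0])
    mua_hat = float(math.exp(p_best[1]))
    ci = int(np.clip(np.searchsorted(x, p_best[0]) - 1, 0, x.size - 2))
    cj = int(np.clip(np.searchsorted(y, p_best[1]) - 1, 0, y.size - 2))
    diagnostics = {
        "residual": res_best,
        "cell": (ci, cj),
        "n_starts": len(starts),
    }
    return mus_prime_hat, mua_hat, diagnostics


def jacobian_singular_values(lut: LookupTable) -> np.ndarray:
    """Smallest singular value of d(T,R)/d(mus', log mua) in each cell.

    Evaluated at cell centers by central differences on the interpolated
    surfaces; all-positive values certify local uniqueness of the
    inversion.
    """
    it, ir = lut.interpolators()
    x = lut.grid_mus_prime
    y = np.log(lut.grid_mua)
    xc = 0.5 * (x[:-1] + x[1:])
    yc = 0.5 * (y[:-1] + y[1:])
    out = np.zeros((xc.size, yc.size))
    hx = 0.25 * np.diff(x)
    hy = 0.25 * np.diff(y)
    for i, xv in enumerate(xc):
        for j, yv in enumerate(yc):
            jac = np.empty((2, 2))
            for func, row in ((it, 0), (ir, 1)):
                jac[row, 0] = (
                    func((xv + hx[i], yv)).item() - func((xv - hx[i], yv)).item()
                ) / (2 * hx[i])
                jac[row, 1] = (
                    func((xv, yv + hy[j])).item() - func((xv, yv - hy[j])).item()
                ) / (2 * hy[j])
            out[i, j] = np.linalg.svd(jac, compute_uv=False)[-1]
    return out
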