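"""Random-phasor simulation of feedback wavefront shaping.

The field at the detector behind a strongly scattering slab is modelled as
a sum of ``N`` independent transmission channels, one per controllable
phase segment of the modulator: ``E = sum_n t_n exp(i phi_n)`` with
``t_n`` i.i.d. circular Gaussian (fully developed speckle).  The stepwise
sequential algorithm (SSA) sweeps one segment's phase at a time over ``K``
equispaced levels, commits the best level after the sweep, and moves on.
The achieved enhancement is quantified by the peak-to-background ratio
(PBR): optimized intensity relative to the mean intensity over random
phase patterns of the same segmentation.

For phase-only control of fully developed speckle the expected enhancement
is ``eta = (pi/4)(N - 1) + 1``.

Two instrument imperfections can be modelled: an uncontrollable intensity
background (a fixed floor of ``beta`` times the mean speckle intensity,
standing in for residual amplitude modulation of a phase-only modulator)
and additive detector noise with standard deviation ``noise_sigma`` times
the mean speckle intensity.  Both scale with the channel power, so a
common attenuation of all ``t_n`` (absorption) leaves the PBR invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optics_core import DetectionAperture
from .pn_solver import partial_transmittance

__all__ = [
    "PhasorField",
    "WFSRun",
    "enhancement_theory",
    "run_ssa",
    "power_plan",
]


def enhancement_theory(n_segments: float) -> float:
    """Theoretical phase-only enhancement ``eta = (pi/4)(N - 1) + 1``.

    ``n_segments`` may be fractional (partially illuminated segments act as
    an effective segment count below one).
    """
    if n_segments <= 0:
        raise ValueError("segment count must be positive")
    return math.pi / 4.0 * (n_segments - 1.0) + 1.0


@dataclass
class PhasorField:
    """Complex transmission channels of one speckle realization.

    ``t[n]`` couples segment ``n`` to the detector; ``background_leak``
    (``beta``) and ``noise_sigma`` are expressed relative to the mean
    speckle intensity ``sum_n |t_n|^2``.
    """

    t: np.ndarray
    background_leak: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=complex)
        if self.t.ndim != 1 or self.t.size < 1:
            raise ValueError("t must be a 1D array with >= 1 channels")
        if not 0 <= self.background_leak < 1:
            raise ValueError("background_leak must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def n_segments(self) -> int:
        return self.t.size

    @property
    def mean_intensity(self) -> float:
        """Mean detected speckle intensity over random phases, sum |t_n|^2."""
        return float(np.sum(np.abs(self.t) ** 2))

    @classmethod
    def draw(
        cls,
        n_segments: int,
        seed: int,
        background_leak: float = 0.0,
        noise_sigma: float = 0.0,
    ) -> "PhasorField":
        """Draw i.i.d. circular-Gaussian channels CN(0, 1)."""
        if n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        rng = np.random.default_rng(seed)
        t = (
            rng.standard_normal(n_segments)
            + 1j * rng.standard_normal(n_segments)
        ) / math.sqrt(2.0)
        return cls(t=t, background_leak=background_leak, noise_sigma=noise_sigma)

    def detect(self, phases: np.ndarray, rng: np.random.Generator | None = None):
        """Detected intensity for a phase pattern (floor and noise applied)."""
        e = self.t @ np.exp(1j * np.asarray(phases))
        i_det = float(np.abs(e) ** 2) + self.background_leak * self.mean_intensity
        if self.noise_sigma > 0:
            if rng is None:
                raise ValueError("noise_sigma > 0 requires an rng")
            i_det += self.noise_sigma * self.mean_intensity * rng.standard_normal()
        return i_det


@dataclass
class WFSRun:
    """Outcome of one SSA optimization run."""

    n_segments: int
    optimized_phases: np.ndarray = field(repr=False)
    i_peak: float
    i_background: float
    pbr: float
    n_phase_steps: int
    n_background: int
    seed: int

    @property
    def eta(self) -> float:
        """Reported enhancement (identified with the measured PBR)."""
        return self.pbr


def _sweep_intensities(field, phases, idx, phi_grid, rng):
    """Detected intensities sweeping segment ``idx`` over ``phi_grid``."""
    e_rest = field.t @ np.exp(1j * phases) - field.t[idx] * np.exp(
        1j * phases[idx]
    )
    e = e_rest + field.t[idx] * np.exp(1j * phi_grid)
    i_det = np.abs(e) ** 2 + field.background_leak * field.mean_intensity
    if field.noise_sigma > 0:
        i_det = i_det + field.noise_sigma * field.mean_intensity * (
            rng.standard_normal(phi_grid.size)
        )
    return i_det


def run_ssa(
    field: PhasorField,
    n_phase_steps: int = 16,
    n_background: int = 100,
    seed: int = 0,
    phase_estimator: str = "argmax",
    n_cycles: int = 2,
) -> WFSRun:
    """Stepwise sequential optimization of the segment phases.

    Each segment in turn is swept over ``n_phase_steps`` equispaced phase
    levels with all other segments held fixed; its phase is then committed
    (to the argmax level, or to the continuous optimum of a cosine fit when
    ``phase_estimator="cosine"``) before the next segment is swept.  During
    the first cycle each segment is aligned against a rest-field that later
    segments still modify, so ``n_cycles = 2`` (default) runs a second
    full pass to let every phase settle against the converged pattern.

    ``i_peak`` is the best intensity *measured* during the final segment's
    sweep — the max-statistic an experiment records — so for very small
    ``N`` under noise the resulting PBR is biased above the theoretical
    enhancement.  ``i_background`` averages ``n_background`` random uniform
    phase patterns of the same segmentation.
    """
    if n_phase_steps < 3:
        raise ValueError("n_phase_steps must be >= 3")
    if n_background < 1:
        raise ValueError("n_background must be >= 1")
    if phase_estimator not in ("argmax", "cosine"):
        raise ValueError("phase_estimator must be 'argmax' or 'cosine'")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    n = field.n_segments
    k = n_phase_steps
    phi_grid = 2.0 * math.pi * np.arange(k) / k
    phases = np.zeros(n)
    i_peak = None
    for _ in range(n_cycles):
        for idx in range(n):
            i_det = _sweep_intensities(field, phases, idx, phi_grid, rng)
            if phase_estimator == "argmax":
                best = int(np.argmax(i_det))
                phases[idx] = phi_grid[best]
                i_peak = float(i_det[best])
            else:
                # single-frequency cosine fit: I(phi) = a0 + a1 cos(phi-phi0)
                c = np.sum(i_det * np.cos(phi_grid))
                s = np.sum(i_det * np.sin(phi_grid))
                phases[idx] = math.atan2(s, c)
                i_peak = float(np.max(i_det))
    if i_peak is None:  # pragma: no cover - n >= 1 guaranteed
        i_peak = field.detect(phases, rng if field.noise_sigma > 0 else None)
    if phase_estimator == "cosine":
        # re-measure at the committed (off-grid) pattern
        i_peak = field.detect(phases, rng if field.noise_sigma > 0 else None)

    bg = 0.0
    for _ in range(n_background):
        rand_phases = rng.uniform(0.0, 2.0 * math.pi, n)
        bg += field.detect(
            rand_phases, rng if field.noise_sigma > 0 else None
        )
    i_background = bg / n_background
    pbr = i_peak / i_background
    return WFSRun(
        n_segments=n,
        optimized_phases=phases,
        i_peak=i_peak,
        i_background=i_background,
        pbr=pbr,
        n_phase_steps=k,
        n_background=n_background,
        seed=seed,
    )


def power_plan(
    samples,
    reference_id: str,
    aperture: DetectionAperture,
    order: int | None = None,
) -> dict:
    """Per-sample laser power factors equalizing the detected transmittance.

    ``factor_i = T_NA(reference) / T_NA(sample_i)`` so that
    ``factor_i * T_NA(sample_i)`` is the same for every sample and the
    reference factor is exactly 1.
    """
    samples = list(samples)
    ids = [s.sample_id for s in samples]
    if reference_id not in ids:
        raise ValueError(f"reference sample {reference_id!r} not in the set")
    t_na = {}
    for slab in samples:
        pt = partial_transmittance(slab, aperture, order=order)
        if pt.t_na <= 0:
            raise ValueError(
                f"sample {slab.sample_id!r} has zero partial transmittance"
            )
        t_na[slab.sample_id] = pt.t_na
    ref = t_na[reference_id]
    return {sid: ref / val for sid, val in t_na.items()}
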