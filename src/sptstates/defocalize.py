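"""Defocalization: loss of emitters from the focal slab by axial diffusion.

Fast-moving particles leave the detection slab quickly, so they are
underrepresented in the observed jumps relative to slow particles. The
fraction of a state's particles that remain in focus after one frame
interval,

    eta(D) = integral of T(z) * [f0 * g](z) dz,

with f0 uniform on the slab, g the Gaussian Green's function of variance
2*D*dt, and T the slab transmission function, quantifies this bias; state
occupations are corrected by dividing by eta and renormalizing.

The propagator works on a regular axial grid: convolution with the sampled
Green's function followed by multiplication with the transmission
function. Slab edges are handled with fractional cell overlap so the
quadrature error is second order in the grid step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .profiles import OccupationProfile

__all__ = [
    "AxialProfile",
    "TransmissionFunction",
    "diffuse_step",
    "fraction_in_focus",
    "correct_occupations",
]


@dataclass
class AxialProfile:
    """Density of particles along the optical axis on a regular grid."""

    z_grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.z_grid.shape != self.density.shape or self.z_grid.ndim != 1:
            raise ValueError("z_grid and density must be equal-length 1D arrays")
        steps = np.diff(self.z_grid)
        if self.z_grid.size < 2 or not np.allclose(steps, steps[0]):
            raise ValueError("z_grid must be regular with at least two points")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    @property
    def dz_step(self) -> float:
        return float(self.z_grid[1] - self.z_grid[0])

    def mass(self) -> float:
        return float(self.density.sum() * self.dz_step)


@dataclass(frozen=True)
class TransmissionFunction:
    """Axial detection profile. Only the ideal slab is implemented:
    T(z) = 1 for |z| <= focal_depth/2, else 0."""

    focal_depth: float
    kind: str = "slab"

    def __post_init__(self) -> None:
        if self.kind != "slab":
            raise NotImplementedError("only the slab transmission function is supported")
        if not self.focal_depth > 0:
            raise ValueError("focal_depth must be > 0")

    def sample(self, z: np.ndarray, step: float) -> np.ndarray:
        """Fraction of each grid cell [z-step/2, z+step/2] inside the slab."""
        half = self.focal_depth / 2.0
        lo = np.clip(z - step / 2.0, -half, half)
        hi = np.clip(z + step / 2.0, -half, half)
        return np.maximum(hi - lo, 0.0) / step


def diffuse_step(f: AxialProfile, D: float, dt: float,
                 T: TransmissionFunction) -> AxialProfile:
    """One frame interval of axial diffusion followed by detection.

    Convolves the density with the Brownian Green's function of variance
    2*D*dt, then multiplies by the transmission function. Total mass never
    increases.
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    step = f.dz_step
    tz = T.sample(f.z_grid, step)
    if D == 0:
        return replace(f, density=f.density * tz)
    sigma = np.sqrt(2.0 * D * dt)
    if step > sigma / 4.0:
        raise ValueError(
            f"axial grid step {step:.3g} um too coarse for sigma_z={sigma:.3g} um; "
            "refine to at most sigma_z/4"
        )
    half_width = int(np.ceil(6.0 * sigma / step))
    kz = np.arange(-half_width, half_width + 1) * step
    kernel = np.exp(-kz**2 / (4.0 * D * dt)) / np.sqrt(4.0 * np.pi * D * dt) * step
    spread = fftconvolve(f.density, kernel, mode="same")
    np.clip(spread, 0.0, None, out=spread)
    return replace(f, density=spread * tz)


def _uniform_slab_profile(focal_depth: float, sigma: float, n_frames: int) -> AxialProfile:
    # choose the step so the slab half-depth is an integer number of cells:
    # slab edges then fall on cell boundaries and the transmission mask is
    # exact, keeping the quadrature second order
    target = min(focal_depth / 200.0, sigma / 8.0) if sigma > 0 else focal_depth / 200.0
    half = focal_depth / 2.0
    step = half / int(np.ceil(half / target))
    extent = half + 6.0 * sigma * np.sqrt(max(n_frames, 1))
    n = int(np.ceil(extent / step))
    # cell centers offset by step/2 so boundaries sit at multiples of step
    z = (np.arange(-n, n) + 0.5) * step
    T = TransmissionFunction(focal_depth)
    density = T.sample(z, step) / focal_depth  # unit mass on the slab
    return AxialProfile(z, density)


def fraction_in_focus(D: float, dt: float, focal_depth: float,
                      n_frames: int = 1) -> float:
    """Probability that a particle uniform in the slab is still in the slab
    after ``n_frames`` frame intervals of Brownian motion with coefficient D.

    Monotonically decreasing in D and in n_frames; eta = 1 at D = 0.
    """
    if not focal_depth > 0:
        raise ValueError("focal_depth must be > 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if D < 0:
        raise ValueError("D must be >= 0")
    sigma = np.sqrt(2.0 * D * dt)
    if sigma < focal_depth * 1e-4:
        # axial step negligible relative to the slab; mass loss < ~1e-4
        return 1.0
    f = _uniform_slab_profile(focal_depth, sigma, n_frames)
    T = TransmissionFunction(focal_depth)
    for _ in range(n_frames):
        f = diffuse_step(f, D, dt, T)
    return float(min(f.mass(), 1.0))


def correct_occupations(profile: OccupationProfile, dt: float,
                        focal_depth: float) -> OccupationProfile:
    """Divide each state's occupation by its one-frame in-focus fraction
    and renormalize.

    The in-focus fraction depends only on the diffusion coefficient (for
    FBME vertices, the modified scaling coefficient plays the role of the
    effective one-frame D, since the first increment is Gaussian with
    variance 2*S-bar*dt). Double correction is refused.
    """
    if profile.corrected:
        raise ValueError("profile is already defocalization-corrected")
    D = profile.diffusion_values
    eta = np.array([fraction_in_focus(d, dt, focal_depth) for d in D])
    if np.any(eta <= 0):
        bad = int(np.flatnonzero(eta <= 0)[0])
        raise ValueError(
            f"in-focus fraction underflowed to zero at D={D[bad]:.4g} um^2/s"
        )
    shape = (-1,) + (1,) * (profile.occupations.ndim - 1)
    occ = profile.occupations / eta.reshape(shape)
    occ /= occ.sum()
    return replace(profile, occupations=occ, corrected=True)
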