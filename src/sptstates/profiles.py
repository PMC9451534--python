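"""Occupation profiles over state-parameter grids."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .grid import ParameterGrid

__all__ = [
    "OccupationProfile",
    "marginalize_loc_error",
    "occupation_in_range",
    "mean_free_diffusion",
]


@dataclass
class OccupationProfile:
    """Posterior (or naive) state occupations on a parameter grid.

    ``occupations`` is shaped over the retained grid axes in order
    (diffusion[, hurst][, loc_error]); axes that have been marginalized out
    carry ``None`` for their value arrays. Occupations are nonnegative and
    sum to one. ``corrected`` marks that the defocalization correction has
    been applied; a corrected profile must not be corrected twice.
    """

    occupations: np.ndarray
    diffusion_values: np.ndarray
    motion_kind: str = "rbme"
    loc_error_values: np.ndarray | None = None
    hurst_values: np.ndarray | None = None
    corrected: bool = False

    def __post_init__(self) -> None:
        self.occupations = np.asarray(self.occupations, dtype=np.float64)
        if np.any(self.occupations < -1e-12):
            raise ValueError("occupations must be nonnegative")
        expect = [self.diffusion_values.size]
        if self.hurst_values is not None:
            expect.append(self.hurst_values.size)
        if self.loc_error_values is not None:
            expect.append(self.loc_error_values.size)
        if self.occupations.shape != tuple(expect):
            raise ValueError(
                f"occupations shape {self.occupations.shape} does not match axes {tuple(expect)}"
            )

    @classmethod
    def from_grid(cls, occupations_flat: np.ndarray, grid: ParameterGrid,
                  corrected: bool = False) -> "OccupationProfile":
        occ = np.asarray(occupations_flat, dtype=np.float64).reshape(grid.shape)
        return cls(
            occ,
            grid.diffusion_values,
            grid.motion_kind,
            loc_error_values=grid.loc_error_values,
            hurst_values=grid.hurst_values,
            corrected=corrected,
        )

    def diffusion_marginal(self) -> np.ndarray:
        """Occupations summed onto the diffusion axis."""
        occ = self.occupations
        while occ.ndim > 1:
            occ = occ.sum(axis=-1)
        return occ

    def total(self) -> float:
        return float(self.occupations.sum())


def marginalize_loc_error(profile: OccupationProfile) -> OccupationProfile:
    """Sum occupations over the localization-error axis.

    Total mass is preserved exactly; for FBME grids the (scaling, Hurst)
    axes are retained.
    """
    if profile.loc_error_values is None:
        warnings.warn("profile has no localization-error axis; returning unchanged",
                      stacklevel=2)
        return profile
    occ = profile.occupations.sum(axis=-1)
    return replace(profile, occupations=occ, loc_error_values=None)


def occupation_in_range(profile: OccupationProfile, d_min: float, d_max: float) -> float:
    """Total occupation at grid vertices with d_min <= D < d_max (half-open)."""
    if not (0 <= d_min < d_max):
        raise ValueError("require 0 <= d_min < d_max")
    D = profile.diffusion_values
    mask = (D >= d_min) & (D < d_max)
    if not mask.any():
        warnings.warn(f"no grid vertices in [{d_min}, {d_max})", stacklevel=2)
        return 0.0
    return float(profile.diffusion_marginal()[mask].sum())


def mean_free_diffusion(profile: OccupationProfile, threshold: float = 0.05) -> float:
    """Occupation-weighted mean diffusion coefficient above a threshold.

    The default threshold 0.05 um^2/s separates the immobile fraction from
    freely diffusing states.
    """
    D = profile.diffusion_values
    occ = profile.diffusion_marginal()
    mask = D >= threshold
    mass = occ[mask].sum()
    if mass <= 0:
        raise ValueError(f"no occupation above threshold {threshold}")
    return float((D[mask] * occ[mask]).sum() / mass)
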