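"""Fixed parameter grids for state-array inference.

A state array replaces the unknown number of diffusive states by a dense,
fixed grid of candidate states; inference then drives the occupation of
most grid vertices to zero. For Brownian motion with localization error
(RBME) the grid spans diffusion coefficient x localization error; for
fractional Brownian motion (FBME) it spans modified scaling coefficient x
Hurst parameter x localization error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ParameterGrid"]

#: default diffusion-coefficient support, um^2/s (log-spaced)
D_MIN, D_MAX = 1e-2, 1e2
#: default localization-error support, um (linear)
SIGMA_MAX = 0.06


@dataclass(frozen=True)
class ParameterGrid:
    """Grid of candidate state parameters.

    Parameters
    ----------
    motion_kind : {"rbme", "fbme"}
        Motion model of every vertex.
    diffusion_values : ndarray
        Strictly increasing diffusion coefficients D (um^2/s) for RBME, or
        modified scaling coefficients S-bar (um^2/s) for FBME.
    loc_error_values : ndarray
        Strictly increasing localization-error standard deviations
        sigma_loc (um).
    hurst_values : ndarray, optional
        Strictly increasing Hurst parameters in (0, 1); FBME only.

    Vertices are ordered C-style over (diffusion, [hurst,] loc_error).
    """

    motion_kind: str
    diffusion_values: np.ndarray
    loc_error_values: np.ndarray
    hurst_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "diffusion_values", np.asarray(self.diffusion_values, dtype=np.float64)
        )
        object.__setattr__(
            self, "loc_error_values", np.asarray(self.loc_error_values, dtype=np.float64)
        )
        if self.motion_kind not in ("rbme", "fbme"):
            raise ValueError("motion_kind must be 'rbme' or 'fbme'")
        for name in ("diffusion_values", "loc_error_values"):
            v = getattr(self, name)
            if v.ndim != 1 or v.size < 1:
                raise ValueError(f"{name} must be a nonempty 1D array")
            if v.size > 1 and not np.all(np.diff(v) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            if np.any(v < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.motion_kind == "fbme":
            if self.hurst_values is None:
                raise ValueError("fbme grid requires hurst_values")
            h = np.asarray(self.hurst_values, dtype=np.float64)
            object.__setattr__(self, "hurst_values", h)
            if h.ndim != 1 or h.size < 1 or (h.size > 1 and not np.all(np.diff(h) > 0)):
                raise ValueError("hurst_values must be a nonempty increasing 1D array")
            if np.any((h <= 0) | (h >= 1)):
                raise ValueError("hurst_values must lie in (0, 1)")
        elif self.hurst_values is not None:
            raise ValueError("hurst_values only valid for fbme grids")

    # -- shape -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        if self.motion_kind == "rbme":
            return (self.diffusion_values.size, self.loc_error_values.size)
        return (
            self.diffusion_values.size,
            self.hurst_values.size,
            self.loc_error_values.size,
        )

    @property
    def K(self) -> int:
        return int(np.prod(self.shape))

    # -- flattened vertex coordinates ------------------------------------
    def vertex_arrays(self) -> dict[str, np.ndarray]:
        """Flattened (K,) coordinate arrays for every vertex."""
        if self.motion_kind == "rbme":
            D, sig = np.meshgrid(self.diffusion_values, self.loc_error_values, indexing="ij")
            return {"diffusion": D.ravel(), "loc_error": sig.ravel()}
        S, H, sig = np.meshgrid(
            self.diffusion_values, self.hurst_values, self.loc_error_values, indexing="ij"
        )
        return {"diffusion": S.ravel(), "hurst": H.ravel(), "loc_error": sig.ravel()}

    # -- constructors ----------------------------------------------------
    @classmethod
    def default_rbme(
        cls,
        d_min: float = D_MIN,
        d_max: float = D_MAX,
        n_diffusion: int = 101,
        sigma_max: float = SIGMA_MAX,
        n_loc_error: int = 36,
    ) -> "ParameterGrid":
        """Default RBME grid: D log-spaced on [1e-2, 1e2] um^2/s,
        sigma_loc linear on [0, 0.06] um."""
        return cls(
            "rbme",
            np.logspace(np.log10(d_min), np.log10(d_max), n_diffusion),
            np.linspace(0.0, sigma_max, n_loc_error),
        )

    @classmethod
    def default_fbme(
        cls,
        s_min: float = D_MIN,
        s_max: float = D_MAX,
        n_scale: int = 31,
        n_hurst: int = 19,
        sigma_max: float = SIGMA_MAX,
        n_loc_error: int = 13,
    ) -> "ParameterGrid":
        """Default FBME grid: S-bar log-spaced, H linear on (0, 1),
        sigma_loc linear on [0, 0.06] um."""
        return cls(
            "fbme",
            np.logspace(np.log10(s_min), np.log10(s_max), n_scale),
            np.linspace(0.0, sigma_max, n_loc_error),
            np.linspace(0.05, 0.95, n_hurst),
        )
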