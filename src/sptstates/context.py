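"""Spatial and temporal aggregation of per-trajectory posteriors.

State arrays infer a posterior distribution over states for every
trajectory jointly with the global occupations. Aggregating those
individual distributions by the trajectories' positions (Gaussian kernel
density maps per diffusion range) or by their starting frames (naive
profiles per temporal block) reveals where and when each diffusive
subpopulation lives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import TrajectoryDataset
from .grid import ParameterGrid
from .state_array import StateArrayPosterior, naive_occupations

__all__ = [
    "DiffusionRangeSet",
    "OccupationMap",
    "trajectory_posteriors",
    "spatial_occupation_map",
    "temporal_naive_profile",
]


@dataclass(frozen=True)
class DiffusionRangeSet:
    """Named, disjoint half-open diffusion-coefficient intervals (um^2/s)."""

    names: tuple
    bounds: tuple  # of (d_min, d_max) pairs

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "bounds", tuple(tuple(b) for b in self.bounds))
        if len(self.names) != len(self.bounds) or not self.names:
            raise ValueError("names and bounds must be nonempty and equal-length")
        ivs = sorted(self.bounds)
        for (a, b) in ivs:
            if not (0 <= a < b):
                raise ValueError(f"invalid interval [{a}, {b})")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ValueError("intervals must be disjoint")

    def __len__(self) -> int:
        return len(self.names)

    def masks(self, d_values: np.ndarray) -> np.ndarray:
        """(n_ranges, n_D) boolean membership of grid vertices."""
        d = np.asarray(d_values)
        return np.stack([(d >= a) & (d < b) for a, b in self.bounds])


@dataclass
class OccupationMap:
    """Per-range spatial density and normalized fractional occupation."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: dict  # range name -> 2D density surface
    fraction: dict  # range name -> 2D normalized fraction (NaN where masked)
    bandwidth: float


def trajectory_posteriors(post: StateArrayPosterior) -> np.ndarray:
    """Per-trajectory posterior distributions over the diffusion axis.

    Row i is the responsibility vector r_i marginalized over the
    localization-error (and Hurst) axes; each row sums to 1.
    """
    shape = (post.r.shape[0],) + post.grid.shape
    r = post.r.reshape(shape)
    while r.ndim > 2:
        r = r.sum(axis=-1)
    return r


def spatial_occupation_map(
    ds: TrajectoryDataset,
    posteriors: np.ndarray,
    ranges: DiffusionRangeSet,
    grid: ParameterGrid | None = None,
    d_values: np.ndarray | None = None,
    bandwidth: float = 0.1,
    pixel: float = 0.1,
    anchor: str = "first",
    density_floor: float = 1e-3,
) -> OccupationMap:
    """Gaussian-kernel density maps of posterior mass per diffusion range.

    Each trajectory contributes, at its anchor point (first observed
    position by default, or the mean position), a weight equal to its
    posterior mass inside each range; a Gaussian KDE with the given
    bandwidth (um) is evaluated per range on a regular pixel grid. The
    normalized fractional map divides each range's density by the summed
    density, masked (NaN) where the sum falls below ``density_floor``
    times its maximum.
    """
    if d_values is None:
        if grid is None:
            raise ValueError("provide grid or d_values")
        d_values = grid.diffusion_values
    posteriors = np.asarray(posteriors, dtype=np.float64)
    if posteriors.shape != (ds.N, d_values.size):
        raise ValueError("posteriors must be (N, n_D) aligned with the dataset")
    if anchor == "first":
        pts = np.array([t.positions[0] for t in ds.trajectories])
    elif anchor == "mean":
        pts = np.array([t.positions.mean(axis=0) for t in ds.trajectories])
    else:
        raise ValueError("anchor must be 'first' or 'mean'")
    masks = ranges.masks(d_values)  # (R, nD)
    weights = posteriors @ masks.T  # (N, R)

    pad = 3.0 * bandwidth
    x0, x1 = pts[:, 0].min() - pad, pts[:, 0].max() + pad
    y0, y1 = pts[:, 1].min() - pad, pts[:, 1].max() + pad
    x_edges = np.arange(x0, x1 + pixel, pixel)
    y_edges = np.arange(y0, y1 + pixel, pixel)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])

    # brute-force separable Gaussian sums; trajectory counts are modest
    gx = np.exp(-0.5 * ((xc[None, :] - pts[:, 0, None]) / bandwidth) ** 2)
    gy = np.exp(-0.5 * ((yc[None, :] - pts[:, 1, None]) / bandwidth) ** 2)
    norm = 1.0 / (2.0 * np.pi * bandwidth**2)
    density = {}
    for j, name in enumerate(ranges.names):
        w = weights[:, j]
        if w.sum() <= 0:
            warnings.warn(f"range {name!r} has zero posterior weight", stacklevel=2)
        density[name] = norm * np.einsum("n,nx,ny->xy", w, gx, gy)
    total = np.sum(list(density.values()), axis=0)
    floor = density_floor * total.max() if total.size and total.max() > 0 else np.inf
    fraction = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in ranges.names:
            f = density[name] / total
            f[total < floor] = np.nan
            fraction[name] = f
    return OccupationMap(x_edges, y_edges, density, fraction, bandwidth)


def temporal_naive_profile(
    ds: TrajectoryDataset,
    grid: ParameterGrid,
    block: int = 100,
) -> list[dict]:
    """Naive occupation profiles over temporal blocks of frames.

    Trajectories are assigned to half-open blocks [b*block, (b+1)*block)
    by their starting frame; the naive (zero-iteration) occupation profile
    is computed per block. Blocks without trajectories are recorded with
    ``profile=None``.
    """
    from .likelihood import evaluate_grid

    if block < 1:
        raise ValueError("block must be >= 1 frame")
    starts = np.array([int(t.frames[0]) for t in ds.trajectories])
    block_idx = starts // block
    out = []
    for b in range(int(block_idx.min()), int(block_idx.max()) + 1):
        sel = np.flatnonzero(block_idx == b)
        rec = {
            "block": b,
            "frame_start": b * block,
            "n_trajectories": int(sel.size),
            "n_localizations": int(sum(len(ds.trajectories[i]) for i in sel)),
            "profile": None,
        }
        if sel.size:
            sub = TrajectoryDataset([ds.trajectories[i] for i in sel], ds.acquisition)
            A = evaluate_grid(sub, grid)
            rec["profile"] = naive_occupations(A)
        out.append(rec)
    return out
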