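"""Trajectory data model and table I/O.

Positions are stored in micrometers. A trajectory is a sequence of
positions measured at strictly consecutive frame intervals; the quantities
used by every downstream likelihood are the jumps (frame-to-frame
displacements), their count ``L`` and the sum of squared 2D jump lengths
``S``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionParams",
    "Trajectory",
    "TrajectoryDataset",
    "read_trajectories",
    "write_trajectories",
    "dataset_summary",
    "TrajectoryFormatError",
]


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory table cannot be interpreted."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata for an SPT experiment.

    Parameters
    ----------
    frame_interval : float
        Time between frames in seconds.
    pixel_size : float
        Camera pixel size in the sample plane, micrometers per pixel.
    focal_depth : float
        Axial extent of the detection slab, micrometers.
    start_frame : int
        Frame index below which localizations are discarded. Experimental
        movies often have a dense initial photoactivation phase; 1000 is a
        common choice for imports, 0 for simulated data.
    """

    frame_interval: float = 0.00748
    pixel_size: float = 0.16
    focal_depth: float = 0.7
    start_frame: int = 0

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.focal_depth > 0:
            raise ValueError("focal_depth must be > 0")
        if self.start_frame < 0:
            raise ValueError("start_frame must be >= 0")


@dataclass
class Trajectory:
    """A single tracked emitter observed over consecutive frames.

    ``positions`` is an (n, 2) array of (x, y) in micrometers; ``frames``
    the corresponding integer frame indices, strictly increasing in unit
    steps.
    """

    id: int
    frames: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if self.frames.shape[0] != self.positions.shape[0]:
            raise ValueError("frames and positions must have equal length")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError(
                "frames must be strictly increasing with unit steps; "
                "split gapped trajectories before constructing Trajectory"
            )

    @property
    def jumps(self) -> np.ndarray:
        """(L, 2) array of frame-to-frame displacements in micrometers."""
        return np.diff(self.positions, axis=0)

    @property
    def L(self) -> int:
        """Number of jumps."""
        return self.positions.shape[0] - 1

    @property
    def S(self) -> float:
        """Sum of squared 2D jump lengths, squared micrometers."""
        d = self.jumps
        return float(np.sum(d * d))

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class TrajectoryDataset:
    """A collection of trajectories plus acquisition metadata."""

    trajectories: list[Trajectory]
    acquisition: AcquisitionParams
    report: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.trajectories)

    @property
    def total_jumps(self) -> int:
        return int(sum(t.L for t in self.trajectories))

    def jump_counts(self) -> np.ndarray:
        return np.array([t.L for t in self.trajectories], dtype=np.int64)

    def sum_squared_jumps(self) -> np.ndarray:
        return np.array([t.S for t in self.trajectories], dtype=np.float64)

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self) -> int:
        return self.N

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns id, frame, x_um, y_um."""
        ids, frames, xs, ys = [], [], [], []
        for t in self.trajectories:
            ids.append(np.full(len(t), t.id, dtype=np.int64))
            frames.append(t.frames)
            xs.append(t.positions[:, 0])
            ys.append(t.positions[:, 1])
        return pd.DataFrame(
            {
                "id": np.concatenate(ids) if ids else np.array([], dtype=np.int64),
                "frame": np.concatenate(frames) if frames else np.array([], dtype=np.int64),
                "x_um": np.concatenate(xs) if xs else np.array([]),
                "y_um": np.concatenate(ys) if ys else np.array([]),
            }
        )

    @classmethod
    def from_arrays(
        cls,
        ids: np.ndarray,
        frames: np.ndarray,
        xy_um: np.ndarray,
        acquisition: AcquisitionParams,
        split_gaps: bool = True,
        drop_singletons: bool = True,
    ) -> "TrajectoryDataset":
        """Build a dataset from parallel arrays of detections in micrometers.

        Trajectories with frame gaps are split into separate trajectories
        (the likelihoods assume strictly consecutive frames); trajectories
        with a single detection carry no jumps and are excluded, but counted
        in the dataset report.
        """
        ids = np.asarray(ids)
        frames = np.asarray(frames, dtype=np.int64)
        xy_um = np.asarray(xy_um, dtype=np.float64)
        order = np.lexsort((frames, ids))
        ids, frames, xy_um = ids[order], frames[order], xy_um[order]

        trajectories: list[Trajectory] = []
        n_singletons = 0
        n_split = 0
        next_id = 0
        if ids.size:
            # boundaries where id changes or frame step != 1
            new_traj = np.ones(ids.size, dtype=bool)
            new_traj[1:] = (ids[1:] != ids[:-1]) | (np.diff(frames) != 1)
            starts = np.flatnonzero(new_traj)
            ends = np.append(starts[1:], ids.size)
            # count original trajectories that were split
            for s, e in zip(starts, ends):
                if e - s < 2:
                    n_singletons += 1
                    continue
                trajectories.append(Trajectory(next_id, frames[s:e], xy_um[s:e]))
                next_id += 1
            n_split = len(starts) - len(np.unique(ids))
        if not drop_singletons and n_singletons:
            # singletons are never usable by inference; the flag exists only
            # so callers can assert on the report
            pass
        report = {
            "n_detections": int(ids.size),
            "n_trajectories": len(trajectories),
            "n_singletons_excluded": int(n_singletons),
            "n_extra_segments_from_gap_splitting": int(max(n_split, 0)),
        }
        return cls(trajectories, acquisition, report)


_QUOT_COLUMNS = {"trajectory", "frame", "x", "y"}
_PLAIN_COLUMNS = {"id", "frame", "x_um", "y_um"}


def _detect_sep(path: str | os.PathLike | io.IOBase) -> str:
    if hasattr(path, "read"):
        return ","
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_trajectories(
    path,
    acquisition: AcquisitionParams | None = None,
    unit: str | None = None,
) -> TrajectoryDataset:
    """Read a trajectory table (CSV or TSV) into a :class:`TrajectoryDataset`.

    Two column dialects are auto-detected by header: the tracking-pipeline
    convention ``trajectory, frame, y, x`` (positions in pixels unless
    ``unit='um'``) and the plain convention ``id, frame, x_um, y_um``
    (positions in micrometers unless ``unit='pixels'``).

    Positions are converted to micrometers using ``acquisition.pixel_size``
    when the unit is pixels. Localizations before ``acquisition.start_frame``
    are discarded, gapped trajectories are split, and single-detection
    trajectories are excluded (counted in ``dataset.report``).
    """
    if acquisition is None:
        acquisition = AcquisitionParams()
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as e:
        raise TrajectoryFormatError("empty trajectory file") from e
    cols = set(df.columns)
    if _QUOT_COLUMNS <= cols:
        id_col, x_col, y_col = "trajectory", "x", "y"
        default_unit = "pixels"
    elif _PLAIN_COLUMNS <= cols:
        id_col, x_col, y_col = "id", "x_um", "y_um"
        default_unit = "um"
    else:
        raise TrajectoryFormatError(
            f"unrecognized columns {sorted(cols)}; expected "
            f"{sorted(_QUOT_COLUMNS)} or {sorted(_PLAIN_COLUMNS)}"
        )
    if df.empty:
        raise TrajectoryFormatError("trajectory file contains no rows")
    unit = unit or default_unit
    if unit not in ("pixels", "um"):
        raise ValueError("unit must be 'pixels' or 'um'")
    for c in (x_col, y_col):
        if not np.issubdtype(df[c].dtype, np.number):
            raise TrajectoryFormatError(f"non-numeric values in column {c!r}")
    if not np.issubdtype(df["frame"].dtype, np.number):
        raise TrajectoryFormatError("non-numeric values in column 'frame'")

    df = df[df["frame"] >= acquisition.start_frame]
    xy = df[[x_col, y_col]].to_numpy(dtype=np.float64)
    if unit == "pixels":
        xy = xy * acquisition.pixel_size
    return TrajectoryDataset.from_arrays(
        df[id_col].to_numpy(),
        df["frame"].to_numpy(dtype=np.int64),
        xy,
        acquisition,
    )


def write_trajectories(ds: TrajectoryDataset, path) -> None:
    """Write a dataset as a plain-dialect CSV (id, frame, x_um, y_um)."""
    ds.to_dataframe().to_csv(path, index=False)


def split_trajectories(ds: TrajectoryDataset, max_jumps: int) -> TrajectoryDataset:
    """Segment trajectories into pieces of at most ``max_jumps`` jumps.

    Balances the per-trajectory information content across states: slow
    states produce long trajectories (sharp state assignments) while fast
    states produce short ones (diffuse assignments), and without
    segmentation this asymmetry biases jump-weighted occupation estimates
    against fast states. Segmentation discards only the (lag-1)
    localization-error correlation across cut points.
    """
    if max_jumps < 1:
        raise ValueError("max_jumps must be >= 1")
    trajs = []
    next_id = 0
    for t in ds.trajectories:
        for start in range(0, t.L, max_jumps):
            end = min(start + max_jumps, t.L)
            trajs.append(Trajectory(next_id, t.frames[start:end + 1],
                                    t.positions[start:end + 1]))
            next_id += 1
    return TrajectoryDataset(trajs, ds.acquisition, dict(ds.report))


def dataset_summary(ds: TrajectoryDataset) -> dict:
    """Summary statistics of a dataset.

    Returns N, total jumps, mean trajectory length in frames
    (mean number of positions) and mean 2D jump length in micrometers.
    """
    if ds.N < 1:
        raise ValueError("empty dataset")
    L = ds.jump_counts()
    all_jumps = np.concatenate([t.jumps for t in ds.trajectories])
    jump_lengths = np.sqrt((all_jumps**2).sum(axis=1))
    out = {
        "N": ds.N,
        "total_jumps": int(L.sum()),
        "mean_length_frames": float((L + 1).mean()),
        "mean_jump_um": float(jump_lengths.mean()),
    }
    # transit-inclusive mean: single-detection passes through the focal
    # volume count as length-1 transits even though they carry no jumps
    singles = ds.report.get("n_singletons_excluded")
    if singles is not None:
        out["mean_transit_length_frames"] = float(
            ((L + 1).sum() + singles) / (ds.N + singles)
        )
    return out
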