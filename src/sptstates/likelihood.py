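"""Trajectory likelihoods for diffusing states.

The measured jumps of a Brownian particle with localization error (RBME)
form a mean-zero Gaussian process whose covariance is tridiagonal: variance
2(D*dt + sigma_loc^2) per axis, and covariance -sigma_loc^2 between
sequential jumps (the same measurement error enters two consecutive jumps
with opposite sign). Fractional Brownian motion with localization error
(FBME) generalizes this to a dense increment covariance controlled by the
Hurst parameter H; H = 1/2 recovers RBME.

Grid evaluation exploits the tridiagonal structure: an LDL^T recurrence
gives the log-determinant and quadratic forms in O(L) per vertex,
vectorized over all vertices and all trajectories of equal length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import Trajectory, TrajectoryDataset
from .grid import ParameterGrid

__all__ = [
    "RBMEParams",
    "FBMEParams",
    "LikelihoodMatrix",
    "rbme_covariance",
    "rbme_log_likelihood",
    "gamma_log_likelihood",
    "fbme_increment_covariance",
    "fbme_log_likelihood",
    "evaluate_grid",
    "expected_radial_displacement",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class RBMEParams:
    """Regular Brownian motion with localization error.

    D in um^2/s; loc_error_var = sigma_loc^2 in um^2.
    """

    D: float
    loc_error_var: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0 or self.loc_error_var < 0:
            raise ValueError("D and loc_error_var must be nonnegative")


@dataclass(frozen=True)
class FBMEParams:
    """Fractional Brownian motion with localization error.

    ``scale_mod`` is the modified scaling coefficient S-bar (um^2/s),
    chosen so the one-frame jump variance is 2*S-bar*dt independent of the
    Hurst parameter; the raw scaling coefficient is
    S = S-bar * dt^(1 - 2H).
    """

    scale_mod: float
    hurst: float = 0.5
    loc_error_var: float = 0.0

    def __post_init__(self) -> None:
        if self.scale_mod < 0 or self.loc_error_var < 0:
            raise ValueError("scale_mod and loc_error_var must be nonnegative")
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("hurst must lie in (0, 1)")


def expected_radial_displacement(D: float, t: float) -> float:
    """Mean 2D radial displacement of a Brownian particle over time t.

    With per-axis displacement variance 2*D*t, |r| is Rayleigh-distributed
    and E|r| = sqrt(pi*D*t) (um for D in um^2/s, t in s).
    """
    return float(np.sqrt(np.pi * D * t))


# ---------------------------------------------------------------------------
# single-state likelihoods
# ---------------------------------------------------------------------------

def rbme_covariance(L: int, params: RBMEParams, dt: float) -> np.ndarray:
    """Tridiagonal covariance of L sequential RBME jumps along one axis."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a = 2.0 * (params.D * dt + params.loc_error_var)
    gamma = np.zeros((L, L), dtype=np.float64)
    np.fill_diagonal(gamma, a)
    idx = np.arange(L - 1)
    gamma[idx, idx + 1] = -params.loc_error_var
    gamma[idx + 1, idx] = -params.loc_error_var
    return gamma


def _gaussian_log_density(jumps: np.ndarray, cov: np.ndarray) -> float:
    """Log density of 2D jumps under per-axis covariance ``cov``."""
    L = cov.shape[0]
    try:
        c, lower = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"jump covariance is not positive definite (L={L})"
        ) from e
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    sol = cho_solve((c, lower), jumps)  # (L, 2)
    quad = float(np.sum(jumps * sol))
    return -0.5 * quad - L * LOG_2PI - logdet


def _as_jumps(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        return traj.jumps
    jumps = np.asarray(traj, dtype=np.float64)
    if jumps.ndim != 2 or jumps.shape[1] != 2:
        raise ValueError("expected a Trajectory or an (L, 2) jump array")
    return jumps


def rbme_log_likelihood(traj, params: RBMEParams, dt: float) -> float:
    """Log likelihood of a trajectory's jumps under an RBME state.

    ``traj`` may be a :class:`Trajectory` or an (L, 2) array of jumps in um.
    """
    jumps = _as_jumps(traj)
    cov = rbme_covariance(jumps.shape[0], params, dt)
    return _gaussian_log_density(jumps, cov)


def gamma_log_likelihood(S, L, phi):
    """Marginal RBME log likelihood in the 1D parameter
    phi = log[4*(D*dt + sigma_loc^2)], up to an additive constant.

    Neglecting the off-diagonal (localization error) terms of the jump
    covariance, the squared-jump sum S with L jumps yields
    log p(X | phi) = -S * exp(-phi) - L * phi + const.
    """
    S = np.asarray(S, dtype=np.float64)
    L = np.asarray(L, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if np.any(S < 0):
        raise ValueError("S must be >= 0")
    if np.any(L < 1):
        raise ValueError("L must be >= 1")
    out = -S * np.exp(-phi) - L * phi
    return out if out.ndim else float(out)


def fbme_increment_covariance(L: int, params: FBMEParams, dt: float) -> np.ndarray:
    """Covariance of L sequential FBME jumps along one axis.

    Cov(dX_i, dX_j) = S*dt^(2H) * (|i-j+1|^(2H) + |i-j-1|^(2H) - 2|i-j|^(2H))
                      + 2*sigma_loc^2 * 1[i=j] - sigma_loc^2 * 1[|i-j|=1]
    with S recovered from the modified scaling via S = S-bar * dt^(1-2H),
    so S*dt^(2H) = S-bar*dt and the jump variance is 2*S-bar*dt + 2*s2.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    H2 = 2.0 * params.hurst
    s2 = params.loc_error_var
    lag = np.abs(np.subtract.outer(np.arange(L), np.arange(L))).astype(np.float64)
    fbm = params.scale_mod * dt * (
        np.abs(lag + 1) ** H2 + np.abs(lag - 1) ** H2 - 2.0 * lag**H2
    )
    cov = fbm + 2.0 * s2 * np.eye(L)
    idx = np.arange(L - 1)
    cov[idx, idx + 1] -= s2
    cov[idx + 1, idx] -= s2
    return cov


def fbme_log_likelihood(traj, params: FBMEParams, dt: float) -> float:
    """Log likelihood of a trajectory's jumps under an FBME state."""
    jumps = _as_jumps(traj)
    cov = fbme_increment_covariance(jumps.shape[0], params, dt)
    return _gaussian_log_density(jumps, cov)


# ---------------------------------------------------------------------------
# grid evaluation
# ---------------------------------------------------------------------------

@dataclass
class LikelihoodMatrix:
    """Per-trajectory x per-grid-vertex likelihoods.

    ``values[i, k]`` holds exp(log L_ik - max_j log L_ij): each row is
    shifted by its maximum before exponentiation, so entries are finite in
    [0, 1] and at least one entry per row equals 1 (or sums to 1 after row
    normalization). Row scaling cancels in every downstream posterior.
    """

    values: np.ndarray
    jumps: np.ndarray
    grid: ParameterGrid
    row_norm: bool = False
    sum_sq: np.ndarray | None = None

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]

    def normalized(self) -> "LikelihoodMatrix":
        if self.row_norm:
            return self
        rows = self.values.sum(axis=1, keepdims=True)
        if np.any(rows <= 0):
            bad = int(np.flatnonzero(rows.ravel() <= 0)[0])
            raise ValueError(f"trajectory {bad} has zero likelihood at every vertex")
        return LikelihoodMatrix(self.values / rows, self.jumps, self.grid, True, self.sum_sq)


def _rbme_grid_log_likelihood(ds: TrajectoryDataset, a: np.ndarray, b: np.ndarray,
                              chunk: int = 1024) -> np.ndarray:
    """Log likelihood matrix for tridiagonal jump covariances.

    ``a``: (K,) diagonal 2(D*dt + s2); ``b``: (K,) magnitude of the
    off-diagonal, s2. Vertices whose covariance is not positive definite
    for some trajectory length get -inf for trajectories of that length.
    """
    N = ds.N
    K = a.size
    out = np.empty((N, K), dtype=np.float64)
    lengths = ds.jump_counts()
    # jump arrays grouped by trajectory length
    jumps_by_traj = [t.jumps for t in ds.trajectories]
    for L in np.unique(lengths):
        idx = np.flatnonzero(lengths == L)
        X = np.stack([jumps_by_traj[i][:, 0] for i in idx])  # (nL, L)
        Y = np.stack([jumps_by_traj[i][:, 1] for i in idx])
        # LDL^T recurrence: delta_1 = a, delta_j = a - b^2/delta_{j-1}
        delta = np.empty((L, K), dtype=np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta[0] = a
            for j in range(1, L):
                delta[j] = a - b * b / delta[j - 1]
        valid = np.all(delta > 0, axis=0)
        if not np.all(valid):
            delta[:, ~valid] = np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            logdet = np.sum(np.log(delta), axis=0)
            coef = b / delta  # (L, K); coef[j-1] multiplies w_{j-1}
            inv_delta = 1.0 / delta
        for s in range(0, idx.size, chunk):
            sl = slice(s, min(s + chunk, idx.size))
            quad = np.zeros((sl.stop - sl.start, K), dtype=np.float64)
            for Z in (X[sl], Y[sl]):
                w = np.broadcast_to(Z[:, 0, None], quad.shape).copy()
                quad += w * w * inv_delta[0]
                for j in range(1, L):
                    w = Z[:, j, None] + coef[j - 1] * w
                    quad += w * w * inv_delta[j]
            block = -0.5 * quad - L * LOG_2PI - logdet
            block[:, ~valid] = -np.inf
            out[idx[sl]] = block
    return out


def _fbme_grid_log_likelihood(ds: TrajectoryDataset, sbar: np.ndarray, hurst: np.ndarray,
                              s2: np.ndarray, dt: float, chunk_k: int = 256) -> np.ndarray:
    N, K = ds.N, sbar.size
    out = np.empty((N, K), dtype=np.float64)
    lengths = ds.jump_counts()
    jumps_by_traj = [t.jumps for t in ds.trajectories]
    for L in np.unique(lengths):
        idx = np.flatnonzero(lengths == L)
        X = np.stack([jumps_by_traj[i] for i in idx])  # (nL, L, 2)
        lag = np.abs(np.subtract.outer(np.arange(L), np.arange(L))).astype(np.float64)
        off1 = (lag == 1)
        eye = np.eye(L, dtype=bool)
        for s in range(0, K, chunk_k):
            ks = slice(s, min(s + chunk_k, K))
            H2 = 2.0 * hurst[ks][:, None, None]
            cov = sbar[ks][:, None, None] * dt * (
                np.abs(lag + 1)[None] ** H2 + np.abs(lag - 1)[None] ** H2
                - 2.0 * lag[None] ** H2
            )
            cov = cov + 2.0 * s2[ks][:, None, None] * eye[None]
            cov = cov - s2[ks][:, None, None] * off1[None]
            sign, logdet = np.linalg.slogdet(cov)
            valid = sign > 0
            cov[~valid] = np.eye(L)
            cinv = np.linalg.inv(cov)  # (k, L, L)
            quad = np.einsum("nla,klm,nma->nk", X, cinv, X, optimize=True)
            block = -0.5 * quad - L * LOG_2PI - logdet[None, :]
            block[:, ~valid] = -np.inf
            out[np.ix_(idx, np.arange(ks.start, ks.stop))] = block
    return out


def evaluate_grid(
    ds: TrajectoryDataset,
    grid: ParameterGrid,
    normalize: bool = True,
) -> LikelihoodMatrix:
    """Evaluate the N x K likelihood matrix of a dataset over a grid.

    Entries are computed in log space, shifted by the per-row maximum and
    exponentiated; rows are normalized to sum to one by default (the
    normalization cancels in posterior responsibilities). Vertices with
    degenerate (non-positive-definite) covariances receive zero likelihood.
    """
    if ds.N < 1:
        raise ValueError("empty dataset")
    if np.any(ds.jump_counts() < 1):
        raise ValueError("every trajectory must have at least one jump")
    dt = ds.acquisition.frame_interval
    v = grid.vertex_arrays()
    s2 = v["loc_error"] ** 2
    if grid.motion_kind == "rbme":
        a = 2.0 * (v["diffusion"] * dt + s2)
        logL = _rbme_grid_log_likelihood(ds, a, s2)
    else:
        logL = _fbme_grid_log_likelihood(ds, v["diffusion"], v["hurst"], s2, dt)
    row_max = np.max(logL, axis=1, keepdims=True)
    if not np.all(np.isfinite(row_max)):
        bad = int(np.flatnonzero(~np.isfinite(row_max.ravel()))[0])
        raise ValueError(f"trajectory {bad} has zero likelihood at every grid vertex")
    n_degenerate = int(np.sum(np.all(~np.isfinite(logL), axis=0)))
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} grid vertices have degenerate covariances; "
            "assigned zero likelihood",
            stacklevel=2,
        )
    A = np.exp(logL - row_max)
    mat = LikelihoodMatrix(A, ds.jump_counts(), grid, False, ds.sum_squared_jumps())
    return mat.normalized() if normalize else mat
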