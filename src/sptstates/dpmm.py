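"""Dirichlet process mixture inference over the marginal jump parameter.

Neglecting the between-jump covariance induced by localization error, a
trajectory's squared-jump sum S with L jumps has log likelihood

    log p(X | phi) = -S * exp(-phi) - L * phi + const,

in the single parameter phi = log[4*(D*dt + sigma_loc^2)]. A Dirichlet
process mixture over phi is sampled with a Chinese-restaurant-process
Gibbs sweep (Neal's auxiliary-candidate algorithm) plus per-state
Metropolis-Hastings nudges with a range-truncated Gaussian proposal.
Because phi confounds diffusion and localization error, sigma_loc^2 must
be estimated separately; the standard estimator is the mean negative
covariance between sequential jumps.

The sweep is sequential by nature and is compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator

from .data import TrajectoryDataset
from .defocalize import correct_occupations
from .grid import ParameterGrid
from .profiles import OccupationProfile

__all__ = [
    "DPMMConfig",
    "DPMMChain",
    "estimate_loc_error",
    "gibbs_sample",
    "posterior_profile",
    "DirichletProcessMixture",
]


@dataclass(frozen=True)
class DPMMConfig:
    """Sampler configuration.

    ``m0`` is both the number of initial states and the number of uniform
    candidates drawn when a trajectory opens a new state. ``nu`` is the
    Metropolis-Hastings proposal standard deviation in phi units. The phi
    support [phi_min, phi_max] should span the diffusion range of
    interest: phi = log[4*(D*dt + sigma_loc^2)].
    """

    alpha: float = 5.0
    m0: int = 20
    nu: float = 0.1
    phi_min: float = -10.0
    phi_max: float = 2.0
    n_iter: int = 2000
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.m0 < 1:
            raise ValueError("m0 must be >= 1")
        if not self.nu > 0:
            raise ValueError("nu must be > 0")
        if not self.phi_min < self.phi_max:
            raise ValueError("phi_min must be < phi_max")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")

    @classmethod
    def for_dataset(cls, ds: TrajectoryDataset, loc_error_var: float,
                    d_min: float = 1e-2, d_max: float = 1e2, **kwargs) -> "DPMMConfig":
        """Map the default diffusion support onto phi at the dataset's dt."""
        dt = ds.acquisition.frame_interval
        return cls(
            phi_min=float(np.log(4.0 * (d_min * dt + loc_error_var))),
            phi_max=float(np.log(4.0 * (d_max * dt + loc_error_var))),
            **kwargs,
        )


@dataclass
class DPMMChain:
    """Gibbs-sampler trace: per-iteration state parameters and jump counts."""

    phi: list  # list of (m_t,) arrays
    n_jumps: list  # list of (m_t,) arrays
    acceptance_rate: float
    total_jumps: int
    config: DPMMConfig
    assignments: np.ndarray | None = None  # final-iteration Z

    @property
    def n_iterations(self) -> int:
        return len(self.phi)

    def samples(self, burn_in: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Post-burn-in phi samples and their jump-count weights."""
        b = self.config.burn_in if burn_in is None else burn_in
        if b >= len(self.phi):
            raise ValueError("no post-burn-in samples in the chain")
        phi = np.concatenate(self.phi[b:])
        w = np.concatenate(self.n_jumps[b:])
        return phi, w


def estimate_loc_error(ds: TrajectoryDataset) -> float:
    """Estimate sigma_loc^2 (um^2) from the negative covariance between
    sequential jumps.

    Measurement error enters two consecutive jumps with opposite sign, so
    the lag-1 jump covariance per axis equals -sigma_loc^2 regardless of
    the diffusion coefficient. Pools all sequential jump pairs over
    trajectories and both axes; clipped below at 0.
    """
    total = 0.0
    count = 0
    for t in ds.trajectories:
        if t.L < 2:
            continue
        j = t.jumps
        total += float(np.sum(j[:-1] * j[1:]))
        count += 2 * (t.L - 1)
    if count == 0:
        raise ValueError("need at least one trajectory with >= 2 jumps")
    return max(-total / count, 0.0)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _gibbs_kernel(S, L, alpha, m0, nu, phi_min, phi_max, n_iter, seed, trace_cap):
    np.random.seed(seed)
    N = S.size
    cap = N + m0 + 1
    phi = np.zeros(cap)
    nj = np.zeros(cap)  # jumps assigned per state
    nt = np.zeros(cap, dtype=np.int64)  # trajectories per state
    sS = np.zeros(cap)  # summed squared-jump sums per state
    logw = np.zeros(cap)
    cand = np.zeros(m0)
    clw = np.zeros(m0)
    Z = np.zeros(N, dtype=np.int64)
    phi_trace = np.zeros((n_iter, trace_cap))
    nj_trace = np.zeros((n_iter, trace_cap))
    m_trace = np.zeros(n_iter, dtype=np.int64)
    width = phi_max - phi_min

    # initialization: m0 uniform candidates; assign by likelihood softmax
    m = m0
    for k in range(m0):
        phi[k] = phi_min + width * np.random.random()
    for i in range(N):
        best = -1.0e300
        for k in range(m):
            logw[k] = -S[i] * math.exp(-phi[k]) - L[i] * phi[k]
            if logw[k] > best:
                best = logw[k]
        tot = 0.0
        for k in range(m):
            logw[k] = math.exp(logw[k] - best)
            tot += logw[k]
        u = np.random.random() * tot
        acc = 0.0
        k_pick = m - 1
        for k in range(m):
            acc += logw[k]
            if u <= acc:
                k_pick = k
                break
        Z[i] = k_pick
        nj[k_pick] += L[i]
        nt[k_pick] += 1
        sS[k_pick] += S[i]

    p_exist = (N - 1.0) / (alpha + N - 1.0)
    n_accept = 0
    n_prop = 0
    for t in range(n_iter):
        for i in range(N):
            kc = Z[i]
            nj[kc] -= L[i]
            nt[kc] -= 1
            sS[kc] -= S[i]
            make_new = np.random.random() >= p_exist
            k_pick = -1
            if not make_new:
                # existing state, weighted by assigned jumps x likelihood
                best = -1.0e300
                any_occ = False
                for k in range(m):
                    if nj[k] > 0:
                        any_occ = True
                        logw[k] = math.log(nj[k]) - S[i] * math.exp(-phi[k]) - L[i] * phi[k]
                        if logw[k] > best:
                            best = logw[k]
                if not any_occ:
                    make_new = True
                else:
                    tot = 0.0
                    for k in range(m):
                        if nj[k] > 0:
                            logw[k] = math.exp(logw[k] - best)
                            tot += logw[k]
                        else:
                            logw[k] = 0.0
                    u = np.random.random() * tot
                    acc = 0.0
                    for k in range(m):
                        acc += logw[k]
                        if u <= acc:
                            k_pick = k
                            break
                    if k_pick < 0:
                        k_pick = m - 1
            if make_new:
                best = -1.0e300
                for c in range(m0):
                    cand[c] = phi_min + width * np.random.random()
                    clw[c] = -S[i] * math.exp(-cand[c]) - L[i] * cand[c]
                    if clw[c] > best:
                        best = clw[c]
                tot = 0.0
                for c in range(m0):
                    clw[c] = math.exp(clw[c] - best)
                    tot += clw[c]
                u = np.random.random() * tot
                acc = 0.0
                c_pick = m0 - 1
                for c in range(m0):
                    acc += clw[c]
                    if u <= acc:
                        c_pick = c
                        break
                k_pick = m
                phi[k_pick] = cand[c_pick]
                nj[k_pick] = 0.0
                nt[k_pick] = 0
                sS[k_pick] = 0.0
                m += 1
            Z[i] = k_pick
            nj[k_pick] += L[i]
            nt[k_pick] += 1
            sS[k_pick] += S[i]

        # remove empty states, compact slots
        new_m = 0
        for k in range(m):
            if nt[k] > 0:
                if new_m != k:
                    phi[new_m] = phi[k]
                    nj[new_m] = nj[k]
                    nt[new_m] = nt[k]
                    sS[new_m] = sS[k]
                logw[k] = new_m  # old -> new slot map, reusing buffer
                new_m += 1
            else:
                logw[k] = -1.0
        for i in range(N):
            Z[i] = int(logw[Z[i]])
        m = new_m

        # Metropolis-Hastings nudges with range-truncated Gaussian proposal
        for k in range(m):
            prop = phi[k] + nu * np.random.standard_normal()
            tries = 0
            while (prop < phi_min or prop > phi_max) and tries < 1000:
                prop = phi[k] + nu * np.random.standard_normal()
                tries += 1
            if prop < phi_min or prop > phi_max:
                continue
            n_prop += 1
            dlog = (-sS[k] * math.exp(-prop) - nj[k] * prop) - (
                -sS[k] * math.exp(-phi[k]) - nj[k] * phi[k]
            )
            zc = _norm_cdf((phi_max - phi[k]) / nu) - _norm_cdf((phi_min - phi[k]) / nu)
            zp = _norm_cdf((phi_max - prop) / nu) - _norm_cdf((phi_min - prop) / nu)
            log_r = dlog + math.log(zc) - math.log(zp)
            u = np.random.random()
            if math.log(u) < log_r:
                phi[k] = prop
                n_accept += 1

        m_rec = min(m, trace_cap)
        m_trace[t] = m
        for k in range(m_rec):
            phi_trace[t, k] = phi[k]
            nj_trace[t, k] = nj[k]
    return phi_trace, nj_trace, m_trace, n_accept, n_prop, Z


def gibbs_sample(ds: TrajectoryDataset, cfg: DPMMConfig) -> DPMMChain:
    """Run the DPMM Gibbs sampler on a dataset.

    Deterministic for a given ``cfg.seed``: every stochastic choice
    (assignment, candidate draws, MH proposals) consumes one seeded
    generator in algorithm order.
    """
    if ds.N < 1:
        raise ValueError("empty dataset")
    S = ds.sum_squared_jumps()
    L = ds.jump_counts().astype(np.float64)
    trace_cap = 1024
    phi_tr, nj_tr, m_tr, n_acc, n_prop, Z = _gibbs_kernel(
        S, L, float(cfg.alpha), int(cfg.m0), float(cfg.nu),
        float(cfg.phi_min), float(cfg.phi_max), int(cfg.n_iter),
        int(cfg.seed) % (2**32), trace_cap,
    )
    if int(m_tr.max()) > trace_cap:
        raise RuntimeError("state count exceeded the trace capacity")
    phi_list = [phi_tr[t, : m_tr[t]].copy() for t in range(cfg.n_iter)]
    nj_list = [nj_tr[t, : m_tr[t]].copy() for t in range(cfg.n_iter)]
    rate = n_acc / n_prop if n_prop else 0.0
    return DPMMChain(phi_list, nj_list, float(rate), int(L.sum()), cfg, Z)


def posterior_profile(
    chain: DPMMChain,
    loc_error_var: float,
    dt: float,
    d_grid: np.ndarray | None = None,
) -> OccupationProfile:
    """Jump-weighted histogram of post-burn-in phi samples mapped to D.

    Each sample phi converts to D = (exp(phi)/4 - sigma_loc^2)/dt; samples
    whose implied D falls below the grid minimum (including those where
    exp(phi)/4 < sigma_loc^2) are clamped to the slowest vertex. The
    result is normalized; apply the defocalization correction afterwards
    (see :mod:`sptstates.defocalize`).
    """
    if d_grid is None:
        d_grid = ParameterGrid.default_rbme().diffusion_values
    d_grid = np.asarray(d_grid, dtype=np.float64)
    phi, w = chain.samples()
    D = (np.exp(phi) / 4.0 - loc_error_var) / dt
    n_clamped = int(np.sum(D < d_grid[0]))
    D = np.clip(D, d_grid[0], None)
    # assign to the nearest grid vertex (geometric midpoints for a log grid)
    edges = np.sqrt(d_grid[:-1] * np.maximum(d_grid[1:], 1e-300))
    idx = np.searchsorted(edges, D)
    occ = np.bincount(idx, weights=w, minlength=d_grid.size)
    occ = occ / occ.sum()
    prof = OccupationProfile(occ, d_grid, motion_kind="rbme")
    prof.n_clamped_samples = n_clamped
    return prof


class DirichletProcessMixture(BaseEstimator):
    """Scikit-learn style estimator for DPMM inference.

    Estimates localization error from sequential-jump covariance (unless
    supplied), runs the Gibbs sampler over phi, and summarizes the
    posterior as an occupation profile over a diffusion-coefficient grid
    with the defocalization correction applied.

    Attributes
    ----------
    chain_ : DPMMChain
    loc_error_var_ : float, sigma_loc^2 used (um^2)
    profile_ : OccupationProfile over the diffusion grid
    acceptance_rate_ : float, MH acceptance fraction
    """

    def __init__(
        self,
        alpha: float = 5.0,
        m0: int = 20,
        nu: float = 0.1,
        n_iter: int = 2000,
        burn_in: int = 500,
        loc_error_var: float | None = None,
        d_grid: np.ndarray | None = None,
        correct_defocalization: bool = True,
        focal_depth: float | None = None,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.m0 = m0
        self.nu = nu
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.loc_error_var = loc_error_var
        self.d_grid = d_grid
        self.correct_defocalization = correct_defocalization
        self.focal_depth = focal_depth
        self.random_state = random_state

    def fit(self, X: TrajectoryDataset, y=None) -> "DirichletProcessMixture":
        if not isinstance(X, TrajectoryDataset):
            raise TypeError("X must be a TrajectoryDataset")
        s2 = self.loc_error_var if self.loc_error_var is not None else estimate_loc_error(X)
        self.loc_error_var_ = float(s2)
        cfg = DPMMConfig.for_dataset(
            X, s2, alpha=self.alpha, m0=self.m0, nu=self.nu,
            n_iter=self.n_iter, burn_in=self.burn_in, seed=self.random_state,
        )
        self.config_ = cfg
        self.chain_ = gibbs_sample(X, cfg)
        self.acceptance_rate_ = self.chain_.acceptance_rate
        d_grid = (self.d_grid if self.d_grid is not None
                  else ParameterGrid.default_rbme().diffusion_values)
        dt = X.acquisition.frame_interval
        prof = posterior_profile(self.chain_, s2, dt, d_grid)
        if self.correct_defocalization:
            dz = self.focal_depth if self.focal_depth is not None else X.acquisition.focal_depth
            prof = correct_occupations(prof, dt, dz)
        self.profile_ = prof
        return self
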