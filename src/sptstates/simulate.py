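"""Stroboscopic SPT trajectory simulator.

Emulates the observation process of a sptPALM experiment: particles
photoactivate uniformly inside a spherical container (a nucleus-sized
compartment), diffuse in 3D with specular reflection at the boundary,
photobleach with exponential lifetimes, and are recorded only on frames
where their axial position falls inside a thin focal slab bisecting the
sphere. Because tracking is gapless, each contiguous passage through the
slab yields a separate trajectory; localization error is injected as iid
Gaussian noise on each recorded position. The result is the highly
fragmented, short-trajectory regime the inference modules are built for.

State assignment is multinomial over the nominal occupations, so the
realized ("true") occupations of a finite simulation fluctuate around the
nominal ones, exactly as in a real experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AcquisitionParams, Trajectory, TrajectoryDataset
from .likelihood import FBMEParams, RBMEParams, fbme_increment_covariance

__all__ = [
    "SimState",
    "SimStateModel",
    "SimGeometry",
    "SimTruth",
    "simulate_dataset",
    "simulate_transitions",
    "simulate_fbm_path",
]


@dataclass(frozen=True)
class SimState:
    """One diffusive state of a simulation model."""

    params: RBMEParams | FBMEParams
    occupation: float


@dataclass(frozen=True)
class SimStateModel:
    """Mixture of diffusive states with nominal occupations summing to 1."""

    states: tuple
    subframes_per_frame: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        occ = np.array([s.occupation for s in self.states], dtype=np.float64)
        if np.any(occ < 0) or not np.isclose(occ.sum(), 1.0, atol=1e-8):
            raise ValueError("state occupations must be nonnegative and sum to 1")

    @property
    def occupations(self) -> np.ndarray:
        return np.array([s.occupation for s in self.states])

    @classmethod
    def brownian(cls, diffusivities, occupations, loc_error=0.035,
                 subframes_per_frame: int = 100) -> "SimStateModel":
        """Convenience constructor for multi-state Brownian models.

        ``loc_error`` is sigma_loc in um, scalar or per-state.
        """
        diffusivities = np.atleast_1d(np.asarray(diffusivities, dtype=np.float64))
        occupations = np.atleast_1d(np.asarray(occupations, dtype=np.float64))
        sig = np.broadcast_to(np.asarray(loc_error, dtype=np.float64),
                              diffusivities.shape)
        states = tuple(
            SimState(RBMEParams(d, s**2), o)
            for d, s, o in zip(diffusivities, sig, occupations)
        )
        return cls(states, subframes_per_frame)


@dataclass(frozen=True)
class SimGeometry:
    """Observation geometry and photophysics of the simulated experiment.

    Defaults reproduce the standard simulated sptPALM conditions: a 5 um
    sphere bisected by a 0.7 um focal slab, 7.48 ms frame intervals, and
    14 Hz Poisson photobleaching.
    """

    radius: float = 5.0
    focal_depth: float = 0.7
    frame_interval: float = 0.00748
    bleach_rate: float = 14.0
    n_trajectories_target: int = 12800

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if not 0 < self.focal_depth < 2 * self.radius:
            raise ValueError("focal_depth must lie in (0, 2*radius)")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if not self.bleach_rate > 0:
            raise ValueError("bleach_rate must be > 0")
        if self.n_trajectories_target < 1:
            raise ValueError("n_trajectories_target must be >= 1")

    def acquisition(self) -> AcquisitionParams:
        return AcquisitionParams(
            frame_interval=self.frame_interval,
            focal_depth=self.focal_depth,
            start_frame=0,
        )


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    state_labels: np.ndarray  # per-trajectory generating state index
    true_occupations: np.ndarray  # realized particle fractions per state
    state_diffusivities: np.ndarray
    state_loc_errors: np.ndarray  # sigma_loc per state, um
    n_particles: int = 0


# ---------------------------------------------------------------------------
# low-level kinematics
# ---------------------------------------------------------------------------

def _reflect_sphere(pos: np.ndarray, radius: float) -> None:
    """Specular reflection of radial overshoots about the sphere surface,
    iterated until all positions are inside. In-place."""
    for _ in range(64):
        r = np.sqrt((pos**2).sum(axis=1))
        out = r > radius
        if not out.any():
            return
        scale = (2.0 * radius - r[out]) / r[out]
        # reflect the radial coordinate to 2R - r, keeping the direction
        pos[out] *= scale[:, None]
    raise RuntimeError("sphere reflection failed to converge")


def _draw_uniform_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * u * radius


def _lifetimes_in_frames(rng: np.random.Generator, n: int, bleach_rate: float,
                         dt: float, cap: int) -> np.ndarray:
    """Number of frames on which each particle is recorded before bleaching."""
    p = -np.expm1(-bleach_rate * dt)
    return np.minimum(rng.geometric(p, size=n), cap)


def _segment_observed(particle_idx, frames, xy, min_len=2):
    """Split per-frame observations into gapless trajectories.

    Inputs are already ordered by (particle, frame). Returns a list of
    (slice arrays) plus the particle index of each segment; segments
    shorter than ``min_len`` positions are dropped (singleton count
    returned).
    """
    n = particle_idx.size
    segments = []
    n_singletons = 0
    if n == 0:
        return segments, n_singletons
    new_seg = np.ones(n, dtype=bool)
    new_seg[1:] = (particle_idx[1:] != particle_idx[:-1]) | (np.diff(frames) != 1)
    starts = np.flatnonzero(new_seg)
    ends = np.append(starts[1:], n)
    for s, e in zip(starts, ends):
        if e - s < min_len:
            n_singletons += 1
            continue
        segments.append((int(particle_idx[s]), frames[s:e], xy[s:e]))
    return segments, n_singletons


def _simulate_brownian_batch(rng, D, n_frames, geom: SimGeometry, n_substeps=10):
    """Simulate a batch of Brownian particles and return per-frame
    observations (particle index, frame, x, y, z in slab only).

    ``D``: (P,) per-particle diffusion coefficient; ``n_frames``: (P,)
    recorded-frame counts.
    """
    P = D.size
    dt_sub = geom.frame_interval / n_substeps
    pos = _draw_uniform_sphere(rng, P, geom.radius)
    half = geom.focal_depth / 2.0
    sigma_sub = np.sqrt(2.0 * D * dt_sub)[:, None]

    obs_p, obs_f, obs_xy = [], [], []
    alive = np.arange(P)
    frame = 0
    in_slab = np.abs(pos[:, 2]) <= half
    if in_slab.any():
        obs_p.append(alive[in_slab].copy())
        obs_f.append(np.zeros(int(in_slab.sum()), dtype=np.int64))
        obs_xy.append(pos[in_slab, :2].copy())
    max_frames = int(n_frames.max())
    cur_pos = pos
    cur_sigma = sigma_sub
    cur_life = n_frames
    for frame in range(1, max_frames):
        keep = cur_life > frame
        if not keep.all():
            alive = alive[keep]
            cur_pos = cur_pos[keep]
            cur_sigma = cur_sigma[keep]
            cur_life = cur_life[keep]
        if alive.size == 0:
            break
        for _ in range(n_substeps):
            cur_pos += cur_sigma * rng.standard_normal(cur_pos.shape)
            _reflect_sphere(cur_pos, geom.radius)
        in_slab = np.abs(cur_pos[:, 2]) <= half
        if in_slab.any():
            obs_p.append(alive[in_slab].copy())
            obs_f.append(np.full(int(in_slab.sum()), frame, dtype=np.int64))
            obs_xy.append(cur_pos[in_slab, :2].copy())
    if not obs_p:
        return (np.array([], dtype=np.int64), np.array([], dtype=np.int64),
                np.empty((0, 2)))
    p = np.concatenate(obs_p)
    f = np.concatenate(obs_f)
    xy = np.concatenate(obs_xy)
    order = np.lexsort((f, p))
    return p[order], f[order], xy[order]


def _simulate_fbm_batch(rng, state: FBMEParams, n_frames, geom: SimGeometry):
    """Free FBM paths observed through the slab (no boundary reflection:
    specular reflection is ill-defined for a non-Markov process, and the
    slab sits far from the sphere wall)."""
    P = n_frames.size
    start = _draw_uniform_sphere(rng, P, geom.radius)
    half = geom.focal_depth / 2.0
    dt = geom.frame_interval
    obs_p, obs_f, obs_xy = [], [], []
    pure = FBMEParams(state.scale_mod, state.hurst, 0.0)
    for L in np.unique(n_frames - 1):
        if L < 1:
            continue
        idx = np.flatnonzero(n_frames - 1 == L)
        cov = fbme_increment_covariance(int(L), pure, dt)
        chol = np.linalg.cholesky(cov)
        inc = np.einsum("lm,nmd->nld", chol,
                        rng.standard_normal((idx.size, int(L), 3)))
        path = np.concatenate(
            [start[idx][:, None, :], start[idx][:, None, :] + np.cumsum(inc, axis=1)],
            axis=1,
        )  # (n, L+1, 3)
        in_slab = np.abs(path[:, :, 2]) <= half
        for j, pi in enumerate(idx):
            mask = in_slab[j]
            if mask.any():
                fr = np.flatnonzero(mask)
                obs_p.append(np.full(fr.size, pi, dtype=np.int64))
                obs_f.append(fr.astype(np.int64))
                obs_xy.append(path[j, mask, :2])
    if not obs_p:
        return (np.array([], dtype=np.int64), np.array([], dtype=np.int64),
                np.empty((0, 2)))
    p = np.concatenate(obs_p)
    f = np.concatenate(obs_f)
    xy = np.concatenate(obs_xy)
    order = np.lexsort((f, p))
    return p[order], f[order], xy[order]


# ---------------------------------------------------------------------------
# public simulators
# ---------------------------------------------------------------------------

_LIFETIME_CAP_TAIL = 1e-7  # survival probability at the frame cap


def _frame_cap(geom: SimGeometry) -> int:
    return max(2, int(np.ceil(-np.log(_LIFETIME_CAP_TAIL)
                              / (geom.bleach_rate * geom.frame_interval))))


def simulate_dataset(
    model: SimStateModel,
    geom: SimGeometry,
    seed: int,
    batch_size: int = 20000,
    max_batches: int = 500,
) -> tuple[TrajectoryDataset, SimTruth]:
    """Simulate trajectories until the target count is reached.

    Returns the observed dataset (localization error included) and the
    ground truth: per-trajectory generating state and the realized
    particle fractions per state.
    """
    rng = np.random.default_rng(seed)
    occ = model.occupations
    n_states = occ.size
    cap = _frame_cap(geom)
    target = geom.n_trajectories_target

    is_fbme = [isinstance(s.params, FBMEParams) for s in model.states]
    sig_loc = np.array([np.sqrt(s.params.loc_error_var) for s in model.states])
    diff = np.array([
        s.params.scale_mod if f else s.params.D
        for s, f in zip(model.states, is_fbme)
    ])

    all_trajs: list[Trajectory] = []
    labels: list[int] = []
    particle_state_counts = np.zeros(n_states, dtype=np.int64)
    n_singletons = 0
    next_id = 0
    for _ in range(max_batches):
        states_b = rng.choice(n_states, size=batch_size, p=occ)
        n_frames = _lifetimes_in_frames(rng, batch_size, geom.bleach_rate,
                                        geom.frame_interval, cap)
        # per-batch observations, grouped per state for FBME
        batch_segments = []
        rb = ~np.asarray(is_fbme, dtype=bool)[states_b]
        if rb.any():
            idx = np.flatnonzero(rb)
            p, f, xy = _simulate_brownian_batch(
                rng, diff[states_b[idx]], n_frames[idx], geom)
            segs, n_single = _segment_observed(idx[p] if p.size else p, f, xy)
            batch_segments += segs
            n_singletons += n_single
        for k in np.unique(states_b[~rb]) if (~rb).any() else []:
            idx = np.flatnonzero((states_b == k) & ~rb)
            p, f, xy = _simulate_fbm_batch(
                rng, model.states[k].params, n_frames[idx], geom)
            segs, n_single = _segment_observed(idx[p] if p.size else p, f, xy)
            batch_segments += segs
            n_singletons += n_single
        # deterministic order within the batch: by particle index
        batch_segments.sort(key=lambda s: (s[0], int(s[1][0])))
        cutoff_particle = batch_size - 1
        for particle, frames, xy in batch_segments:
            if len(all_trajs) >= target:
                cutoff_particle = min(cutoff_particle, particle - 1)
                break
            k = int(states_b[particle])
            noisy = xy + sig_loc[k] * rng.standard_normal(xy.shape)
            all_trajs.append(Trajectory(next_id, frames, noisy))
            labels.append(k)
            next_id += 1
        n_counted = cutoff_particle + 1
        particle_state_counts += np.bincount(states_b[:n_counted], minlength=n_states)
        if len(all_trajs) >= target:
            break
    else:
        raise RuntimeError(
            f"failed to reach {target} trajectories in {max_batches} batches; "
            "check bleach rate and geometry"
        )
    ds = TrajectoryDataset(
        all_trajs,
        geom.acquisition(),
        report={"n_singletons_excluded": int(n_singletons),
                "n_particles": int(particle_state_counts.sum())},
    )
    truth = SimTruth(
        state_labels=np.array(labels, dtype=np.int64),
        true_occupations=particle_state_counts / particle_state_counts.sum(),
        state_diffusivities=diff,
        state_loc_errors=sig_loc,
        n_particles=int(particle_state_counts.sum()),
    )
    return ds, truth


def simulate_transitions(
    D1: float,
    D2: float,
    rate: float,
    geom: SimGeometry,
    seed: int,
    loc_error: float = 0.035,
    subframes_per_frame: int = 100,
    batch_size: int = 10000,
    max_batches: int = 500,
) -> tuple[TrajectoryDataset, SimTruth]:
    """Two-state symmetric Markov switching between diffusion coefficients.

    The state chain is discretized on ``subframes_per_frame`` substeps per
    frame; within each substep the state is constant and the particle
    takes an Euler-Maruyama Brownian step with the current coefficient.
    Observation, bleaching and localization error as in
    :func:`simulate_dataset`. State labels are reported as the state at a
    trajectory's first frame.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    dt_sub = geom.frame_interval / subframes_per_frame
    if rate * dt_sub > 0.5:
        raise ValueError("rate * frame_interval / subframes > 0.5; use finer subframes")
    p_switch = -np.expm1(-rate * dt_sub)
    rng = np.random.default_rng(seed)
    cap = _frame_cap(geom)
    target = geom.n_trajectories_target
    half = geom.focal_depth / 2.0
    sig = np.sqrt(2.0 * np.array([D1, D2]) * dt_sub)

    all_trajs: list[Trajectory] = []
    labels: list[int] = []
    n_particles = 0
    state_counts = np.zeros(2, dtype=np.int64)
    n_singletons = 0
    next_id = 0
    for _ in range(max_batches):
        n_frames = _lifetimes_in_frames(rng, batch_size, geom.bleach_rate,
                                        geom.frame_interval, cap)
        pos = _draw_uniform_sphere(rng, batch_size, geom.radius)
        state = rng.integers(0, 2, size=batch_size)
        state0 = state.copy()
        obs_p, obs_f, obs_xy, obs_s = [], [], [], []
        alive = np.arange(batch_size)
        in_slab = np.abs(pos[:, 2]) <= half
        if in_slab.any():
            obs_p.append(alive[in_slab].copy())
            obs_f.append(np.zeros(int(in_slab.sum()), dtype=np.int64))
            obs_xy.append(pos[in_slab, :2].copy())
            obs_s.append(state[in_slab].copy())
        cur_pos, cur_state, cur_life = pos, state, n_frames
        max_f = int(n_frames.max())
        for frame in range(1, max_f):
            keep = cur_life > frame
            alive, cur_pos = alive[keep], cur_pos[keep]
            cur_state, cur_life = cur_state[keep], cur_life[keep]
            if alive.size == 0:
                break
            for _ in range(subframes_per_frame):
                if p_switch > 0:
                    flip = rng.uniform(size=alive.size) < p_switch
                    cur_state[flip] = 1 - cur_state[flip]
                cur_pos += sig[cur_state][:, None] * rng.standard_normal(cur_pos.shape)
                _reflect_sphere(cur_pos, geom.radius)
            in_slab = np.abs(cur_pos[:, 2]) <= half
            if in_slab.any():
                obs_p.append(alive[in_slab].copy())
                obs_f.append(np.full(int(in_slab.sum()), frame, dtype=np.int64))
                obs_xy.append(cur_pos[in_slab, :2].copy())
                obs_s.append(cur_state[in_slab].copy())
        if obs_p:
            p = np.concatenate(obs_p)
            f = np.concatenate(obs_f)
            xy = np.concatenate(obs_xy)
            order = np.lexsort((f, p))
            p, f, xy = p[order], f[order], xy[order]
            segs, n_single = _segment_observed(p, f, xy)
            n_singletons += n_single
            segs.sort(key=lambda s: (s[0], int(s[1][0])))
        else:
            segs = []
        cutoff = batch_size - 1
        for particle, frames, xy in segs:
            if len(all_trajs) >= target:
                cutoff = min(cutoff, particle - 1)
                break
            noisy = xy + loc_error * rng.standard_normal(xy.shape)
            all_trajs.append(Trajectory(next_id, frames, noisy))
            labels.append(int(state0[particle]))
            next_id += 1
        state_counts += np.bincount(state0[: cutoff + 1], minlength=2)
        n_particles += cutoff + 1
        if len(all_trajs) >= target:
            break
    else:
        raise RuntimeError(f"failed to reach {target} trajectories")
    ds = TrajectoryDataset(
        all_trajs, geom.acquisition(),
        report={"n_singletons_excluded": int(n_singletons),
                "n_particles": n_particles},
    )
    truth = SimTruth(
        state_labels=np.array(labels, dtype=np.int64),
        true_occupations=state_counts / max(state_counts.sum(), 1),
        state_diffusivities=np.array([D1, D2]),
        state_loc_errors=np.array([loc_error, loc_error]),
        n_particles=n_particles,
    )
    return ds, truth


def _fgn_davies_harte(n: int, gamma: np.ndarray, rng: np.random.Generator,
                      n_dim: int) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding.

    ``gamma`` holds the autocovariances gamma(0..n). Returns (n, n_dim).
    """
    m = 2 * n
    c = np.concatenate([gamma[: n + 1], gamma[n - 1:0:-1]])
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * lam.max():
        raise np.linalg.LinAlgError("circulant embedding is not nonnegative")
    lam = np.clip(lam, 0.0, None)
    out = np.empty((n, n_dim))
    for d in range(n_dim):
        u = rng.standard_normal(n + 1)
        v = rng.standard_normal(n - 1)
        W = np.zeros(m, dtype=complex)
        W[0] = np.sqrt(lam[0] / m) * u[0]
        W[n] = np.sqrt(lam[n] / m) * u[n]
        W[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (u[1:n] + 1j * v)
        W[n + 1:] = np.conj(W[1:n][::-1])
        out[:, d] = np.fft.fft(W).real[:n]
    return out


def simulate_fbm_path(
    params: FBMEParams,
    n_steps: int,
    dt: float,
    seed: int | np.random.Generator,
    n_dim: int = 2,
) -> np.ndarray:
    """Exact sample path of fractional Brownian motion with localization
    error, starting at the origin.

    Increments form a mean-zero Gaussian vector with exactly the FBME
    increment covariance: fractional Gaussian noise (sampled by Cholesky
    factorization for short paths, circulant embedding for long ones) plus
    the first difference of iid positional noise when
    ``params.loc_error_var`` > 0. Axes are independent. Returns an
    (n_steps + 1, n_dim) position array.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pure = FBMEParams(params.scale_mod, params.hurst, 0.0)
    if n_steps <= 1024:
        cov = fbme_increment_covariance(n_steps, pure, dt)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "FBME increment covariance is not positive definite") from e
        inc = chol @ rng.standard_normal((n_steps, n_dim))
    else:
        k = np.arange(n_steps + 1, dtype=np.float64)
        H2 = 2.0 * params.hurst
        gamma = params.scale_mod * dt * (
            np.abs(k + 1) ** H2 + np.abs(k - 1) ** H2 - 2.0 * k**H2
        )
        inc = _fgn_davies_harte(n_steps, gamma, rng, n_dim)
    if params.loc_error_var > 0:
        eps = np.sqrt(params.loc_error_var) * rng.standard_normal((n_steps + 1, n_dim))
        inc = inc + np.diff(eps, axis=0)
    out = np.zeros((n_steps + 1, n_dim))
    out[1:] = np.cumsum(inc, axis=0)
    return out
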