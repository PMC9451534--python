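import numpy as np
import pytest
from scipy.stats import multivariate_normal

from sptstates.data import AcquisitionParams, TrajectoryDataset
from sptstates.grid import ParameterGrid
from sptstates.likelihood import (
    FBMEParams,
    RBMEParams,
    evaluate_grid,
    expected_radial_displacement,
    fbme_increment_covariance,
    fbme_log_likelihood,
    gamma_log_likelihood,
    rbme_covariance,
    rbme_log_likelihood,
)
from .conftest import make_rbme_dataset, make_rbme_trajectory


def mvn_log_density_2d(jumps, cov):
    """Oracle: generic multivariate-normal log density on the stacked
    (x-jumps, y-jumps) vector with block-diagonal covariance diag(cov, cov)."""
    L = cov.shape[0]
    big = np.zeros((2 * L, 2 * L))
    big[:L, :L] = cov
    big[L:, L:] = cov
    vec = np.concatenate([jumps[:, 0], jumps[:, 1]])
    return multivariate_normal(mean=np.zeros(2 * L), cov=big).logpdf(vec)


class TestRBMECovariance:
    def test_printed_values(self):
        got = rbme_covariance(2, RBMEParams(1.0, 0.0009), 0.00748)
        np.testing.assert_allclose(
            got, [[0.01676, -0.0009], [-0.0009, 0.01676]], atol=1e-12
        )

    def test_zero_error_is_diagonal(self):
        got = rbme_covariance(5, RBMEParams(2.0, 0.0), 0.01)
        np.testing.assert_allclose(got, 2 * 2.0 * 0.01 * np.eye(5))

    def test_matches_generic_tridiagonal_constructor(self):
        D, s2, dt, L = 2.0, 0.0016, 0.01, 4
        expect = (np.diag(np.full(L, 2 * (D * dt + s2)))
                  + np.diag(np.full(L - 1, -s2), 1)
                  + np.diag(np.full(L - 1, -s2), -1))
        np.testing.assert_allclose(rbme_covariance(L, RBMEParams(D, s2), dt), expect)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            rbme_covariance(0, RBMEParams(1.0), 0.01)


class TestRBMELogLikelihood:
    def test_single_zero_jump_closed_form(self):
        # D*dt + s2 = 0.5 so the per-axis variance is 1; density 1/(2 pi)
        t = make_rbme_trajectory(np.random.default_rng(0), 1, 0.0, 0.5, 1.0)
        t.positions[:] = 0.0
        got = rbme_log_likelihood(t, RBMEParams(0.0, 0.5), 1.0)
        assert got == pytest.approx(np.log(1.0 / (2 * np.pi)), abs=1e-12)

    def test_markov_limit_zero_loc_error(self, rng):
        t = make_rbme_trajectory(rng, 6, 3.0, 0.0, 0.00748)
        got = rbme_log_likelihood(t, RBMEParams(3.0, 0.0), 0.00748)
        var = 2 * 3.0 * 0.00748
        per_jump = -0.5 * (t.jumps**2).sum() / var - t.L * np.log(2 * np.pi * var)
        assert got == pytest.approx(per_jump, rel=1e-12)

    def test_oracle_equivalence_random_instances(self, rng):
        """RBME likelihood == generic MVN oracle to 1e-8 relative tolerance
        over 1000 random small instances."""
        for _ in range(1000):
            L = int(rng.integers(1, 9))
            D = float(10 ** rng.uniform(-2, 2))
            s2 = float(rng.uniform(0, 0.0036))
            dt = float(rng.uniform(0.002, 0.02))
            t = make_rbme_trajectory(rng, L, D, s2, dt)
            got = rbme_log_likelihood(t, RBMEParams(D, s2), dt)
            want = mvn_log_density_2d(t.jumps, rbme_covariance(L, RBMEParams(D, s2), dt))
            assert got == pytest.approx(want, rel=1e-8, abs=1e-8)


class TestGammaLikelihood:
    def test_printed_substitution(self):
        phi = np.log(0.04)
        got = gamma_log_likelihood(0.12, 3, phi)
        assert got == pytest.approx(-0.12 / 0.04 - 3 * phi)

    def test_zero_S(self):
        assert gamma_log_likelihood(0.0, 5, 1.3) == pytest.approx(-5 * 1.3)

    def test_argmax_matches_rbme_scan_at_zero_error(self, rng):
        """With no localization error the marginal likelihood's argmax over
        phi coincides with the RBME likelihood's argmax over D (the MSD
        estimator 4 D dt = S / L)."""
        dt = 0.00748
        t = make_rbme_trajectory(rng, 30, 1.5, 0.0, dt)
        S, L = t.S, t.L
        d_scan = np.logspace(-2, 2, 2001)
        phi_scan = np.log(4 * d_scan * dt)
        g = gamma_log_likelihood(S, L, phi_scan)
        r = np.array([rbme_log_likelihood(t, RBMEParams(d, 0.0), dt) for d in d_scan])
        assert abs(np.argmax(g) - np.argmax(r)) <= 1
        d_hat = d_scan[np.argmax(g)]
        assert d_hat == pytest.approx(S / (4 * L * dt), rel=1e-2)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            gamma_log_likelihood(-1.0, 3, 0.0)
        with pytest.raises(ValueError):
            gamma_log_likelihood(1.0, 0, 0.0)


class TestFBME:
    def test_h_half_reduces_to_rbme(self):
        for L in (1, 2, 5, 9):
            for s2 in (0.0, 0.0012):
                for dt in (0.005, 0.00748):
                    f = fbme_increment_covariance(L, FBMEParams(2.3, 0.5, s2), dt)
                    r = rbme_covariance(L, RBMEParams(2.3, s2), dt)
                    np.testing.assert_allclose(f, r, atol=1e-12)

    def test_printed_subdiffusive_offdiagonal(self):
        # 2 S-bar dt = 1, H = 0.3, no error: diag 1, off-diag (2^0.6 - 2)/2
        dt = 0.01
        sbar = 1.0 / (2 * dt)
        cov = fbme_increment_covariance(2, FBMEParams(sbar, 0.3, 0.0), dt)
        assert cov[0, 0] == pytest.approx(1.0)
        assert cov[0, 1] == pytest.approx((2**0.6 - 2) / 2)
        assert cov[0, 1] == pytest.approx(-0.2421, abs=2e-4)

    def test_jump_variance_independent_of_hurst(self):
        dt = 0.00748
        for H in (0.2, 0.35, 0.5, 0.7, 0.9):
            cov = fbme_increment_covariance(4, FBMEParams(1.7, H, 0.001), dt)
            np.testing.assert_allclose(np.diag(cov), 2 * 1.7 * dt + 2 * 0.001)

    def test_log_likelihood_matches_mvn_oracle(self, rng):
        dt = 0.00748
        p = FBMEParams(0.8, 0.35, 0.0009)
        t = make_rbme_trajectory(rng, 5, 0.8, 0.0009, dt)
        got = fbme_log_likelihood(t, p, dt)
        want = mvn_log_density_2d(t.jumps, fbme_increment_covariance(5, p, dt))
        assert got == pytest.approx(want, rel=1e-10)


class TestEvaluateGrid:
    def test_rows_normalized_and_finite(self, small_rbme_dataset):
        A = evaluate_grid(small_rbme_dataset, ParameterGrid.default_rbme())
        assert np.all(np.isfinite(A.values)) and np.all(A.values >= 0)
        np.testing.assert_allclose(A.values.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_per_trajectory_log_likelihood(self, rng):
        """Vectorized grid evaluation == direct per-vertex evaluation."""
        ds, _ = make_rbme_dataset(rng, 12, 0.5, 0.0012, mean_jumps=3.0)
        grid = ParameterGrid("rbme", np.array([0.05, 0.5, 5.0]),
                             np.array([0.0, 0.02, 0.04]))
        A = evaluate_grid(ds, grid, normalize=False)
        v = grid.vertex_arrays()
        for i, t in enumerate(ds.trajectories):
            logl = np.array([
                rbme_log_likelihood(t, RBMEParams(d, s**2), ds.acquisition.frame_interval)
                for d, s in zip(v["diffusion"], v["loc_error"])
            ])
            np.testing.assert_allclose(A.values[i], np.exp(logl - logl.max()),
                                       rtol=1e-9, atol=1e-12)

    def test_duplicate_vertices_identical_columns(self, rng):
        ds, _ = make_rbme_dataset(rng, 10, 1.0, 0.001)
        # duplicate D with distinct-but-equal rows via two identical sigma values
        grid = ParameterGrid("rbme", np.array([1.0]), np.array([0.01, 0.02]))
        dup = ParameterGrid("rbme", np.array([0.999999999, 1.000000001]),
                            np.array([0.01]))
        A = evaluate_grid(ds, dup, normalize=False)
        np.testing.assert_allclose(A.values[:, 0], A.values[:, 1], rtol=1e-6)

    def test_true_vertex_wins_for_long_trajectory(self, rng):
        """For long trajectories the generating vertex carries the larger
        likelihood with high probability."""
        dt = 0.00748
        wins = 0
        n_rep = 200
        grid = ParameterGrid("rbme", np.array([0.3, 3.0]), np.array([0.02]))
        for _ in range(n_rep):
            t = make_rbme_trajectory(rng, 60, 3.0, 0.0004, dt)
            ds = TrajectoryDataset([t], AcquisitionParams(frame_interval=dt))
            A = evaluate_grid(ds, grid, normalize=False)
            wins += A.values[0, 1] > A.values[0, 0]
        assert wins / n_rep > 0.95

    def test_fbme_grid_matches_direct(self, rng):
        ds, _ = make_rbme_dataset(rng, 8, 1.0, 0.0009, mean_jumps=3.0)
        grid = ParameterGrid("fbme", np.array([0.3, 1.0]), np.array([0.0, 0.03]),
                             np.array([0.3, 0.5]))
        A = evaluate_grid(ds, grid, normalize=False)
        v = grid.vertex_arrays()
        dt = ds.acquisition.frame_interval
        for i, t in enumerate(ds.trajectories):
            logl = np.array([
                fbme_log_likelihood(t, FBMEParams(sb, h, s**2), dt)
                for sb, h, s in zip(v["diffusion"], v["hurst"], v["loc_error"])
            ])
            np.testing.assert_allclose(A.values[i], np.exp(logl - logl.max()),
                                       rtol=1e-8, atol=1e-12)


def test_sequential_jump_covariance_matches_model(rng):
    """Data simulated from RBME shows lag-1 jump covariance ~ -sigma_loc^2."""
    dt, D, s2 = 0.00748, 1.0, 0.0012
    t = make_rbme_trajectory(rng, 100000, D, s2, dt)
    j = t.jumps
    cov = float(np.mean(j[:-1] * j[1:]))
    se = float(np.std(j[:-1] * j[1:])) / np.sqrt(j.shape[0] * 2)
    assert abs(cov + s2) < 4 * se


def test_expected_radial_displacement_printed_value():
    # Brownian particle, D = 10 um^2/s over 1 ms: sqrt(pi D t) ~ 180 nm
    r = expected_radial_displacement(10.0, 0.001)
    assert round(r * 1000, -1) == 180
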