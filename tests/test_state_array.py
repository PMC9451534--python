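import numpy as np
import pytest
from scipy.special import digamma

from sptstates.grid import ParameterGrid
from sptstates.likelihood import LikelihoodMatrix, evaluate_grid
from sptstates.profiles import (
    OccupationProfile,
    marginalize_loc_error,
    mean_free_diffusion,
    occupation_in_range,
)
from sptstates.state_array import SAHyperparams, StateArray, infer, naive_occupations
from .conftest import make_rbme_dataset


def matrix(values, jumps, grid=None):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = ParameterGrid("rbme", np.arange(1.0, values.shape[1] + 1.0),
                             np.array([0.0]))
    return LikelihoodMatrix(values, np.asarray(jumps), grid)


class TestInfer:
    def test_single_state(self):
        A = matrix(np.ones((4, 1)), [2, 3, 1, 6])
        post = infer(A, hyper=SAHyperparams(alpha=2.0))
        assert np.all(post.r == 1.0)
        assert post.n[0] == pytest.approx(2.0 + 12)
        assert post.occupations()[0] == 1.0
        assert post.converged and post.iterations == 1

    def test_one_hot_jump_weighting(self):
        # 3 trajectories (L=2) pinned on state 1, one (L=6) on state 2:
        # occupations follow jump totals (6, 6) -> (0.5, 0.5)
        A = matrix([[1, 0]] * 3 + [[0, 1]], [2, 2, 2, 6])
        post = infer(A, hyper=SAHyperparams(alpha=1e-8))
        np.testing.assert_allclose(post.occupations(), [0.5, 0.5], atol=1e-6)

    def test_fixed_point_at_convergence(self, rng):
        ds, _ = make_rbme_dataset(rng, 150, [0.1, 5.0], 0.001)
        grid = ParameterGrid("rbme", np.logspace(-2, 2, 21), np.array([0.0, 0.04]))
        A = evaluate_grid(ds, grid)
        hyper = SAHyperparams(alpha=0.01 * A.K, max_iter=20000, tol=1e-10)
        post = infer(A, hyper=hyper)
        assert post.converged
        # substitute (r, n) into both printed updates
        n_check = hyper.alpha / A.K + post.r.T @ A.jumps.astype(float)
        np.testing.assert_allclose(n_check, post.n, rtol=1e-6)
        w = np.exp(digamma(post.n))
        r_check = A.values * w
        r_check /= r_check.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(r_check, post.r, atol=1e-8)

    def test_pseudocount_budget(self, rng):
        ds, _ = make_rbme_dataset(rng, 100, 1.0, 0.001)
        A = evaluate_grid(ds, ParameterGrid.default_rbme(n_diffusion=21, n_loc_error=6))
        alpha = 3.0
        post = infer(A, hyper=SAHyperparams(alpha=alpha, max_iter=50))
        assert post.n.min() >= alpha / A.K - 1e-12
        assert post.n.sum() == pytest.approx(alpha + A.jumps.sum(), rel=1e-9)
        np.testing.assert_allclose(post.r.sum(axis=1), 1.0, atol=1e-9)

    def test_duplication_preserves_occupations_sharpens_counts(self, rng):
        ds, _ = make_rbme_dataset(rng, 120, [0.1, 2.0], 0.0009)
        grid = ParameterGrid("rbme", np.logspace(-2, 2, 31), np.array([0.0, 0.03]))
        A = evaluate_grid(ds, grid)
        hyper = SAHyperparams(alpha=1.0, max_iter=5000, tol=1e-10)
        post1 = infer(A, hyper=hyper)
        A2 = LikelihoodMatrix(np.vstack([A.values, A.values]),
                              np.concatenate([A.jumps, A.jumps]), grid)
        post2 = infer(A2, hyper=hyper)
        assert np.max(np.abs(post1.occupations() - post2.occupations())) < 5e-3
        assert post2.n.sum() > 1.5 * post1.n.sum()

    def test_zero_row_rejected(self):
        A = matrix([[1.0, 0.0], [0.0, 0.0]], [1, 1])
        with pytest.raises(ValueError, match="trajectory 1"):
            infer(A)

    def test_sparsity_single_state(self, rng):
        """Posterior mass concentrates within one grid spacing of the true
        diffusion coefficient for single-state data."""
        ds, _ = make_rbme_dataset(rng, 5000, 1.0, 0.0012)
        grid = ParameterGrid.default_rbme()
        post = infer(evaluate_grid(ds, grid))
        prof = marginalize_loc_error(post.profile())
        D = prof.diffusion_values
        i = np.argmin(np.abs(np.log(D) - np.log(1.0)))
        assert prof.occupations[max(i - 1, 0):i + 2].sum() >= 0.90
        assert prof.occupations[max(i - 2, 0):i + 3].sum() >= 0.95

    def test_close_states_merge_with_summed_occupation(self, rng):
        """States under 2-fold apart merge into one mode whose integrated
        occupation matches the summed truth within 5 points."""
        ds, labels = make_rbme_dataset(rng, 4000, [0.6, 1.0], 0.0009,
                                       occupations=[0.5, 0.5])
        post = infer(evaluate_grid(ds, ParameterGrid.default_rbme()))
        prof = marginalize_loc_error(post.profile())
        L = ds.jump_counts()
        true_frac = L[labels == 0].sum() / L.sum() + L[labels == 1].sum() / L.sum()
        got = occupation_in_range(prof, 0.3, 2.0)
        assert got == pytest.approx(true_frac, abs=0.05)

    def test_alpha_sensitivity(self, rng):
        """Occupation estimates stable for alpha/K in [0.1, 2]."""
        ds, _ = make_rbme_dataset(rng, 2000, [0.05, 2.0], 0.0009,
                                  occupations=[0.4, 0.6])
        A = evaluate_grid(ds, ParameterGrid.default_rbme())
        outs = []
        for ak in (0.1, 2.0):
            post = infer(A, hyper=SAHyperparams(alpha=ak * A.K, max_iter=500))
            prof = marginalize_loc_error(post.profile())
            outs.append([occupation_in_range(prof, 0, 0.3),
                         occupation_in_range(prof, 0.3, 100)])
        assert np.max(np.abs(np.array(outs[0]) - np.array(outs[1]))) < 0.02


class TestNaive:
    def test_uniform_single_row(self):
        A = matrix([[0.5, 0.5]], [4])
        prof = naive_occupations(A)
        np.testing.assert_allclose(prof.occupations.ravel(), [0.5, 0.5])

    def test_printed_two_row_example(self):
        A = matrix([[1.0, 0.0], [0.5, 0.5]], [2, 2])
        prof = naive_occupations(A)
        np.testing.assert_allclose(prof.occupations.ravel(), [0.75, 0.25])

    def test_equals_zero_iteration_inference(self, rng):
        ds, _ = make_rbme_dataset(rng, 50, 1.0, 0.001)
        A = evaluate_grid(ds, ParameterGrid.default_rbme(n_diffusion=11, n_loc_error=4))
        naive = naive_occupations(A)
        # the first n-update from r^(0) with alpha -> 0 is the naive profile
        post = infer(A, hyper=SAHyperparams(alpha=1e-12, max_iter=1))
        np.testing.assert_allclose(naive.occupations.ravel(),
                                   post.occupations(), atol=1e-9)


class TestProfiles:
    def test_marginalize_conserves_mass(self):
        occ = np.random.default_rng(0).random((5, 3))
        occ /= occ.sum()
        prof = OccupationProfile(occ, np.arange(1.0, 6.0),
                                 loc_error_values=np.array([0.0, 0.01, 0.02]))
        out = marginalize_loc_error(prof)
        assert out.total() == pytest.approx(prof.total(), abs=1e-12)
        assert out.occupations.shape == (5,)

    def test_marginalize_uniform_2x3(self):
        prof = OccupationProfile(np.full((2, 3), 1 / 6), np.array([0.1, 1.0]),
                                 loc_error_values=np.array([0.0, 0.01, 0.02]))
        np.testing.assert_allclose(marginalize_loc_error(prof).occupations, [0.5, 0.5])

    def test_marginalize_fbme_keeps_hurst(self):
        occ = np.full((2, 3, 4), 1 / 24)
        prof = OccupationProfile(occ, np.array([0.1, 1.0]), motion_kind="fbme",
                                 loc_error_values=np.linspace(0, 0.03, 4),
                                 hurst_values=np.array([0.3, 0.5, 0.7]))
        out = marginalize_loc_error(prof)
        assert out.occupations.shape == (2, 3)
        assert out.total() == pytest.approx(1.0)

    def test_no_error_axis_warns(self):
        prof = OccupationProfile(np.array([1.0]), np.array([1.0]))
        with pytest.warns(UserWarning):
            out = marginalize_loc_error(prof)
        assert out is prof

    def test_occupation_in_range(self):
        prof = OccupationProfile(np.array([0.2, 0.3, 0.5]),
                                 np.array([0.02, 0.5, 5.0]))
        assert occupation_in_range(prof, 0, np.inf) == pytest.approx(1.0)
        assert occupation_in_range(prof, 0, 0.08) == pytest.approx(0.2)
        # half-open: a vertex exactly at d_max is excluded
        assert occupation_in_range(prof, 0.02, 0.5) == pytest.approx(0.2)
        parts = [occupation_in_range(prof, a, b)
                 for a, b in [(0, 0.08), (0.08, 1.5), (1.5, 40)]]
        assert sum(parts) == pytest.approx(1.0)

    def test_empty_range_warns(self):
        prof = OccupationProfile(np.array([1.0]), np.array([1.0]))
        with pytest.warns(UserWarning):
            assert occupation_in_range(prof, 5.0, 6.0) == 0.0

    def test_mean_free_diffusion(self):
        prof = OccupationProfile(np.array([0.5, 0.5]), np.array([2.0, 4.0]))
        assert mean_free_diffusion(prof) == pytest.approx(3.0)
        prof2 = OccupationProfile(np.array([0.7, 0.3]), np.array([0.01, 1.0]))
        assert mean_free_diffusion(prof2) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            mean_free_diffusion(OccupationProfile(np.array([1.0]), np.array([0.01])))


class TestEstimator:
    def test_fit_sets_attributes(self, small_rbme_dataset):
        sa = StateArray(grid=ParameterGrid.default_rbme(n_diffusion=21, n_loc_error=6),
                        max_iter=50).fit(small_rbme_dataset)
        assert sa.occupations_.shape == (21 * 6,)
        assert sa.profile_.corrected
        assert sa.profile_.occupations.shape == (21,)
        assert sa.naive_profile_.corrected
        assert sa.n_iter_ <= 50

    def test_get_set_params_roundtrip(self):
        sa = StateArray(alpha=2.0, max_iter=7)
        params = sa.get_params()
        sa2 = StateArray(**params)
        assert sa2.alpha == 2.0 and sa2.max_iter == 7
        sa2.set_params(tol=1e-3)
        assert sa2.tol == 1e-3

    def test_rejects_non_dataset(self):
        with pytest.raises(TypeError):
            StateArray().fit(np.zeros((3, 2)))


class TestRangePartitionProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=5, max_size=40))
    def test_partition_closure(self, weights):
        """Occupations over a partition of the grid sum to the total mass
        below the partition's upper edge."""
        occ = np.array(weights)
        occ /= occ.sum()
        D = np.logspace(-2, 2, occ.size)
        prof = OccupationProfile(occ, D)
        parts = [occupation_in_range(prof, a, b)
                 for a, b in [(0, 0.08), (0.08, 1.5), (1.5, 40.0)]]
        below_40 = occ[D < 40.0].sum()
        assert np.isclose(sum(parts), below_40, atol=1e-12)
        assert np.isclose(sum(parts) + occupation_in_range(prof, 40.0, np.inf),
                          1.0, atol=1e-12)
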