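"""Solver: objective, gradient, proximal operators and the splitting iteration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fbfdeblur.solver as solver_mod
from fbfdeblur import (
    DegradationSpec,
    DegradedObservation,
    DivergenceError,
    InvalidParameterError,
    RestorationProblem,
    SolverConfig,
    degrade,
    grad_f,
    make_motion_psf,
    objective,
    optimality_residual,
    prox_euclidean_norm,
    prox_l1,
    tseng_solve,
    tseng_step,
)

from oracles import (
    dense_circulant_matrix,
    grid_search_prox_l1,
    grid_search_prox_l2,
    ista_minimize,
)


def identity_problem(y):
    """Restoration problem with D = identity (length-1 PSF) and data y."""
    obs = DegradedObservation(
        observed=np.asarray(y, dtype=float),
        psf=make_motion_psf(1, 0),
        spec=DegradationSpec(psf_length=1, noise_family="none", noise_level=0.0),
    )
    return RestorationProblem(obs)


class TestObjective:
    def test_zero_at_exact_fit_without_regularization(self, rng):
        clean = rng.random((12, 12))
        obs = degrade(clean, DegradationSpec(psf_length=5, noise_family="none"))
        problem = RestorationProblem(obs)
        assert objective(clean, problem, reg_weight=0.0) == pytest.approx(0.0, abs=1e-20)

    def test_zero_for_zero_image_and_data(self):
        problem = identity_problem(np.zeros((6, 6)))
        assert objective(np.zeros((6, 6)), problem, reg_weight=0.7) == 0.0

    def test_matches_dense_hand_summation(self, rng):
        psf = make_motion_psf(3, 45)  # 3x3 kernel fits the 4x4 image
        clean = rng.random((4, 4))
        obs = degrade(
            clean,
            DegradationSpec(psf_length=3, psf_angle=45, noise_family="gaussian",
                            noise_level=0.001, seed=11),
        )
        problem = RestorationProblem(obs)
        x = rng.random((4, 4))
        D = dense_circulant_matrix(psf.kernel, (4, 4))
        resid = D @ x.ravel() - obs.observed.ravel()
        mu = 0.25
        expected = 0.5 * float(np.sum(resid**2)) + mu * float(np.abs(x).sum())
        assert objective(x, problem, mu, "l1") == pytest.approx(expected, abs=1e-10)

    def test_euclidean_variant(self, rng):
        x = rng.random((5, 5))
        problem = identity_problem(np.zeros((5, 5)))
        expected = 0.5 * np.sum(x**2) + 0.4 * np.linalg.norm(x)
        assert objective(x, problem, 0.4, "euclidean_norm") == pytest.approx(expected, rel=1e-12)


class TestGradF:
    def test_zero_residual_gives_zero_gradient(self, rng):
        clean = rng.random((10, 10))
        obs = degrade(clean, DegradationSpec(psf_length=7, psf_angle=45, noise_family="none"))
        np.testing.assert_allclose(
            grad_f(clean, RestorationProblem(obs)), 0.0, atol=1e-12
        )

    def test_identity_blur_zero_data_gives_x(self, rng):
        x = rng.random((8, 8))
        problem = identity_problem(np.zeros((8, 8)))
        np.testing.assert_allclose(grad_f(x, problem), x, atol=1e-12)

    def test_matches_finite_differences(self, rng, small_observation):
        problem = RestorationProblem(small_observation)
        x = rng.random((16, 16))
        g = grad_f(x, problem)
        h = 1e-6
        for idx in [(0, 0), (3, 7), (15, 15), (8, 2)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = (objective(xp, problem, 0.0) - objective(xm, problem, 0.0)) / (2 * h)
            assert g[idx] == pytest.approx(fd, abs=1e-5)


class TestProx:
    def test_zero_threshold_is_identity(self, rng):
        v = rng.standard_normal((6, 6))
        np.testing.assert_array_equal(prox_l1(v, 0.0), v)
        np.testing.assert_array_equal(prox_euclidean_norm(v, 0.0), v)

    def test_soft_threshold_closed_form_reference_parameters(self):
        # lam * mu = 0.001 * 0.3
        assert prox_l1(np.array([[0.5]]), 3e-4)[0, 0] == pytest.approx(0.4997, abs=1e-15)

    def test_l1_matches_grid_search(self, rng):
        for _ in range(50):
            v = float(rng.uniform(-2, 2))
            t = float(rng.uniform(0, 0.5))
            got = prox_l1(np.array([[v]]), t)[0, 0]
            assert got == pytest.approx(grid_search_prox_l1(v, t), abs=1.01e-4)

    def test_euclidean_matches_grid_search(self, rng):
        for _ in range(10):
            v = rng.uniform(-1.5, 1.5, size=2)
            t = float(rng.uniform(0, 1.0))
            got = prox_euclidean_norm(v, t)
            np.testing.assert_allclose(got, grid_search_prox_l2(v, t), atol=1.5e-4)

    def test_euclidean_shrinks_to_zero_below_threshold(self, rng):
        v = rng.standard_normal((4, 4)) * 0.01
        out = prox_euclidean_norm(v, np.linalg.norm(v) + 0.1)
        np.testing.assert_array_equal(out, 0.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(InvalidParameterError):
            prox_l1(np.zeros((2, 2)), -0.1)
        with pytest.raises(InvalidParameterError):
            prox_euclidean_norm(np.zeros((2, 2)), -0.1)

    @given(t=st.floats(0, 1), scale=st.floats(0.1, 3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_l1_prox_is_nonexpansive(self, t, scale):
        rng = np.random.default_rng(17)
        u = rng.standard_normal((5, 5)) * scale
        v = rng.standard_normal((5, 5)) * scale
        assert np.linalg.norm(prox_l1(u, t) - prox_l1(v, t)) <= np.linalg.norm(u - v) + 1e-12


class TestTsengStep:
    def test_hand_computed_two_pixel_problem(self):
        # D = identity, y = (1, 0), lam = 0.5, mu = 0.2, start at x = y:
        # grad f(y) = 0, w = soft(y, 0.1) = (0.9, 0),
        # grad f(w) = w - y = (-0.1, 0), x+ = w - 0.5*grad f(w) = (0.95, 0)
        y = np.array([[1.0, 0.0]])
        problem = identity_problem(y)
        config = SolverConfig(step_size=0.5, reg_weight=0.2, max_iters=1)
        w, x_next = tseng_step(y, problem, config)
        np.testing.assert_allclose(w, [[0.9, 0.0]], atol=1e-12)
        np.testing.assert_allclose(x_next, [[0.95, 0.0]], atol=1e-12)

    def test_fixed_point_is_preserved(self, rng):
        # for D = identity the minimizer is the soft-thresholded data
        y = rng.random((6, 6))
        mu = 0.2
        x_star = prox_l1(y, mu)
        problem = identity_problem(y)
        config = SolverConfig(step_size=0.5, reg_weight=mu)
        w, x_next = tseng_step(x_star, problem, config)
        np.testing.assert_allclose(w, x_star, atol=1e-12)
        np.testing.assert_allclose(x_next, x_star, atol=1e-12)

    def test_vanishing_step_size_freezes_iterate(self, rng):
        x = rng.random((5, 5))
        problem = identity_problem(rng.random((5, 5)))
        config = SolverConfig(step_size=1e-15, reg_weight=0.3)
        w, x_next = tseng_step(x, problem, config)
        np.testing.assert_allclose(w, x, atol=1e-12)
        np.testing.assert_allclose(x_next, x, atol=1e-12)

    def test_exactly_two_gradient_and_one_prox_evaluations(self, rng, monkeypatch):
        calls = {"grad": 0, "prox": 0}
        real_grad, real_prox = solver_mod.grad_f, solver_mod._prox

        def counting_grad(*a, **k):
            calls["grad"] += 1
            return real_grad(*a, **k)

        def counting_prox(*a, **k):
            calls["prox"] += 1
            return real_prox(*a, **k)

        monkeypatch.setattr(solver_mod, "grad_f", counting_grad)
        monkeypatch.setattr(solver_mod, "_prox", counting_prox)
        problem = identity_problem(rng.random((4, 4)))
        tseng_step(rng.random((4, 4)), problem, SolverConfig(step_size=0.5))
        assert calls == {"grad": 2, "prox": 1}


class TestTsengSolve:
    def test_noise_free_identity_problem_converges_immediately(self, chest64):
        obs = degrade(chest64, DegradationSpec(psf_length=1, noise_family="none"))
        config = SolverConfig(step_size=0.5, reg_weight=0.0, rel_tol=1e-8)
        result = tseng_solve(RestorationProblem(obs), config)
        assert result.trace.iterations_run == 1
        assert result.trace.converged
        np.testing.assert_allclose(result.restored, chest64, atol=1e-14)

    def test_agrees_with_ista_reference(self, rng):
        clean = rng.random((16, 16))
        obs = degrade(
            clean,
            DegradationSpec(psf_length=3, psf_angle=30, noise_family="gaussian",
                            noise_level=0.001, seed=21),
        )
        problem = RestorationProblem(obs)
        mu = 0.05
        D = dense_circulant_matrix(obs.psf.kernel, (16, 16))
        x_ref = ista_minimize(D, obs.observed.ravel(), mu, n_iters=30_000)
        f_ref = 0.5 * np.sum((D @ x_ref - obs.observed.ravel()) ** 2) + mu * np.abs(x_ref).sum()
        config = SolverConfig(step_size=0.5, reg_weight=mu, max_iters=20_000, rel_tol=1e-12)
        result = tseng_solve(problem, config)
        f_got = objective(result.restored, problem, mu)
        assert abs(f_got - f_ref) / f_ref < 1e-4

    def test_fejer_monotone_toward_reference_solution(self, rng):
        clean = rng.random((7, 7))
        obs = degrade(
            clean,
            DegradationSpec(psf_length=3, psf_angle=0, noise_family="gaussian",
                            noise_level=0.001, seed=5),
        )
        mu = 0.05
        D = dense_circulant_matrix(obs.psf.kernel, (7, 7))
        x_star = ista_minimize(D, obs.observed.ravel(), mu, n_iters=100_000).reshape(7, 7)
        config = SolverConfig(step_size=0.45, reg_weight=mu, max_iters=2000, rel_tol=0)
        result = tseng_solve(RestorationProblem(obs), config, keep_iterates=True)
        dists = [np.linalg.norm(it - x_star) for it in result.trace.iterates_kept]
        for d_prev, d_next in zip(dists, dists[1:]):
            assert d_next <= d_prev + 1e-12

    def test_converged_solution_satisfies_optimality_residual(self, small_observation):
        problem = RestorationProblem(small_observation)
        config = SolverConfig(step_size=0.5, reg_weight=0.05, max_iters=50_000, rel_tol=1e-13)
        result = tseng_solve(problem, config)
        assert optimality_residual(result.restored, problem, config) <= 1e-6

    def test_step_norms_fall_below_tolerance(self, small_observation):
        problem = RestorationProblem(small_observation)
        config = SolverConfig(step_size=0.5, reg_weight=0.05, max_iters=20_000, rel_tol=1e-8)
        result = tseng_solve(problem, config)
        assert result.trace.converged
        assert result.trace.iterations_run < config.max_iters
        assert all(s >= 0 for s in result.trace.step_norm)
        assert len(result.trace.objective) == result.trace.iterations_run
        assert len(result.trace.step_norm) == result.trace.iterations_run

    def test_deterministic_bitwise(self, small_observation):
        problem = RestorationProblem(small_observation)
        config = SolverConfig(step_size=0.5, reg_weight=0.05, max_iters=200)
        a = tseng_solve(problem, config)
        b = tseng_solve(problem, config)
        np.testing.assert_array_equal(a.restored, b.restored)
        assert a.trace.objective == b.trace.objective

    def test_step_size_above_lipschitz_limit_rejected(self, small_observation):
        problem = RestorationProblem(small_observation)
        with pytest.raises(InvalidParameterError):
            tseng_solve(problem, SolverConfig(step_size=1.5))

    def test_default_initial_iterate_is_observation(self, small_observation):
        problem = RestorationProblem(small_observation)
        config = SolverConfig(step_size=0.5, reg_weight=0.0, max_iters=1)
        from_default = tseng_solve(problem, config).restored
        from_explicit = tseng_solve(problem, config, x0=small_observation.observed).restored
        np.testing.assert_array_equal(from_default, from_explicit)

    def test_divergence_detector_raises(self, small_observation, monkeypatch):
        problem = RestorationProblem(small_observation)

        def exploding_step(x_k, problem, config):
            return x_k * 3.0, x_k * 3.0 + 1.0

        monkeypatch.setattr(solver_mod, "tseng_step", exploding_step)
        with pytest.raises(DivergenceError):
            solver_mod.tseng_solve(problem, SolverConfig(step_size=0.5, max_iters=100))
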