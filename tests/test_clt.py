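"""Fluctuation machinery: jumps, drift/diffusion, covariance ODE, projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgedrop import EpidemicParams, PoissonDegree, truncate
from edgedrop.clt import (
    CovarianceSolution,
    JumpModel,
    diffusion_G,
    drift,
    final_size_variance_ode_route,
    hitting_projection,
    jacobian_dF,
    nsw_initial_covariance,
    prevalence_moments,
    solve_covariance,
)

M_FIX = 6


@pytest.fixture(scope="module")
def small_dist():
    return truncate(PoissonDegree(3.0), M_FIX, tail_tol=1.0)


@pytest.fixture(scope="module")
def params():
    return EpidemicParams(1.5, 1.0, 1.0)


def random_state(rng, M=M_FIX):
    w = rng.random(2 * M + 3) + 0.02
    return w / w.sum()


class TestDriftDiffusion:
    @pytest.mark.parametrize("variant", ["real", "transformed"])
    def test_closed_form_equals_jump_sum(self, variant, params, rng):
        jm = JumpModel(M_FIX, params, variant)
        for _ in range(10):
            w = random_state(rng)
            assert np.abs(drift(w, params, M_FIX, variant)
                          - jm.drift_from_jumps(w)).max() < 1e-12

    def test_no_infectives_real_drift_zero(self, params):
        w = np.zeros(2 * M_FIX + 3)
        w[:M_FIX + 1] = 1.0 / (M_FIX + 1)
        assert np.abs(drift(w, params, M_FIX, "real")).max() == 0.0

    def test_z_drift_at_z_zero(self, params, rng):
        """z_E-component of the real-time drift is gamma*y_E when z_E = 0."""
        w = random_state(rng)
        w[-1] = 0.0
        i = np.arange(M_FIX + 1)
        yE = float(i @ w[M_FIX + 1:2 * M_FIX + 2])
        assert drift(w, params, M_FIX, "real")[-1] == pytest.approx(
            params.gamma * yE, abs=1e-14)

    @pytest.mark.parametrize("variant", ["real", "transformed"])
    def test_diffusion_psd_and_trace(self, variant, params, rng):
        jm = JumpModel(M_FIX, params, variant)
        for _ in range(10):
            w = random_state(rng)
            G = diffusion_G(w, params, M_FIX, variant, model=jm)
            assert np.abs(G - G.T).max() < 1e-15
            assert np.linalg.eigvalsh(G).min() > -1e-9
            tr = sum(float(v @ v) * b
                     for v, b in zip(jm.vectors, jm.intensities(w)))
            assert np.trace(G) == pytest.approx(tr, rel=1e-12)

    @pytest.mark.parametrize("variant", ["real", "transformed"])
    def test_jacobian_matches_finite_differences(self, variant, params, rng):
        h = 1e-6
        for _ in range(5):
            w = random_state(rng)
            J = jacobian_dF(w, params, M_FIX, variant)
            for c in range(2 * M_FIX + 3):
                e = np.zeros_like(w)
                e[c] = h
                col = (drift(w + e, params, M_FIX, variant)
                       - drift(w - e, params, M_FIX, variant)) / (2 * h)
                assert np.abs(J[:, c] - col).max() < 1e-5 * max(
                    1.0, np.abs(col).max())

    def test_pure_death_y_block(self):
        """omega = beta = 0: the y-block of the Jacobian is -gamma I."""
        p = EpidemicParams(0.0, 1.3, 0.0)
        rng = np.random.default_rng(3)
        w = random_state(rng)
        J = jacobian_dF(w, p, M_FIX, "real")
        yb = J[M_FIX + 1:2 * M_FIX + 2, M_FIX + 1:2 * M_FIX + 2]
        assert np.abs(yb + 1.3 * np.eye(M_FIX + 1)).max() < 1e-12


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_drift_jump_consistency_property(seed):
    """Drift equals jump-vector sum for random states and random rates."""
    rng = np.random.default_rng(seed)
    p = EpidemicParams(0.1 + 2 * rng.random(), 0.1 + rng.random(),
                       2 * rng.random())
    jm = JumpModel(4, p, "real")
    w = rng.random(11) + 0.01
    w /= w.sum()
    assert np.abs(drift(w, p, 4, "real") - jm.drift_from_jumps(w)).max() < 1e-12


class TestCovarianceODE:
    def test_mr_start_symmetric_psd(self, params, small_dist):
        eps = 0.05 * small_dist.pmf
        cs = solve_covariance(params, small_dist, eps, 1.5,
                              t_eval=np.linspace(0, 1.5, 7))
        assert np.abs(cs.sigma[0]).max() == 0.0
        for S in cs.sigma:
            assert np.abs(S - S.T).max() < 1e-9
            assert np.linalg.eigvalsh(S).min() > -1e-7

    def test_pure_death_closed_form(self, small_dist):
        """beta = omega = 0: var(y_i) = eps_i e^{-gt}(1 - e^{-gt})."""
        g = 1.0
        p = EpidemicParams(0.0, g, 0.0)
        eps = 0.05 * small_dist.pmf
        t_eval = np.linspace(0, 2, 9)
        cs = solve_covariance(p, small_dist, eps, 2.0, t_eval=t_eval)
        for k, t in enumerate(t_eval):
            pred = eps * np.exp(-g * t) * (1 - np.exp(-g * t))
            got = np.diag(cs.block("yy", k))
            assert np.abs(got - pred).max() < 1e-6

    def test_initial_covariance_additivity(self, params, small_dist):
        """Sigma_{Sigma0}(t) - Sigma_0ic(t) solves the homogeneous ODE."""
        eps = 0.05 * small_dist.pmf
        S0 = nsw_initial_covariance(small_dist, 0.05)
        t_eval = np.linspace(0, 1.0, 5)
        full = solve_covariance(params, small_dist, eps, 1.0, sigma0=S0,
                                t_eval=t_eval)
        base = solve_covariance(params, small_dist, eps, 1.0, t_eval=t_eval)
        hom = solve_covariance(params, small_dist, eps, 1.0, sigma0=S0,
                               t_eval=t_eval, homogeneous=True)
        diff = full.sigma - base.sigma
        assert np.abs(diff - hom.sigma).max() < 1e-7


class TestNSWInitialCovariance:
    def test_epsilon_zero_y_block(self, small_dist):
        S = nsw_initial_covariance(small_dist, 0.0)
        assert np.abs(S[M_FIX + 1:, M_FIX + 1:]).max() == 0.0

    def test_x_block_sums_to_zero(self, small_dist):
        """Total susceptible count is non-random given i0."""
        S = nsw_initial_covariance(small_dist, 0.05)
        assert S[:M_FIX + 1, :M_FIX + 1].sum() == pytest.approx(0.0, abs=1e-12)

    def test_multinomial_psd(self, small_dist):
        S = nsw_initial_covariance(small_dist, 0.3)
        assert np.linalg.eigvalsh(S).min() > -1e-12


@pytest.fixture(scope="module")
def stopped(params, small_dist):
    eps = 0.05 * small_dist.pmf
    return solve_covariance(params, small_dist, eps, 50.0,
                            variant="transformed", stop_at=0.02)


class TestHittingProjection:
    def test_projection_kills_phi_direction(self, stopped, params, small_dist):
        proj = hitting_projection(stopped.sigma[-1], stopped.w[-1], params,
                                  small_dist.support_max)
        grad = np.zeros(2 * M_FIX + 3)
        grad[M_FIX + 1:2 * M_FIX + 2] = np.arange(M_FIX + 1)
        assert abs(grad @ proj @ grad) < 1e-10

    def test_projector_idempotent(self, stopped, params, small_dist):
        from edgedrop.clt import drift as _drift

        w = stopped.w[-1]
        dim = 2 * M_FIX + 3
        grad = np.zeros(dim)
        grad[M_FIX + 1:2 * M_FIX + 2] = np.arange(M_FIX + 1)
        F = _drift(w, params, M_FIX, "transformed")
        B = np.eye(dim) - np.outer(F, grad) / (grad @ F)
        assert np.abs(B @ B - B).max() < 1e-10

    def test_ode_route_matches_explicit_variance(self, small_dist):
        """delta-extrapolated projection route vs the quadrature formula."""
        from edgedrop import sigma2_mr

        p = EpidemicParams(1.5, 1.0, 1.0)
        eps = 0.05 * small_dist.pmf
        s2_ode = final_size_variance_ode_route(p, small_dist, eps,
                                               deltas=(0.02, 0.01, 0.005))
        s2 = sigma2_mr(p, small_dist, epsilon_vec=eps).sigma2_mr
        assert s2_ode == pytest.approx(s2, rel=0.01)


class TestAgainstSimulation:
    def test_prevalence_mean_sd_bands(self, poisson5_t15):
        """CLT prevalence curves vs an ensemble of simulated epidemics."""
        from edgedrop.effective_degree import InitSpec, simulate, trajectory_at

        p = EpidemicParams(1.5, 1.0, 1.0)
        N, reps = 1000, 300
        epsilon = 0.05
        eps_vec = epsilon * poisson5_t15.pmf
        S0 = nsw_initial_covariance(poisson5_t15, epsilon)
        checkpoints = np.array([0.3, 0.5, 0.7, 0.9, 1.1])
        cs = solve_covariance(p, poisson5_t15, eps_vec, 1.2, sigma0=S0,
                              t_eval=checkpoints)
        mean_frac, sd_frac = prevalence_moments(cs)
        ss = np.random.SeedSequence(424242)
        prev = np.empty((reps, checkpoints.size))
        for k, child in enumerate(ss.spawn(reps)):
            out = simulate(p, poisson5_t15, N, InitSpec("NSW", epsilon),
                           seed=np.random.default_rng(child),
                           record="trajectory")
            prev[k] = trajectory_at(out, checkpoints)[:, 0]
        pred_mean = N * mean_frac
        pred_sd = np.sqrt(N) * sd_frac
        # ensemble mean within 4 standard errors (+ small finite-N slack)
        se_mean = pred_sd / np.sqrt(reps)
        assert np.all(np.abs(prev.mean(axis=0) - pred_mean)
                      < 4 * se_mean + 0.003 * N)
        # ensemble sd within ~3 sampling standard errors + 5% bias allowance
        sd_emp = prev.std(axis=0, ddof=1)
        se_sd = sd_emp / np.sqrt(2 * (reps - 1))
        assert np.all(np.abs(sd_emp - pred_sd) < 3 * se_sd + 0.05 * pred_sd)
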