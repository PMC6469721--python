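"""Stochastic simulation: trivial laws, exact-enumeration oracle, backends."""

import numpy as np
import pytest

from edgedrop import EpidemicParams, FinitePMF, PoissonDegree, truncate
from edgedrop.effective_degree import (
    InitSpec,
    estimate_major_outbreak,
    exact_ctmc_final_size,
    largest_remainder,
    mr_degree_sequence,
    simulate,
    simulate_graph_backend,
    trajectory_at,
)


class TestDegreeSequences:
    def test_largest_remainder_exact_total(self, rng):
        for _ in range(10):
            w = rng.random(8)
            n = int(rng.integers(1, 500))
            alloc = largest_remainder(w, n)
            assert alloc.sum() == n and np.all(alloc >= 0)

    def test_mr_counts_match_proportions(self, poisson5_t15):
        counts = mr_degree_sequence(poisson5_t15, 1000)
        assert counts.sum() == 1000
        assert np.abs(counts - 1000 * poisson5_t15.pmf).max() <= 1.0


class TestTrivialLaws:
    def test_no_transmission(self, poisson5_t15):
        p = EpidemicParams(0.0, 1.0, 0.0)
        for seed in range(5):
            out = simulate(p, poisson5_t15, 200, InitSpec("MR", 7), seed=seed)
            assert out.final_size == 7

    def test_si_on_single_edge(self):
        d = FinitePMF([0.0, 1.0])
        p = EpidemicParams(1.0, 0.0, 0.0)
        for seed in range(10):
            assert simulate(p, d, 2, InitSpec("MR", 1), seed=seed).final_size == 2

    def test_empty_graph_backend(self):
        p = EpidemicParams(1.0, 1.0, 0.0)
        out = simulate_graph_backend(p, np.zeros(10, int), i0=2, seed=0)
        assert out.final_size == 2

    def test_graph_backend_single_edge(self):
        p = EpidemicParams(1.0, 0.0, 0.0)
        for seed in range(5):
            out = simulate_graph_backend(p, [1, 1], i0=1, seed=seed)
            assert out.final_size == 2

    def test_bookkeeping_consistency(self, poisson5_t15):
        p = EpidemicParams(1.5, 1.0, 1.0)
        out = simulate(p, poisson5_t15, 500, InitSpec("MR", 5), seed=3,
                       record="trajectory")
        # ever infected = N - remaining susceptibles
        assert out.final_size == 500 - out.final_susceptibles_by_effective_degree.sum()
        arr = np.asarray(out.trajectory)
        assert np.all(np.diff(arr[:, 0]) >= 0)          # time increases
        assert np.all(np.diff(arr[:, 2]) <= 0)          # susceptibles decrease
        assert arr[-1, 1] == 0                          # ends with no infectives


class TestExactEnumerator:
    def test_beta_zero_point_mass(self):
        pmf = exact_ctmc_final_size(EpidemicParams(0.0, 1.0, 0.0),
                                    [2, 2, 1, 1], i0=1)
        assert pmf == {1: 1.0}

    def test_single_edge_race(self):
        """Degrees (1,1): infection requires the pairing to beat recovery."""
        pmf = exact_ctmc_final_size(EpidemicParams(1.0, 1.0, 0.0), [1, 1], 1)
        assert pmf[2] == pytest.approx(0.5, abs=1e-12)
        assert pmf[1] == pytest.approx(0.5, abs=1e-12)

    def test_omega_dominates(self):
        """Huge dropping rate: warnings beat every infection."""
        pmf = exact_ctmc_final_size(EpidemicParams(1.0, 1.0, 1e6),
                                    [2, 2, 2, 0], 1)
        assert pmf[1] == pytest.approx(1.0, abs=1e-3)

    def test_pmf_sums_to_one(self):
        pmf = exact_ctmc_final_size(EpidemicParams(1.3, 0.7, 0.4),
                                    [1, 2, 2, 1, 2], 1)
        assert sum(pmf.values()) == pytest.approx(1.0, abs=1e-12)

    def test_simulator_matches_enumerator(self):
        """Empirical final-size pmf vs exact absorption probabilities."""
        par = EpidemicParams(1.0, 1.0, 0.5)
        # degrees: two of degree 1, two of degree 2 (6 stubs); infective of
        # degree 1 (the largest-remainder initial-infective choice)
        exact = exact_ctmc_final_size(par, [1, 1, 2, 2], i0=1)
        d = FinitePMF([0.0, 0.5, 0.5])
        n = 20_000
        ss = np.random.SeedSequence(9)
        sizes = np.array([
            simulate(par, d, 4, InitSpec("MR", 1),
                     seed=np.random.default_rng(c)).final_size
            for c in ss.spawn(n)])
        for k, pk in exact.items():
            emp = np.mean(sizes == k)
            se = np.sqrt(pk * (1 - pk) / n)
            assert abs(emp - pk) < 3 * se + 1e-9, (k, emp, pk)

    def test_guards(self):
        with pytest.raises(ValueError):
            exact_ctmc_final_size(EpidemicParams(1, 1, 0), [5] * 20, 1)
        with pytest.raises(ValueError):
            exact_ctmc_final_size(EpidemicParams(1, 1, 0), [1, 1, 1], 1)


class TestBackendEquivalence:
    def test_final_size_distributions_agree(self):
        """Effective-degree vs explicit-graph backend, NSW generative law."""
        par = EpidemicParams(1.5, 1.0, 1.0)
        dist = truncate(PoissonDegree(5.0), 12, 1e-2)
        N, reps = 300, 1200
        ss = np.random.SeedSequence(17)
        eff = np.array([
            simulate(par, dist, N, InitSpec("NSW", 1),
                     seed=np.random.default_rng(c)).final_size
            for c in ss.spawn(reps)])
        ss2 = np.random.SeedSequence(18)
        gb = np.empty(reps)
        for k, c in enumerate(ss2.spawn(reps)):
            rng = np.random.default_rng(c)
            degs = rng.choice(dist.pmf.size, size=N, p=dist.pmf)
            gb[k] = simulate_graph_backend(par, degs, i0=1, seed=rng).final_size
        se = np.sqrt(eff.var(ddof=1) / reps + gb.var(ddof=1) / reps)
        assert abs(eff.mean() - gb.mean()) < 3 * se
        # major-outbreak fractions also agree
        pe, pg = np.mean(eff > 0.15 * N), np.mean(gb > 0.15 * N)
        se_p = np.sqrt(pe * (1 - pe) / reps + pg * (1 - pg) / reps)
        assert abs(pe - pg) < 3 * se_p + 1e-9


class TestMajorOutbreakEstimator:
    def test_threshold_zero_all_major(self, poisson5_t15):
        est = estimate_major_outbreak(EpidemicParams(1.5, 1, 1), poisson5_t15,
                                      200, InitSpec("NSW", 1), 50,
                                      threshold_frac=0.0, seed=1)
        assert est.p_hat == 1.0

    def test_subcritical_no_major(self, poisson5_t15):
        est = estimate_major_outbreak(EpidemicParams(0.1, 1.0, 1.0),
                                      poisson5_t15, 1000, InitSpec("NSW", 5),
                                      100, seed=2)
        assert est.p_hat == pytest.approx(0.0, abs=0.02)
        if est.n_major == 0:
            assert est.mean_major is None and est.sd_major is None

    def test_deterministic_given_seed(self, poisson5_t15):
        kw = dict(threshold_frac=0.15, seed=99)
        p = EpidemicParams(1.5, 1.0, 2.0)
        e1 = estimate_major_outbreak(p, poisson5_t15, 300, InitSpec("NSW", 1),
                                     40, **kw)
        e2 = estimate_major_outbreak(p, poisson5_t15, 300, InitSpec("NSW", 1),
                                     40, **kw)
        assert np.array_equal(e1.final_sizes, e2.final_sizes)


class TestLLNTracking:
    def test_scaled_trajectories_follow_ode(self, poisson5_t15):
        """Simulated prevalence stays within the CLT band around the LLN."""
        from edgedrop.deterministic import solve_real_time

        p = EpidemicParams(1.5, 1.0, 1.0)
        N, reps = 1000, 150
        eps_vec = 0.05 * poisson5_t15.pmf
        checkpoints = np.linspace(0.2, 1.2, 6)
        sol = solve_real_time(p, poisson5_t15, eps_vec, 1.3,
                              t_eval=checkpoints)
        ss = np.random.SeedSequence(77)
        prev = np.empty((reps, checkpoints.size))
        for k, c in enumerate(ss.spawn(reps)):
            out = simulate(p, poisson5_t15, N, InitSpec("MR", 0.05),
                           seed=np.random.default_rng(c), record="trajectory")
            prev[k] = trajectory_at(out, checkpoints)[:, 0]
        ode_prev = N * sol.y_total
        # ensemble-mean prevalence tracks the LLN curve within 2% of N
        assert np.all(np.abs(prev.mean(axis=0) - ode_prev) < 0.02 * N)
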