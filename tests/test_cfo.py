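"""Catch Fish Optimization: update equations, phase discipline, selection."""

import numpy as np
import pytest

from denseinceps import cfo
from denseinceps.cfo import (
    CFOParams,
    OBJECTIVES,
    capture_rate,
    exploitation_step,
    group_capture,
    independent_search,
    init_population,
    optimize,
    select_features,
    selection_objective,
)


class _FakeRng:
    """Deterministic stand-in for a Generator: fixed draws for formula checks."""

    def __init__(self, integers=0, random=0.0, uniform=0.0, normal=0.0):
        self._integers, self._random = integers, random
        self._uniform, self._normal = uniform, normal

    def integers(self, *a, **k):
        return self._integers

    def random(self, *a, **k):
        return self._random

    def uniform(self, lo, hi, size=None):
        return np.full(size, self._uniform) if size else self._uniform

    def standard_normal(self, size=None):
        return np.full(size, self._normal) if size else self._normal

    def normal(self, mu, sd, size=None):
        return np.full(size, self._normal) if size else self._normal


def _pop(positions, fitness, lb=-10.0, ub=10.0, EFs=0, MaxEFs=100):
    positions = np.asarray(positions, dtype=float)
    return cfo.FisherPopulation(
        positions=positions, fitness=np.asarray(fitness, dtype=float),
        lb=np.full(positions.shape[1], lb), ub=np.full(positions.shape[1], ub),
        EFs=EFs, MaxEFs=MaxEFs)


class TestCaptureRate:
    def test_starts_at_one(self):
        assert capture_rate(0, 1000) == 1.0

    def test_value_at_one_third_of_budget(self):
        assert capture_rate(100, 300) == pytest.approx(0.5 ** 0.5, abs=1e-12)

    def test_value_near_phase_boundary(self):
        assert capture_rate(49, 100) == pytest.approx(
            (1 - 0.735) ** 0.735, abs=1e-12)

    def test_domain_error_beyond_two_thirds(self):
        with pytest.raises(ValueError):
            capture_rate(70, 100)


class TestInitPopulation:
    def test_degenerate_box_collapses_to_point(self):
        p = init_population(CFOParams(M=5, MaxEFs=10, seed=0),
                            [2.0, 2.0], [2.0, 2.0])
        np.testing.assert_array_equal(p.positions, 2.0)

    def test_positions_respect_bounds(self):
        p = init_population(CFOParams(M=50, MaxEFs=50, seed=1),
                            [-1.0, 0.0], [2.0, 5.0])
        assert np.all(p.positions >= [-1.0, 0.0])
        assert np.all(p.positions <= [2.0, 5.0])

    def test_midpoint_draw_lands_mid_box(self):
        # x = (ub-lb)*n + lb with n=0.5 -> (1, 2) for box (0,0)-(2,4)
        lb, ub = np.array([0.0, 0.0]), np.array([2.0, 4.0])
        np.testing.assert_allclose((ub - lb) * 0.5 + lb, [1.0, 2.0])

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            init_population(CFOParams(M=4, MaxEFs=8, seed=0), [1.0], [0.0])

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            CFOParams(M=3, MaxEFs=100)


class TestIndependentSearch:
    def test_equal_fitness_leaves_position_unchanged(self):
        # fit_max == fit_min -> Exp = 0 -> zero drift and zero noise radius
        pop = _pop([[0.0], [5.0], [-5.0]], [1.0, 1.0, 1.0])
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(independent_search(pop, 0, rng), [0.0])

    def test_drift_follows_empirical_gap(self):
        # fit_j=2, fit_ref=1, fit range [1,3] -> Exp=0.5; with zero noise the
        # update is x_j + 0.5*(x_ref - x_j)
        pop = _pop([[0.0, 0.0], [2.0, 4.0], [1.0, 1.0]], [2.0, 1.0, 3.0],
                   EFs=20, MaxEFs=100)
        new = independent_search(pop, 0, _FakeRng(integers=0, random=0.0,
                                                  normal=0.0))
        np.testing.assert_allclose(new, [1.0, 2.0])

    def test_noise_radius_is_bounded_by_exploration_range(self):
        # S = D * |Exp| * (1 - EFs/MaxEFs) = 0.4 D here; the step must end
        # within radius S of the deterministic drift point for its reference
        pop = _pop([[0.0], [2.0], [1.0]], [2.0, 1.0, 3.0], EFs=20, MaxEFs=100)
        rng = np.random.default_rng(0)
        balls = []
        for ref, exp in ((1, 0.5), (2, -0.5)):
            diff = pop.positions[ref] - pop.positions[0]
            drift = pop.positions[0] + diff * exp
            balls.append((drift, 0.4 * abs(diff[0])))
        for _ in range(200):
            new = independent_search(pop, 0, rng)
            assert any(np.linalg.norm(new - drift) <= s + 1e-9
                       for drift, s in balls)

    def test_single_agent_rejected(self):
        pop = _pop([[0.0]], [1.0])
        with pytest.raises(ValueError):
            independent_search(pop, 0, np.random.default_rng(0))


class TestGroupCapture:
    def test_coincident_group_stays_put_without_noise(self):
        pop = _pop([[1.0, 2.0]] * 4, [1.0] * 4)
        new = group_capture(pop, [0, 1, 2], _FakeRng(random=0.5, uniform=0.0))
        np.testing.assert_array_equal(new, [[1.0, 2.0]] * 3)

    def test_unit_speed_lands_on_centroid(self):
        pop = _pop([[0.0], [3.0], [6.0]], [1.0, 2.0, 3.0])
        new = group_capture(pop, [0, 1, 2], _FakeRng(random=1.0, uniform=0.0))
        np.testing.assert_allclose(new, [[3.0]] * 3)

    def test_centroid_is_arithmetic_mean_per_dimension(self):
        rng = np.random.default_rng(5)
        pos = rng.standard_normal((4, 3))
        pop = _pop(pos, np.arange(4.0))
        new = group_capture(pop, [0, 1, 2, 3], _FakeRng(random=1.0, uniform=0.0))
        np.testing.assert_allclose(new, np.tile(pos.mean(axis=0), (4, 1)),
                                   atol=1e-12)

    def test_wrong_group_size_rejected(self):
        pop = _pop([[0.0]] * 6, [1.0] * 6)
        with pytest.raises(ValueError):
            group_capture(pop, [0, 1], np.random.default_rng(0))


class TestExploitation:
    def test_exhausted_budget_collapses_to_gbest(self):
        pop = _pop([[1.0], [2.0], [3.0], [4.0]], [1, 2, 3, 4],
                   EFs=100, MaxEFs=100)
        pop.Gbest = np.array([1.0])
        new = exploitation_step(pop, np.random.default_rng(0))
        np.testing.assert_array_equal(new, [[1.0]] * 4)

    def test_population_mean_at_gbest_gives_zero_spread(self):
        pop = _pop([[2.0], [0.0], [4.0], [2.0]], [1, 2, 3, 4],
                   EFs=60, MaxEFs=100)
        pop.Gbest = np.array([2.0])
        new = exploitation_step(pop, np.random.default_rng(0))
        np.testing.assert_array_equal(new, [[2.0]] * 4)

    def test_monte_carlo_variance_matches_spread_parameter(self):
        # per-dimension variance of the Gaussian is n4 * eta * |mean - G| / 3;
        # mixing n4 uniformly over {1,2,3} gives overall variance 2*eta*spread
        pop = _pop([[0.0], [1.0], [2.0], [3.0]], [1, 2, 3, 4],
                   EFs=60, MaxEFs=100, lb=-1e9, ub=1e9)
        pop.Gbest = np.array([0.0])
        eta = cfo._eta(60, 100)
        spread = abs(1.5 - 0.0) / 3.0
        rng = np.random.default_rng(42)
        draws = np.concatenate([exploitation_step(pop, rng).ravel()
                                for _ in range(25000)])
        assert draws.var() == pytest.approx(2.0 * eta * spread, rel=0.02)


class TestOptimize:
    def test_constant_objective_reports_constant(self):
        _, fbest, _ = optimize(lambda x: 7.5, [-1] * 2, [1] * 2,
                               CFOParams(M=5, MaxEFs=50, seed=0))
        assert fbest == 7.5

    def test_recovers_quadratic_minimum(self):
        g, f, _ = optimize(OBJECTIVES["quadratic"], [-10], [10],
                           CFOParams(M=20, MaxEFs=2000, seed=1))
        grid = np.linspace(-10, 10, 100001)
        grid_best = grid[np.argmin((grid - 3.0) ** 2)]
        assert abs(g[0] - 3.0) < 0.1
        assert abs(g[0] - grid_best) < 0.1

    @pytest.mark.parametrize("name", ["sphere", "quadratic", "rastrigin"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trace_is_monotone_and_budget_exact(self, name, seed):
        _, _, trace = optimize(OBJECTIVES[name], [-5] * 3, [5] * 3,
                               CFOParams(M=10, MaxEFs=500, seed=seed))
        assert len(trace) == 500  # one record per evaluation, EFs == MaxEFs
        assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_positions_stay_in_bounds_throughout(self):
        seen = []

        def fobj(x):
            seen.append(x.copy())
            return float(np.sum(x ** 2))

        optimize(fobj, [-0.5] * 4, [0.5] * 4, CFOParams(M=8, MaxEFs=400, seed=3))
        arr = np.array(seen)
        assert np.all(arr >= -0.5) and np.all(arr <= 0.5)

    def test_same_seed_gives_bit_identical_trace(self):
        runs = [optimize(OBJECTIVES["sphere"], [-5] * 2, [5] * 2,
                         CFOParams(M=6, MaxEFs=300, seed=9)) for _ in range(2)]
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        assert runs[0][2] == runs[1][2]

    def test_phase_discipline(self, monkeypatch):
        """Exploitation never before half budget; exploration never after."""
        phases = []
        real_exploit = cfo.exploitation_step
        real_indep = cfo.independent_search

        def spy_exploit(pop, rng):
            phases.append(("exploit", pop.EFs / pop.MaxEFs))
            return real_exploit(pop, rng)

        def spy_indep(pop, j, rng):
            phases.append(("explore", pop.EFs / pop.MaxEFs))
            return real_indep(pop, j, rng)

        monkeypatch.setattr(cfo, "exploitation_step", spy_exploit)
        monkeypatch.setattr(cfo, "independent_search", spy_indep)
        optimize(OBJECTIVES["sphere"], [-1] * 2, [1] * 2,
                 CFOParams(M=10, MaxEFs=200, seed=4))
        assert phases
        for kind, ratio in phases:
            if kind == "exploit":
                assert ratio >= 0.5
            else:
                assert ratio < 0.5

    def test_budget_below_population_rejected(self):
        with pytest.raises(ValueError):
            CFOParams(M=10, MaxEFs=5)


class TestFeatureSelection:
    @staticmethod
    def _problem(seed, n=120, d=6, informative=2, shift=3.0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, d))
        X[:, :informative] += shift * y[:, None]
        return X, y

    def test_perfect_feature_is_selected_without_penalty(self):
        rng = np.random.default_rng(0)
        n = 100
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 4))
        X[:, 2] = y * 10.0  # perfectly predictive
        mask = select_features(X, y, lam=0.0,
                               params=CFOParams(M=10, MaxEFs=300, seed=0))
        assert mask.mask[2]

    def test_pure_noise_with_penalty_selects_single_feature(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 5))
        y = rng.integers(0, 2, 80)
        mask = select_features(X, y, lam=0.5,
                               params=CFOParams(M=10, MaxEFs=400, seed=1))
        assert mask.selected_count == 1

    def test_matches_exhaustive_search_on_small_problem(self):
        X, y = self._problem(7)
        m = select_features(X, y, lam=0.05,
                            params=CFOParams(M=12, MaxEFs=600, seed=7))
        score = selection_objective(X, y, 0.05, seed=7)
        best = min(score(np.array([b >> i & 1 for i in range(6)], bool))
                   for b in range(1, 64))
        assert m.fitness == pytest.approx(best, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_features(np.zeros((10, 3)), np.zeros(10, dtype=int))
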