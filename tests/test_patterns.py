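"""Averaging-pattern construction, budget projection, and integer rounding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

import kspace_design as kd
from kspace_design.patterns import (
    budget_effective,
    center_distance,
    exhaustive_integer_rounding,
    load_pattern_txt,
    save_pattern_txt,
)


class TestUniformPattern:
    def test_full_grid_gives_reference_averages(self):
        assert np.allclose(kd.uniform_pattern(320, 320, 8).w, 8.0)

    def test_half_grid_quadruples_effective_averages(self):
        pat = kd.uniform_pattern(160, 320, 8)
        assert np.allclose(pat.w, 32.0)
        assert pat.w.sum() == pytest.approx(8 * 320 ** 2 / 160)

    @pytest.mark.parametrize("N,N0,w0", [(4, 16, 2), (10, 30, 3), (64, 64, 8)])
    def test_budget_residual_zero(self, N, N0, w0):
        pat = kd.uniform_pattern(N, N0, w0)
        assert pat.is_feasible
        assert kd.project_to_budget(pat.w, pat.budget) == pytest.approx(pat.w)


class TestProjectToBudget:
    def test_feasible_input_unchanged(self):
        w = np.array([2.0, 3.0, 4.0])
        assert np.allclose(kd.project_to_budget(w, 9.0), w)

    def test_worked_example_matches_qp_oracle(self):
        w = np.array([1.0, 2.0, 3.0])
        got = kd.project_to_budget(w, 9.0)
        assert np.allclose(got, [2.0, 3.0, 4.0])
        # generic equality-constrained quadratic program oracle
        res = minimize(
            lambda v: 0.5 * np.sum((v - w) ** 2),
            w,
            constraints={"type": "eq", "fun": lambda v: v.sum() - 9.0},
        )
        assert np.allclose(got, res.x, atol=1e-6)

    def test_projection_is_closest_feasible_point(self, rng):
        w = rng.uniform(0.5, 5.0, size=10)
        budget = 60.0
        proj = kd.project_to_budget(w, budget)
        assert proj.sum() == pytest.approx(budget, rel=1e-12)
        for _ in range(100):
            v = rng.uniform(0.001, 10.0, size=10)
            v = v * budget / v.sum()
            assert np.linalg.norm(proj - w) <= np.linalg.norm(v - w) + 1e-9

    def test_idempotent(self, rng):
        w = rng.uniform(-1.0, 5.0, size=8)
        p1 = kd.project_to_budget(w, 20.0)
        assert np.allclose(kd.project_to_budget(p1, 20.0), p1)

    def test_positivity_floor_redistributes(self):
        w = np.array([10.0, 10.0, 0.0005])
        out = kd.project_to_budget(w, 12.0)
        assert out.min() >= 1e-3 - 1e-15
        assert out.sum() == pytest.approx(12.0)

    def test_nonpositive_budget_rejected(self):
        with pytest.raises(ValueError):
            kd.project_to_budget(np.ones(3), 0.0)

    @given(st.lists(st.floats(0.01, 50.0), min_size=2, max_size=16), st.floats(5.0, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_budget_met_exactly(self, w, budget):
        out = kd.project_to_budget(np.array(w), budget)
        assert abs(out.sum() - budget) <= 1e-9 * max(1.0, budget)


class TestNormalizeGradient:
    def test_three_four_five(self):
        assert np.allclose(kd.normalize_gradient(np.array([3.0, 4.0])), [0.6, 0.8])

    def test_zero_gradient_returns_zero(self):
        assert np.array_equal(kd.normalize_gradient(np.zeros(5)), np.zeros(5))

    def test_unit_norm(self, rng):
        g = rng.standard_normal(32)
        assert np.linalg.norm(kd.normalize_gradient(g)) == pytest.approx(1.0, abs=1e-12)


class TestRounding:
    def test_integer_fixed_point(self):
        # (N/N0) w already integer with the right sum: returned unchanged
        w = kd.effective_averages(np.array([3.0, 5.0, 5.0, 3.0]), N=4, N0=8)
        pat = kd.AveragingPattern(N=4, w=w, N0=8, w0=2)
        assert np.array_equal(kd.round_to_integer_averages(pat).q, [3, 5, 5, 3])

    def test_worked_example_terminates_at_nearest_integer(self):
        v = np.array([3.6, 5.05, 4.95, 2.4])
        pat = kd.AveragingPattern(N=4, w=v * 8 / 4, N0=8, w0=2)
        q = kd.round_to_integer_averages(pat).q
        assert np.array_equal(q, [4, 5, 5, 2])
        assert np.abs(q - v).sum() == pytest.approx(exhaustive_integer_rounding(v, 16))

    def test_greedy_equals_exhaustive_small_instances(self, rng):
        """Global optimality of greedy rounding over the small integer simplex."""
        for _ in range(60):
            n = int(rng.choice([2, 4]))
            target = int(rng.integers(n, 13))
            v = rng.uniform(0.05, 2.0 * target / n, size=n)
            v = v * target / v.sum()
            # budget w0*N0 = target with N0 = target, w0 = 1
            pat = kd.AveragingPattern(N=n, w=v * target / n, N0=target, w0=1)
            q = kd.round_to_integer_averages(pat).q
            cost = np.abs(q - v).sum()
            assert cost == pytest.approx(exhaustive_integer_rounding(v, target), abs=1e-9)
            assert q.sum() == target and np.all(q >= 0)

    def test_tie_breaks_preserve_center(self):
        # all-equal fractional parts: the greedy removals must hit the
        # outermost lines first, leaving the central pair at 3 averages
        v = np.full(4, 2.5)  # nearest-integer start [3,3,3,3], target sum 10
        pat = kd.AveragingPattern(N=4, w=v * 10 / 4, N0=10, w0=1)
        q = kd.round_to_integer_averages(pat).q
        assert np.array_equal(q, [2, 3, 3, 2])

    def test_center_distance_even_grid(self):
        d = center_distance(4)  # m in {-2,-1,0,1} -> |m+1/2|
        assert np.allclose(d, [1.5, 0.5, 0.5, 1.5])

    def test_infeasible_budget_rejected(self):
        pat = kd.uniform_pattern(4, 4, 0.5)  # budget 2 TRs < 4 lines
        with pytest.raises(ValueError):
            kd.round_to_integer_averages(pat, require_sampled=True)

    def test_round_trip_text_io(self, tmp_path):
        q = kd.round_to_integer_averages(kd.uniform_pattern(8, 16, 8))
        path = tmp_path / "pattern.txt"
        save_pattern_txt(path, q)
        back = load_pattern_txt(path)
        assert np.array_equal(back.q, q.q)
        assert (back.N, back.N0, back.w0) == (q.N, q.N0, q.w0)


class TestBudgetConservationSweep:
    def test_thousand_random_instances(self, rng):
        """Projection meets the budget to 1e-9 relative; rounding exactly."""
        for _ in range(1000):
            N = int(rng.choice([4, 8, 16]))
            N0 = int(N * rng.choice([1, 2, 4]))
            w0 = int(rng.integers(1, 9))
            budget = budget_effective(N, N0, w0)
            w = rng.uniform(0.01, 4.0, size=N) * budget / N
            proj = kd.project_to_budget(w, budget)
            assert abs(proj.sum() - budget) <= 1e-9 * budget
            q = kd.round_to_integer_averages(kd.AveragingPattern(N=N, w=proj, N0=N0, w0=w0))
            assert int(q.q.sum()) == w0 * N0
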