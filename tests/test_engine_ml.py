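"""ML engine: grouped summation, CG pieces, line search, full refinement."""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ptychokit.datamodel import ProbeStack
from ptychokit.engine_dm import dm_error
from ptychokit.engine_ml import (
    LineSearchError,
    MLSettings,
    _apply_step,
    _combine,
    _inner,
    grouped_sum,
    line_search,
    ml_gradient,
    ml_iterate,
    ml_objective,
    pr_plus_beta,
)
from ptychokit.simulator import initial_state

from conftest import make_manual_state


def exact_sum(values):
    return float(mpmath.fsum([mpmath.mpf(float(v)) for v in values]))


class TestGroupedSum:
    def test_empty_is_zero(self):
        assert grouped_sum([]) == 0.0

    def test_single_precision_cancellation(self):
        """Alternating +-1e8 with unit terms: naive float32 summation
        loses the units entirely; grouped summation keeps them."""
        block = np.array([1e8, 1.0, -1e8, 1.0], dtype=np.float32)
        values = np.tile(block, 10_000)
        naive = np.float32(0.0)
        for v in values:
            naive = np.float32(naive + v)
        assert naive != 20_000.0  # the failure mode being mitigated
        assert grouped_sum(values) == 20_000.0

    def test_wide_dynamic_range_within_bound(self):
        rng = np.random.default_rng(17)
        values = rng.standard_normal(100_000) * 10.0 ** rng.uniform(-8, 8, 100_000)
        bound = 64 * np.finfo(float).eps * np.sum(np.abs(values))
        assert abs(grouped_sum(values) - exact_sum(values)) <= bound

    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance_within_bound(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.standard_normal(200) * 10.0 ** rng.uniform(-6, 6, 200)
        bound = 64 * np.finfo(float).eps * np.sum(np.abs(values))
        reference = exact_sum(values)
        assert abs(grouped_sum(values) - reference) <= bound
        assert abs(grouped_sum(rng.permutation(values)) - reference) <= bound


def vec(seed, scale=1.0):
    rng = np.random.default_rng(seed)
    probe = scale * (rng.standard_normal((3, 3, 1, 1)) + 1j * rng.standard_normal((3, 3, 1, 1)))
    obj = scale * (rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4)))
    return probe, {1: obj}


class TestPRPlusBeta:
    def test_equal_gradients_restart(self):
        g = vec(18)
        assert pr_plus_beta(g, g) == 0.0

    def test_orthogonal_gradients_give_norm_ratio(self):
        g_old = (np.zeros((2, 2, 1, 1), complex), {1: np.array([[1.0 + 0j, 0], [0, 0]])})
        g_new = (np.zeros((2, 2, 1, 1), complex), {1: np.array([[0, 2.0 + 0j], [0, 0]])})
        assert pr_plus_beta(g_new, g_old, powell_threshold=0.2) == pytest.approx(4.0)

    def test_matches_direct_formula(self):
        g_old, g_new = vec(19), vec(20)

        def flat(g):
            return np.concatenate([g[0].ravel(), g[1][1].ravel()])

        a, b = flat(g_new), flat(g_old)
        num = np.vdot(b, a).real  # <g_new, g_old>
        gn2 = np.vdot(a, a).real
        expected = 0.0 if abs(num) >= 0.2 * gn2 else max(
            0.0, (gn2 - num) / np.vdot(b, b).real
        )
        assert pr_plus_beta(g_new, g_old) == pytest.approx(expected, rel=1e-12)

    def test_zero_old_gradient_rejected(self):
        zero = (np.zeros((2, 2, 1, 1), complex), {1: np.zeros((2, 2), complex)})
        with pytest.raises(ValueError):
            pr_plus_beta(vec(21), zero)

    def test_zero_threshold_always_restarts(self):
        assert pr_plus_beta(vec(22), vec(23), powell_threshold=0.0) == 0.0


class TestLineSearch:
    settings = MLSettings()

    def test_exact_quadratic_found_by_fit(self):
        evals = []

        def f(a):
            evals.append(a)
            return (a - 2.0) ** 2

        alpha, falpha, n = line_search(f, f0=4.0, slope0=-4.0, settings=self.settings)
        assert 1.0 <= alpha <= 3.0
        assert alpha == pytest.approx(2.0, abs=1e-6)
        assert len(evals) <= 3

    def test_decreasing_function_accepts_first_point(self):
        alpha, falpha, _ = line_search(
            lambda a: 10.0 - 0.9 * a, f0=10.0, slope0=-1.0, settings=self.settings
        )
        assert alpha > 0
        assert falpha <= 10.0 - self.settings.armijo_c1 * alpha

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            line_search(lambda a: a, f0=0.0, slope0=1.0, settings=self.settings)

    def test_no_armijo_point_raises(self):
        # claims descent but immediately jumps up and stays there
        with pytest.raises(LineSearchError):
            line_search(lambda a: 1.0, f0=0.0, slope0=-1.0, settings=self.settings)

    def test_narrow_valley_needs_bisection(self):
        f = lambda a: abs(a - 0.001) + 0.001  # minimum far below initial step
        alpha, falpha, _ = line_search(f, f0=1.001, slope0=-1.0, settings=self.settings)
        assert falpha <= 1.001 + self.settings.armijo_c1 * alpha * -1.0


class TestObjectiveAndGradient:
    def test_zero_at_exact_solution(self, manual_state):
        assert ml_objective(manual_state) < 1e-18

    def test_equals_raw_dm_error(self, manual_state):
        state = manual_state.copy()
        state.objects.objects[1] *= 0.7 + 0.1j
        raw, _ = dm_error(state)
        assert ml_objective(state) == pytest.approx(raw, rel=1e-10)

    def test_toy_hand_sum(self):
        state = make_manual_state(n=2, seed=24)
        state.data.intensities = (np.sqrt(state.data.intensities) + 0.2) ** 2
        assert ml_objective(state) == pytest.approx(4 * 0.2**2, rel=1e-9)

    def test_gradient_vanishes_at_solution(self, tiny_sim):
        state, _ = tiny_sim
        pg, og = ml_gradient(state)
        flux = state.data.intensities.sum()
        norm = np.sqrt(np.sum(np.abs(pg) ** 2) + np.sum(np.abs(og[1]) ** 2))
        assert norm < 1e-8 * flux

    def test_gradient_wrt_object_zero_for_zero_probe(self, manual_state):
        state = manual_state.copy()
        state.probes = ProbeStack(np.zeros_like(state.probes.values))
        _, og = ml_gradient(state)
        assert np.all(og[1] == 0)

    def test_matches_central_finite_differences(self, tiny_sim):
        """Directional derivative from the objective equals <g, d>."""
        state, _ = tiny_sim
        st_ = initial_state(state)
        rng = np.random.default_rng(25)
        scale = np.sqrt((np.abs(st_.probes.values) ** 2).mean())
        st_.probes.values += 0.05 * scale * (
            rng.standard_normal(st_.probes.values.shape)
            + 1j * rng.standard_normal(st_.probes.values.shape)
        )
        o = st_.objects.field2d(1)
        st_.objects.set_field2d(
            1, o + 0.05 * (rng.standard_normal(o.shape) + 1j * rng.standard_normal(o.shape))
        )
        grad = ml_gradient(st_)
        dp = scale * (
            rng.standard_normal(st_.probes.values.shape)
            + 1j * rng.standard_normal(st_.probes.values.shape)
        )
        do = {1: rng.standard_normal(o.shape) + 1j * rng.standard_normal(o.shape)}
        direction = (dp, do)
        analytic = _inner(grad, direction)
        eps = 1e-6
        fd = (
            ml_objective(_apply_step(st_, direction, eps))
            - ml_objective(_apply_step(st_, direction, -eps))
        ) / (2 * eps)
        assert fd == pytest.approx(analytic, rel=1e-4)


class TestMLIterate:
    def test_exact_solution_terminates_unchanged(self, manual_state):
        rec = ml_iterate(manual_state, MLSettings(max_iterations=5))
        assert rec.error_history == []
        assert np.array_equal(rec.probes.values, manual_state.probes.values)

    def test_objective_non_increasing(self, dm_ml):
        errors = [v for e, _, v in dm_ml.error_history if e == "ml"]
        assert all(b <= a * (1 + 1e-12) for a, b in zip(errors, errors[1:]))

    def test_reaches_target_after_dm(self, dm_ml):
        errors = [v for e, _, v in dm_ml.error_history if e == "ml"]
        assert errors[-1] < 1e-6

    def test_powell_zero_reduces_to_steepest_descent(self):
        """Forced restarts every iteration == an independent steepest-descent
        loop with no CG memory, step for step."""
        state = make_manual_state(n=4, seed=5)
        rng = np.random.default_rng(7)
        o = state.objects.field2d(1)
        state.objects.set_field2d(1, o * np.exp(1j * rng.uniform(-0.3, 0.3, o.shape)))
        settings = MLSettings(
            max_iterations=6, powell_threshold=0.0, optimize_probe=False
        )
        rec = ml_iterate(state.copy(), settings)

        # oracle: plain gradient descent built from the verified pieces
        st_ = state.copy()
        f_cur = ml_objective(st_)
        prev_alpha = None
        for _ in range(6):
            g = ml_gradient(st_)
            g = (np.zeros_like(g[0]), g[1])
            gn2 = _inner(g, g)
            d = _combine(g, g, -1.0, 0.0)
            slope0 = -gn2
            init = prev_alpha if prev_alpha else min(1.0, 2.0 * f_cur / -slope0)
            alpha, f_cur, _ = line_search(
                lambda a, _d=d: ml_objective(_apply_step(st_, _d, a)),
                f_cur,
                slope0,
                settings,
                init,
            )
            st_ = _apply_step(st_, d, alpha)
            prev_alpha = alpha
        assert np.max(np.abs(rec.objects.field2d(1) - st_.objects.field2d(1))) < 1e-6
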