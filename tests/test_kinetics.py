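"""Swollen-fraction kinetics, the delayed volume equation, and diagnostics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mitoswell as ms
from mitoswell.kinetics import ClosedFormUnavailableError


def params(a=0.2, b=0.021, k=0.75, tau=10.0, r=1.0):
    return ms.SwellingParameters(a=a, b=b, k=k, tau=tau, r=r)


class TestSwellingRate:
    @pytest.mark.parametrize(
        "x, p, expected",
        [
            (0.0, params(a=0.3), 0.021 * 0.9),          # X'(0+) = b * X_p
            (0.9, params(), 0.0),                        # fixed point at X_p
            (0.5, params(a=0.1882), (0.1882 * 0.5 + 0.021) * 0.4),
        ],
    )
    def test_rate_values(self, x, p, expected, consts):
        assert ms.swelling_rate(x, p, consts) == pytest.approx(expected, abs=1e-15)

    def test_rejects_fraction_outside_domain(self, consts):
        with pytest.raises(ValueError):
            ms.swelling_rate(-0.1, params(), consts)
        with pytest.raises(ValueError):
            ms.swelling_rate(0.95, params(), consts)


class TestClosedForm:
    def test_initial_and_limit(self, consts):
        p = params()
        assert ms.swelling_fraction(0.0, p, consts) == 0.0
        assert ms.swelling_fraction(1e4, p, consts) == pytest.approx(consts.X_p, abs=1e-9)

    def test_negative_time_is_zero_history(self):
        assert ms.swelling_fraction(-3.0, params()) == 0.0
        vals = ms.swelling_fraction(np.array([-1.0, 0.0, 1.0]), params())
        assert vals[0] == 0.0 and vals[1] == 0.0 and vals[2] > 0.0

    def test_first_order_reduction(self, consts):
        # a = 0: X(t) = X_p * (1 - exp(-b t)); at t = 1/b that is X_p(1 - 1/e)
        p = params(a=0.0, b=0.021)
        t = 1.0 / 0.021
        assert ms.swelling_fraction(t, p, consts) == pytest.approx(
            0.9 * (1 - np.exp(-1)), rel=1e-12
        )

    def test_requires_first_order_feedback(self):
        with pytest.raises(ClosedFormUnavailableError):
            ms.swelling_fraction(5.0, params(r=1.3))

    def test_matches_numeric_integration(self, grid, consts):
        p = params(a=0.1882, b=0.021)
        numeric = ms.integrate_fraction(p, consts, grid)
        closed = ms.swelling_fraction(grid, p, consts)
        assert np.max(np.abs(numeric.values - closed)) <= 1e-8

    @given(
        a=st.floats(0.05, 0.6),
        b=st.floats(0.005, 0.04),
        t1=st.floats(0.0, 50.0),
        dt=st.floats(0.01, 10.0),
    )
    def test_monotone_and_bounded(self, a, b, t1, dt):
        p = params(a=a, b=b)
        x1 = ms.swelling_fraction(t1, p)
        x2 = ms.swelling_fraction(t1 + dt, p)
        assert 0.0 <= x1 <= 0.9 and 0.0 <= x2 <= 0.9
        assert x2 >= x1

    @given(a=st.floats(0.05, 0.6), b=st.floats(0.005, 0.03))
    def test_single_inflection_in_feedback_regime(self, a, b):
        # with feedback strong enough that a*X_p > b, X turns from convex
        # to concave exactly once
        if a * 0.9 <= b:
            return
        p = params(a=a, b=b)
        t = np.linspace(0.0, 400.0, 8001)
        x = ms.swelling_fraction(t, p)
        d2 = np.diff(x, 2)
        signs = np.sign(d2[np.abs(d2) > 1e-14])
        changes = np.sum(np.diff(signs) != 0)
        assert changes == 1


class TestIntegrator:
    def test_no_swelling_without_background_rate(self, grid):
        res = ms.integrate_fraction(params(b=0.0), grid=grid)
        assert np.all(res.values == 0.0)
        assert np.all(ms.swelling_fraction(grid, params(b=0.0)) == 0.0)

    def test_higher_order_converges_to_plateau(self):
        p = params(a=0.3, b=0.021, r=1.6)
        grid = np.linspace(0.0, 600.0, 1201)
        res = ms.integrate_fraction(p, grid=grid)
        assert np.all(np.diff(res.values) >= -1e-12)
        assert res.values[-1] == pytest.approx(0.9, abs=1e-6)

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            ms.integrate_fraction(params(), grid=np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            ms.integrate_fraction(params(), grid=np.array([1.0, 2.0, 3.0]))


class TestSubpopulations:
    def test_all_unswollen_at_start(self):
        u, s, d = ms.subpopulation_split(0.0, params())
        assert (u, s, d) == (1.0, 0.0, 0.0)

    def test_none_finished_before_delay(self):
        p = params(tau=10.0)
        t = np.array([2.0, 5.0, 9.9])
        u, s, d = ms.subpopulation_split(t, p)
        assert np.all(d == 0.0)
        assert np.allclose(s, ms.swelling_fraction(t, p))

    def test_long_time_limits(self, consts):
        u, s, d = ms.subpopulation_split(1e4, params())
        assert u == pytest.approx(1 - consts.X_p, abs=1e-8)
        assert s == pytest.approx(0.0, abs=1e-8)
        assert d == pytest.approx(consts.X_p, abs=1e-8)

    @given(t=st.floats(0.0, 200.0), a=st.floats(0.0, 0.6), tau=st.floats(0.0, 40.0))
    def test_fractions_sum_to_one(self, t, a, tau):
        u, s, d = ms.subpopulation_split(t, params(a=a, tau=tau))
        total = u + s + d
        assert total == pytest.approx(1.0, abs=1e-12)
        for frac in (u, s, d):
            assert -1e-12 <= frac <= 1 + 1e-12


class TestVolume:
    def test_initial_and_limit_volumes(self, consts, grid):
        v = ms.total_volume(grid, params(), consts)
        assert v.values[0] == consts.V0 == 1.2
        v_inf = ms.total_volume(1e4, params(), consts).values[0]
        assert v_inf == pytest.approx(0.1 * 1.2 + 0.9 * 1.7, abs=1e-8)  # 1.65
        assert np.allclose(v.components.sum(axis=0), v.values)
        assert np.all(v.values <= max(consts.V0, consts.V_p) + 1e-12)

    def test_shrinking_regime_dips_below_initial_volume(self, consts):
        # k*V_p = 0.935 < V0 = 1.2: mean volume transiently shrinks
        p = params(a=0.7, b=0.02, k=0.55, tau=5.0)
        t = np.linspace(0.0, 60.0, 2401)
        v = ms.total_volume(t, p, consts).values
        assert np.min(v) < consts.V0
        assert v[-1] > consts.V0

    def test_massari_limit_volume_is_exponential_saturation(self, consts, grid):
        # a = 0, tau = 0: V(t) = V0 + (V_p - V0) * X_p * (1 - exp(-b t))
        p = params(a=0.0, b=0.021, tau=0.0)
        v = ms.total_volume(grid, p, consts).values
        expected = consts.V0 + (consts.V_p - consts.V0) * consts.X_p * (
            1 - np.exp(-0.021 * grid)
        )
        assert np.allclose(v, expected, atol=1e-12)


class TestDerivativeBreak:
    def test_no_break_when_swelling_volume_is_final(self):
        assert ms.derivative_break(params(k=1.0)) == 0.0

    def test_break_vanishes_with_background_rate(self):
        sizes = [ms.derivative_break(params(b=b)) for b in (0.02, 0.002, 0.0002)]
        assert sizes[0] > sizes[1] > sizes[2]
        assert sizes[2] == pytest.approx(0.0, abs=1e-4)

    def test_matches_finite_difference_jump(self, consts):
        p = params(a=0.1882, b=0.021, k=0.737, tau=18.0899)
        analytic = ms.derivative_break(p, consts)
        assert analytic == pytest.approx(0.021 * 0.9 * 1.7 * 0.263, rel=1e-10)
        h = 1e-5

        def v(t):
            return ms.total_volume(np.atleast_1d(t), p, consts).values[0]

        right = (v(p.tau + 2 * h) - v(p.tau + h)) / h
        left = (v(p.tau - h) - v(p.tau - 2 * h)) / h
        assert right - left == pytest.approx(analytic, abs=1e-4)


class TestLogVolumeDiagnostic:
    def test_zero_at_start_and_nonincreasing(self, consts, grid):
        v = ms.total_volume(grid, params(), consts)
        L, valid = ms.log_volume_transform(v, consts)
        assert L[0] == 0.0
        assert np.all(valid)
        assert np.all(np.diff(L) <= 1e-12)

    def test_reduced_model_decays_linearly(self, consts):
        # a = 0, tau = 0: L(t) = -b t exactly
        p = params(a=0.0, b=0.021, tau=0.0)
        t = np.array([0.0, 5.0, 10.0, 30.0])
        v = ms.total_volume(t, p, consts)
        L, _ = ms.log_volume_transform(v, consts)
        assert np.allclose(L, -0.021 * t, atol=1e-12)
        assert L[2] == pytest.approx(-0.21, abs=1e-12)

    def test_full_model_straightens_only_late(self, consts, table50_params):
        # delayed second-order kinetics: L is markedly curved early on and
        # approaches a straight line only once most swelling is done
        t = np.linspace(0.0, 60.0, 241)
        v = ms.total_volume(t, table50_params, consts)
        L, valid = ms.log_volume_transform(v, consts)
        L = L[valid]
        curv = np.abs(np.diff(L, 2))
        n = len(curv)
        assert np.max(curv[3 * n // 4:]) < 0.1 * np.max(curv[: n // 2])

    def test_saturated_points_flagged(self, consts):
        p = params()
        v = ms.total_volume(np.array([0.0, 1e5, 2e5]), p, consts)
        L, valid = ms.log_volume_transform(v, consts)
        assert valid[0]
        assert np.all(np.isnan(L[~valid]))
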