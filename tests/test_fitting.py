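"""Curve-fit correctness: self-fits, constraints, round trips, determinism."""

import numpy as np
import pytest

from aplysia_hill import fitting
from aplysia_hill import model_core as mc
from aplysia_hill.fitting import FitError

A_BEST = [1.55, 7.90, 0.33, 8.33]
B_BEST = [7.44, -29.74, 37.17, -13.87]
C_BEST = [-1.89, 1.70, 0.75, 0.55]
D_A5 = [-0.82, 0.07, 0.37, 0.01]


class TestForceFrequencyFit:
    def test_self_fit_reproduces_curve(self):
        f = np.arange(2.0, 39.0, 2.0)
        u = mc.force_frequency_response(f, A_BEST)
        res = fitting.fit_force_frequency(f, u)
        dense = np.linspace(2, 38, 181)
        err = np.abs(
            mc.force_frequency_response(dense, res.coefficients)
            - mc.force_frequency_response(dense, A_BEST)
        )
        assert err.max() < 1e-4

    def test_degenerate_saturation(self):
        f = np.array([5.0, 15.0, 25.0, 35.0])
        res = fitting.fit_force_frequency(f, np.ones(4))
        fitted = mc.force_frequency_response(f, res.coefficients)
        assert np.allclose(fitted, 1.0, atol=1e-3)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fitting.fit_force_frequency([10, 20, 30], [0.2, 0.6, 0.9])

    def test_deterministic(self):
        f = np.arange(2.0, 39.0, 6.0)
        u = mc.force_frequency_response(f, A_BEST)
        r1 = fitting.fit_force_frequency(f, u)
        r2 = fitting.fit_force_frequency(f, u)
        assert np.array_equal(r1.coefficients, r2.coefficients)


class TestConstrainedCubic:
    def test_recovers_printed_curve(self):
        # the printed coefficients satisfy the equality constraints only
        # to their printed rounding (derivative residual 0.01), so the
        # exactly-constrained fit returns a nearby cubic: coefficient-level
        # agreement is limited by that rounding, curve-level is tight
        l = np.linspace(0.83, 1.25, 30)
        y = np.polyval(B_BEST, l)
        res = fitting.fit_active_lt_constrained(l, y)
        dense = np.linspace(0.83, 1.25, 200)
        assert np.max(np.abs(np.polyval(res.coefficients, dense) - np.polyval(B_BEST, dense))) < 2e-3

    def test_recovers_exactly_constrained_cubic_to_four_decimals(self):
        # a cubic that satisfies the constraints exactly is recovered to
        # (better than) four decimals
        b2 = -29.74
        b1 = 7.44
        b3 = -3 * b1 - 2 * b2  # exact stationarity at 1
        b4 = 1 - b1 - b2 - b3  # exact value 1 at 1
        B_exact = [b1, b2, b3, b4]
        l = np.linspace(0.83, 1.25, 30)
        res = fitting.fit_active_lt_constrained(l, np.polyval(B_exact, l))
        assert np.allclose(res.coefficients, B_exact, atol=1e-4)

    def test_kkt_conditions(self):
        rng = np.random.default_rng(7)
        l = np.linspace(0.8, 1.3, 25)
        y = 1 - 3 * (l - 1.0) ** 2 + rng.normal(0, 0.05, l.size)
        res = fitting.fit_active_lt_constrained(l, y)
        eq = res.diagnostics["equality_residual"]
        assert np.max(np.abs(eq)) < 1e-8
        assert np.all(res.diagnostics["inequality_slack"] <= 1e-8)
        b = res.coefficients
        assert np.polyval(b, 1.0) == pytest.approx(1.0, abs=1e-8)
        assert 3 * b[0] + 2 * b[1] + b[2] == pytest.approx(0.0, abs=1e-8)

    def test_concavity_across_data_range(self):
        # symmetric peak data: second derivative must be <= 0 end to end
        l = np.linspace(0.7, 1.3, 31)
        y = 1 - 2.5 * (l - 1.0) ** 2
        res = fitting.fit_active_lt_constrained(l, y)
        b = res.coefficients
        for x in (l.min(), l.max()):
            assert 6 * b[0] * x + 2 * b[1] <= 1e-8

    def test_active_set_binds_when_needed(self):
        # convex-ish data would violate concavity; the solution must sit
        # on the inequality boundary, not inside the infeasible region
        l = np.linspace(0.8, 1.2, 21)
        y = 1 + 2.0 * (l - 1.0) ** 2
        res = fitting.fit_active_lt_constrained(l, y)
        assert np.all(res.diagnostics["inequality_slack"] <= 1e-8)


class TestSeriesElasticityShift:
    def test_zero_force_is_identity(self):
        l = np.array([0.9, 1.0, 1.1])
        assert np.array_equal(
            fitting.shift_to_contractile_length(l, np.zeros(3), 11.95), l
        )

    def test_shift_magnitude(self):
        out = fitting.shift_to_contractile_length(1.0, 0.5, 11.95)
        assert out == pytest.approx(1.0 - 0.5 / 11.95)
        assert 1.0 - out == pytest.approx(0.0418, abs=1e-4)

    def test_rigid_spring_limit(self):
        l = np.linspace(0.9, 1.1, 5)
        f = np.full(5, 0.8)
        out = fitting.shift_to_contractile_length(l, f, 1e9)
        assert np.allclose(out, l, atol=1e-8)


class TestPassiveFit:
    def test_self_fit_curve_agreement(self):
        l = np.linspace(0.87, 1.25, 40)
        y = mc.passive_length_tension(l, C_BEST)
        res = fitting.fit_passive_lt(l, y)
        fitted = mc.passive_length_tension(
            l, res.coefficients, res.diagnostics["threshold"]
        )
        assert np.max(np.abs(fitted - y)) < 1e-3

    def test_threshold_recovery(self):
        l = np.linspace(0.80, 1.30, 60)
        y = mc.passive_length_tension(l, C_BEST)
        res = fitting.fit_passive_lt(l, y)
        assert res.diagnostics["threshold"] == pytest.approx(0.87, abs=0.02)

    def test_all_zero_points_flagged_degenerate(self):
        l = np.linspace(0.7, 0.85, 10)
        res = fitting.fit_passive_lt(l, np.zeros(10))
        assert res.diagnostics["degenerate"]
        assert res.diagnostics["threshold"] == pytest.approx(l.max())


class TestForceVelocityFits:
    def test_self_fit_recovers_branches(self):
        v = np.concatenate([np.linspace(-0.4, -0.01, 25), np.linspace(0.01, 0.5, 25)])
        fv = mc.force_velocity(v, D_A5)
        res = fitting.fit_fv_piecewise(v, fv)
        assert np.allclose(res.coefficients, D_A5, rtol=0.01)

    def test_single_sided_data_flags_missing_branch(self):
        v = np.linspace(0.05, 0.5, 10)
        fv = mc.force_velocity(v, D_A5)
        res = fitting.fit_fv_piecewise(v, fv)
        assert res.diagnostics["missing_branches"] == ["lengthening"]
        assert np.allclose(res.coefficients[:2], D_A5[:2], rtol=0.02)

    def test_inverse_round_trip_with_fresh_fit(self):
        # a double exponential freshly fitted to samples of the inverse
        # curve must round-trip to < 0.01 velocity units on the data range
        D = [-0.77, 0.07, 0.35, 0.07]
        v = np.linspace(-0.25, 0.25, 101)
        fv = mc.force_velocity(v, D)
        res = fitting.fit_inverse_fv(fv, v)
        back = mc.inverse_force_velocity(fv, res.coefficients)
        assert np.max(np.abs(back - v)) < 0.01

    def test_weighted_refit_round_trip_bounded_by_residual(self):
        # the slope-weighted self-consistency refit trades some velocity
        # accuracy for force-ratio accuracy; its round-trip error stays
        # bounded by the family's cross-fit residual on the working range
        D = [-0.77, 0.07, 0.35, 0.07]
        res = fitting.refit_inverse_fv_from_forward(D)
        v = np.linspace(-0.25, 0.25, 101)
        back = mc.inverse_force_velocity(mc.force_velocity(v, D), res.coefficients)
        assert np.max(np.abs(back - v)) < 0.02

    def test_inverse_fit_is_monotone_and_isometric_consistent(self):
        res = fitting.refit_inverse_fv_from_forward(D_A5)
        fv_grid = np.linspace(0.3, 1.3, 101)
        vals = mc.inverse_force_velocity(fv_grid, res.coefficients)
        assert np.all(np.diff(vals) < 0)
        assert abs(mc.inverse_force_velocity(1.0, res.coefficients)) < 0.02

    def test_inverse_fit_needs_five_points(self):
        with pytest.raises(FitError):
            fitting.fit_inverse_fv([0.5, 0.8, 1.0, 1.2], [0.3, 0.1, 0.0, -0.2])


class TestActivationFit:
    def test_zero_drive_is_unidentifiable(self, gt_params):
        from aplysia_hill.simulator import DriveSignal

        t = np.linspace(0, 10, 101)
        drive = DriveSignal(np.array([0.0]), np.array([0.0]))
        episodes = [(drive, (t, np.full(t.size, gt_params.L_0)), t, np.zeros(t.size))]
        with pytest.raises(FitError):
            fitting.fit_activation_parameters(gt_params, episodes)

    def test_rise_only_data_warns(self, gt_params):
        from aplysia_hill.simulator import DriveSignal, simulate_isometric_force

        drive = DriveSignal(np.array([0.0, 1.0]), np.array([0.0, 26.0]))
        t = np.linspace(0, 6, 61)
        f = simulate_isometric_force(gt_params, drive, gt_params.L_0, t)
        episodes = [(drive, (t, np.full(t.size, gt_params.L_0)), t, f)]
        with pytest.warns(fitting.IdentifiabilityWarning):
            fitting.fit_activation_parameters(gt_params, episodes, maxiter=5)
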