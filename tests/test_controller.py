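"""Switching mobility control law: unit behavior and oracle equivalence."""

import math

import numpy as np
import pytest

from sidestep import LEFT, RIGHT, TRUNK, ContactState, SystemState
from sidestep.controller import (
    COEFFICIENT_VALUES,
    actuator_force,
    axis_vectors,
    combine_commands,
    control_step,
    cross_requests,
    local_residual,
    mobility,
    produced_velocity,
    switching_coefficient_interleg,
    switching_coefficient_leg,
)
from sidestep.dynamics import classify_contact
from sidestep.state import INTERLEG, LEFT_LEG, RIGHT_LEG

from oracle_impl import oracle_control, random_state


def _state(trunk, rfoot, lfoot, vel=None):
    pos = np.array([trunk, rfoot, lfoot], dtype=float)
    v = np.zeros((3, 2)) if vel is None else np.asarray(vel, dtype=float)
    return SystemState(0.0, pos, v)


class TestAxisVectors:
    def test_interleg_axis_points_from_trailing_to_leading(self):
        s = _state([0, 0.92], [0.5, 0.0], [-0.5, 0.0])
        axes = axis_vectors(s, classify_contact(s, +1))
        np.testing.assert_allclose(axes[INTERLEG], [1.0, 0.0])

    def test_leg_axis_points_from_foot_to_trunk(self):
        s = _state([0, 0.92], [0.5, 0.0], [-0.5, 0.0])
        axes = axis_vectors(s, classify_contact(s, +1))
        expect = np.array([-0.5, 0.92]) / math.hypot(0.5, 0.92)
        np.testing.assert_allclose(axes[RIGHT_LEG], expect, rtol=1e-12)
        assert np.linalg.norm(axes[LEFT_LEG]) == pytest.approx(1.0)

    def test_mirrored_configuration_gives_mirrored_axes(self, params, rng):
        s = random_state(rng, params)
        m = s.mirrored()
        a = axis_vectors(s, classify_contact(s, +1))
        b = axis_vectors(m, classify_contact(m, -1))
        np.testing.assert_array_equal(b[INTERLEG], a[INTERLEG] * [-1, 1])
        np.testing.assert_array_equal(b[RIGHT_LEG], a[LEFT_LEG] * [-1, 1])
        np.testing.assert_array_equal(b[LEFT_LEG], a[RIGHT_LEG] * [-1, 1])

    def test_coincident_endpoints_rejected(self):
        s = _state([0.5, 0.0], [0.5, 0.0], [-0.5, 0.0])
        with pytest.raises(ValueError, match="coincident"):
            axis_vectors(s, ContactState(True, True, RIGHT))


class TestSwitchingCoefficientLeg:
    """Role selection: propulsion, flight 1/2, balance and swing overrides."""

    @pytest.mark.parametrize(
        "grounded,anterior,dist,length_ratio,expected",
        [
            (True, False, 0.5, 1.0, 1.0),     # grounded, no overrides: propulsion
            (False, False, 0.5, 0.9, 0.5),    # flight halves the magnitude
            (True, True, 0.15, 1.0, -1.0),    # balance: trunk close to anterior leg
            (False, True, 0.15, 1.0, -0.5),   # balance in flight composes with 1/2
            (False, False, 0.5, 1.05, -0.5),  # swing: posterior flight over-extension
            (True, False, 0.5, 1.05, 1.0),    # over-extension ignored when grounded
            (True, True, 0.25, 1.0, 1.0),     # anterior but beyond balance distance
        ],
    )
    def test_rule_table(self, params, grounded, anterior, dist, length_ratio, expected):
        a = switching_coefficient_leg(
            grounded, anterior, dist, length_ratio * params.natural_length_leg, params
        )
        assert a == expected

    def test_balance_takes_precedence_over_swing(self, params):
        # anterior + close would give -1; a (contrived) over-extended anterior
        # flight leg must not double-flip back to positive
        a = switching_coefficient_leg(
            False, True, 0.1, 1.2 * params.natural_length_leg, params
        )
        assert a == -0.5


class TestSwitchingCoefficientInterleg:
    def _contact(self, gr, gl, anterior=RIGHT):
        return ContactState(gr, gl, anterior)

    def test_double_support_is_neutral(self, params):
        assert switching_coefficient_interleg(
            self._contact(True, True), params.natural_length_leg, params) == 0.0

    def test_double_flight_short_posterior(self, params):
        a = switching_coefficient_interleg(
            self._contact(False, False), 0.5 * params.natural_length_leg, params)
        assert a == 0.5

    def test_double_flight_long_posterior_swings(self, params):
        a = switching_coefficient_interleg(
            self._contact(False, False), 0.7 * params.natural_length_leg, params)
        assert a == -0.5

    def test_anterior_support_long_posterior_swings(self, params):
        a = switching_coefficient_interleg(
            self._contact(True, False, anterior=RIGHT),
            0.7 * params.natural_length_leg, params)
        assert a == -1.0

    def test_trailing_stance_is_neutral(self, params):
        a = switching_coefficient_interleg(
            self._contact(False, True, anterior=RIGHT),
            0.7 * params.natural_length_leg, params)
        assert a == 0.0


class TestLocalResidual:
    def test_parallel_command_fully_local(self):
        vd = np.array([2.0, 0.0])
        e = np.array([1.0, 0.0])
        vl, vr = local_residual(vd, e, 1.0)
        np.testing.assert_allclose(vl, vd)
        np.testing.assert_allclose(vr, 0.0)

    def test_perpendicular_command_fully_residual(self):
        vd = np.array([2.0, 0.0])
        e = np.array([0.0, 1.0])
        vl, vr = local_residual(vd, e, 1.0)
        np.testing.assert_allclose(vl, 0.0)
        np.testing.assert_allclose(vr, vd)

    def test_zero_coefficient_gives_zero_local(self):
        vd = np.array([2.0, 0.0])
        e = np.array([0.6, 0.8])
        vl, vr = local_residual(vd, e, 0.0)
        np.testing.assert_array_equal(vl, 0.0)
        np.testing.assert_array_equal(vr, vd)

    def test_split_identity(self, rng):
        for _ in range(100):
            vd = rng.uniform(-3, 3, 2)
            e = rng.normal(size=2)
            e /= np.linalg.norm(e)
            a = rng.choice(COEFFICIENT_VALUES)
            vl, vr = local_residual(vd, e, a)
            np.testing.assert_allclose(vl + vr, vd, atol=1e-12)


class TestProducedVelocity:
    def test_static_state_produces_zero(self, params):
        s = _state([0, 0.92], [0.5, 0.0], [-0.5, 0.0])
        axes = axis_vectors(s, classify_contact(s, +1))
        for i, (prox, dist) in ((INTERLEG, (LEFT, RIGHT)), (RIGHT_LEG, (RIGHT, TRUNK))):
            np.testing.assert_array_equal(
                produced_velocity(s, axes[i], prox, dist), 0.0
            )

    def test_trunk_moving_along_leg_axis(self, params):
        s = _state([0, 0.92], [0.5, 0.0], [-0.5, 0.0])
        axes = axis_vectors(s, classify_contact(s, +1))
        s.vel[TRUNK] = 0.3 * axes[RIGHT_LEG]
        v = produced_velocity(s, axes[RIGHT_LEG], RIGHT, TRUNK)
        np.testing.assert_allclose(v, 0.3 * axes[RIGHT_LEG], rtol=1e-12)


class TestMobility:
    def test_achieved_command_is_fully_mobile(self, params):
        v = np.array([1.0, 0.0])
        k = mobility(v, v, params)
        assert k == pytest.approx(1.0, abs=1e-8)

    def test_stalled_actuator_is_nearly_immobile(self, params):
        # velocity error equal to the command: ratio ~ 1 -> k ~ 2^-4
        k = mobility(np.array([1.0, 0.0]), np.zeros(2), params)
        assert k == pytest.approx(2.0 ** -4, rel=1e-3)

    def test_idle_actuator_with_no_command_is_mobile(self, params):
        k = mobility(np.zeros(2), np.zeros(2), params)
        assert k == pytest.approx(1.0, abs=1e-5)

    def test_strictly_within_unit_interval(self, params, rng):
        for _ in range(200):
            vl = rng.uniform(-5, 5, 2)
            va = rng.uniform(-5, 5, 2)
            assert 0.0 < mobility(vl, va, params) < 1.0


class TestCrossRequestsAndCombination:
    def test_perpendicular_residual_requests_nothing(self):
        axes = np.array([[1.0, 0.0], [0.0, 1.0], [0.6, 0.8]])
        residuals = np.zeros((3, 2))
        residuals[1] = [0.0, 1.5]   # perpendicular to axis 0
        req = cross_requests(residuals, axes)
        np.testing.assert_allclose(req[0, 1], 0.0, atol=1e-15)

    def test_parallel_residual_requested_in_full(self):
        axes = np.array([[1.0, 0.0], [0.0, 1.0], [0.6, 0.8]])
        residuals = np.zeros((3, 2))
        residuals[1] = [2.0, 0.0]
        req = cross_requests(residuals, axes)
        np.testing.assert_allclose(req[0, 1], [2.0, 0.0], rtol=1e-12)

    def test_combination_limits(self, rng):
        axes = rng.normal(size=(3, 2))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        locals_ = rng.uniform(-2, 2, (3, 2))
        req = cross_requests(rng.uniform(-2, 2, (3, 2)), axes)
        near0 = np.full(3, 1e-12)
        np.testing.assert_allclose(
            combine_commands(locals_, req, near0), locals_, rtol=1e-9, atol=1e-9
        )
        near1 = np.full(3, 1.0 - 1e-12)
        expect = np.array([req[i, [j for j in range(3) if j != i]].sum(axis=0)
                           for i in range(3)])
        np.testing.assert_allclose(
            combine_commands(locals_, req, near1), expect, rtol=1e-9, atol=1e-9
        )

    def test_combination_matches_direct_formula(self, rng):
        for _ in range(100):
            locals_ = rng.uniform(-2, 2, (3, 2))
            req = rng.uniform(-2, 2, (3, 3, 2))
            k = rng.uniform(0.01, 0.99, 3)
            got = combine_commands(locals_, req, k)
            for i in range(3):
                others = [j for j in range(3) if j != i]
                expect = np.prod([1 - k[j] for j in others]) * locals_[i]
                for j in others:
                    expect = expect + k[j] * req[i, j]
                np.testing.assert_allclose(got[i], expect, rtol=1e-12, atol=1e-14)


class TestActuatorForce:
    def test_zero_error_zero_force(self, params):
        v = np.array([0.4, 0.1])
        np.testing.assert_array_equal(actuator_force(v, v, params), 0.0)

    def test_gain_scales_velocity_error(self, params):
        e = np.array([0.6, 0.8])
        f = actuator_force(0.1 * e, np.zeros(2), params)
        assert np.linalg.norm(f) == pytest.approx(params.gain * 0.1, rel=1e-12)

    def test_sign_reversal(self, params):
        a = actuator_force(np.array([0.3, 0.0]), np.zeros(2), params)
        b = actuator_force(np.array([-0.3, 0.0]), np.zeros(2), params)
        np.testing.assert_array_equal(a, -b)


class TestControlStep:
    def test_symmetric_rest_with_zero_command_is_balanced(self, params, initial_state):
        c = classify_contact(initial_state, 0.0)
        per_mass, diag = control_step(
            initial_state, c, np.array([0.0, 0.0]), params
        )
        assert per_mass[TRUNK, 0] == 0.0
        # zero command -> zero local commands -> zero forces
        np.testing.assert_allclose(per_mass, 0.0, atol=1e-12)

    def test_mirror_equivariance(self, params, rng):
        for _ in range(100):
            s = random_state(rng, params)
            m = s.mirrored()
            fa, da = control_step(s, classify_contact(s, +2.0),
                                  np.array([2.0, 0.0]), params)
            fb, db = control_step(m, classify_contact(m, -2.0),
                                  np.array([-2.0, 0.0]), params)
            swapped = fa[[0, 2, 1]].copy()
            swapped[:, 0] = -swapped[:, 0]
            np.testing.assert_array_equal(fb, swapped)
            np.testing.assert_array_equal(db.mobility, da.mobility[[0, 2, 1]])
            np.testing.assert_array_equal(db.a, da.a[[0, 2, 1]])

    def test_matches_independent_oracle(self, params, rng):
        """Packaged controller == straight-line re-implementation, 1000 states."""
        for _ in range(1000):
            s = random_state(rng, params)
            vd_x = rng.choice([-2.0, 2.0]) * rng.uniform(0.2, 1.5)
            per_mass, diag = control_step(
                s, classify_contact(s, vd_x), np.array([vd_x, 0.0]), params
            )
            expect, od = oracle_control(s.pos, s.vel, vd_x, params)
            np.testing.assert_allclose(per_mass, expect, rtol=1e-12, atol=1e-9)
            np.testing.assert_array_equal(diag.a, od["a"])
            # atol covers the package's underflow clamp on k_i
            np.testing.assert_allclose(diag.mobility, od["mobility"],
                                       rtol=1e-12, atol=1e-300)
            np.testing.assert_allclose(diag.v_command, od["v_command"],
                                       rtol=1e-12, atol=1e-12)

    def test_diagnostics_invariants_on_random_states(self, params, rng):
        for _ in range(200):
            s = random_state(rng, params)
            vd = np.array([rng.uniform(-2.5, 2.5), 0.0])
            _, diag = control_step(s, classify_contact(s, vd[0]), vd, params)
            assert set(np.unique(diag.a)) <= set(COEFFICIENT_VALUES)
            assert np.all(diag.mobility > 0) and np.all(diag.mobility < 1)
            np.testing.assert_allclose(
                diag.v_local + diag.v_residual, np.tile(vd, (3, 1)), atol=1e-12
            )
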