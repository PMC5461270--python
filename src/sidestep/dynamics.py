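"""Passive mechanics of the three-mass model and the fixed-step integrator.

The trunk and two feet are point masses linked by three linear actuators
(inter-leg plus two legs), each paralleled by a spring-damper.  Additional
passive elements: an extension-limit stiffening of the legs, a unilateral
viscoelastic ground, and an auxiliary horizontal trunk tether that resists
the trunk approaching either foot too closely (anti-fall).

Equation of motion per mass:  m x'' = F_active + m g + F_passive,
integrated with explicit (forward) Euler at a fixed step ``params.dt``.

This module is the plain-Python reference; :mod:`sidestep.engine` runs the
same arithmetic in a compiled loop for long simulations.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ModelParameters
from .state import (
    LEFT,
    RIGHT,
    TRUNK,
    ContactState,
    PassiveForces,
    SystemState,
)

__all__ = [
    "desired_direction",
    "classify_contact",
    "passive_leg_force",
    "ground_reaction",
    "auxiliary_trunk_force",
    "assemble_passive_forces",
    "step_dynamics",
]


def desired_direction(v_d_x: float) -> float:
    """Sign of the commanded lateral velocity (+1 for a zero command)."""
    return -1.0 if v_d_x < 0.0 else 1.0


def classify_contact(state: SystemState, desired_dir: float) -> ContactState:
    """Ground the feet at z <= 0 and label the anterior (leading) foot.

    The anterior foot is the one farther along the desired direction of
    travel; on an exact tie the foot on the desired side is chosen, which
    keeps the labelling equivariant under the mirror map.
    """
    s = desired_direction(desired_dir)
    xr = s * state.pos[RIGHT, 0]
    xl = s * state.pos[LEFT, 0]
    if xr > xl:
        anterior = RIGHT
    elif xl > xr:
        anterior = LEFT
    else:
        anterior = RIGHT if s > 0 else LEFT
    return ContactState(
        grounded_right=bool(state.pos[RIGHT, 1] <= 0.0),
        grounded_left=bool(state.pos[LEFT, 1] <= 0.0),
        anterior=anterior,
    )


def passive_leg_force(
    length: float,
    lengthening_rate: float,
    grounded: bool,
    params: ModelParameters,
) -> tuple[float, float]:
    """Axial passive force of one leg, split into base and stiffening parts.

    Returns ``(base, extension)`` where ``base`` is the spring-damper force
    on the phase-dependent elasticity branch and ``extension`` the extra
    elastic force once the leg exceeds ``ext_trigger_ratio`` times its
    natural length (piecewise-linear, continuous at the trigger).  The sign
    convention is the force applied to the distal endpoint along the
    proximal-to-distal unit axis, so a stretched leg yields a negative
    (restoring) value.
    """
    if length <= 0.0:
        raise ValueError(f"leg length must be positive, got {length}")
    l0 = params.natural_length_leg
    k = params.k_leg_contact if grounded else params.k_leg_flight
    base = -(k * (length - l0) + params.b_leg * lengthening_rate)
    trigger = params.ext_trigger_ratio * l0
    if length > trigger:
        extension = -(params.ext_stiffen_mult - 1.0) * k * (length - trigger)
    else:
        extension = 0.0
    return base, extension


def ground_reaction(
    foot_pos: np.ndarray, foot_vel: np.ndarray, params: ModelParameters
) -> np.ndarray:
    """Unilateral ground force on one foot.

    Vertical: Kelvin-Voigt spring-damper clamped to be non-negative (the
    ground can only push).  Horizontal: viscous resistance while the foot
    is at or below ground level.  Zero above ground.
    """
    z = foot_pos[1]
    if z > 0.0:
        return np.zeros(2)
    fz = -params.k_ground_z * z - params.b_ground_z * foot_vel[1]
    if fz < 0.0:
        fz = 0.0
    fx = -params.b_ground_x * foot_vel[0]
    return np.array([fx, fz])


def auxiliary_trunk_force(
    state: SystemState, params: ModelParameters
) -> np.ndarray:
    """Horizontal anti-fall tether forces, shape (3, 2).

    When the horizontal trunk-foot distance drops strictly below
    ``aux_distance`` (0.15 m), a horizontal viscoelastic force pair pushes
    trunk and that foot apart, resisting further approach.  Internal:
    the per-pair forces are equal and opposite.
    """
    out = np.zeros((3, 2))
    for foot in (RIGHT, LEFT):
        d = state.pos[TRUNK, 0] - state.pos[foot, 0]
        ad = abs(d)
        if ad < params.aux_distance:
            u = 1.0 if d > 0.0 else (-1.0 if d < 0.0 else 0.0)
            sep_rate = (state.vel[TRUNK, 0] - state.vel[foot, 0]) * u
            fmag = params.k_aux * (params.aux_distance - ad) - params.b_aux * sep_rate
            out[TRUNK, 0] += u * fmag
            out[foot, 0] -= u * fmag
    return out


def _axis_and_rate(
    state: SystemState, proximal: int, distal: int
) -> tuple[np.ndarray, float, float]:
    """Unit axis proximal->distal, current length and lengthening rate."""
    dx = state.pos[distal, 0] - state.pos[proximal, 0]
    dz = state.pos[distal, 1] - state.pos[proximal, 1]
    length = math.sqrt(dx * dx + dz * dz)
    if length <= 0.0:
        raise ValueError(f"coincident masses {proximal} and {distal}")
    e = np.array([dx / length, dz / length])
    rate = (state.vel[distal, 0] - state.vel[proximal, 0]) * e[0] + (
        state.vel[distal, 1] - state.vel[proximal, 1]
    ) * e[1]
    return e, length, rate


def assemble_passive_forces(
    state: SystemState, contact: ContactState, params: ModelParameters
) -> PassiveForces:
    """Evaluate every passive element and return the per-mass decomposition.

    Leg and inter-leg elements are internal force pairs (action-reaction);
    gravity is *not* included here — the integrator adds it separately.
    """
    f = PassiveForces()

    leg_axial = {}
    for foot, grounded in ((RIGHT, contact.grounded_right), (LEFT, contact.grounded_left)):
        e, length, rate = _axis_and_rate(state, foot, TRUNK)
        base, ext = passive_leg_force(length, rate, grounded, params)
        leg_axial[foot] = (e, base, ext)
        f.leg[foot] = -base * e
        f.extension[foot] = -ext * e
    # one commutative addition so that swapping the feet mirrors exactly
    f.leg[TRUNK] = leg_axial[RIGHT][1] * leg_axial[RIGHT][0] + (
        leg_axial[LEFT][1] * leg_axial[LEFT][0]
    )
    f.extension[TRUNK] = leg_axial[RIGHT][2] * leg_axial[RIGHT][0] + (
        leg_axial[LEFT][2] * leg_axial[LEFT][0]
    )

    e_il, length_il, rate_il = _axis_and_rate(state, LEFT, RIGHT)
    axial_il = -(
        params.k_interleg * (length_il - params.natural_length_interleg)
        + params.b_interleg * rate_il
    )
    f.interleg[RIGHT] = axial_il * e_il
    f.interleg[LEFT] = -axial_il * e_il

    for foot in (RIGHT, LEFT):
        f.ground[foot] = ground_reaction(state.pos[foot], state.vel[foot], params)

    f.auxiliary = auxiliary_trunk_force(state, params)
    return f


def step_dynamics(
    state: SystemState,
    active_forces: np.ndarray,
    params: ModelParameters,
) -> SystemState:
    """One forward-Euler step of the equation of motion.

    ``active_forces`` is the per-mass (3, 2) actuator force array produced
    by the controller.  Positions advance with the pre-step velocities;
    velocities advance with the pre-step accelerations.
    """
    active_forces = np.asarray(active_forces, dtype=np.float64)
    contact = ContactState(
        grounded_right=bool(state.pos[RIGHT, 1] <= 0.0),
        grounded_left=bool(state.pos[LEFT, 1] <= 0.0),
        anterior=RIGHT,  # role labels do not affect passive mechanics
    )
    passive = assemble_passive_forces(state, contact, params)
    masses = np.array([params.m_trunk, params.m_foot, params.m_foot])
    total = active_forces + passive.total
    total[:, 1] -= masses * params.gravity
    acc = total / masses[:, None]
    if not np.all(np.isfinite(acc)):
        raise FloatingPointError(
            f"non-finite acceleration at t={state.t!r}: "
            f"pos={state.pos.tolist()} vel={state.vel.tolist()} acc={acc.tolist()}"
        )
    dt = params.dt
    new_pos = state.pos + state.vel * dt
    new_vel = state.vel + acc * dt
    return SystemState(state.t + dt, new_pos, new_vel)
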