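"""Switching mobility control for the three-actuator sidestep model.

Each actuator i (1 inter-leg, 2 right leg, 3 left leg) autonomously splits
the global desired velocity v_d into a local part it can generate along its
own axis and a residual it requests from the others:

    v_di^l = a_i (e_xi . v_d) e_xi,        v_di^r = v_d - v_di^l

The discrete switching coefficient a_i in {-1, -1/2, 0, 1/2, 1} reassigns
the actuator between propulsion, balance, leg swing and neutral roles from
contact phase and simple geometric thresholds.  A mobility index

    k_i = exp[-4 ln2 (||v_di^l - v_i||^2 + e1) / (||v_di^l||^2 + e2)]

scores how well the actuator currently realises its local command (1 =
mobile, -> 0 = immobile), and the actuators mix their own command with the
others' requests weighted by mobility:

    v~_di = prod_{j != i} (1 - k_j) v_di^l  +  sum_{j != i} k_j v_dic_j,
    F_ai  = G_i (v~_di - v_i)

applied as an equal-and-opposite axial force pair, so the controller adds
no net force to the system.
"""

from __future__ import annotations

import math

import numpy as np

from .dynamics import desired_direction
from .params import ModelParameters
from .state import (
    INTERLEG,
    LEFT,
    LEFT_LEG,
    RIGHT,
    RIGHT_LEG,
    TRUNK,
    ContactState,
    ControlDiagnostics,
    SystemState,
)

__all__ = [
    "axis_vectors",
    "switching_coefficient_leg",
    "switching_coefficient_interleg",
    "local_residual",
    "produced_velocity",
    "mobility",
    "cross_requests",
    "combine_commands",
    "actuator_force",
    "control_step",
]

#: admissible switching-coefficient values
COEFFICIENT_VALUES = (-1.0, -0.5, 0.0, 0.5, 1.0)

#: underflow guard: the mobility exponential can underflow to exactly 0
#: (e.g. a zero local command while the actuator moves); the index is
#: clamped to the smallest normal double to stay strictly inside (0, 1)
MIN_MOBILITY = 2.2250738585072014e-308


def _unit(dx: float, dz: float) -> np.ndarray:
    n = math.sqrt(dx * dx + dz * dz)
    if n <= 0.0:
        raise ValueError("coincident actuator endpoints")
    return np.array([dx / n, dz / n])


def axis_vectors(state: SystemState, contact: ContactState) -> np.ndarray:
    """Unit force axes e_xi, shape (3, 2).

    Inter-leg: from the trailing (posterior) foot to the leading (anterior)
    foot.  Legs: from the foot to the trunk, so positive actuator action
    drives the trunk away from the foot.
    """
    ant, post = contact.anterior, contact.posterior
    axes = np.empty((3, 2))
    axes[INTERLEG] = _unit(
        state.pos[ant, 0] - state.pos[post, 0],
        state.pos[ant, 1] - state.pos[post, 1],
    )
    axes[RIGHT_LEG] = _unit(
        state.pos[TRUNK, 0] - state.pos[RIGHT, 0],
        state.pos[TRUNK, 1] - state.pos[RIGHT, 1],
    )
    axes[LEFT_LEG] = _unit(
        state.pos[TRUNK, 0] - state.pos[LEFT, 0],
        state.pos[TRUNK, 1] - state.pos[LEFT, 1],
    )
    return axes


def switching_coefficient_leg(
    grounded: bool,
    anterior: bool,
    trunk_foot_distance: float,
    leg_length: float,
    params: ModelParameters,
) -> float:
    """Switching coefficient for a leg actuator.

    Base role is propulsion (+1).  In flight the magnitude halves because
    the leg cannot push on the ground.  Two sign overrides, balance taking
    precedence over swing:

    * balance — the trunk horizontally within ``balance_distance`` of the
      *anterior* leg flips the sign, any phase;
    * swing — a *posterior* leg in flight stretched beyond its natural
      length flips the sign to pull the leg back toward the trunk.
    """
    sign = 1.0
    if anterior and trunk_foot_distance < params.balance_distance:
        sign = -1.0
    elif (not anterior) and (not grounded) and leg_length > params.natural_length_leg:
        sign = -1.0
    return sign if grounded else 0.5 * sign


def switching_coefficient_interleg(
    contact: ContactState, posterior_length: float, params: ModelParameters
) -> float:
    """Switching coefficient for the inter-leg (hip) actuator.

    Neutral (0) whenever the posterior leg is grounded (double support or
    trailing-leg stance); 1/2 in double flight.  When the posterior leg is
    longer than ``swing_length_ratio`` times its natural length during
    double flight or anterior-leg support, the sign flips to pull the
    posterior leg toward the trunk (the flight 1/2 factor still applies).
    """
    threshold = params.swing_length_ratio * params.natural_length_leg
    if contact.double_support:
        return 0.0
    if contact.double_flight:
        return -0.5 if posterior_length > threshold else 0.5
    if contact.grounded(contact.anterior):
        return -1.0 if posterior_length > threshold else 0.0
    return 0.0  # trailing-leg stance


def local_residual(
    v_d: np.ndarray, e_xi: np.ndarray, a_i: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split v_d into the local command along e_xi and the residual."""
    proj = e_xi[0] * v_d[0] + e_xi[1] * v_d[1]
    v_local = (a_i * proj) * e_xi
    return v_local, v_d - v_local


def produced_velocity(
    state: SystemState, e_xi: np.ndarray, proximal: int, distal: int
) -> np.ndarray:
    """Velocity the actuator currently produces along its axis.

    Relative velocity of the distal endpoint with respect to the proximal
    one, projected onto e_xi: positive when the actuator lengthens in the
    direction that drives its distal mass along the axis.
    """
    rel = (state.vel[distal, 0] - state.vel[proximal, 0]) * e_xi[0] + (
        state.vel[distal, 1] - state.vel[proximal, 1]
    ) * e_xi[1]
    return rel * e_xi


def mobility(v_local: np.ndarray, v_actual: np.ndarray, params: ModelParameters) -> float:
    """Mobility index k_i in (0, 1); 1 = mobile, -> 0 = immobile."""
    dx = v_local[0] - v_actual[0]
    dz = v_local[1] - v_actual[1]
    num = dx * dx + dz * dz + params.eps1
    den = v_local[0] * v_local[0] + v_local[1] * v_local[1] + params.eps2
    k = math.exp(-4.0 * math.log(2.0) * num / den)
    return k if k > 0.0 else MIN_MOBILITY


def cross_requests(residuals: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Required velocities v_dic_j: residual of j projected on axis i.

    Returns shape (3, 3, 2); entry [i, j] is the velocity actuator j asks
    actuator i to produce (the diagonal is zero by convention).
    """
    out = np.zeros((3, 3, 2))
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            proj = axes[i, 0] * residuals[j, 0] + axes[i, 1] * residuals[j, 1]
            out[i, j] = proj * axes[i]
    return out


def combine_commands(
    v_locals: np.ndarray, v_required: np.ndarray, mobilities: np.ndarray
) -> np.ndarray:
    """Mix local commands and cross requests by mobility (one per actuator)."""
    out = np.empty((3, 2))
    for i in range(3):
        j, k = [m for m in range(3) if m != i]
        inhib = (1.0 - mobilities[j]) * (1.0 - mobilities[k])
        out[i] = inhib * v_locals[i] + (
            mobilities[j] * v_required[i, j] + mobilities[k] * v_required[i, k]
        )
    return out


def actuator_force(
    v_command: np.ndarray, v_actual: np.ndarray, params: ModelParameters
) -> np.ndarray:
    """Proportional force F_ai = G (v~_di - v_i) on the distal endpoint."""
    return params.gain * (v_command - v_actual)


def control_step(
    state: SystemState,
    contact: ContactState,
    v_d: np.ndarray,
    params: ModelParameters,
) -> tuple[np.ndarray, ControlDiagnostics]:
    """One full controller evaluation.

    Returns the per-mass (3, 2) active force array and the complete
    diagnostics record.  The endpoint convention: each leg actuator pushes
    the trunk with +F and its foot with -F; the inter-leg actuator pushes
    the anterior foot with +F and the posterior foot with -F.
    """
    v_d = np.asarray(v_d, dtype=np.float64)
    ant, post = contact.anterior, contact.posterior
    axes = axis_vectors(state, contact)

    lengths = {}
    for foot in (RIGHT, LEFT):
        dx = state.pos[TRUNK, 0] - state.pos[foot, 0]
        dz = state.pos[TRUNK, 1] - state.pos[foot, 1]
        lengths[foot] = math.sqrt(dx * dx + dz * dz)

    a = np.empty(3)
    a[INTERLEG] = switching_coefficient_interleg(contact, lengths[post], params)
    for foot, idx in ((RIGHT, RIGHT_LEG), (LEFT, LEFT_LEG)):
        a[idx] = switching_coefficient_leg(
            grounded=contact.grounded(foot),
            anterior=(foot == ant),
            trunk_foot_distance=abs(state.pos[TRUNK, 0] - state.pos[foot, 0]),
            leg_length=lengths[foot],
            params=params,
        )

    v_locals = np.empty((3, 2))
    v_residuals = np.empty((3, 2))
    for i in range(3):
        v_locals[i], v_residuals[i] = local_residual(v_d, axes[i], a[i])

    v_actuals = np.empty((3, 2))
    v_actuals[INTERLEG] = produced_velocity(state, axes[INTERLEG], post, ant)
    v_actuals[RIGHT_LEG] = produced_velocity(state, axes[RIGHT_LEG], RIGHT, TRUNK)
    v_actuals[LEFT_LEG] = produced_velocity(state, axes[LEFT_LEG], LEFT, TRUNK)

    mob = np.array([mobility(v_locals[i], v_actuals[i], params) for i in range(3)])
    v_required = cross_requests(v_residuals, axes)
    v_commands = combine_commands(v_locals, v_required, mob)

    forces = np.empty((3, 2))
    for i in range(3):
        forces[i] = actuator_force(v_commands[i], v_actuals[i], params)

    per_mass = np.zeros((3, 2))
    per_mass[TRUNK] = forces[RIGHT_LEG] + forces[LEFT_LEG]
    per_mass[RIGHT] = -forces[RIGHT_LEG]
    per_mass[LEFT] = -forces[LEFT_LEG]
    per_mass[ant] += forces[INTERLEG]
    per_mass[post] -= forces[INTERLEG]

    diag = ControlDiagnostics(
        axes=axes,
        a=a,
        v_local=v_locals,
        v_residual=v_residuals,
        v_actual=v_actuals,
        mobility=mob,
        v_required=v_required,
        v_command=v_commands,
        force=forces,
    )
    return per_mass, diag
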