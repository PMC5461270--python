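"""State containers for the three-mass sidestep model.

The three point masses live in the 2D frontal plane: coordinate 0 is the
lateral position x [m], coordinate 1 the vertical position z [m].  Mass
order everywhere is (trunk, right foot, left foot); actuator order is
(inter-leg, right leg, left leg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TRUNK", "RIGHT", "LEFT",
    "INTERLEG", "RIGHT_LEG", "LEFT_LEG",
    "SystemState", "ContactState", "PassiveForces", "ControlDiagnostics",
]

TRUNK, RIGHT, LEFT = 0, 1, 2
INTERLEG, RIGHT_LEG, LEFT_LEG = 0, 1, 2

_SWAP = np.array([TRUNK, LEFT, RIGHT])


@dataclass
class SystemState:
    """Positions and velocities of the three point masses at time ``t``."""

    t: float
    pos: np.ndarray  # shape (3, 2): [mass, (x, z)]
    vel: np.ndarray  # shape (3, 2)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.float64).reshape(3, 2)
        self.vel = np.asarray(self.vel, dtype=np.float64).reshape(3, 2)

    @property
    def trunk_pos(self) -> np.ndarray:
        return self.pos[TRUNK]

    @property
    def foot_pos(self) -> np.ndarray:
        return self.pos[RIGHT:]

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.pos)) and np.all(np.isfinite(self.vel)))

    def copy(self) -> "SystemState":
        return SystemState(self.t, self.pos.copy(), self.vel.copy())

    def mirrored(self) -> "SystemState":
        """Reflect laterally: x -> -x and swap the two feet.

        The model dynamics and controller commute with this map (together
        with negating the desired velocity), which the test suite exploits.
        """
        pos = self.pos[_SWAP].copy()
        vel = self.vel[_SWAP].copy()
        pos[:, 0] = -pos[:, 0]
        vel[:, 0] = -vel[:, 0]
        return SystemState(self.t, pos, vel)


@dataclass(frozen=True)
class ContactState:
    """Ground contact flags and leg role labels.

    ``anterior`` is the index (RIGHT or LEFT) of the foot farther along the
    current desired direction of travel; it is the leading leg of the
    sidestep and flips when the commanded direction flips.
    """

    grounded_right: bool
    grounded_left: bool
    anterior: int

    def __post_init__(self) -> None:
        if self.anterior not in (RIGHT, LEFT):
            raise ValueError("anterior must be RIGHT or LEFT")

    @property
    def posterior(self) -> int:
        return LEFT if self.anterior == RIGHT else RIGHT

    def grounded(self, foot: int) -> bool:
        return self.grounded_right if foot == RIGHT else self.grounded_left

    @property
    def double_support(self) -> bool:
        return self.grounded_right and self.grounded_left

    @property
    def double_flight(self) -> bool:
        return not (self.grounded_right or self.grounded_left)

    @property
    def phase(self) -> str:
        if self.double_support:
            return "double_support"
        if self.double_flight:
            return "double_flight"
        return "single_support"


@dataclass
class PassiveForces:
    """Per-mass passive force decomposition, shape (3, 2) each [N].

    ``leg`` is the axial spring-damper force on the phase-dependent base
    elasticity branch, ``extension`` the additional elastic force from the
    stiffened branch beyond the extension-limit trigger, ``interleg`` the
    hip spring-damper, ``ground`` the contact reaction and ``auxiliary``
    the horizontal trunk-foot anti-fall tether.
    """

    leg: np.ndarray = field(default_factory=lambda: np.zeros((3, 2)))
    extension: np.ndarray = field(default_factory=lambda: np.zeros((3, 2)))
    interleg: np.ndarray = field(default_factory=lambda: np.zeros((3, 2)))
    ground: np.ndarray = field(default_factory=lambda: np.zeros((3, 2)))
    auxiliary: np.ndarray = field(default_factory=lambda: np.zeros((3, 2)))

    @property
    def total(self) -> np.ndarray:
        return self.leg + self.extension + self.interleg + self.ground + self.auxiliary

    @property
    def internal(self) -> np.ndarray:
        """Components exchanged between the masses (exclude ground)."""
        return self.leg + self.extension + self.interleg + self.auxiliary


@dataclass
class ControlDiagnostics:
    """Full intermediate record of one controller evaluation.

    Actuator order is (inter-leg, right leg, left leg).  ``force[i]`` is the
    force vector applied to the actuator's distal endpoint (the trunk for the
    leg actuators, the anterior foot for the inter-leg actuator); the other
    endpoint receives the opposite force.
    """

    axes: np.ndarray          # (3, 2) unit vectors e_xi
    a: np.ndarray             # (3,) switching coefficients
    v_local: np.ndarray       # (3, 2) local desired velocities
    v_residual: np.ndarray    # (3, 2) residual desired velocities
    v_actual: np.ndarray      # (3, 2) actuator-produced velocities
    mobility: np.ndarray      # (3,) mobility indices k_i
    v_required: np.ndarray    # (3, 3, 2) v_required[i, j]: request from j to i
    v_command: np.ndarray     # (3, 2) combined commands
    force: np.ndarray         # (3, 2) actuator forces on the distal endpoint
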