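"""Model parameters for the three-mass sidestep model.

All quantities are SI.  The default set is the package's documented
reference configuration: thresholds, gain, tolerances and the integration
step follow the published control rules, while masses and viscoelastic
constants are a human-like calibration chosen so that the default model
locomotes laterally and completes a direction change at every tested
switch timing (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParameters", "PARAM_SIZE"]

_SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class ModelParameters:
    """Physical and control parameters of the three-mass model.

    Natural lengths default to the side of the equilateral triangle formed
    by the trunk apex at ``trunk_height`` and the two feet on the ground,
    so the initial posture carries no spring force.
    """

    # masses and gravity (trunk-dominant human-like split)
    m_trunk: float = 48.0
    m_foot: float = 2.5358043729726876
    gravity: float = 9.8

    # geometry
    trunk_height: float = 0.92
    natural_length_leg: float | None = None
    natural_length_interleg: float | None = None

    # leg viscoelasticity (axial spring-damper about the natural length).
    # The viscoelastic constants below are the package's calibrated default
    # set (see docs/methods.md); the closed loop is chaotic, so they are
    # stored at full precision — rounding them changes every emergent
    # observable.
    k_leg_flight: float = 16357.582460661079
    k_leg_contact: float = 16357.582460661079
    b_leg: float = 76.76481696858193

    # extension limit: elastic coefficient multiplier beyond the trigger
    ext_stiffen_mult: float = 89.98065691808708
    ext_trigger_ratio: float = 1.1

    # inter-leg (hip ab/adductor) viscoelasticity
    k_interleg: float = 111238.74643767868
    b_interleg: float = 399.7987063237286

    # ground contact (vertical Kelvin-Voigt, horizontal viscous)
    k_ground_z: float = 86052.34296198368
    b_ground_z: float = 84.70449305839352
    b_ground_x: float = 25695.836003919743

    # auxiliary trunk viscoelasticity (anti-fall tether)
    k_aux: float = 10927.367138097383
    b_aux: float = 24.909055980798424
    aux_distance: float = 0.15

    # switching thresholds
    balance_distance: float = 0.2
    swing_length_ratio: float = 0.6

    # actuator gain and mobility regularisers
    gain: float = 3000.0
    eps1: float = 1e-10
    eps2: float = 1e-4

    # integration and failure detection
    dt: float = 1e-5
    fall_height: float = 0.4

    def __post_init__(self) -> None:
        side = 2.0 * self.trunk_height / _SQRT3
        if self.natural_length_leg is None:
            object.__setattr__(self, "natural_length_leg", side)
        if self.natural_length_interleg is None:
            object.__setattr__(self, "natural_length_interleg", side)
        self._validate()

    def _validate(self) -> None:
        positive = (
            "m_trunk", "m_foot", "gravity", "trunk_height",
            "natural_length_leg", "natural_length_interleg",
            "k_leg_flight", "k_leg_contact", "b_leg",
            "ext_stiffen_mult", "ext_trigger_ratio",
            "k_interleg", "b_interleg",
            "k_ground_z", "b_ground_z", "b_ground_x",
            "k_aux", "b_aux", "aux_distance",
            "balance_distance", "swing_length_ratio",
            "gain", "eps1", "eps2", "dt", "fall_height",
        )
        for name in positive:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"{name} must be a finite number, got {value!r}")
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.k_leg_contact < self.k_leg_flight:
            raise ValueError(
                "contact-phase leg elasticity must be >= flight-phase elasticity"
            )
        if self.ext_trigger_ratio <= 1.0:
            raise ValueError("ext_trigger_ratio must exceed 1")

    # -- convenience -------------------------------------------------------

    @property
    def foot_half_separation(self) -> float:
        """Half the initial foot separation (equilateral triangle base)."""
        return self.trunk_height / _SQRT3

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def scaled(self, which: str, factor: float) -> "ModelParameters":
        """Return a copy with one sensitivity parameter multiplied by *factor*.

        ``which`` is one of ``'leg_elasticity'`` (both flight and contact
        coefficients), ``'ground_elasticity'`` or ``'gain'``.
        """
        if factor <= 0:
            raise ValueError("factor must be positive")
        if which == "leg_elasticity":
            return self.replace(
                k_leg_flight=self.k_leg_flight * factor,
                k_leg_contact=self.k_leg_contact * factor,
            )
        if which == "ground_elasticity":
            return self.replace(k_ground_z=self.k_ground_z * factor)
        if which == "gain":
            return self.replace(gain=self.gain * factor)
        raise ValueError(f"unknown sensitivity parameter {which!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_array(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the compiled engine."""
        return np.array(
            [
                self.m_trunk,
                self.m_foot,
                self.gravity,
                self.natural_length_leg,
                self.natural_length_interleg,
                self.k_leg_flight,
                self.k_leg_contact,
                self.b_leg,
                self.ext_stiffen_mult,
                self.ext_trigger_ratio,
                self.k_interleg,
                self.b_interleg,
                self.k_ground_z,
                self.b_ground_z,
                self.b_ground_x,
                self.k_aux,
                self.b_aux,
                self.aux_distance,
                self.balance_distance,
                self.swing_length_ratio,
                self.gain,
                self.eps1,
                self.eps2,
                self.dt,
                self.fall_height,
            ],
            dtype=np.float64,
        )


#: length of the packed parameter vector
PARAM_SIZE = 25
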