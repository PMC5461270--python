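"""Experiment protocols: straight sidestep, direction-change trials,
timing sweeps and parameter-sensitivity sweeps.

The evaluation methodology: run lateral locomotion at a constant commanded
speed, flip the sign of the command at an arbitrary switch time, and
measure the *reaching time* — the interval from the command flip until the
trunk has moved 2 m in the new direction.  Scanning the switch time over a
dense grid probes whether the controller can reverse from any phase of the
gait cycle ("direction change at any time").

Everything here is deterministic: a given parameter set and protocol
configuration reproduces trajectories bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .dynamics import classify_contact
from .engine import (
    STATUS_FALL,
    STATUS_NONFINITE,
    STATUS_OK,
    STATUS_REACHED,
    SegmentResult,
    run_segment,
)
from .params import ModelParameters
from .state import LEFT, RIGHT, SystemState
from .trajectory import Trajectory

__all__ = [
    "SimulationRun",
    "TrialResult",
    "SweepResult",
    "SensitivityEntry",
    "make_initial_state",
    "run_sidestep",
    "direction_change_trial",
    "sweep_timings",
    "sensitivity_sweep",
    "SENSITIVITY_FACTORS",
]

#: multiplicative factor grid of the sensitivity analysis
SENSITIVITY_FACTORS = (10.0 ** -1, 10.0 ** -0.5, 1.0, 10.0 ** 0.5, 10.0)

#: default reach target of a direction-change trial [m]
REACH_DISTANCE = 2.0

_FOOT_NAMES = {RIGHT: "right", LEFT: "left"}


def make_initial_state(params: ModelParameters) -> SystemState:
    """Motionless double-support start in an equilateral triangular posture.

    Trunk at (0, trunk_height); feet on the ground symmetric about x = 0,
    so every spring is at its natural length and total momentum is zero.
    """
    half = params.foot_half_separation
    pos = np.array([
        [0.0, params.trunk_height],
        [half, 0.0],
        [-half, 0.0],
    ])
    return SystemState(0.0, pos, np.zeros((3, 2)))


@dataclass
class SimulationRun:
    """A completed (possibly multi-segment) simulation."""

    status: int
    trajectory: Trajectory
    final_state: SystemState

    @property
    def fell(self) -> bool:
        return self.status == STATUS_FALL

    @property
    def diverged(self) -> bool:
        return self.status == STATUS_NONFINITE


def run_sidestep(
    params: ModelParameters,
    schedule: list[tuple[float, float]],
    duration: float,
    *,
    initial_state: SystemState | None = None,
    log_every: int = 100,
    record_diag: bool = False,
) -> SimulationRun:
    """Integrate with a piecewise-constant desired-velocity schedule.

    ``schedule`` is a list of (start_time, v_d_x) pairs, the first starting
    at the initial state's time.  Terminates at ``duration``, at a fall, or
    on numerical divergence (reported via ``status``, not raised).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not schedule:
        raise ValueError("schedule must contain at least one segment")
    state = (initial_state or make_initial_state(params)).copy()
    t0 = state.t
    starts = [s for s, _ in schedule]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("schedule times must be strictly increasing")
    if not math.isclose(starts[0], t0):
        raise ValueError("schedule must start at the initial state's time")

    bounds = starts[1:] + [t0 + duration]
    parts: list[Trajectory] = []
    status = STATUS_OK
    for (seg_start, vd), seg_end in zip(schedule, bounds):
        n_steps = round((seg_end - t0) / params.dt) - round((seg_start - t0) / params.dt)
        if n_steps <= 0:
            continue
        seg = run_segment(
            state, params, vd, n_steps,
            log_every=log_every, record_diag=record_diag,
        )
        parts.append(seg.trajectory)
        state = seg.final_state
        status = seg.status
        if status in (STATUS_FALL, STATUS_NONFINITE):
            break
    return SimulationRun(status, Trajectory.concatenate(parts), state)


@dataclass
class TrialResult:
    """One direction-change trial."""

    switch_time: float
    reaching_time: float | None
    success: bool
    fell: bool
    timed_out: bool
    trailing_stance_at_switch: bool
    leading_foot: int                       # post-switch leading foot index
    steps_leading: int
    steps_trailing: int
    max_height_leading: float
    max_height_trailing: float
    trajectory: Trajectory | None = None    # post-switch segment

    def as_record(self) -> dict:
        return {
            "switch_time": self.switch_time,
            "reaching_time": math.nan if self.reaching_time is None else self.reaching_time,
            "success": self.success,
            "fell": self.fell,
            "timed_out": self.timed_out,
            "trailing_stance_at_switch": self.trailing_stance_at_switch,
            "leading_foot": _FOOT_NAMES[self.leading_foot],
            "steps_leading": self.steps_leading,
            "steps_trailing": self.steps_trailing,
            "max_height_leading": self.max_height_leading,
            "max_height_trailing": self.max_height_trailing,
        }


def _finish_trial(
    params: ModelParameters,
    state_at_switch: SystemState,
    t_switch: float,
    v_target: float,
    timeout: float,
    log_every: int,
    keep_trajectory: bool,
    debounce: float,
) -> TrialResult:
    """Run the post-switch phase from a state at the switch instant."""
    pre_contact = classify_contact(state_at_switch, v_target)
    trailing_stance = pre_contact.grounded(pre_contact.posterior)
    post_contact = classify_contact(state_at_switch, -v_target)
    leading = post_contact.anterior
    trailing = post_contact.posterior

    sign = -1.0 if v_target > 0 else 1.0
    seg = run_segment(
        state_at_switch, params, -v_target, round(timeout / params.dt),
        log_every=log_every,
        stop_displacement=(sign, state_at_switch.pos[0, 0], REACH_DISTANCE),
    )
    fell = seg.status == STATUS_FALL or seg.status == STATUS_NONFINITE
    reached = seg.status == STATUS_REACHED
    timed_out = seg.status == STATUS_OK
    # exact interval from the step count (independent of accumulated time)
    reaching_time = seg.steps_done * params.dt if reached else None

    traj = seg.trajectory
    events = metrics.detect_events(traj, debounce=debounce)
    t_end = seg.final_state.t
    steps = {
        foot: metrics.count_steps(events, (t_switch, t_end))[foot]
        for foot in (RIGHT, LEFT)
    }
    heights = {
        foot: float(traj.foot_height(foot).max()) if len(traj) else 0.0
        for foot in (RIGHT, LEFT)
    }
    return TrialResult(
        switch_time=t_switch,
        reaching_time=reaching_time,
        success=reached,
        fell=fell,
        timed_out=timed_out,
        trailing_stance_at_switch=trailing_stance,
        leading_foot=leading,
        steps_leading=steps[leading],
        steps_trailing=steps[trailing],
        max_height_leading=heights[leading],
        max_height_trailing=heights[trailing],
        trajectory=traj if keep_trajectory else None,
    )


def direction_change_trial(
    params: ModelParameters,
    t_switch: float,
    *,
    v_target: float = 2.0,
    timeout: float = 15.0,
    log_every: int = 100,
    keep_trajectory: bool = False,
    debounce: float = 0.02,
) -> TrialResult:
    """Sidestep at +v_target until ``t_switch``, then command -v_target.

    The reaching time is the interval from the command flip until the
    trunk's lateral displacement from its switch-instant position reaches
    2 m in the new direction; a fall or the ``timeout`` cap marks failure.
    """
    if t_switch <= 0:
        raise ValueError("t_switch must be positive")
    state = make_initial_state(params)
    seg = run_segment(
        state, params, v_target, round(t_switch / params.dt), log_every=log_every
    )
    if seg.status != STATUS_OK:
        contact = classify_contact(seg.final_state, v_target)
        return TrialResult(
            switch_time=t_switch, reaching_time=None, success=False,
            fell=True, timed_out=False,
            trailing_stance_at_switch=contact.grounded(contact.posterior),
            leading_foot=classify_contact(seg.final_state, -v_target).anterior,
            steps_leading=0, steps_trailing=0,
            max_height_leading=0.0, max_height_trailing=0.0,
        )
    return _finish_trial(
        params, seg.final_state, seg.final_state.t, v_target, timeout,
        log_every, keep_trajectory, debounce,
    )


@dataclass
class SweepResult:
    """Direction-change trials over a uniform switch-time grid."""

    t_start: float
    spacing: float
    trials: list[TrialResult] = field(default_factory=list)

    @property
    def switch_times(self) -> np.ndarray:
        return np.array([tr.switch_time for tr in self.trials])

    @property
    def reaching_times(self) -> np.ndarray:
        return np.array(
            [math.nan if tr.reaching_time is None else tr.reaching_time
             for tr in self.trials]
        )

    @property
    def trailing_stance(self) -> np.ndarray:
        return np.array([tr.trailing_stance_at_switch for tr in self.trials])

    @property
    def all_success(self) -> bool:
        return all(tr.success for tr in self.trials)

    def summary(self) -> dict:
        rt = self.reaching_times
        ok = rt[~np.isnan(rt)]
        groups = self.trailing_stance
        rt_trail = rt[groups & ~np.isnan(rt)]
        rt_other = rt[~groups & ~np.isnan(rt)]
        return {
            "n_trials": len(self.trials),
            "n_success": int(sum(tr.success for tr in self.trials)),
            "n_fall": int(sum(tr.fell for tr in self.trials)),
            "n_timeout": int(sum(tr.timed_out for tr in self.trials)),
            "reaching_mean": float(ok.mean()) if ok.size else math.nan,
            "reaching_sd": float(ok.std(ddof=1)) if ok.size > 1 else math.nan,
            "reaching_mean_trailing_stance": float(rt_trail.mean()) if rt_trail.size else math.nan,
            "reaching_sd_trailing_stance": float(rt_trail.std(ddof=1)) if rt_trail.size > 1 else math.nan,
            "reaching_mean_other": float(rt_other.mean()) if rt_other.size else math.nan,
            "reaching_sd_other": float(rt_other.std(ddof=1)) if rt_other.size > 1 else math.nan,
            "n_trailing_stance": int(groups.sum()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([tr.as_record() for tr in self.trials])


def sweep_timings(
    params: ModelParameters,
    *,
    t_start: float = 1.5,
    spacing: float = 0.03,
    n: int = 101,
    v_target: float = 2.0,
    timeout: float = 15.0,
    log_every: int = 100,
    keep_trajectories: bool = False,
    debounce: float = 0.02,
) -> SweepResult:
    """Run ``n`` direction-change trials at ``t_start + j * spacing``.

    The pre-switch locomotion is shared: one baseline run is advanced
    segment by segment and snapshotted at every grid time, which is exact
    because the integration is deterministic and the grid times land on
    integer step counts.  Trial failures (fall/timeout) are recorded in the
    result, not raised.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    dt = params.dt
    step_idx = [round((t_start + j * spacing) / dt) for j in range(n)]
    state = make_initial_state(params)
    result = SweepResult(t_start=t_start, spacing=spacing)
    done = 0
    baseline_dead = False
    for j in range(n):
        t_switch = t_start + j * spacing
        if not baseline_dead:
            seg = run_segment(
                state, params, v_target, step_idx[j] - done, log_every=log_every
            )
            state = seg.final_state
            done = step_idx[j]
            if seg.status != STATUS_OK:
                baseline_dead = True
        if baseline_dead:
            contact = classify_contact(state, v_target)
            result.trials.append(TrialResult(
                switch_time=t_switch, reaching_time=None, success=False,
                fell=True, timed_out=False,
                trailing_stance_at_switch=contact.grounded(contact.posterior),
                leading_foot=classify_contact(state, -v_target).anterior,
                steps_leading=0, steps_trailing=0,
                max_height_leading=0.0, max_height_trailing=0.0,
            ))
            continue
        result.trials.append(_finish_trial(
            params, state, t_switch, v_target, timeout,
            log_every, keep_trajectories, debounce,
        ))
    return result


@dataclass
class SensitivityEntry:
    parameter: str
    factor: float
    n_trials: int
    n_success: int

    @property
    def all_success(self) -> bool:
        return self.n_success == self.n_trials

    def as_record(self) -> dict:
        return {
            "parameter": self.parameter,
            "factor": self.factor,
            "n_trials": self.n_trials,
            "n_success": self.n_success,
            "all_success": self.all_success,
        }


def sensitivity_sweep(
    params: ModelParameters,
    which: tuple[str, ...] = ("leg_elasticity", "ground_elasticity", "gain"),
    factors: tuple[float, ...] = SENSITIVITY_FACTORS,
    *,
    t_start: float = 1.5,
    spacing: float = 0.3,
    n: int = 10,
    v_target: float = 2.0,
    timeout: float = 15.0,
    log_every: int = 100,
) -> list[SensitivityEntry]:
    """Rerun a reduced timing sweep with each parameter scaled in turn.

    Each of the swept parameters (leg elasticity, ground elasticity,
    actuator gain) is multiplied by each factor and the direction-change
    success over the reduced switch-time grid is tabulated.
    """
    if any(f <= 0 for f in factors):
        raise ValueError("factors must be positive")
    entries = []
    for name in which:
        for factor in factors:
            scaled = params.scaled(name, factor)
            sweep = sweep_timings(
                scaled, t_start=t_start, spacing=spacing, n=n,
                v_target=v_target, timeout=timeout, log_every=log_every,
            )
            entries.append(SensitivityEntry(
                parameter=name,
                factor=factor,
                n_trials=len(sweep.trials),
                n_success=sum(tr.success for tr in sweep.trials),
            ))
    return entries
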