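"""Compiled fixed-step simulation loop.

The controller and the mechanics are deliberately re-stated here in scalar
form for numba: one loop iteration evaluates the switching mobility
controller and then advances the equation of motion by one forward-Euler
step, replicating the arithmetic of :mod:`sidestep.controller` and
:mod:`sidestep.dynamics` operation for operation (the test suite checks
step-level agreement between the two paths).

The loop runs with a constant desired velocity; piecewise-constant command
schedules (e.g. the direction-change protocol) chain several calls, which
is exact because the state hand-off is bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import ModelParameters
from .state import SystemState
from .trajectory import DIAG_COLUMNS, Trajectory

__all__ = ["STATUS_OK", "STATUS_REACHED", "STATUS_FALL", "STATUS_NONFINITE",
           "SegmentResult", "run_segment"]

STATUS_OK = 0          # completed the requested number of steps
STATUS_REACHED = 1     # displacement stop condition met
STATUS_FALL = 2        # trunk dropped below the fall threshold
STATUS_NONFINITE = 3   # numerical blow-up

# packed parameter vector layout (see ModelParameters.to_array)
_M_TRUNK, _M_FOOT, _G, _L0_LEG, _L0_IL = 0, 1, 2, 3, 4
_K_LEG_F, _K_LEG_C, _B_LEG, _EXT_MULT, _EXT_RATIO = 5, 6, 7, 8, 9
_K_IL, _B_IL, _K_GZ, _B_GZ, _B_GX = 10, 11, 12, 13, 14
_K_AUX, _B_AUX, _D_AUX, _D_BAL, _SWING = 15, 16, 17, 18, 19
_GAIN, _EPS1, _EPS2, _DT, _FALL = 20, 21, 22, 23, 24

_M4LN2 = -4.0 * math.log(2.0)
_MIN_MOB = 2.2250738585072014e-308  # keep k_i strictly positive (underflow guard)


@njit(cache=True)
def _run(pos, vel, t0, vd_x, n_steps, P, log_every,
         log_t, log_pos, log_vel, log_grd, log_diag, record_diag,
         stop_sign, stop_ref, stop_target):
    """Advance the model ``n_steps`` steps (or until a stop condition).

    ``pos``/``vel`` are (3, 2) arrays updated in place.  Logging writes the
    pre-step state every ``log_every`` steps into the provided buffers.
    Returns (status, steps_done, t_final, n_logged).
    """
    dt = P[_DT]
    l0 = P[_L0_LEG]
    l0_il = P[_L0_IL]
    m_trunk = P[_M_TRUNK]
    m_foot = P[_M_FOOT]
    grav = P[_G]
    gain = P[_GAIN]
    swing_thr = P[_SWING] * l0
    trigger = P[_EXT_RATIO] * l0

    axes = np.empty((3, 2))
    lens = np.empty(3)
    rels = np.empty(3)
    a = np.empty(3)
    vl = np.empty((3, 2))
    vr = np.empty((3, 2))
    va = np.empty((3, 2))
    mob = np.empty(3)
    req = np.zeros((3, 3, 2))
    vc = np.empty((3, 2))
    fvec = np.empty((3, 2))
    active = np.empty((3, 2))

    t = t0
    n_logged = 0
    status = STATUS_OK
    step = 0
    while step < n_steps:
        log_now = (step % log_every) == 0
        if log_now:
            log_t[n_logged] = t
            for m in range(3):
                log_pos[n_logged, m, 0] = pos[m, 0]
                log_pos[n_logged, m, 1] = pos[m, 1]
                log_vel[n_logged, m, 0] = vel[m, 0]
                log_vel[n_logged, m, 1] = vel[m, 1]
            log_grd[n_logged, 0] = 1 if pos[1, 1] <= 0.0 else 0
            log_grd[n_logged, 1] = 1 if pos[2, 1] <= 0.0 else 0

        # ---- contact classification -------------------------------------
        s = -1.0 if vd_x < 0.0 else 1.0
        sxr = s * pos[1, 0]
        sxl = s * pos[2, 0]
        if sxr > sxl:
            ant = 1
        elif sxl > sxr:
            ant = 2
        else:
            ant = 1 if s > 0.0 else 2
        post = 3 - ant
        gr = pos[1, 1] <= 0.0
        gl = pos[2, 1] <= 0.0
        g_ant = gr if ant == 1 else gl
        g_post = gr if post == 1 else gl

        # ---- actuator axes and lengths ----------------------------------
        # inter-leg: posterior foot -> anterior foot
        dx = pos[ant, 0] - pos[post, 0]
        dz = pos[ant, 1] - pos[post, 1]
        L = math.sqrt(dx * dx + dz * dz)
        if L <= 0.0:
            status = STATUS_NONFINITE
            break
        axes[0, 0] = dx / L
        axes[0, 1] = dz / L
        lens[0] = L
        # legs: foot -> trunk
        for i in range(1, 3):
            dx = pos[0, 0] - pos[i, 0]
            dz = pos[0, 1] - pos[i, 1]
            L = math.sqrt(dx * dx + dz * dz)
            if L <= 0.0:
                status = STATUS_NONFINITE
                break
            axes[i, 0] = dx / L
            axes[i, 1] = dz / L
            lens[i] = L
        if status == STATUS_NONFINITE:
            break

        # ---- switching coefficients -------------------------------------
        L_post = lens[post]
        if g_ant and g_post:
            a[0] = 0.0
        elif (not g_ant) and (not g_post):
            a[0] = -0.5 if L_post > swing_thr else 0.5
        elif g_ant:
            a[0] = -1.0 if L_post > swing_thr else 0.0
        else:
            a[0] = 0.0
        for i in range(1, 3):
            grounded = gr if i == 1 else gl
            hdist = abs(pos[0, 0] - pos[i, 0])
            sign = 1.0
            if i == ant and hdist < P[_D_BAL]:
                sign = -1.0
            elif i == post and (not grounded) and lens[i] > l0:
                sign = -1.0
            a[i] = sign if grounded else 0.5 * sign

        # ---- local / residual decomposition -----------------------------
        for i in range(3):
            proj = axes[i, 0] * vd_x + axes[i, 1] * 0.0
            c = a[i] * proj
            vl[i, 0] = c * axes[i, 0]
            vl[i, 1] = c * axes[i, 1]
            vr[i, 0] = vd_x - vl[i, 0]
            vr[i, 1] = 0.0 - vl[i, 1]

        # ---- produced velocities ----------------------------------------
        rels[0] = (vel[ant, 0] - vel[post, 0]) * axes[0, 0] + (
            vel[ant, 1] - vel[post, 1]
        ) * axes[0, 1]
        for i in range(1, 3):
            rels[i] = (vel[0, 0] - vel[i, 0]) * axes[i, 0] + (
                vel[0, 1] - vel[i, 1]
            ) * axes[i, 1]
        for i in range(3):
            va[i, 0] = rels[i] * axes[i, 0]
            va[i, 1] = rels[i] * axes[i, 1]

        # ---- mobility indices -------------------------------------------
        for i in range(3):
            ddx = vl[i, 0] - va[i, 0]
            ddz = vl[i, 1] - va[i, 1]
            num = ddx * ddx + ddz * ddz + P[_EPS1]
            den = vl[i, 0] * vl[i, 0] + vl[i, 1] * vl[i, 1] + P[_EPS2]
            k = math.exp(_M4LN2 * num / den)
            mob[i] = k if k > 0.0 else _MIN_MOB

        # ---- cross requests and command mixing --------------------------
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                proj = axes[i, 0] * vr[j, 0] + axes[i, 1] * vr[j, 1]
                req[i, j, 0] = proj * axes[i, 0]
                req[i, j, 1] = proj * axes[i, 1]
        for i in range(3):
            if i == 0:
                j, k = 1, 2
            elif i == 1:
                j, k = 0, 2
            else:
                j, k = 0, 1
            inhib = (1.0 - mob[j]) * (1.0 - mob[k])
            for c in range(2):
                vc[i, c] = inhib * vl[i, c] + (
                    mob[j] * req[i, j, c] + mob[k] * req[i, k, c]
                )

        # ---- actuator forces --------------------------------------------
        for i in range(3):
            fvec[i, 0] = gain * (vc[i, 0] - va[i, 0])
            fvec[i, 1] = gain * (vc[i, 1] - va[i, 1])
        for c in range(2):
            active[0, c] = fvec[1, c] + fvec[2, c]
            active[1, c] = -fvec[1, c]
            active[2, c] = -fvec[2, c]
            active[ant, c] += fvec[0, c]
            active[post, c] -= fvec[0, c]

        if log_now and record_diag:
            log_diag[n_logged, 0] = a[0]
            log_diag[n_logged, 1] = a[1]
            log_diag[n_logged, 2] = a[2]
            log_diag[n_logged, 3] = mob[0]
            log_diag[n_logged, 4] = mob[1]
            log_diag[n_logged, 5] = mob[2]
            log_diag[n_logged, 6] = gain * (vc[0, 0] * axes[0, 0] + vc[0, 1] * axes[0, 1] - rels[0])
            log_diag[n_logged, 7] = gain * (vc[1, 0] * axes[1, 0] + vc[1, 1] * axes[1, 1] - rels[1])
            log_diag[n_logged, 8] = gain * (vc[2, 0] * axes[2, 0] + vc[2, 1] * axes[2, 1] - rels[2])
            err = 0.0
            for i in range(3):
                e0 = abs(vl[i, 0] + vr[i, 0] - vd_x)
                e1 = abs(vl[i, 1] + vr[i, 1])
                if e0 > err:
                    err = e0
                if e1 > err:
                    err = e1
            log_diag[n_logged, 9] = err
        if log_now:
            n_logged += 1

        # ---- passive forces + equation of motion ------------------------
        # legs (base branch + extension-limit stiffening)
        base_r = 0.0
        ext_r = 0.0
        base_l = 0.0
        ext_l = 0.0
        for i in range(1, 3):
            grounded = gr if i == 1 else gl
            k_leg = P[_K_LEG_C] if grounded else P[_K_LEG_F]
            base = -(k_leg * (lens[i] - l0) + P[_B_LEG] * rels[i])
            if lens[i] > trigger:
                ext = (-(P[_EXT_MULT] - 1.0)) * k_leg * (lens[i] - trigger)
            else:
                ext = 0.0
            if i == 1:
                base_r = base
                ext_r = ext
            else:
                base_l = base
                ext_l = ext

        # inter-leg spring-damper (left foot -> right foot axis)
        dx = pos[1, 0] - pos[2, 0]
        dz = pos[1, 1] - pos[2, 1]
        L_il = math.sqrt(dx * dx + dz * dz)
        e_il_x = dx / L_il
        e_il_z = dz / L_il
        rate_il = (vel[1, 0] - vel[2, 0]) * e_il_x + (vel[1, 1] - vel[2, 1]) * e_il_z
        axial_il = -(P[_K_IL] * (L_il - l0_il) + P[_B_IL] * rate_il)

        # ground reaction
        gx_r = 0.0
        gz_r = 0.0
        gx_l = 0.0
        gz_l = 0.0
        if pos[1, 1] <= 0.0:
            gz_r = -P[_K_GZ] * pos[1, 1] - P[_B_GZ] * vel[1, 1]
            if gz_r < 0.0:
                gz_r = 0.0
            gx_r = -P[_B_GX] * vel[1, 0]
        if pos[2, 1] <= 0.0:
            gz_l = -P[_K_GZ] * pos[2, 1] - P[_B_GZ] * vel[2, 1]
            if gz_l < 0.0:
                gz_l = 0.0
            gx_l = -P[_B_GX] * vel[2, 0]

        # auxiliary trunk tether (horizontal only)
        aux_t = 0.0
        aux_r = 0.0
        aux_l = 0.0
        for i in range(1, 3):
            d = pos[0, 0] - pos[i, 0]
            ad = abs(d)
            if ad < P[_D_AUX]:
                u = 1.0 if d > 0.0 else (-1.0 if d < 0.0 else 0.0)
                sep = (vel[0, 0] - vel[i, 0]) * u
                fmag = P[_K_AUX] * (P[_D_AUX] - ad) - P[_B_AUX] * sep
                if i == 1:
                    aux_t = aux_t + u * fmag
                    aux_r = -u * fmag
                else:
                    aux_t = aux_t + u * fmag
                    aux_l = -u * fmag

        # per-mass totals (categories summed in the reference order)
        leg_tx = base_r * axes[1, 0] + (base_l * axes[2, 0])
        leg_tz = base_r * axes[1, 1] + (base_l * axes[2, 1])
        ext_tx = ext_r * axes[1, 0] + (ext_l * axes[2, 0])
        ext_tz = ext_r * axes[1, 1] + (ext_l * axes[2, 1])
        tot_tx = active[0, 0] + ((((leg_tx + ext_tx) + 0.0) + 0.0) + aux_t)
        tot_tz = active[0, 1] + ((((leg_tz + ext_tz) + 0.0) + 0.0) + 0.0)
        tot_rx = active[1, 0] + (
            (((-base_r * axes[1, 0] + -ext_r * axes[1, 0]) + axial_il * e_il_x) + gx_r)
            + aux_r
        )
        tot_rz = active[1, 1] + (
            (((-base_r * axes[1, 1] + -ext_r * axes[1, 1]) + axial_il * e_il_z) + gz_r)
            + 0.0
        )
        tot_lx = active[2, 0] + (
            (((-base_l * axes[2, 0] + -ext_l * axes[2, 0]) + -axial_il * e_il_x) + gx_l)
            + aux_l
        )
        tot_lz = active[2, 1] + (
            (((-base_l * axes[2, 1] + -ext_l * axes[2, 1]) + -axial_il * e_il_z) + gz_l)
            + 0.0
        )

        ax_t = tot_tx / m_trunk
        az_t = (tot_tz - m_trunk * grav) / m_trunk
        ax_r = tot_rx / m_foot
        az_r = (tot_rz - m_foot * grav) / m_foot
        ax_l = tot_lx / m_foot
        az_l = (tot_lz - m_foot * grav) / m_foot

        if not (
            math.isfinite(ax_t) and math.isfinite(az_t)
            and math.isfinite(ax_r) and math.isfinite(az_r)
            and math.isfinite(ax_l) and math.isfinite(az_l)
        ):
            status = STATUS_NONFINITE
            break

        # forward Euler: positions advance with pre-step velocities
        for m in range(3):
            pos[m, 0] = pos[m, 0] + vel[m, 0] * dt
            pos[m, 1] = pos[m, 1] + vel[m, 1] * dt
        vel[0, 0] = vel[0, 0] + ax_t * dt
        vel[0, 1] = vel[0, 1] + az_t * dt
        vel[1, 0] = vel[1, 0] + ax_r * dt
        vel[1, 1] = vel[1, 1] + az_r * dt
        vel[2, 0] = vel[2, 0] + ax_l * dt
        vel[2, 1] = vel[2, 1] + az_l * dt
        t = t + dt
        step += 1

        if pos[0, 1] < P[_FALL]:
            status = STATUS_FALL
            break
        if stop_sign != 0.0 and (pos[0, 0] - stop_ref) * stop_sign >= stop_target:
            status = STATUS_REACHED
            break

    return status, step, t, n_logged


@dataclass
class SegmentResult:
    """Outcome of one constant-command engine run."""

    status: int
    steps_done: int
    final_state: SystemState
    trajectory: Trajectory


def run_segment(
    state: SystemState,
    params: ModelParameters,
    v_d_x: float,
    n_steps: int,
    *,
    log_every: int = 100,
    record_diag: bool = False,
    stop_displacement: tuple[float, float, float] | None = None,
) -> SegmentResult:
    """Run the compiled loop for ``n_steps`` with a constant command.

    ``stop_displacement`` is an optional ``(sign, reference_x, target)``
    triple: the run ends with ``STATUS_REACHED`` as soon as the trunk's
    lateral displacement from ``reference_x``, measured along ``sign``,
    reaches ``target``.  The input ``state`` is not modified.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    pos = state.pos.copy()
    vel = state.vel.copy()
    n_log = n_steps // log_every + 1
    log_t = np.empty(n_log)
    log_pos = np.empty((n_log, 3, 2))
    log_vel = np.empty((n_log, 3, 2))
    log_grd = np.zeros((n_log, 2), dtype=np.int8)
    log_diag = np.zeros((n_log, len(DIAG_COLUMNS)) if record_diag else (1, len(DIAG_COLUMNS)))
    if stop_displacement is None:
        stop_sign, stop_ref, stop_target = 0.0, 0.0, 0.0
    else:
        stop_sign, stop_ref, stop_target = stop_displacement
    status, steps_done, t_final, n_logged = _run(
        pos, vel, state.t, float(v_d_x), int(n_steps), params.to_array(),
        int(log_every), log_t, log_pos, log_vel, log_grd, log_diag,
        bool(record_diag), float(stop_sign), float(stop_ref), float(stop_target),
    )
    traj = Trajectory(
        t=log_t[:n_logged].copy(),
        pos=log_pos[:n_logged].copy(),
        vel=log_vel[:n_logged].copy(),
        grounded=log_grd[:n_logged].copy(),
        diag=log_diag[:n_logged].copy() if record_diag else None,
    )
    return SegmentResult(
        status=status,
        steps_done=steps_done,
        final_state=SystemState(t_final, pos, vel),
        trajectory=traj,
    )
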