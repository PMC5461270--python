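"""Independent straight-line re-implementation of the switching mobility
control law, used as the oracle the packaged controller is checked against.

Deliberately written in a different style (dense numpy, no shared helpers)
so that an error in the package implementation cannot hide in the oracle.
"""

import numpy as np

FOUR_LN2 = 4.0 * np.log(2.0)


def oracle_control(pos, vel, vd_x, p):
    """Evaluate the full control law for one state.

    pos, vel: (3, 2) arrays (trunk, right foot, left foot).
    p: ModelParameters.
    Returns (per_mass_force (3,2), dict of intermediates).
    """
    vd = np.array([vd_x, 0.0])
    s = -1.0 if vd_x < 0 else 1.0
    # anterior foot = farther along s
    if s * pos[1, 0] > s * pos[2, 0]:
        ant, post = 1, 2
    elif s * pos[2, 0] > s * pos[1, 0]:
        ant, post = 2, 1
    else:
        ant, post = (1, 2) if s > 0 else (2, 1)
    gr = pos[1, 1] <= 0.0
    gl = pos[2, 1] <= 0.0
    grounded = {1: gr, 2: gl}

    # axes: 0 inter-leg (post -> ant), 1/2 legs (foot -> trunk)
    endpoints = {0: (post, ant), 1: (1, 0), 2: (2, 0)}
    e = np.zeros((3, 2))
    for i, (a_, b_) in endpoints.items():
        d = pos[b_] - pos[a_]
        e[i] = d / np.linalg.norm(d)
    leg_len = {i: np.linalg.norm(pos[0] - pos[i]) for i in (1, 2)}

    # switching coefficients
    a = np.zeros(3)
    thr = p.swing_length_ratio * p.natural_length_leg
    if grounded[ant] and grounded[post]:
        a[0] = 0.0
    elif not grounded[ant] and not grounded[post]:
        a[0] = 0.5 * (-1.0 if leg_len[post] > thr else 1.0)
    elif grounded[ant]:
        a[0] = -1.0 if leg_len[post] > thr else 0.0
    else:
        a[0] = 0.0
    for i in (1, 2):
        sign = 1.0
        if i == ant and abs(pos[0, 0] - pos[i, 0]) < p.balance_distance:
            sign = -1.0
        elif i == post and not grounded[i] and leg_len[i] > p.natural_length_leg:
            sign = -1.0
        a[i] = sign * (1.0 if grounded[i] else 0.5)

    v_loc = np.array([a[i] * (e[i] @ vd) * e[i] for i in range(3)])
    v_res = vd[None, :] - v_loc
    v_act = np.array(
        [((vel[endpoints[i][1]] - vel[endpoints[i][0]]) @ e[i]) * e[i] for i in range(3)]
    )
    k = np.array([
        np.exp(-FOUR_LN2
               * (np.sum((v_loc[i] - v_act[i]) ** 2) + p.eps1)
               / (np.sum(v_loc[i] ** 2) + p.eps2))
        for i in range(3)
    ])
    v_req = np.zeros((3, 3, 2))
    for i in range(3):
        for j in range(3):
            if i != j:
                v_req[i, j] = (e[i] @ v_res[j]) * e[i]
    v_cmd = np.zeros((3, 2))
    for i in range(3):
        others = [j for j in range(3) if j != i]
        v_cmd[i] = np.prod([1.0 - k[j] for j in others]) * v_loc[i]
        for j in others:
            v_cmd[i] += k[j] * v_req[i, j]
    f = p.gain * (v_cmd - v_act)

    per_mass = np.zeros((3, 2))
    per_mass[0] = f[1] + f[2]
    per_mass[1] -= f[1]
    per_mass[2] -= f[2]
    per_mass[ant] += f[0]
    per_mass[post] -= f[0]
    return per_mass, {
        "axes": e, "a": a, "v_local": v_loc, "v_residual": v_res,
        "v_actual": v_act, "mobility": k, "v_required": v_req,
        "v_command": v_cmd, "force": f, "anterior": ant,
    }


def random_state(rng, p):
    """A random mechanically plausible state (non-coincident masses)."""
    from sidestep.state import SystemState

    while True:
        trunk = np.array([rng.uniform(-1.0, 1.0), rng.uniform(0.5, 1.1)])
        feet = np.array([
            [trunk[0] + rng.uniform(0.05, 0.9), rng.uniform(-0.05, 0.4)],
            [trunk[0] - rng.uniform(0.05, 0.9), rng.uniform(-0.05, 0.4)],
        ])
        if rng.random() < 0.5:
            feet = feet[::-1]
        pos = np.vstack([trunk[None, :], feet])
        vel = rng.uniform(-2.5, 2.5, size=(3, 2))
        d01 = np.linalg.norm(pos[0] - pos[1])
        d02 = np.linalg.norm(pos[0] - pos[2])
        d12 = np.linalg.norm(pos[1] - pos[2])
        if min(d01, d02, d12) > 0.05:
            return SystemState(0.0, pos, vel)
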