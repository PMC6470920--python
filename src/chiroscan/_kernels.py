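"""Numba-compiled inner loops for the grid scan and the MD integrator.

Determinism contract
--------------------
Pair sums over host atoms are accumulated two-at-a-time in storage order
(j, j+1), then sequentially.  Fixture hosts store mirror-partner atoms
adjacently, so a reflected guest interacting with the (identical) host
produces energies and per-atom forces that are *exact bitwise mirrors* of
the unreflected ones: IEEE addition is commutative and sign-symmetric, and
every other operation in the kernels is a fixed arithmetic formula.  This
is what makes the L/D mirror-null test hold exactly, not just to rounding.

All kernels are compiled without fastmath for the same reason.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: sentinel for a singular (coincident-atom) energy; converted to +inf by callers.
SINGULAR_ENERGY = 1e30

_R2_MIN = 1e-12


@njit(cache=True)
def pair_energy_forces(coords, host, A, B, C, D, QQ, HB, forces):
    """Total interaction energy and per-guest-atom forces.

    ``forces`` is an (n_guest, 3) output buffer.  Returns the energy;
    SINGULAR_ENERGY flags a coincident pair (forces are then meaningless).
    """
    G = coords.shape[0]
    H = host.shape[0]
    e_tot = 0.0
    for i in range(G):
        fx = 0.0
        fy = 0.0
        fz = 0.0
        ei = 0.0
        j = 0
        while j < H:
            # first of the adjacent (mirror-partner) pair
            e1, f1x, f1y, f1z = _one_pair(coords, host, A, B, C, D, QQ, HB, i, j)
            if j + 1 < H:
                e2, f2x, f2y, f2z = _one_pair(coords, host, A, B, C, D, QQ, HB, i, j + 1)
                ei += e1 + e2
                fx += f1x + f2x
                fy += f1y + f2y
                fz += f1z + f2z
                j += 2
            else:
                ei += e1
                fx += f1x
                fy += f1y
                fz += f1z
                j += 1
        e_tot += ei
        forces[i, 0] = fx
        forces[i, 1] = fy
        forces[i, 2] = fz
    return e_tot


@njit(cache=True, inline="always")
def _one_pair(coords, host, A, B, C, D, QQ, HB, i, j):
    dx = coords[i, 0] - host[j, 0]
    dy = coords[i, 1] - host[j, 1]
    dz = coords[i, 2] - host[j, 2]
    r2 = dx * dx + dy * dy + dz * dz
    if r2 < _R2_MIN:
        return SINGULAR_ENERGY, 0.0, 0.0, 0.0
    r = math.sqrt(r2)
    inv_r2 = 1.0 / r2
    inv_r6 = inv_r2 * inv_r2 * inv_r2
    inv_r12 = inv_r6 * inv_r6
    qq = QQ[i, j]
    e_ele = qq / r
    dele = -qq * inv_r2
    if HB[i, j]:
        inv_r10 = inv_r12 * r2
        e_vdw = C[i, j] * inv_r12 - D[i, j] * inv_r10
        dvdw = (-12.0 * C[i, j] * inv_r12 + 10.0 * D[i, j] * inv_r10) / r
    else:
        e_vdw = A[i, j] * inv_r12 - B[i, j] * inv_r6
        dvdw = (-12.0 * A[i, j] * inv_r12 + 6.0 * B[i, j] * inv_r6) / r
    dedr = dvdw + dele
    s = -dedr / r
    return e_vdw + e_ele, s * dx, s * dy, s * dz


@njit(cache=True, inline="always")
def _pair_energy_only(coords, host, A, B, C, D, QQ, HB):
    """Interaction energy only, same paired reduction as the force kernel."""
    G = coords.shape[0]
    H = host.shape[0]
    e_tot = 0.0
    for i in range(G):
        ei = 0.0
        j = 0
        while j < H:
            e1 = _one_pair_e(coords, host, A, B, C, D, QQ, HB, i, j)
            if j + 1 < H:
                e2 = _one_pair_e(coords, host, A, B, C, D, QQ, HB, i, j + 1)
                ei += e1 + e2
                j += 2
            else:
                ei += e1
                j += 1
        e_tot += ei
    return e_tot


@njit(cache=True, inline="always")
def _one_pair_e(coords, host, A, B, C, D, QQ, HB, i, j):
    dx = coords[i, 0] - host[j, 0]
    dy = coords[i, 1] - host[j, 1]
    dz = coords[i, 2] - host[j, 2]
    r2 = dx * dx + dy * dy + dz * dz
    if r2 < _R2_MIN:
        return SINGULAR_ENERGY
    r = math.sqrt(r2)
    inv_r2 = 1.0 / r2
    inv_r6 = inv_r2 * inv_r2 * inv_r2
    inv_r12 = inv_r6 * inv_r6
    e = QQ[i, j] / r
    if HB[i, j]:
        e += C[i, j] * inv_r12 - D[i, j] * (inv_r12 * r2)
    else:
        e += A[i, j] * inv_r12 - B[i, j] * inv_r6
    return e


# ---------------------------------------------------------------------------
# grid x orientation scan
# ---------------------------------------------------------------------------

@njit(cache=True)
def scan_kernel(body, host, A, B, C, D, QQ, HB, rotmats, xs, ys, zs, beta):
    """Exhaustive energy scan over grid points x orientations.

    ``body``   (G, 3) guest coordinates relative to its COM;
    ``rotmats`` (O, 3, 3) rotation matrices, applied as r = R b;
    ``beta``   1/(k_B T) for the streaming Boltzmann average.

    Returns per-point arrays ordered p = (iz*ny + iy)*nx + ix:
    minimum energy, argmin orientation index, and the Boltzmann-average
    numerator/denominator relative to the running minimum (so that
    boltz = se/s1 after the loop).  Ties keep the lowest orientation index.
    """
    O = rotmats.shape[0]
    G = body.shape[0]
    nx, ny, nz = xs.shape[0], ys.shape[0], zs.shape[0]
    P = nx * ny * nz
    emin = np.full(P, SINGULAR_ENERGY)
    argo = np.zeros(P, dtype=np.int64)
    s1 = np.zeros(P)
    se = np.zeros(P)
    rot = np.empty((G, 3))
    coords = np.empty((G, 3))
    for o in range(O):
        for i in range(G):
            for a in range(3):
                rot[i, a] = (
                    rotmats[o, a, 0] * body[i, 0]
                    + rotmats[o, a, 1] * body[i, 1]
                    + rotmats[o, a, 2] * body[i, 2]
                )
        p = 0
        for iz in range(nz):
            for iy in range(ny):
                for ix in range(nx):
                    for i in range(G):
                        coords[i, 0] = rot[i, 0] + xs[ix]
                        coords[i, 1] = rot[i, 1] + ys[iy]
                        coords[i, 2] = rot[i, 2] + zs[iz]
                    e = _pair_energy_only(coords, host, A, B, C, D, QQ, HB)
                    if e < emin[p]:
                        f = math.exp(-(emin[p] - e) * beta)
                        s1[p] *= f
                        se[p] *= f
                        emin[p] = e
                        argo[p] = o
                    w = math.exp(-(e - emin[p]) * beta)
                    s1[p] += w
                    se[p] += e * w
                    p += 1
    return emin, argo, s1, se


# ---------------------------------------------------------------------------
# rigid-body MD
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _quat_to_mat(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)


@njit(cache=True, inline="always")
def _quat_mult(p, q, out):
    out[0] = p[0] * q[0] - p[1] * q[1] - p[2] * q[2] - p[3] * q[3]
    out[1] = p[0] * q[1] + p[1] * q[0] + p[2] * q[3] - p[3] * q[2]
    out[2] = p[0] * q[2] - p[1] * q[3] + p[2] * q[0] + p[3] * q[1]
    out[3] = p[0] * q[3] + p[1] * q[2] - p[2] * q[1] + p[3] * q[0]


@njit(cache=True, inline="always")
def _omega_halfkick(w, Ib, Ibinv, tau_b, half_dt, n_iter):
    """Implicit midpoint half-kick for the body-frame angular velocity:
    w' = w + h I^-1 (tau - w' x (I w')), solved by fixed-point iteration
    (fixed count for determinism)."""
    w0x, w0y, w0z = w[0], w[1], w[2]
    wx, wy, wz = w0x, w0y, w0z
    for _ in range(n_iter):
        lx = Ib[0, 0] * wx + Ib[0, 1] * wy + Ib[0, 2] * wz
        ly = Ib[1, 0] * wx + Ib[1, 1] * wy + Ib[1, 2] * wz
        lz = Ib[2, 0] * wx + Ib[2, 1] * wy + Ib[2, 2] * wz
        gx = tau_b[0] - (wy * lz - wz * ly)
        gy = tau_b[1] - (wz * lx - wx * lz)
        gz = tau_b[2] - (wx * ly - wy * lx)
        wx = w0x + half_dt * (Ibinv[0, 0] * gx + Ibinv[0, 1] * gy + Ibinv[0, 2] * gz)
        wy = w0y + half_dt * (Ibinv[1, 0] * gx + Ibinv[1, 1] * gy + Ibinv[1, 2] * gz)
        wz = w0z + half_dt * (Ibinv[2, 0] * gx + Ibinv[2, 1] * gy + Ibinv[2, 2] * gz)
    w[0], w[1], w[2] = wx, wy, wz


@njit(cache=True, inline="always")
def _rotate_quat(q, w, dt):
    """q <- q * exp(dt * w / 2): rotation by |w| dt about the body axis w."""
    wn = math.sqrt(w[0] * w[0] + w[1] * w[1] + w[2] * w[2])
    if wn > 0.0:
        half = 0.5 * dt * wn
        c = math.cos(half)
        s = math.sin(half) / wn
        dq0 = c
        dq1 = s * w[0]
        dq2 = s * w[1]
        dq3 = s * w[2]
        t0 = q[0] * dq0 - q[1] * dq1 - q[2] * dq2 - q[3] * dq3
        t1 = q[0] * dq1 + q[1] * dq0 + q[2] * dq3 - q[3] * dq2
        t2 = q[0] * dq2 - q[1] * dq3 + q[2] * dq0 + q[3] * dq1
        t3 = q[0] * dq3 + q[1] * dq2 - q[2] * dq1 + q[3] * dq0
        q[0], q[1], q[2], q[3] = t0, t1, t2, t3
    n = math.sqrt(q[0] * q[0] + q[1] * q[1] + q[2] * q[2] + q[3] * q[3])
    q[0] /= n
    q[1] /= n
    q[2] /= n
    q[3] /= n


@njit(cache=True)
def _eval_forces(body, host, A, B, C, D, QQ, HB, q, c, R, coords, forces, out):
    """Place the guest, evaluate energy/net force/body torque.

    ``out`` receives (E, fx, fy, fz, taubx, tauby, taubz)."""
    G = body.shape[0]
    _quat_to_mat(q, R)
    for i in range(G):
        for a in range(3):
            coords[i, a] = (
                R[a, 0] * body[i, 0]
                + R[a, 1] * body[i, 1]
                + R[a, 2] * body[i, 2]
                + c[a]
            )
    e = pair_energy_forces(coords, host, A, B, C, D, QQ, HB, forces)
    fx = 0.0
    fy = 0.0
    fz = 0.0
    tx = 0.0
    ty = 0.0
    tz = 0.0
    for i in range(G):
        fx += forces[i, 0]
        fy += forces[i, 1]
        fz += forces[i, 2]
        rx = coords[i, 0] - c[0]
        ry = coords[i, 1] - c[1]
        rz = coords[i, 2] - c[2]
        tx += ry * forces[i, 2] - rz * forces[i, 1]
        ty += rz * forces[i, 0] - rx * forces[i, 2]
        tz += rx * forces[i, 1] - ry * forces[i, 0]
    # body-frame torque: tau_b = R^T tau_space
    out[0] = e
    out[1] = fx
    out[2] = fy
    out[3] = fz
    out[4] = R[0, 0] * tx + R[1, 0] * ty + R[2, 0] * tz
    out[5] = R[0, 1] * tx + R[1, 1] * ty + R[2, 1] * tz
    out[6] = R[0, 2] * tx + R[1, 2] * ty + R[2, 2] * tz


REASON_TIME = 0
REASON_ESCAPED = 1
REASON_BLOWUP = 2


@njit(cache=True)
def md_kernel(
    body,
    masses,
    Ib,
    Ibinv,
    host,
    A,
    B,
    C,
    D,
    QQ,
    HB,
    q0,
    c0,
    v0,
    w0,
    dt,
    n_steps,
    record_every,
    thermostat,
    ke_target,
    acc_conv,
    resc2,
    e_escape,
    escape_frames,
):
    """Constant-temperature rigid-body leap-frog (velocity-Verlet form).

    Translational and rotational kinetic energies are separately rescaled
    to ``ke_target`` (kcal/mol) after every step when ``thermostat`` is on.
    Recording happens at step 0 and every ``record_every`` steps; the
    escape rule (|COM|^2 > resc2 and E > e_escape for ``escape_frames``
    consecutive recorded frames) terminates the trajectory early.

    Returns (n_recorded, times, coms, quats, vels, omegas, W, ke_t, ke_r,
    reason).
    """
    G = body.shape[0]
    mtot = 0.0
    for i in range(G):
        mtot += masses[i]

    max_frames = n_steps // record_every + 1
    times = np.empty(max_frames)
    coms = np.empty((max_frames, 3))
    quats = np.empty((max_frames, 4))
    vels = np.empty((max_frames, 3))
    omegas = np.empty((max_frames, 3))
    W = np.empty(max_frames)
    ke_t_arr = np.empty(max_frames)
    ke_r_arr = np.empty(max_frames)

    q = q0.copy()
    c = c0.copy()
    v = v0.copy()
    w = w0.copy()
    R = np.empty((3, 3))
    coords = np.empty((G, 3))
    forces = np.empty((G, 3))
    out = np.empty(7)
    tau_b = np.empty(3)

    _eval_forces(body, host, A, B, C, D, QQ, HB, q, c, R, coords, forces, out)
    e = out[0]
    fnet = np.empty(3)
    fnet[0], fnet[1], fnet[2] = out[1], out[2], out[3]
    # torque converted to amu·Å²·rad/ps² once per evaluation
    tau_b[0] = out[4] * acc_conv
    tau_b[1] = out[5] * acc_conv
    tau_b[2] = out[6] * acc_conv

    reason = REASON_TIME
    nrec = 0
    esc_count = 0

    # frame 0
    times[0] = 0.0
    for a in range(3):
        coms[0, a] = c[a]
        vels[0, a] = v[a]
        omegas[0, a] = w[a]
    for a in range(4):
        quats[0, a] = q[a]
    W[0] = e
    ke_t_arr[0], ke_r_arr[0] = _kinetic(masses, mtot, Ib, v, w, acc_conv)
    nrec = 1

    half_dt = 0.5 * dt
    kick = half_dt * acc_conv / mtot

    for step in range(1, n_steps + 1):
        # first half kick: gyroscopic term explicit (one iteration); the
        # closing half kick is implicit, making the pair time-symmetric
        for a in range(3):
            v[a] += kick * fnet[a]
        _omega_halfkick(w, Ib, Ibinv, tau_b, half_dt, 1)
        # drift
        for a in range(3):
            c[a] += dt * v[a]
        _rotate_quat(q, w, dt)
        # new forces
        _eval_forces(body, host, A, B, C, D, QQ, HB, q, c, R, coords, forces, out)
        e = out[0]
        fnet[0], fnet[1], fnet[2] = out[1], out[2], out[3]
        tau_b[0] = out[4] * acc_conv
        tau_b[1] = out[5] * acc_conv
        tau_b[2] = out[6] * acc_conv
        if not (math.isfinite(e) and math.isfinite(fnet[0])) or e >= SINGULAR_ENERGY:
            reason = REASON_BLOWUP
            break
        # closing half kick (implicit in the end-point angular velocity)
        for a in range(3):
            v[a] += kick * fnet[a]
        _omega_halfkick(w, Ib, Ibinv, tau_b, half_dt, 6)
        # thermostat: exact kinetic-energy constraints
        if thermostat:
            ke_t, ke_r = _kinetic(masses, mtot, Ib, v, w, acc_conv)
            if ke_t > 0.0:
                s = math.sqrt(ke_target / ke_t)
                for a in range(3):
                    v[a] *= s
            if ke_r > 0.0:
                s = math.sqrt(ke_target / ke_r)
                for a in range(3):
                    w[a] *= s
        # record
        if step % record_every == 0:
            times[nrec] = step * dt
            for a in range(3):
                coms[nrec, a] = c[a]
                vels[nrec, a] = v[a]
                omegas[nrec, a] = w[a]
            for a in range(4):
                quats[nrec, a] = q[a]
            W[nrec] = e
            ke_t_arr[nrec], ke_r_arr[nrec] = _kinetic(masses, mtot, Ib, v, w, acc_conv)
            nrec += 1
            # escape rule
            cc = c[0] * c[0] + c[1] * c[1] + c[2] * c[2]
            if cc > resc2 and e > e_escape:
                esc_count += 1
                if esc_count >= escape_frames:
                    reason = REASON_ESCAPED
                    break
            else:
                esc_count = 0

    return (
        nrec,
        times[:nrec],
        coms[:nrec],
        quats[:nrec],
        vels[:nrec],
        omegas[:nrec],
        W[:nrec],
        ke_t_arr[:nrec],
        ke_r_arr[:nrec],
        reason,
    )


@njit(cache=True, inline="always")
def _kinetic(masses, mtot, Ib, v, w, acc_conv):
    ke_t = 0.5 * mtot * (v[0] * v[0] + v[1] * v[1] + v[2] * v[2]) / acc_conv
    lx = Ib[0, 0] * w[0] + Ib[0, 1] * w[1] + Ib[0, 2] * w[2]
    ly = Ib[1, 0] * w[0] + Ib[1, 1] * w[1] + Ib[1, 2] * w[2]
    lz = Ib[2, 0] * w[0] + Ib[2, 1] * w[1] + Ib[2, 2] * w[2]
    ke_r = 0.5 * (w[0] * lx + w[1] * ly + w[2] * lz) / acc_conv
    return ke_t, ke_r
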