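"""Rigid-body constant-temperature molecular dynamics.

Host and guest are rigid; only the guest moves, translating under the net
intermolecular force and rotating under the net torque about its COM.
Orientations are integrated as quaternions (body-frame angular velocity,
exponential-map update, renormalized every step), which avoids the
singularities of Euler-angle equations of motion.  Constant temperature is
imposed in the Brown-Clarke manner: the translational and rotational
kinetic energies are *separately* rescaled to exactly (3/2) k_B T after
every step.

Because both molecules are rigid, the intramolecular energy is an additive
constant along a trajectory; the recorded per-frame energy sample W_i is
therefore the intermolecular energy, and any constant offset cancels in
free-energy *differences* between enantiomers.

A trajectory ends either at the simulation time t_s or by the escape rule:
the guest COM farther than R_esc from the host COM while the interaction
energy is above a (weakly attractive) threshold, sustained for a number of
consecutive recorded frames — the operational reading of "outside the
cavity, not attracted strongly enough to be included again".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import KB, KCAL_TO_AKMA
from .errors import ChiroscanError, DomainError
from .forcefield import (
    ForceFieldParams,
    PairTable,
    SolventSpec,
    intermolecular_energy,
)
from .rigid import (
    Disposition,
    apply_disposition,
    center_of_mass,
    inertia_tensor,
    inverse_3x3,
    quaternion_to_matrix,
)
from .structure import Structure

__all__ = [
    "MDConfig",
    "RigidBodyState",
    "Trajectory",
    "sample_initial_velocities",
    "mirror_velocities",
    "rim_start_dispositions",
    "select_initial_dispositions",
    "leapfrog_step",
    "run_trajectory",
]


@dataclass(frozen=True)
class MDConfig:
    """Integration parameters.

    Defaults: 1 fs step, 293 K, recording
    every 100 steps — but with a desk-scale simulation time of 50 ps
    (the full 5 ns is a matter of setting ``t_s=5000``).
    """

    dt: float = 0.001  # ps
    t_s: float = 50.0  # ps
    record_every: int = 100
    temperature: float = 293.0  # K
    seed: int = 0
    thermostat: bool = True
    r_escape: float = 15.0  # Å
    escape_energy: float = -0.5  # kcal/mol
    escape_frames: int = 10

    def __post_init__(self):
        if self.dt <= 0:
            raise DomainError("dt must be > 0")
        if self.record_every < 1:
            raise DomainError("record_every must be >= 1")
        if self.temperature <= 0:
            raise DomainError("temperature must be > 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_s / self.dt))

    @property
    def frame_spacing(self) -> float:
        return self.dt * self.record_every


@dataclass
class RigidBodyState:
    """Instantaneous rigid-body state of the guest.

    ``omega`` is the body-frame angular velocity; ``inertia`` the full
    body-frame inertia tensor (kept un-diagonalized so mirror-image guests
    carry exactly sign-patterned tensors).
    """

    disposition: Disposition
    velocity: np.ndarray  # Å/ps
    omega: np.ndarray  # rad/ps, body frame
    inertia: np.ndarray  # amu·Å², body frame

    def kinetic_energies(self, mass: float) -> tuple[float, float]:
        """(translational, rotational) kinetic energy in kcal/mol."""
        ke_t = 0.5 * mass * float(self.velocity @ self.velocity) / KCAL_TO_AKMA
        ke_r = 0.5 * float(self.omega @ self.inertia @ self.omega) / KCAL_TO_AKMA
        return ke_t, ke_r


_REASONS = {
    _kernels.REASON_TIME: "time-exhausted",
    _kernels.REASON_ESCAPED: "escaped",
}


@dataclass
class Trajectory:
    """Recorded frames of one trajectory (arrays indexed by frame).

    ``W`` holds the per-frame intermolecular energy samples W_i that enter
    the binding free energy.  ``body_coords`` are the guest atom positions
    relative to its COM, so frame coordinates can be reconstructed as
    R(q_k) body + com_k.
    """

    times: np.ndarray
    coms: np.ndarray
    quaternions: np.ndarray
    velocities: np.ndarray
    omegas: np.ndarray
    W: np.ndarray
    ke_trans: np.ndarray
    ke_rot: np.ndarray
    termination: str
    initial: Disposition
    frame_spacing: float
    body_coords: np.ndarray
    inertia: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def guest_coords(self, k: int) -> np.ndarray:
        rot = quaternion_to_matrix(self.quaternions[k])
        return self.body_coords @ rot.T + self.coms[k]

    def frame(self, k: int) -> RigidBodyState:
        return RigidBodyState(
            disposition=Disposition(com=self.coms[k], quaternion=self.quaternions[k]),
            velocity=self.velocities[k],
            omega=self.omegas[k],
            inertia=self.inertia,
        )


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def sample_initial_velocities(
    temperature: float,
    mass: float,
    inertia: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random directions, exact kinetic-energy magnitudes.

    Speeds are fixed so the translational and rotational kinetic energies
    each equal (3/2) k_B T exactly (the thermostat would constrain them
    there anyway); only the directions are random, drawn uniformly on the
    sphere from the seeded generator.  Axes with (numerically) zero inertia
    are excluded and the rotational target scaled to the active axes.
    """
    if temperature <= 0:
        raise DomainError("temperature must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kt = KB * temperature

    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    v = u * np.sqrt(3.0 * kt * KCAL_TO_AKMA / mass)

    inertia = np.asarray(inertia, dtype=float)
    moments, axes = np.linalg.eigh(inertia)
    active = moments > 1e-9 * max(moments.max(), 1.0)
    n_active = int(active.sum())
    if n_active == 0:
        return v, np.zeros(3)
    d = rng.normal(size=3)
    d = axes @ (active * (axes.T @ d))  # project onto active principal axes
    d /= np.linalg.norm(d)
    quad = float(d @ inertia @ d)
    omega = d * np.sqrt(n_active * kt * KCAL_TO_AKMA / quad)
    return v, omega


def mirror_velocities(
    v: np.ndarray, omega: np.ndarray, plane: str = "xz"
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror-image initial velocities for the enantiomer partner.

    The linear velocity transforms as a vector (one component negated);
    the body-frame angular velocity of the mirrored body transforms as a
    pseudovector (the *other two* components negated).
    """
    idx = {"xy": 2, "xz": 1, "yz": 0}[plane]
    v2 = np.array(v, dtype=float)
    v2[idx] = -v2[idx]
    w2 = -np.array(omega, dtype=float)
    w2[idx] = -w2[idx]
    return v2, w2


def rim_start_dispositions(
    n_per_rim: int,
    z_offset: float,
    orientations: "np.ndarray | None" = None,
    seed: int = 0,
) -> list[Disposition]:
    """Starting dispositions in front of both rims of the host.

    ``n_per_rim`` slots per rim at z = ±z_offset on the cavity axis, cycled
    through a pool of orientations (by default a small set covering
    "parallel to the rim" and "one side chain pointing towards the cavity":
    identity plus 90° tilts about x and y and a 180° flip), azimuthally
    randomized about Z from the seed so slots differ.
    """
    from .rigid import euler_to_quaternion, quaternion_multiply

    rng = np.random.default_rng(seed)
    if orientations is None:
        orientations = np.stack(
            [
                euler_to_quaternion(0.0, 0.0, 0.0),
                euler_to_quaternion(0.0, np.pi / 2, 0.0),
                euler_to_quaternion(np.pi / 2, np.pi / 2, 0.0),
                euler_to_quaternion(0.0, np.pi, 0.0),
            ]
        )
    out = []
    for sign in (+1.0, -1.0):
        for k in range(n_per_rim):
            base = orientations[k % len(orientations)]
            spin = euler_to_quaternion(rng.uniform(0.0, 2.0 * np.pi), 0.0, 0.0)
            q = quaternion_multiply(spin, base)
            out.append(Disposition(com=np.array([0.0, 0.0, sign * z_offset]), quaternion=q))
    return out


@dataclass
class InitialPair:
    """A matched (L, D) starting disposition with its pairing metrics."""

    d_l: Disposition
    d_d: Disposition
    mean_atomic_distance: float  # Å
    energy_difference: float  # kcal/mol


def select_initial_dispositions(
    host: Structure,
    guest_l: Structure,
    guest_d: Structure,
    ff: ForceFieldParams,
    solvent: SolventSpec,
    candidates: list[Disposition],
    orientation_pool: np.ndarray | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
) -> list[InitialPair]:
    """Pair each L starting disposition with the best D disposition.

    For every candidate L disposition, the D orientation (same COM, from
    ``orientation_pool``; by default the mirrored L orientation plus a
    10x10x10 Euler grid) minimizing

        weights[0] * mean_i |r_i(L) - r_i(D)|  +  weights[1] * |E_L - E_D|

    is selected — simultaneously matching the initial geometries and the
    initial host interaction energies of the two enantiomers.
    """
    if not candidates:
        raise DomainError("candidate disposition set is empty")
    if orientation_pool is None:
        from .scan import generate_orientations

        orientation_pool = generate_orientations(10, 10, 10).quaternions
    out = []
    for d_l in candidates:
        placed_l = apply_disposition(guest_l, d_l)
        e_l = intermolecular_energy(host, placed_l, ff, solvent).e_inter
        pool = np.vstack([d_l.mirrored("xz").quaternion[None, :], orientation_pool])
        best = None
        for q in pool:
            d_d = Disposition(com=d_l.com.copy(), quaternion=q / np.linalg.norm(q))
            placed_d = apply_disposition(guest_d, d_d)
            dist = float(
                np.mean(np.linalg.norm(placed_l.coords - placed_d.coords, axis=1))
            )
            de = abs(
                e_l - intermolecular_energy(host, placed_d, ff, solvent).e_inter
            )
            score = weights[0] * dist + weights[1] * de
            if best is None or score < best[0]:
                best = (score, d_d, dist, de)
        out.append(InitialPair(d_l=d_l, d_d=best[1], mean_atomic_distance=best[2], energy_difference=best[3]))
    return out


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def leapfrog_step(
    state: RigidBodyState,
    force_torque,
    mass: float,
    dt: float,
    thermostat: bool = False,
    temperature: float = 293.0,
) -> RigidBodyState:
    """One velocity-Verlet-form leap-frog step (pure-Python reference).

    ``force_torque(com, quaternion) -> (force, space_torque)`` in
    kcal/mol/Å and kcal/mol·rad.  With ``thermostat`` on, translational and
    rotational velocities are rescaled after the step so each kinetic
    energy equals (3/2) k_B T exactly.  The numba production path
    (:func:`run_trajectory`) implements the identical scheme.
    """
    from .rigid import quaternion_from_axis_angle, quaternion_multiply

    inertia = state.inertia
    inertia_inv = inverse_3x3(inertia)
    c = np.array(state.disposition.com)
    q = np.array(state.disposition.quaternion)
    v = np.array(state.velocity)
    w = np.array(state.omega)

    def omega_halfkick(w, tau_b, n_iter):
        # fixed-point solve of w' = w + h I^-1 (tau - w' x I w'); one
        # iteration = explicit evaluation at w (opening kick), several =
        # implicit end-point evaluation (closing kick)
        w_new = w.copy()
        for _ in range(n_iter):
            gyro = np.cross(w_new, inertia @ w_new)
            w_new = w + 0.5 * dt * (inertia_inv @ (tau_b * KCAL_TO_AKMA - gyro))
        return w_new

    f, tau_s = force_torque(c, q)
    if not np.all(np.isfinite(f)):
        raise ChiroscanError("non-finite force")
    rot = quaternion_to_matrix(q)
    v = v + 0.5 * dt * np.asarray(f) * KCAL_TO_AKMA / mass
    w = omega_halfkick(w, rot.T @ np.asarray(tau_s), 1)
    c = c + dt * v
    wn = np.linalg.norm(w)
    q = quaternion_multiply(q, quaternion_from_axis_angle(w, wn * dt) if wn > 0 else np.array([1.0, 0, 0, 0]))
    q = q / np.linalg.norm(q)
    f, tau_s = force_torque(c, q)
    rot = quaternion_to_matrix(q)
    v = v + 0.5 * dt * np.asarray(f) * KCAL_TO_AKMA / mass
    w = omega_halfkick(w, rot.T @ np.asarray(tau_s), 6)

    if thermostat:
        target = 1.5 * KB * temperature
        ke_t = 0.5 * mass * float(v @ v) / KCAL_TO_AKMA
        ke_r = 0.5 * float(w @ inertia @ w) / KCAL_TO_AKMA
        if ke_t > 0:
            v = v * np.sqrt(target / ke_t)
        if ke_r > 0:
            w = w * np.sqrt(target / ke_r)

    return RigidBodyState(
        disposition=Disposition(com=c, quaternion=q),
        velocity=v,
        omega=w,
        inertia=inertia,
    )


def run_trajectory(
    host: Structure,
    guest: Structure,
    ff: ForceFieldParams,
    solvent: SolventSpec,
    d0: Disposition,
    cfg: MDConfig,
    v0: np.ndarray | None = None,
    w0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate one trajectory from disposition ``d0``.

    Initial velocities are sampled from ``cfg.seed`` unless given
    explicitly (mirror-image runs pass the mirrored velocities of their
    partner).  Identical inputs and seed give a bit-identical trajectory.
    """
    table = PairTable.build(host, guest, ff, solvent)
    body = guest.coords - center_of_mass(guest)
    inertia = inertia_tensor(guest)
    try:
        inertia_inv = inverse_3x3(inertia)
    except DomainError:
        # point mass / degenerate body: no rotational response
        inertia_inv = np.zeros((3, 3))
    if v0 is None or w0 is None:
        v_s, w_s = sample_initial_velocities(
            cfg.temperature, float(guest.masses.sum()), inertia, cfg.seed
        )
        v0 = v_s if v0 is None else v0
        w0 = w_s if w0 is None else w0

    (nrec, times, coms, quats, vels, omegas, W, ke_t, ke_r, reason) = _kernels.md_kernel(
        np.ascontiguousarray(body),
        guest.masses,
        inertia,
        inertia_inv,
        np.ascontiguousarray(host.coords),
        table.A,
        table.B,
        table.C,
        table.D,
        table.qq,
        table.hb.astype(np.uint8),
        np.asarray(d0.quaternion, dtype=float),
        np.asarray(d0.com, dtype=float),
        np.asarray(v0, dtype=float),
        np.asarray(w0, dtype=float),
        cfg.dt,
        cfg.n_steps,
        cfg.record_every,
        cfg.thermostat,
        1.5 * KB * cfg.temperature,
        KCAL_TO_AKMA,
        cfg.r_escape**2,
        cfg.escape_energy,
        cfg.escape_frames,
    )
    if reason == _kernels.REASON_BLOWUP:
        raise ChiroscanError(
            f"numerical blow-up after {nrec} recorded frames "
            f"(last COM {coms[-1]}, last W {W[-1]})"
        )
    return Trajectory(
        times=times,
        coms=coms,
        quaternions=quats,
        velocities=vels,
        omegas=omegas,
        W=W,
        ke_trans=ke_t,
        ke_rot=ke_r,
        termination=_REASONS[reason],
        initial=d0,
        frame_spacing=cfg.frame_spacing,
        body_coords=body,
        inertia=inertia,
    )
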