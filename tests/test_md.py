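"""MD engine: velocity initialization, the leap-frog integrator and its
conservation laws, the kinetic-energy-constraint thermostat, trajectory
bookkeeping and the escape rule."""

import numpy as np
import pytest
from scipy.stats import chisquare

import chiroscan as cs
from chiroscan.constants import KB, KCAL_TO_AKMA
from chiroscan.errors import DomainError
from chiroscan.md import (
    RigidBodyState,
    leapfrog_step,
    mirror_velocities,
    rim_start_dispositions,
    sample_initial_velocities,
    select_initial_dispositions,
)
from chiroscan.rigid import inertia_tensor
from chiroscan.structure import AtomRecord, Structure

from conftest import single_atom, toy_pair_ff


@pytest.fixture(scope="module")
def system(host, guest_pair, ff, solv):
    gl, gd = guest_pair
    return host, gl, gd, ff, solv


def _ke(v, w, mass, inertia):
    ke_t = 0.5 * mass * float(v @ v) / KCAL_TO_AKMA
    ke_r = 0.5 * float(w @ inertia @ w) / KCAL_TO_AKMA
    return ke_t, ke_r


# ---------------------------------------------------------------------------
# initial velocities
# ---------------------------------------------------------------------------

def test_initial_velocities_exact_kinetic_energy(guest_pair):
    gl, _ = guest_pair
    inertia = inertia_tensor(gl)
    mass = float(gl.masses.sum())
    v, w = sample_initial_velocities(293.0, mass, inertia, seed=5)
    ke_t, ke_r = _ke(v, w, mass, inertia)
    target = 1.5 * KB * 293.0
    assert ke_t == pytest.approx(target, abs=1e-12)
    assert ke_r == pytest.approx(target, abs=1e-12)


def test_initial_velocities_deterministic(guest_pair):
    gl, _ = guest_pair
    inertia = inertia_tensor(gl)
    a = sample_initial_velocities(293.0, 100.0, inertia, seed=42)
    b = sample_initial_velocities(293.0, 100.0, inertia, seed=42)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_initial_velocity_directions_uniform_over_octants(guest_pair):
    gl, _ = guest_pair
    inertia = inertia_tensor(gl)
    rng = np.random.default_rng(0)
    dirs = np.array(
        [sample_initial_velocities(293.0, 100.0, inertia, rng)[0] for _ in range(10000)]
    )
    octant = (
        (dirs[:, 0] > 0).astype(int) * 4
        + (dirs[:, 1] > 0).astype(int) * 2
        + (dirs[:, 2] > 0).astype(int)
    )
    counts = np.bincount(octant, minlength=8)
    assert chisquare(counts).pvalue > 0.01


def test_initial_velocities_linear_molecule_excludes_dead_axis():
    # two masses on the x axis: zero moment about x
    s = Structure(
        atoms=[AtomRecord(id=i, element="C", mass=12.0, lj_type="X") for i in range(2)],
        coords=np.array([[1.0, 0, 0], [-1.0, 0, 0]]),
    )
    inertia = inertia_tensor(s)
    v, w = sample_initial_velocities(293.0, 24.0, inertia, seed=8)
    # no spin about the dead axis; rotational KE scaled to 2 active axes
    assert abs(w[0]) < 1e-9
    ke_r = 0.5 * float(w @ inertia @ w) / KCAL_TO_AKMA
    assert ke_r == pytest.approx(KB * 293.0, abs=1e-12)  # (2/2) k_B T


def test_mirror_velocities_transform():
    v, w = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
    v2, w2 = mirror_velocities(v, w, "xz")
    assert np.array_equal(v2, [1.0, -2.0, 3.0])  # polar vector
    assert np.array_equal(w2, [-4.0, 5.0, -6.0])  # pseudovector


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def test_leapfrog_free_motion_is_uniform(guest_pair):
    gl, _ = guest_pair
    inertia = inertia_tensor(gl)
    mass = float(gl.masses.sum())
    state = RigidBodyState(
        disposition=cs.Disposition(com=[0.0, 0.0, 0.0]),
        velocity=np.array([1.0, -0.5, 0.25]),
        omega=np.array([0.0, 0.0, 2.0]),  # spin about a principal-ish axis
        inertia=np.diag(np.diag(inertia)),
    )
    zero = lambda c, q: (np.zeros(3), np.zeros(3))
    dt = 0.01
    for k in range(100):
        state = leapfrog_step(state, zero, mass, dt)
    assert np.allclose(state.disposition.com, [1.0, -0.5, 0.25], atol=1e-10)
    assert np.allclose(state.velocity, [1.0, -0.5, 0.25], atol=1e-14)
    # constant quaternion rate: rotation angle = |omega| * t about z
    a, b, g = state.disposition.euler
    assert b == pytest.approx(0.0, abs=1e-9)
    assert (a + g) % (2 * np.pi) == pytest.approx(2.0 * 1.0 % (2 * np.pi), abs=1e-8)


def test_kernel_matches_python_leapfrog(system):
    host, gl, _, ff, solv = system
    d0 = cs.Disposition(com=[0.2, 0.1, 1.5])
    v0 = np.array([0.4, -0.2, 0.1])
    w0 = np.array([0.5, 1.0, -0.3])
    cfg = cs.MDConfig(t_s=0.005, dt=0.001, record_every=1, thermostat=False)
    traj = cs.run_trajectory(host, gl, ff, solv, d0, cfg, v0=v0, w0=w0)

    from chiroscan.forcefield import PairTable
    table = PairTable.build(host, gl, ff, solv)
    body = gl.coords - cs.center_of_mass(gl)

    def force_torque(com, quat):
        placed = gl.with_coords(body @ cs.quaternion_to_matrix(quat).T + com)
        return cs.forces_and_torques(host, placed, ff, solv)

    state = RigidBodyState(
        disposition=d0, velocity=v0.copy(), omega=w0.copy(), inertia=inertia_tensor(gl)
    )
    mass = float(gl.masses.sum())
    for k in range(1, traj.n_frames):
        state = leapfrog_step(state, force_torque, mass, cfg.dt)
        assert np.allclose(state.disposition.com, traj.coms[k], atol=1e-10)
        assert np.allclose(state.velocity, traj.velocities[k], atol=1e-10)
        assert np.allclose(state.omega, traj.omegas[k], atol=1e-10)


def test_thermostat_constrains_kinetic_energies_every_frame(system):
    host, gl, _, ff, solv = system
    for temp in (293.0, 350.0):
        cfg = cs.MDConfig(t_s=2.0, temperature=temp, thermostat=True, seed=1)
        traj = cs.run_trajectory(host, gl, ff, solv, cs.Disposition(com=[0, 0, 1.0]), cfg)
        target = 1.5 * KB * temp
        assert np.abs(traj.ke_trans - target).max() < 1e-10
        assert np.abs(traj.ke_rot - target).max() < 1e-10


def test_nve_energy_conservation_short(system):
    host, gl, _, ff, solv = system
    cfg = cs.MDConfig(t_s=5.0, thermostat=False, r_escape=1e6, seed=2)
    traj = cs.run_trajectory(host, gl, ff, solv, cs.Disposition(com=[0, 0, 1.0]), cfg)
    etot = traj.W + traj.ke_trans + traj.ke_rot
    ke0 = traj.ke_trans[0] + traj.ke_rot[0]
    assert np.abs(etot - etot[0]).max() < 1e-3 * ke0


def test_torque_free_angular_momentum_conserved(guest_pair):
    # asymmetric rotor in a null interaction field: space-frame L constant
    gl, _ = guest_pair
    null_host = single_atom(500.0, 0, 0)
    ffp = toy_pair_ff(A=0.0, B=0.0)
    host_like = null_host
    gl0 = gl.with_charges(np.zeros(gl.n_atoms))
    # retype every guest atom to the null pair type
    from dataclasses import replace
    gl0.atoms = [replace(a, lj_type="X", hbond_role="none") for a in gl0.atoms]
    cfg = cs.MDConfig(t_s=10.0, thermostat=False, r_escape=1e6, record_every=100)
    w0 = np.array([1.3, -0.8, 2.1])
    traj = cs.run_trajectory(
        host_like, gl0, ffp, cs.SolventSpec(1.0, "NP"),
        cs.Disposition(com=[0, 0, 0]), cfg, v0=np.zeros(3), w0=w0,
    )
    inertia = traj.inertia
    L = np.array(
        [
            cs.quaternion_to_matrix(traj.quaternions[k]) @ (inertia @ traj.omegas[k])
            for k in range(traj.n_frames)
        ]
    )
    rel = np.abs(L - L[0]).max() / np.linalg.norm(L[0])
    assert rel < 1e-6


def test_time_reversal_returns_to_start(system):
    host, gl, _, ff, solv = system
    cfg = cs.MDConfig(t_s=0.1, record_every=1, thermostat=False, r_escape=1e6)
    v0, w0 = sample_initial_velocities(293.0, float(gl.masses.sum()), inertia_tensor(gl), 7)
    fwd = cs.run_trajectory(host, gl, ff, solv, cs.Disposition(com=[0, 0, 1.0]), cfg, v0=v0, w0=w0)
    end = fwd.frame(-1)
    back = cs.run_trajectory(
        host, gl, ff, solv, end.disposition, cfg, v0=-end.velocity, w0=-end.omega
    )
    assert np.abs(back.coms[-1] - fwd.coms[0]).max() < 1e-6


# ---------------------------------------------------------------------------
# trajectory bookkeeping
# ---------------------------------------------------------------------------

def test_frame_count_and_spacing(system):
    host, gl, _, ff, solv = system
    cfg = cs.MDConfig(t_s=10 * 0.001 * 100, dt=0.001, record_every=100, r_escape=1e6)
    traj = cs.run_trajectory(host, gl, ff, solv, cs.Disposition(com=[0, 0, 1.0]), cfg)
    assert traj.n_frames == 11  # includes t = 0
    assert np.allclose(np.diff(traj.times), cfg.frame_spacing, atol=1e-12)


def test_same_seed_bit_identical_trajectory(system):
    host, gl, _, ff, solv = system
    cfg = cs.MDConfig(t_s=1.0, seed=13)
    t1 = cs.run_trajectory(host, gl, ff, solv, cs.Disposition(com=[0, 0, 1.0]), cfg)
    t2 = cs.run_trajectory(host, gl, ff, solv, cs.Disposition(com=[0, 0, 1.0]), cfg)
    assert np.array_equal(t1.coms, t2.coms)
    assert np.array_equal(t1.W, t2.W)


def test_escape_rule_terminates_unbound_guest():
    # purely repulsive host; guest launched outward from beyond the escape radius
    h = single_atom(0, 0, 0)
    g = single_atom(0, 0, 0, mass=12.0)
    ffp = toy_pair_ff(A=4096.0, B=0.0)
    cfg = cs.MDConfig(t_s=20.0, r_escape=10.0, escape_frames=3, thermostat=False)
    traj = cs.run_trajectory(
        h, g, ffp, cs.SolventSpec(1.0, "NP"),
        cs.Disposition(com=[12.0, 0, 0]), cfg, v0=np.array([1.0, 0, 0]), w0=np.zeros(3),
    )
    assert traj.termination == "escaped"
    assert traj.times[-1] < cfg.t_s


def test_mdconfig_validation():
    with pytest.raises(DomainError):
        cs.MDConfig(dt=0.0)
    with pytest.raises(DomainError):
        cs.MDConfig(record_every=0)


# ---------------------------------------------------------------------------
# initial dispositions
# ---------------------------------------------------------------------------

def test_rim_starts_cover_both_rims():
    starts = rim_start_dispositions(n_per_rim=5, z_offset=5.0, seed=0)
    zs = np.array([d.com[2] for d in starts])
    assert (zs > 0).sum() == 5 and (zs < 0).sum() == 5


def test_select_initial_dispositions_metrics(system):
    host, gl, gd, ff, solv = system
    starts = rim_start_dispositions(n_per_rim=1, z_offset=5.0, seed=0)
    pool = cs.generate_orientations(5, 4, 5).quaternions
    pairs = select_initial_dispositions(host, gl, gd, ff, solv, starts, orientation_pool=pool)
    assert len(pairs) == len(starts)
    for p in pairs:
        assert p.mean_atomic_distance >= 0.0
        assert p.energy_difference >= 0.0
    # brute-force oracle: no pool member scores lower than the returned one
    p = pairs[0]
    placed_l = cs.apply_disposition(gl, p.d_l)
    e_l = cs.intermolecular_energy(host, placed_l, ff, solv).e_inter
    best = p.mean_atomic_distance + p.energy_difference
    for q in pool:
        d_d = cs.Disposition(com=p.d_l.com, quaternion=q / np.linalg.norm(q))
        placed_d = cs.apply_disposition(gd, d_d)
        dist = float(np.mean(np.linalg.norm(placed_l.coords - placed_d.coords, axis=1)))
        de = abs(e_l - cs.intermolecular_energy(host, placed_d, ff, solv).e_inter)
        assert dist + de >= best - 1e-9


def test_select_initial_dispositions_achiral_guest_scores_zero(host, ff, solv):
    # a planar (y = 0) "guest" is its own mirror image: the matched D
    # disposition reproduces the L configuration exactly
    planar = Structure(
        atoms=[
            AtomRecord(id=i, element="C", mass=12.0, lj_type="CT") for i in range(3)
        ],
        coords=np.array([[0.0, 0, 0], [1.5, 0, 0], [0.0, 0, 1.5]]),
    )
    mirrored = cs.mirror_structure(planar, "xz")
    starts = [cs.Disposition(com=[0.0, 0.0, 5.0])]
    pairs = select_initial_dispositions(host, planar, mirrored, ff, solv, starts)
    assert pairs[0].mean_atomic_distance == pytest.approx(0.0, abs=1e-9)
    assert pairs[0].energy_difference == pytest.approx(0.0, abs=1e-9)


def test_select_initial_dispositions_empty_candidates_raises(system):
    host, gl, gd, ff, solv = system
    with pytest.raises(DomainError):
        select_initial_dispositions(host, gl, gd, ff, solv, [])
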