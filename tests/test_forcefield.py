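"""Energy-model unit tests: elementary pair terms against closed-form
values, assembled energies against brute-force pair enumeration, and the
analytic gradient against central finite differences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chiroscan as cs
from chiroscan.errors import DomainError, ParameterizationError, SingularityError
from chiroscan.forcefield import PairTable
from chiroscan.structure import AtomRecord, Structure

from conftest import single_atom, toy_pair_ff

KAPPA = 332.0522


@pytest.mark.parametrize(
    "A,B,R,expected",
    [
        (4096.0, 1.0, 4.0, 0.0),  # zero at R^6 = A/B
        (4096.0, 1.0, 2.0, 0.984375),
        (0.0, 0.0, 3.0, 0.0),
    ],
)
def test_lj_pair_energy_closed_form(A, B, R, expected):
    assert cs.lj_pair_energy(A, B, R) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "q1,q2,R,eps,expected",
    [
        (0.0, 1.0, 2.0, 1.0, 0.0),
        (1.0, 1.0, 1.0, 1.0, KAPPA),
        (1.0, -1.0, 2.0, 2.0, -KAPPA / 4.0),  # = -83.01305
    ],
)
def test_coulomb_pair_energy_closed_form(q1, q2, R, eps, expected):
    assert cs.coulomb_pair_energy(q1, q2, R, eps, KAPPA) == pytest.approx(
        expected, abs=1e-12
    )


@pytest.mark.parametrize(
    "C,D,R,expected",
    [
        (5.0, 2.0, np.sqrt(2.5), 0.0),  # zero at R^2 = C/D
        (0.0, 0.0, 2.0, 0.0),
        (7557.0, 2385.0, 2.0, 7557.0 / 4096.0 - 2385.0 / 1024.0),  # ~ -0.484, an
        # H-bond-well magnitude of about -0.5 kcal/mol
    ],
)
def test_hbond_pair_energy_closed_form(C, D, R, expected):
    assert cs.hbond_pair_energy(C, D, R) == pytest.approx(expected, abs=1e-12)


def test_bonded_terms_closed_form():
    assert cs.angle_energy(50.0, 1.2, 1.2) == 0.0
    assert cs.bond_energy(300.0, 1.6, 1.5) == pytest.approx(3.0, abs=1e-12)
    assert cs.angle_energy(50.0, 1.3, 1.2) == pytest.approx(0.5, abs=1e-12)


@pytest.mark.parametrize(
    "terms,phi,expected",
    [
        ([(2.0, 1, 0.0)], np.pi, 0.0),
        ([(2.0, 1, 0.0)], 0.0, 2.0),
        ([(2.0, 3, np.pi)], np.pi / 3.0, 2.0),
    ],
)
def test_torsion_energy_closed_form(terms, phi, expected):
    assert cs.torsion_energy(terms, phi) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad_r", [0.0, -1.0])
def test_pair_terms_reject_nonpositive_distance(bad_r):
    with pytest.raises(DomainError):
        cs.lj_pair_energy(1.0, 1.0, bad_r)
    with pytest.raises(DomainError):
        cs.coulomb_pair_energy(1.0, 1.0, bad_r)
    with pytest.raises(DomainError):
        cs.hbond_pair_energy(1.0, 1.0, bad_r)


def test_coulomb_rejects_epsilon_below_one():
    with pytest.raises(DomainError):
        cs.coulomb_pair_energy(1.0, 1.0, 1.0, epsilon=0.5)


@settings(derandomize=True, max_examples=50)
@given(
    v=st.floats(0.1, 10.0),
    n=st.integers(1, 6),
    gamma=st.sampled_from([0.0, np.pi]),
    phi=st.floats(-np.pi, np.pi),
)
def test_torsion_energy_bounds_and_periodicity(v, n, gamma, phi):
    e = cs.torsion_energy([(v, n, gamma)], phi)
    assert -1e-12 <= e <= v + 1e-12
    assert e == pytest.approx(
        cs.torsion_energy([(v, n, gamma)], phi + 2 * np.pi), abs=1e-9
    )


# ---------------------------------------------------------------------------
# assembled intermolecular / intramolecular energies
# ---------------------------------------------------------------------------

def test_intermolecular_single_pair_equals_lj():
    h = single_atom(0, 0, 0)
    g = single_atom(2.0, 0, 0)
    e = cs.intermolecular_energy(h, g, toy_pair_ff())
    assert e.e_inter == pytest.approx(cs.lj_pair_energy(4096.0, 1.0, 2.0), abs=1e-12)
    assert e.e_ele == 0.0 and e.e_hbond == 0.0


def test_intermolecular_symmetric_host_doubles_single_pair():
    g = single_atom(0, 0, 0)
    h = Structure(
        atoms=[
            AtomRecord(id=0, element="C", mass=12.0, lj_type="X"),
            AtomRecord(id=1, element="C", mass=12.0, lj_type="X"),
        ],
        coords=np.array([[3.0, 0, 0], [-3.0, 0, 0]]),
    )
    e = cs.intermolecular_energy(h, g, toy_pair_ff())
    assert e.e_inter == pytest.approx(2 * cs.lj_pair_energy(4096.0, 1.0, 3.0), rel=1e-12)


def test_intermolecular_host_guest_swap_invariance(host, guest_pair, ff, solv):
    gl, _ = guest_pair
    e1 = cs.intermolecular_energy(host, gl, ff, solv)
    e2 = cs.intermolecular_energy(gl, host, ff, solv)
    assert e1.e_inter == pytest.approx(e2.e_inter, rel=1e-12)
    assert e1.e_hbond == pytest.approx(e2.e_hbond, rel=1e-12)


def test_hbond_pairs_replace_lj_term():
    h = single_atom(0, 0, 0, role="acceptor")
    g = single_atom(2.0, 0, 0, role="donor-H")
    ffp = toy_pair_ff(C=10240.0, D=3072.0)
    e = cs.intermolecular_energy(h, g, ffp)
    assert e.e_lj == 0.0
    assert e.e_hbond == pytest.approx(cs.hbond_pair_energy(10240.0, 3072.0, 2.0), abs=1e-12)


def test_coincident_atoms_raise_singularity():
    h = single_atom(0, 0, 0)
    g = single_atom(0, 0, 0)
    with pytest.raises(SingularityError):
        cs.intermolecular_energy(h, g, toy_pair_ff())


def test_unresolvable_pair_type_raises():
    h = single_atom(0, 0, 0, lj_type="ZZ")
    g = single_atom(2.0, 0, 0)
    with pytest.raises(ParameterizationError):
        cs.intermolecular_energy(h, g, toy_pair_ff())


def test_intramolecular_equilibrium_geometry_is_zero():
    ffp = cs.ForceFieldParams(bonds={"X-X": (300.0, 1.5)}, angles={}, torsions={})
    s = Structure(
        atoms=[
            AtomRecord(id=i, element="C", mass=12.0, lj_type="X") for i in range(2)
        ],
        coords=np.array([[0.0, 0, 0], [1.5, 0, 0]]),
        bonds=[(0, 1, "X-X")],
    )
    assert cs.intramolecular_energy(s, ffp).e_intra == 0.0
    # stretched by 0.1 Å
    s2 = s.with_coords(np.array([[0.0, 0, 0], [1.6, 0, 0]]))
    e = cs.intramolecular_energy(s2, ffp)
    assert e.e_bond == pytest.approx(3.0, abs=1e-10)
    assert e.e_torsion == 0.0  # empty torsion list


def test_intramolecular_missing_parameter_raises(guest_pair):
    gl, _ = guest_pair
    with pytest.raises(ParameterizationError):
        cs.intramolecular_energy(gl, cs.ForceFieldParams())


def test_total_energy_separates_at_large_distance(host, guest_pair, ff, solv):
    gl, _ = guest_pair
    far = cs.apply_disposition(gl, cs.Disposition(com=[0.0, 0.0, 2000.0]))
    e = cs.total_energy(host, far, ff, solv)
    e_intra = (
        cs.intramolecular_energy(host, ff).e_intra
        + cs.intramolecular_energy(far, ff).e_intra
    )
    assert e.e_total == pytest.approx(e_intra, abs=1e-6)


def test_total_energy_term_additivity(host, guest_pair, ff, solv):
    gl, _ = guest_pair
    placed = cs.apply_disposition(
        gl, cs.Disposition.from_euler([0.5, -0.3, 1.2], 0.3, 0.9, 2.0)
    )
    tot = cs.total_energy(host, placed, ff, solv)
    inter = cs.intermolecular_energy(host, placed, ff, solv)
    intra = cs.intramolecular_energy(host, ff) + cs.intramolecular_energy(placed, ff)
    assert tot.e_total == pytest.approx(inter.e_inter + intra.e_intra, rel=1e-12)
    assert tot.e_inter == pytest.approx(
        tot.e_lj + tot.e_ele + tot.e_hbond, rel=1e-12
    )


def test_electrostatic_magnitude_nonincreasing_in_epsilon(host, guest_pair, ff):
    gl, _ = guest_pair
    placed = cs.apply_disposition(gl, cs.Disposition(com=[0.0, 0.0, 1.0]))
    mags = [
        abs(
            cs.intermolecular_energy(
                host, placed, ff, cs.SolventSpec(epsilon=e, guest_variant="NP")
            ).e_ele
        )
        for e in (1.0, 2.0, 21.0, 80.0)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(mags, mags[1:]))


def test_energy_invariant_under_rigid_motion_of_complex(host, guest_pair, ff, solv):
    gl, _ = guest_pair
    placed = cs.apply_disposition(gl, cs.Disposition(com=[0.3, 0.1, 1.4]))
    e0 = cs.intermolecular_energy(host, placed, ff, solv)
    rot = cs.quaternion_to_matrix(cs.euler_to_quaternion(0.7, 0.4, 1.9))
    shift = np.array([3.0, -2.0, 5.0])
    h2 = host.with_coords(host.coords @ rot.T + shift)
    g2 = placed.with_coords(placed.coords @ rot.T + shift)
    e1 = cs.intermolecular_energy(h2, g2, ff, solv)
    for attr in ("e_lj", "e_ele", "e_hbond"):
        assert getattr(e0, attr) == pytest.approx(getattr(e1, attr), abs=1e-10)


# ---------------------------------------------------------------------------
# analytic forces and torques
# ---------------------------------------------------------------------------

def _fd_force_torque(host, placed, ff, solv, h=1e-5):
    """Central finite differences of E_inter wrt COM translation and
    rotation about the COM."""
    force = np.empty(3)
    torque = np.empty(3)
    com = cs.center_of_mass(placed)
    for ax in range(3):
        d = np.zeros(3)
        d[ax] = h
        ep = cs.intermolecular_energy(host, placed.with_coords(placed.coords + d), ff, solv).e_inter
        em = cs.intermolecular_energy(host, placed.with_coords(placed.coords - d), ff, solv).e_inter
        force[ax] = -(ep - em) / (2 * h)
        axis = np.zeros(3)
        axis[ax] = 1.0
        rp = cs.quaternion_to_matrix(cs.rigid.quaternion_from_axis_angle(axis, h))
        rm = cs.quaternion_to_matrix(cs.rigid.quaternion_from_axis_angle(axis, -h))
        cp = (placed.coords - com) @ rp.T + com
        cm = (placed.coords - com) @ rm.T + com
        ep = cs.intermolecular_energy(host, placed.with_coords(cp), ff, solv).e_inter
        em = cs.intermolecular_energy(host, placed.with_coords(cm), ff, solv).e_inter
        torque[ax] = -(ep - em) / (2 * h)
    return force, torque


def test_forces_match_finite_differences(host, guest_pair, ff, solv):
    gl, _ = guest_pair
    rng = np.random.default_rng(11)
    for _ in range(20):
        com = rng.uniform(-3, 3, 3)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        placed = cs.apply_disposition(gl, cs.Disposition(com=com, quaternion=q))
        f, tau = cs.forces_and_torques(host, placed, ff, solv)
        f_fd, tau_fd = _fd_force_torque(host, placed, ff, solv)
        scale = max(np.abs(np.concatenate([f, tau])).max(), 1.0)
        assert np.abs(f - f_fd).max() / scale < 1e-5
        assert np.abs(tau - tau_fd).max() / scale < 1e-5


def test_force_vanishes_at_lj_minimum_distance():
    # 1-atom host, guest at the 12-6 minimum R = (2A/B)^(1/6)
    A, B = 4096.0, 1.0
    r_min = (2 * A / B) ** (1.0 / 6.0)
    h = single_atom(0, 0, 0)
    g = single_atom(r_min, 0, 0)
    f, tau = cs.forces_and_torques(h, g, toy_pair_ff(A=A, B=B))
    assert np.abs(f).max() < 1e-8
    assert np.abs(tau).max() < 1e-8


def test_torque_transverse_components_vanish_on_symmetry_axis():
    # symmetric dimer host, single-atom guest on the axis
    h = Structure(
        atoms=[AtomRecord(id=i, element="C", mass=12.0, lj_type="X") for i in range(2)],
        coords=np.array([[0.0, 3.0, 0.0], [0.0, -3.0, 0.0]]),
    )
    g = single_atom(0.0, 0.0, 2.0)
    f, tau = cs.forces_and_torques(h, g, toy_pair_ff())
    assert abs(f[0]) < 1e-12 and abs(f[1]) < 1e-12
    assert np.abs(tau).max() < 1e-12


def test_pair_table_matches_python_energy(host, guest_pair, ff, solv):
    """The kernel-facing pair table reproduces the reference energy path."""
    gl, _ = guest_pair
    from chiroscan import _kernels

    placed = cs.apply_disposition(gl, cs.Disposition(com=[0.2, -0.4, 1.1]))
    table = PairTable.build(host, placed, ff, solv)
    forces = np.empty((placed.n_atoms, 3))
    e_kernel = _kernels.pair_energy_forces(
        np.ascontiguousarray(placed.coords),
        np.ascontiguousarray(host.coords),
        table.A, table.B, table.C, table.D, table.qq,
        table.hb.astype(np.uint8), forces,
    )
    e_py = cs.intermolecular_energy(host, placed, ff, solv).e_inter
    assert e_kernel == pytest.approx(e_py, rel=1e-12)
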