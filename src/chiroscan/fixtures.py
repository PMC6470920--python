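"""Synthetic fixtures: an achiral macrocyclic toy host, a chiral guest in
neutral (NP) and zwitterionic (P) variants, and a matching force field.

The toy host stands in for a cyclodextrin-like macrocycle: two stacked
rings of Lennard-Jones sites about the Z (cavity) axis, the lower ring
slightly narrower than the upper one (narrow/wide rims of a truncated
cone).  It is built *exactly* mirror-symmetric about the xz plane —
ring sites sit at angles ±theta with the -y coordinate written as the
exact negation of the +y one — and mirror-partner atoms are stored
adjacently, which the energy kernels exploit to make mirror-image energies
bitwise exact.  An optional chiral decoration (a counter-twisted
quadrupolar charge term, odd in theta and opposite on the two rings)
turns it into a discriminating host that cannot be superimposed on its
mirror image.

The guest is a single-stereocenter amino-acid-like molecule: a central
carbon bearing H, an amine group, a carboxyl group and a two-carbon alkyl
chain.  The D enantiomer is the exact xz-mirror of L.  NP and P variants
share the skeleton and differ in the partial charges and in the position
of one hydrogen (on the carboxyl oxygen in NP, transferred to the nitrogen
in the zwitterion), with group charges 0/0 (NP) and +1/-1 (P).

Everything is deterministic: identical inputs give bit-identical
structures regardless of the seed argument.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import DomainError
from .forcefield import ForceFieldParams
from .rigid import mirror_structure
from .scan import CavityDef
from .structure import AtomRecord, ELEMENT_MASSES, Structure

__all__ = [
    "make_toy_forcefield",
    "make_toy_host",
    "make_chiral_guest",
    "cavity_for_host",
    "best_superposition_rmsd",
]


def _lj(rm: float, eps: float) -> tuple[float, float]:
    """A, B of a 12-6 well with minimum at rm (Å) and depth eps (kcal/mol)."""
    return eps * rm**12, 2.0 * eps * rm**6


def make_toy_forcefield() -> ForceFieldParams:
    """Force-field parameters covering every typed pair/bond/angle/dihedral
    of the fixture host + guest.  Magnitudes follow common AMBER-scale
    values; the 12-10 well has its minimum at 2.0 Å with depth 0.5 kcal/mol
    (a typical H-bond well)."""
    lj_pairs = {
        ("CT", "CR"): _lj(4.0, 0.30),
        ("HC", "CR"): _lj(3.2, 0.10),
        ("NT", "CR"): _lj(3.8, 0.30),
        ("HD", "CR"): _lj(3.0, 0.075),
        ("CO", "CR"): _lj(3.9, 0.30),
        ("OC", "CR"): _lj(3.6, 0.375),
    }
    # C/R^12 - D/R^10 with minimum at R0 = 2.0 Å, depth 0.5 kcal/mol
    hbond_pairs = {("HD", "CR"): (10240.0, 3072.0)}
    bonds = {
        "CT-HC": (340.0, 1.09),
        "CT-NT": (337.0, 1.47),
        "NT-HD": (434.0, 1.01),
        "CT-CO": (317.0, 1.52),
        "CO-OC": (550.0, 1.25),
        "CT-CT": (310.0, 1.526),
        "OC-HD": (553.0, 0.96),
    }
    _tet = 1.9111  # ~109.5 deg
    angles = {
        "HC-CT-NT": (50.0, _tet),
        "NT-CT-CO": (63.0, _tet),
        "HC-CT-CT": (50.0, _tet),
        "CO-CT-CT": (63.0, _tet),
        "CT-NT-HD": (50.0, _tet),
        "CT-CO-OC": (70.0, 2.0944),
        "OC-CO-OC": (80.0, 2.0944),
        "CT-CT-CT": (40.0, _tet),
        "CO-OC-HD": (50.0, 1.8850),
        "HD-NT-HD": (40.0, _tet),
    }
    # gamma restricted to {0, pi} so mirror images have identical E_intra
    torsions = {
        "HD-NT-CT-CO": [(1.4, 3, 0.0)],
        "OC-CO-CT-NT": [(2.0, 2, np.pi)],
        "CT-CT-CT-NT": [(1.4, 3, 0.0)],
    }
    return ForceFieldParams(
        lj_pairs=lj_pairs,
        hbond_pairs=hbond_pairs,
        bonds=bonds,
        angles=angles,
        torsions=torsions,
    )


def make_toy_host(
    n_sites: int = 7,
    ring_radius: float = 5.0,
    half_height: float = 2.0,
    charge_amplitude: float = 0.3,
    chiral: bool = False,
    chiral_charge_twist: float = 0.6,
    seed: int = 0,
) -> Structure:
    """Two stacked rings of LJ sites forming a cavity about the Z axis.

    ``n_sites`` per ring at angles (2m+1)·pi/n (no site on the +x axis, so
    reflection through xz maps site m to site n-1-m); the narrow rim ring
    (radius - 0.5 Å) sits at z = -half_height with its sites flagged as
    H-bond acceptors, the wide rim (+0.5 Å) at +z.  Charges follow a
    dipolar pattern amp·cos(theta) (net zero per ring, mirror-symmetric).

    ``chiral=True`` adds a *counter-twisted quadrupolar* charge decoration,
    +twist·sin(2·theta) on the wide ring and -twist·sin(2·theta) on the
    narrow ring.  The opposite phases on the two rings cannot be removed by
    any rotation, so the decorated host is chiral (in its charge
    distribution; the site geometry itself stays achiral), and its strength
    is chosen so the enantioselective energy split dominates desk-scale
    trajectory sampling noise.  The construction is deterministic (``seed``
    kept for interface symmetry with the guest).
    """
    if n_sites < 6:
        raise DomainError("n_sites must be >= 6")
    if ring_radius <= 1.0:
        raise DomainError("degenerate ring radius")

    # Mirror-partner atoms are stored adjacently, *all pairs first* across
    # both rings, with the on-plane (theta = pi, y = 0) singles at the end:
    # the kernels reduce pair sums two-at-a-time from index 0, so every
    # stride-2 block must hold exactly one reflection pair.
    rings = (
        (-half_height, ring_radius - 0.5, "acceptor", -1.0),
        (+half_height, ring_radius + 0.5, "none", +1.0),
    )
    paired: list[tuple] = []  # (x, y, z, q, role)
    singles: list[tuple] = []
    for z0, radius, role, ring_sign in rings:
        m = 0
        while m < n_sites - 1 - m:
            theta = (2 * m + 1) * np.pi / n_sites
            x = radius * np.cos(theta)
            y = radius * np.sin(theta)
            q = charge_amplitude * np.cos(theta)
            dq = 0.0
            if chiral:
                dq = ring_sign * chiral_charge_twist * np.sin(2 * theta)
            # the partner carries exact negations of the odd-in-theta parts
            paired.append((x, y, z0, q + dq, role))
            paired.append((x, -y, z0, q - dq, role))
            m += 1
        if n_sites % 2 == 1:
            # theta = pi exactly: on the mirror plane, even charge part only
            singles.append((-radius, 0.0, z0, -charge_amplitude, role))

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    for aid, (x, y, z, q, role) in enumerate(paired + singles):
        atoms.append(
            AtomRecord(
                id=aid,
                element="C",
                mass=ELEMENT_MASSES["C"],
                charge=q,
                lj_type="CR",
                hbond_role=role,
                name=f"R{aid}",
            )
        )
        coords.append(np.array([x, y, z]))

    host = Structure(atoms=atoms, coords=np.array(coords), conformer="toy-host")
    # center the COM at the origin exactly in x and z (y is 0 by symmetry
    # construction up to exact pairing; subtract the mean anyway, which is
    # mirror-neutral because the y-mean of exact +/- pairs is computed from
    # identical magnitudes)
    com = host.coords.mean(axis=0)
    com[1] = 0.0  # keep the exact mirror pairing intact
    host.coords = host.coords - com
    return host


def cavity_for_host(
    ring_radius: float = 5.0, half_height: float = 2.0
) -> CavityDef:
    """Cavity cylinder derived from the host annulus: the radius retreats
    from the ring by roughly an LJ contact distance, the half-height
    extends one Å beyond the ring planes."""
    return CavityDef(r_c=ring_radius - 1.5, h_c=half_height + 1.0)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _place(origin, prev, length: float, angle: float, perp_hint) -> np.ndarray:
    """Position an atom at ``length`` from ``origin`` making the given bond
    angle with the origin->prev direction, tilted toward ``perp_hint``."""
    u = _unit(np.asarray(prev) - np.asarray(origin))
    p = np.asarray(perp_hint, dtype=float)
    p = _unit(p - (p @ u) * u)
    return np.asarray(origin) + length * (np.cos(angle) * u + np.sin(angle) * p)


def make_chiral_guest(variant: str = "NP", seed: int = 0) -> tuple[Structure, Structure]:
    """Amino-acid-like chiral guest; returns (L, D) with D = xz-mirror of L.

    Atoms: CA (stereocenter), HA, N, HN, C' (carboxyl C), O1, O2, CB, CG
    (alkyl chain) and HX — the mobile hydrogen, bonded to O2 in the NP
    variant and to N in the zwitterion.  Group charges: amine/carboxyl sum
    to 0 each in NP, to +1/-1 in P; the molecule is neutral in both.
    """
    if variant not in ("NP", "P"):
        raise DomainError(f"variant must be NP or P, got {variant!r}")
    s3 = 1.0 / np.sqrt(3.0)
    t0 = np.array([s3, s3, s3])
    t1 = np.array([s3, -s3, -s3])
    t2 = np.array([-s3, s3, -s3])
    t3 = np.array([-s3, -s3, s3])

    _tet = 1.9111  # ~109.5 deg
    _sp2 = 2.0944  # 120 deg
    ca = np.zeros(3)
    ha = 1.09 * t0
    n = 1.47 * t1
    hn = _place(n, ca, 1.01, _tet, np.array([0.2, 0.9, -0.3]))
    cp = 1.52 * t2
    # planar carboxyl: both oxygens at 120 deg from CA, opposite tilts
    o_perp = np.array([0.9, 0.3, 0.1])
    o1 = _place(cp, ca, 1.25, _sp2, o_perp)
    o2 = _place(cp, ca, 1.25, _sp2, -o_perp)
    cb = 1.526 * t3
    cg = _place(cb, ca, 1.526, _tet, np.array([0.5, -0.7, 0.6]))
    if variant == "NP":
        hx = _place(o2, cp, 0.96, 1.8850, o_perp)
        charges = {
            "CA": 0.0, "HA": 0.0,
            "N": -0.30, "HN": 0.30,
            "CP": 0.45, "O1": -0.45, "O2": -0.38, "HX": 0.38,
            "CB": 0.0, "CG": 0.0,
        }
        hx_bond = (6, 9, "OC-HD")
        extra_angles = [(4, 6, 9, "CO-OC-HD")]
    else:
        # second amine H: 120 deg azimuth from HN about the N-CA axis,
        # giving the tetrahedral H-N-H angle
        u_n = _unit(ca - n)
        p1 = np.array([0.2, 0.9, -0.3])
        p1 = _unit(p1 - (p1 @ u_n) * u_n)
        p2 = -0.5 * p1 + (np.sqrt(3.0) / 2.0) * np.cross(u_n, p1)
        hx = _place(n, ca, 1.01, _tet, p2)
        charges = {
            "CA": 0.0, "HA": 0.0,
            "N": -0.30, "HN": 0.65, "HX": 0.65,
            "CP": 0.40, "O1": -0.70, "O2": -0.70,
            "CB": 0.0, "CG": 0.0,
        }
        hx_bond = (2, 9, "NT-HD")
        extra_angles = [(0, 2, 9, "CT-NT-HD"), (3, 2, 9, "HD-NT-HD")]

    atom_spec = [
        ("CA", "C", "CT", "none", ca),
        ("HA", "H", "HC", "none", ha),
        ("N", "N", "NT", "acceptor", n),
        ("HN", "H", "HD", "donor-H", hn),
        ("CP", "C", "CO", "none", cp),
        ("O1", "O", "OC", "acceptor", o1),
        ("O2", "O", "OC", "acceptor", o2),
        ("CB", "C", "CT", "none", cb),
        ("CG", "C", "CT", "none", cg),
        ("HX", "H", "HD", "donor-H", hx),
    ]
    atoms = [
        AtomRecord(
            id=i,
            element=el,
            mass=ELEMENT_MASSES[el],
            charge=charges[name],
            lj_type=lj,
            hbond_role=role,
            name=name,
        )
        for i, (name, el, lj, role, _) in enumerate(atom_spec)
    ]
    coords = np.array([xyz for *_, xyz in atom_spec])
    bonds = [
        (0, 1, "CT-HC"),
        (0, 2, "CT-NT"),
        (2, 3, "NT-HD"),
        (0, 4, "CT-CO"),
        (4, 5, "CO-OC"),
        (4, 6, "CO-OC"),
        (0, 7, "CT-CT"),
        (7, 8, "CT-CT"),
        hx_bond,
    ]
    angles = [
        (1, 0, 2, "HC-CT-NT"),
        (2, 0, 4, "NT-CT-CO"),
        (1, 0, 7, "HC-CT-CT"),
        (4, 0, 7, "CO-CT-CT"),
        (0, 2, 3, "CT-NT-HD"),
        (0, 4, 5, "CT-CO-OC"),
        (5, 4, 6, "OC-CO-OC"),
        (0, 7, 8, "CT-CT-CT"),
    ] + extra_angles
    dihedrals = [
        (3, 2, 0, 4, "HD-NT-CT-CO"),
        (5, 4, 0, 2, "OC-CO-CT-NT"),
        (8, 7, 0, 2, "CT-CT-CT-NT"),
    ]
    guest_l = Structure(
        atoms=atoms,
        coords=coords,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        conformer=f"toy-guest-{variant}",
        variant=variant,
    )
    guest_l.validate()
    guest_d = mirror_structure(guest_l, "xz")
    guest_d.conformer = guest_l.conformer
    return guest_l, guest_d


def best_superposition_rmsd(
    s1: Structure, s2: Structure, n_axis: int = 24, charge_weight: float = 1.0
) -> float:
    """Minimum configuration distance of s2 onto s1 over the host's
    plausible symmetry moves.

    Tries rotations about Z (n_axis evenly spaced angles) optionally
    composed with a 180° flip about X, resolving the atom correspondence by
    optimal assignment at each candidate.  Superimposing *molecules* must
    match per-atom properties, not just positions, so the per-atom distance
    is sqrt(|dr|^2 + (charge_weight * dq)^2) with ``charge_weight`` in Å/e
    — a charge-decorated chiral host scores > 0 even when its site geometry
    is achiral.  Suited to the ring-shaped fixture host (a general-purpose
    chirality test would need a full alignment search).
    """
    best = np.inf
    p = s1.coords - s1.coords.mean(axis=0)
    q0 = s2.coords - s2.coords.mean(axis=0)
    qc1 = s1.charges
    qc2 = s2.charges
    dq2 = (charge_weight * (qc1[:, None] - qc2[None, :])) ** 2
    flip = np.diag([1.0, -1.0, -1.0])  # pi about x
    for k in range(n_axis):
        ang = 2.0 * np.pi * k / n_axis
        ca, sa = np.cos(ang), np.sin(ang)
        rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        for rot in (rz, rz @ flip):
            q = q0 @ rot.T
            cost2 = np.sum((p[:, None, :] - q[None, :, :]) ** 2, axis=2) + dq2
            rows, cols = linear_sum_assignment(np.sqrt(cost2))
            rmsd = float(np.sqrt(np.mean(cost2[rows, cols])))
            best = min(best, rmsd)
    return best
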