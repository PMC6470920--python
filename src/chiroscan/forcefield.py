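"""AMBER-type molecular-mechanics energy model and its analytic gradient.

The total potential is

    E_total = E_inter + E_intra

    E_inter = sum over host x guest atom pairs of
                A/R^12 - B/R^6            (Lennard-Jones 12-6)
              or, for (donor-H, acceptor) pairs,
                C/R^12 - D/R^10           (hydrogen-bond 12-10)
              plus, for every pair,
                kappa * q_i q_j / (eps * R)   (screened Coulomb)

    E_intra = sum k_r (r - r_eq)^2  +  sum k_theta (theta - theta_eq)^2
              + sum_n V_n/2 (1 + cos(n*phi - gamma))

The 12-10 term *replaces* the 12-6 term for flagged pairs (classic
AMBER-1984 handling, which is why the H-bond energy is reported as a
separate column of the energy breakdown).  Intramolecular non-bonded
interactions are not computed: the intramolecular energy carries only the
bonded columns.  No distance cutoffs are applied; the systems are small
and aperiodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_K
from .errors import DomainError, ParameterizationError, SingularityError
from .rigid import center_of_mass
from .structure import Structure

__all__ = [
    "SolventSpec",
    "ForceFieldParams",
    "EnergyBreakdown",
    "PairTable",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "hbond_pair_energy",
    "bond_energy",
    "angle_energy",
    "torsion_energy",
    "dihedral_angle",
    "intermolecular_energy",
    "intramolecular_energy",
    "total_energy",
    "forces_and_torques",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolventSpec:
    """Implicit-solvent model: a dielectric constant screening the Coulomb
    term plus the guest charge variant the solvent polarity selects
    ("NP" neutral or "P" zwitterion)."""

    epsilon: float = 1.0
    guest_variant: str = "NP"

    def __post_init__(self):
        if self.epsilon < 1.0:
            raise DomainError(f"dielectric constant must be >= 1, got {self.epsilon}")
        if self.guest_variant not in ("NP", "P"):
            raise DomainError(f"guest_variant must be NP or P, got {self.guest_variant!r}")


#: vacuum: eps = 1 and the neutral guest.
VACUUM = SolventSpec(epsilon=1.0, guest_variant="NP")


@dataclass
class ForceFieldParams:
    """All force-field constants, keyed by type tokens.

    ``lj_pairs``   (type, type) -> (A [kcal·Å^12/mol], B [kcal·Å^6/mol]),
                   symmetric under swap;
    ``hbond_pairs`` (donor-H type, acceptor type) -> (C [kcal·Å^12/mol],
                   D [kcal·Å^10/mol]), symmetric under swap;
    ``bonds``      token -> (k_r [kcal/mol/Å^2], r_eq [Å]);
    ``angles``     token -> (k_theta [kcal/mol/rad^2], theta_eq [rad]);
    ``torsions``   token -> list of (V_n [kcal/mol], n [int >= 1], gamma [rad]);
    ``coulomb_constant`` kappa [kcal·Å/(mol·e^2)].
    """

    lj_pairs: dict = field(default_factory=dict)
    hbond_pairs: dict = field(default_factory=dict)
    bonds: dict = field(default_factory=dict)
    angles: dict = field(default_factory=dict)
    torsions: dict = field(default_factory=dict)
    coulomb_constant: float = COULOMB_K

    def __post_init__(self):
        for d in (self.lj_pairs, self.hbond_pairs):
            for key, val in list(d.items()):
                if any(v < 0 for v in val):
                    raise DomainError(f"negative pair coefficient for {key}: {val}")

    def lj(self, t1: str, t2: str) -> tuple[float, float]:
        for key in ((t1, t2), (t2, t1)):
            if key in self.lj_pairs:
                return self.lj_pairs[key]
        raise ParameterizationError(f"no Lennard-Jones parameters for pair ({t1}, {t2})")

    def hbond(self, t_donor_h: str, t_acceptor: str) -> tuple[float, float]:
        for key in ((t_donor_h, t_acceptor), (t_acceptor, t_donor_h)):
            if key in self.hbond_pairs:
                return self.hbond_pairs[key]
        raise ParameterizationError(
            f"no 12-10 parameters for donor-H/acceptor pair ({t_donor_h}, {t_acceptor})"
        )

    def bond(self, token: str) -> tuple[float, float]:
        try:
            return self.bonds[token]
        except KeyError:
            raise ParameterizationError(f"no bond parameters for type {token!r}") from None

    def angle(self, token: str) -> tuple[float, float]:
        try:
            return self.angles[token]
        except KeyError:
            raise ParameterizationError(f"no angle parameters for type {token!r}") from None

    def torsion(self, token: str) -> list[tuple[float, int, float]]:
        try:
            return self.torsions[token]
        except KeyError:
            raise ParameterizationError(f"no torsion parameters for type {token!r}") from None


@dataclass
class EnergyBreakdown:
    """Per-term energies in kcal/mol, mirroring the columns of a
    minimum-energy report: LJ, electrostatic, H-bond (intermolecular);
    bond, angle, torsion (intramolecular); and their sums."""

    e_lj: float = 0.0
    e_ele: float = 0.0
    e_hbond: float = 0.0
    e_bond: float = 0.0
    e_angle: float = 0.0
    e_torsion: float = 0.0

    @property
    def e_inter(self) -> float:
        return self.e_lj + self.e_ele + self.e_hbond

    @property
    def e_intra(self) -> float:
        return self.e_bond + self.e_angle + self.e_torsion

    @property
    def e_total(self) -> float:
        return self.e_inter + self.e_intra

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.e_lj + other.e_lj,
            self.e_ele + other.e_ele,
            self.e_hbond + other.e_hbond,
            self.e_bond + other.e_bond,
            self.e_angle + other.e_angle,
            self.e_torsion + other.e_torsion,
        )

    def as_dict(self) -> dict:
        return {
            "E_total": self.e_total,
            "E_LJ": self.e_lj,
            "E_ele": self.e_ele,
            "E_Hbond": self.e_hbond,
            "E_bond": self.e_bond,
            "E_angle": self.e_angle,
            "E_torsion": self.e_torsion,
            "E_inter": self.e_inter,
            "E_intra": self.e_intra,
        }


# ---------------------------------------------------------------------------
# elementary pair / bonded terms
# ---------------------------------------------------------------------------

def lj_pair_energy(A: float, B: float, R: float) -> float:
    """Lennard-Jones 12-6 pair energy A/R^12 - B/R^6."""
    if R <= 0:
        raise DomainError(f"pair distance must be > 0, got {R}")
    r6 = R ** 6
    return A / (r6 * r6) - B / r6


def coulomb_pair_energy(
    q1: float, q2: float, R: float, epsilon: float = 1.0, kappa: float = COULOMB_K
) -> float:
    """Screened Coulomb pair energy kappa q1 q2 / (epsilon R)."""
    if R <= 0:
        raise DomainError(f"pair distance must be > 0, got {R}")
    if epsilon < 1.0:
        raise DomainError(f"dielectric constant must be >= 1, got {epsilon}")
    return kappa * q1 * q2 / (epsilon * R)


def hbond_pair_energy(C: float, D: float, R: float) -> float:
    """Hydrogen-bond 12-10 pair energy C/R^12 - D/R^10."""
    if R <= 0:
        raise DomainError(f"pair distance must be > 0, got {R}")
    r2 = R * R
    r10 = r2 ** 5
    return C / (r10 * r2) - D / r10


def bond_energy(k_r: float, r: float, r_eq: float) -> float:
    """Harmonic stretch k_r (r - r_eq)^2."""
    if k_r < 0:
        raise DomainError("bond force constant must be >= 0")
    return k_r * (r - r_eq) ** 2


def angle_energy(k_theta: float, theta: float, theta_eq: float) -> float:
    """Harmonic bend k_theta (theta - theta_eq)^2."""
    if k_theta < 0:
        raise DomainError("angle force constant must be >= 0")
    return k_theta * (theta - theta_eq) ** 2


def torsion_energy(terms, phi: float) -> float:
    """Cosine torsion sum_n V_n/2 (1 + cos(n phi - gamma))."""
    e = 0.0
    for v_n, n, gamma in terms:
        if int(n) < 1:
            raise DomainError(f"torsion periodicity must be >= 1, got {n}")
        e += 0.5 * v_n * (1.0 + np.cos(n * phi - gamma))
    return float(e)


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion angle about the p1-p2 bond (IUPAC convention, rad)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return float(np.arctan2(m1 @ n2, n1 @ n2))


# ---------------------------------------------------------------------------
# resolved pair table (guest x host)
# ---------------------------------------------------------------------------

@dataclass
class PairTable:
    """Per-pair coefficients for all guest x host atom pairs, resolved once.

    Arrays are shaped (n_guest, n_host).  ``qq`` already carries
    kappa q_i q_j / epsilon, so the Coulomb energy of a pair is qq / R.
    ``hb`` flags pairs that use the 12-10 term instead of the 12-6 term.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    qq: np.ndarray
    hb: np.ndarray

    @classmethod
    def build(
        cls, host: Structure, guest: Structure, ff: ForceFieldParams, solvent: SolventSpec
    ) -> "PairTable":
        g, h = guest.n_atoms, host.n_atoms
        A = np.zeros((g, h))
        B = np.zeros((g, h))
        C = np.zeros((g, h))
        D = np.zeros((g, h))
        hb = np.zeros((g, h), dtype=bool)
        for i, ga in enumerate(guest.atoms):
            for j, ha in enumerate(host.atoms):
                roles = {ga.hbond_role, ha.hbond_role}
                if roles == {"donor-H", "acceptor"}:
                    donor = ga if ga.hbond_role == "donor-H" else ha
                    acc = ha if donor is ga else ga
                    C[i, j], D[i, j] = ff.hbond(donor.lj_type, acc.lj_type)
                    hb[i, j] = True
                else:
                    A[i, j], B[i, j] = ff.lj(ga.lj_type, ha.lj_type)
        qq = (
            ff.coulomb_constant
            * np.outer(guest.charges, host.charges)
            / solvent.epsilon
        )
        return cls(A=A, B=B, C=C, D=D, qq=qq, hb=hb)


def _pair_distances(host: Structure, guest: Structure) -> np.ndarray:
    diff = guest.coords[:, None, :] - host.coords[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.any(r2 < 1e-12):
        raise SingularityError("coincident host/guest atoms (R_ij ~ 0)")
    return np.sqrt(r2)


def intermolecular_energy(
    host: Structure,
    guest: Structure,
    ff: ForceFieldParams,
    solvent: SolventSpec = VACUUM,
    table: PairTable | None = None,
) -> EnergyBreakdown:
    """Sum the three non-bonded pair terms over all host x guest pairs."""
    t = table if table is not None else PairTable.build(host, guest, ff, solvent)
    r = _pair_distances(host, guest)
    r6 = r ** 6
    r10 = r ** 10
    r12 = r6 * r6
    lj = np.where(t.hb, 0.0, t.A / r12 - t.B / r6)
    hbond = np.where(t.hb, t.C / r12 - t.D / r10, 0.0)
    ele = t.qq / r
    return EnergyBreakdown(
        e_lj=float(lj.sum()), e_ele=float(ele.sum()), e_hbond=float(hbond.sum())
    )


def intramolecular_energy(s: Structure, ff: ForceFieldParams) -> EnergyBreakdown:
    """Sum bonded terms over the structure's topology."""
    e_bond = 0.0
    for i, j, token in s.bonds:
        k_r, r_eq = ff.bond(token)
        r = float(np.linalg.norm(s.coords[i] - s.coords[j]))
        e_bond += bond_energy(k_r, r, r_eq)
    e_angle = 0.0
    for i, j, k, token in s.angles:
        k_t, t_eq = ff.angle(token)
        u = s.coords[i] - s.coords[j]
        v = s.coords[k] - s.coords[j]
        cosang = np.clip(
            (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0
        )
        e_angle += angle_energy(k_t, float(np.arccos(cosang)), t_eq)
    e_torsion = 0.0
    for i, j, k, l, token in s.dihedrals:
        phi = dihedral_angle(s.coords[i], s.coords[j], s.coords[k], s.coords[l])
        e_torsion += torsion_energy(ff.torsion(token), phi)
    return EnergyBreakdown(e_bond=e_bond, e_angle=e_angle, e_torsion=e_torsion)


def total_energy(
    host: Structure,
    guest: Structure,
    ff: ForceFieldParams,
    solvent: SolventSpec = VACUUM,
) -> EnergyBreakdown:
    """E_total = E_inter + E_intra(host) + E_intra(guest)."""
    return (
        intermolecular_energy(host, guest, ff, solvent)
        + intramolecular_energy(host, ff)
        + intramolecular_energy(guest, ff)
    )


def forces_and_torques(
    host: Structure,
    guest: Structure,
    ff: ForceFieldParams,
    solvent: SolventSpec = VACUUM,
    table: PairTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic net force (kcal/mol/Å) and torque about the guest COM
    (kcal/mol·rad) exerted on the rigid guest by the host.

    force  = -grad_COM E_inter;  torque = sum_i (r_i - COM) x f_i.
    """
    t = table if table is not None else PairTable.build(host, guest, ff, solvent)
    diff = guest.coords[:, None, :] - host.coords[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.any(r2 < 1e-12):
        raise SingularityError("coincident host/guest atoms (R_ij ~ 0)")
    r = np.sqrt(r2)
    r6 = r2 ** 3
    r12 = r6 * r6
    # dE/dR for each pair
    dlj = np.where(t.hb, 0.0, -12.0 * t.A / (r12 * r) + 6.0 * t.B / (r6 * r))
    dhb = np.where(t.hb, -12.0 * t.C / (r12 * r) + 10.0 * t.D / (r12 / r2 * r), 0.0)
    dele = -t.qq / r2
    dedr = dlj + dhb + dele
    # f_i = -dE/dR * rhat, summed over host atoms
    fij = -(dedr / r)[:, :, None] * diff
    f_atoms = fij.sum(axis=1)
    force = f_atoms.sum(axis=0)
    com = center_of_mass(guest)
    torque = np.cross(guest.coords - com, f_atoms).sum(axis=0)
    return force, torque
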