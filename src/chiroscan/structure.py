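"""Molecular structures: atoms, coordinates and bonded topology.

A :class:`Structure` is the in-memory container shared by every module:
a flat list of :class:`AtomRecord` (element, mass, partial charge,
Lennard-Jones type token and hydrogen-bond role) plus an ``(N, 3)``
coordinate array in Å and explicit bond/angle/dihedral index tuples, each
carrying the type token used to look up force-field parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError

#: Allowed hydrogen-bond roles. Only (donor-H, acceptor) pairs participate
#: in the 12-10 term.
HBOND_ROLES = ("donor-H", "acceptor", "none")

#: Standard atomic masses (amu) for elements used by the fixtures.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "X": 1.0,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity and per-atom force-field attributes.

    ``charge`` is the partial charge q_i in elementary-charge units,
    ``lj_type`` the token used to resolve Lennard-Jones (and H-bond) pair
    parameters, ``hbond_role`` one of :data:`HBOND_ROLES`.
    """

    id: int
    element: str
    mass: float
    charge: float = 0.0
    lj_type: str = "X"
    hbond_role: str = "none"
    name: str = ""

    def __post_init__(self):
        if self.mass <= 0:
            raise DomainError(f"atom {self.id}: mass must be > 0, got {self.mass}")
        if self.hbond_role not in HBOND_ROLES:
            raise DomainError(
                f"atom {self.id}: hbond_role must be one of {HBOND_ROLES}, "
                f"got {self.hbond_role!r}"
            )


@dataclass
class Structure:
    """Atoms + coordinates + bonded topology.

    ``bonds`` are ``(i, j, type_token)``, ``angles`` ``(i, j, k, token)``
    with the angle at j, ``dihedrals`` ``(i, j, k, l, token)`` for the
    torsion about the j-k bond. ``variant`` records which guest charge
    variant this is ("NP" neutral, "P" zwitterion, or "n/a").
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    bonds: list[tuple[int, int, str]] = field(default_factory=list)
    angles: list[tuple[int, int, int, str]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, str]] = field(default_factory=list)
    conformer: str = ""
    variant: str = "n/a"
    inferred_topology: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.atoms), 3)

    # -- derived arrays ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def lj_types(self) -> list[str]:
        return [a.lj_type for a in self.atoms]

    @property
    def hbond_roles(self) -> list[str]:
        return [a.hbond_role for a in self.atoms]

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    # -- copies ------------------------------------------------------------
    def copy(self) -> "Structure":
        return Structure(
            atoms=list(self.atoms),
            coords=self.coords.copy(),
            bonds=list(self.bonds),
            angles=list(self.angles),
            dihedrals=list(self.dihedrals),
            conformer=self.conformer,
            variant=self.variant,
            inferred_topology=self.inferred_topology,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        s = self.copy()
        s.coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        return s

    def with_charges(self, charges) -> "Structure":
        s = self.copy()
        s.atoms = [replace(a, charge=float(q)) for a, q in zip(s.atoms, charges)]
        return s

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check index ranges and bonded-graph consistency.

        Angles must reference two existing bonds (i-j and j-k); dihedrals
        three consecutive bonds.  Raises :class:`DomainError` on violation.
        """
        n = self.n_atoms
        bond_set = {frozenset((i, j)) for i, j, _ in self.bonds}
        for i, j, t in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise DomainError(f"bond ({i},{j},{t!r}) has out-of-range or equal indices")
        for i, j, k, t in self.angles:
            if len({i, j, k}) != 3 or not all(0 <= x < n for x in (i, j, k)):
                raise DomainError(f"angle ({i},{j},{k},{t!r}) has bad indices")
            if frozenset((i, j)) not in bond_set or frozenset((j, k)) not in bond_set:
                raise DomainError(f"angle ({i},{j},{k},{t!r}) not supported by bonds")
        for i, j, k, l, t in self.dihedrals:
            if len({i, j, k, l}) != 4 or not all(0 <= x < n for x in (i, j, k, l)):
                raise DomainError(f"dihedral ({i},{j},{k},{l},{t!r}) has bad indices")
            for a, b in ((i, j), (j, k), (k, l)):
                if frozenset((a, b)) not in bond_set:
                    raise DomainError(
                        f"dihedral ({i},{j},{k},{l},{t!r}) not supported by bonds"
                    )


def infer_topology(structure: Structure, scale: float = 1.25) -> Structure:
    """Infer bonds by a covalent-distance rule and derive angles.

    Two atoms are bonded when their separation is below ``scale`` times the
    sum of rough covalent radii. Bond/angle type tokens are built from
    element symbols ("C-H", "C-C-H", ...). The result is flagged with
    ``inferred_topology=True``; dihedrals are not inferred.
    """
    radii = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07, "X": 0.8}
    s = structure.copy()
    n = s.n_atoms
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            ei, ej = s.atoms[i].element, s.atoms[j].element
            cutoff = scale * (radii.get(ei, 0.8) + radii.get(ej, 0.8))
            r = float(np.linalg.norm(s.coords[i] - s.coords[j]))
            if r < cutoff:
                bonds.append((i, j, f"{ei}-{ej}"))
    neighbours: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j, _ in bonds:
        neighbours[i].append(j)
        neighbours[j].append(i)
    angles = []
    for j in range(n):
        nb = sorted(neighbours[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                token = f"{s.atoms[i].element}-{s.atoms[j].element}-{s.atoms[k].element}"
                angles.append((i, j, k, token))
    s.bonds = bonds
    s.angles = angles
    s.dihedrals = []
    s.inferred_topology = True
    return s
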