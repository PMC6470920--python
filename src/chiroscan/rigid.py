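"""Rigid-body kinematics: centre of mass, inertia, rotations, mirrors.

Orientations are parameterized either by ZYZ Euler angles (alpha, beta,
gamma_e), right-handed, with the host-frame Z axis along the cavity axis,
or by unit quaternions (w, x, y, z).  Quaternions are the working
representation everywhere dynamics is involved, since the Euler-angle
equations of motion are singular at beta = 0, pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .structure import Structure

_PLANES = {"xy": 2, "xz": 1, "yz": 0}


# ---------------------------------------------------------------------------
# mass properties
# ---------------------------------------------------------------------------

def center_of_mass(s: Structure) -> np.ndarray:
    """Mass-weighted mean position, Å."""
    m = s.masses
    total = m.sum()
    if s.n_atoms == 0 or total <= 0:
        raise DomainError("center_of_mass of an empty structure")
    return (m[:, None] * s.coords).sum(axis=0) / total


def inertia_tensor(s: Structure, about: np.ndarray | None = None) -> np.ndarray:
    """Inertia tensor about the centre of mass (amu·Å²), symmetric PSD.

    Built with a fixed component-wise formula (no linear-algebra library
    call) so that mirrored structures yield exactly sign-patterned tensors.
    """
    if s.n_atoms == 0:
        raise DomainError("inertia_tensor of an empty structure")
    c = center_of_mass(s) if about is None else np.asarray(about, dtype=float)
    r = s.coords - c
    m = s.masses
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    ixx = float(np.sum(m * (y * y + z * z)))
    iyy = float(np.sum(m * (x * x + z * z)))
    izz = float(np.sum(m * (x * x + y * y)))
    ixy = -float(np.sum(m * x * y))
    ixz = -float(np.sum(m * x * z))
    iyz = -float(np.sum(m * y * z))
    return np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])


def principal_axes(inertia: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal moments (ascending) and axes (columns) of an inertia tensor."""
    w, v = np.linalg.eigh(np.asarray(inertia, dtype=float))
    return w, v


def inverse_3x3(a: np.ndarray) -> np.ndarray:
    """Explicit adjugate-formula inverse of a 3x3 matrix.

    Used instead of a LAPACK call inside the dynamics so sign-patterned
    (mirror-image) inputs invert to exactly sign-patterned outputs.
    """
    a = np.asarray(a, dtype=float)
    c00 = a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1]
    c01 = a[1, 2] * a[2, 0] - a[1, 0] * a[2, 2]
    c02 = a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0]
    c10 = a[0, 2] * a[2, 1] - a[0, 1] * a[2, 2]
    c11 = a[0, 0] * a[2, 2] - a[0, 2] * a[2, 0]
    c12 = a[0, 1] * a[2, 0] - a[0, 0] * a[2, 1]
    c20 = a[0, 1] * a[1, 2] - a[0, 2] * a[1, 1]
    c21 = a[0, 2] * a[1, 0] - a[0, 0] * a[1, 2]
    c22 = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    det = a[0, 0] * c00 + a[0, 1] * c01 + a[0, 2] * c02
    if det == 0.0:
        raise DomainError("singular 3x3 matrix")
    return np.array([[c00, c10, c20], [c01, c11, c21], [c02, c12, c22]]) / det


# ---------------------------------------------------------------------------
# quaternions (w, x, y, z convention; unit norm = rotation)
# ---------------------------------------------------------------------------

def quaternion_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quaternion_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quaternion_from_axis_angle(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    half = 0.5 * angle
    s = np.sin(half) / n
    return np.array([np.cos(half), axis[0] * s, axis[1] * s, axis[2] * s])


def euler_to_quaternion(alpha: float, beta: float, gamma_e: float) -> np.ndarray:
    """ZYZ Euler angles -> unit quaternion: R = Rz(alpha) Ry(beta) Rz(gamma_e)."""
    qa = quaternion_from_axis_angle([0, 0, 1], alpha)
    qb = quaternion_from_axis_angle([0, 1, 0], beta)
    qg = quaternion_from_axis_angle([0, 0, 1], gamma_e)
    return quaternion_multiply(quaternion_multiply(qa, qb), qg)


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (orthogonal, det +1)."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_to_euler(q: np.ndarray) -> tuple[float, float, float]:
    """ZYZ Euler angles of a unit quaternion (beta in [0, pi])."""
    r = quaternion_to_matrix(q)
    beta = float(np.arccos(np.clip(r[2, 2], -1.0, 1.0)))
    if np.sin(beta) > 1e-12:
        alpha = float(np.arctan2(r[1, 2], r[0, 2]))
        gamma = float(np.arctan2(r[2, 1], -r[2, 0]))
    else:  # gimbal: fold the whole z-rotation into alpha
        alpha = float(np.arctan2(r[1, 0], r[0, 0]))
        if r[2, 2] < 0:
            alpha = -alpha
        gamma = 0.0
    return alpha, beta, gamma


def mirror_quaternion(q: np.ndarray, plane: str = "xz") -> np.ndarray:
    """Quaternion of the mirrored rotation S R S for reflection through a
    coordinate plane: the quaternion component along the plane's normal is
    kept, the other two vector components are negated."""
    axis = _PLANES[plane]
    out = np.array(q, dtype=float)
    for k in range(3):
        if k != axis:
            out[k + 1] = -out[k + 1]
    return out


# ---------------------------------------------------------------------------
# dispositions
# ---------------------------------------------------------------------------

@dataclass
class Disposition:
    """Guest centre-of-mass position (host frame, Å) + orientation.

    The orientation is stored as a unit quaternion; Euler angles are
    available through :meth:`euler` / :meth:`from_euler`.
    """

    com: np.ndarray
    quaternion: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float).reshape(3)
        self.quaternion = np.asarray(self.quaternion, dtype=float).reshape(4)
        n = float(np.linalg.norm(self.quaternion))
        if abs(n - 1.0) > 1e-9:
            raise DomainError(f"quaternion norm {n} deviates from 1 by more than 1e-9")

    @classmethod
    def from_euler(cls, com, alpha: float, beta: float, gamma_e: float) -> "Disposition":
        return cls(com=np.asarray(com, dtype=float), quaternion=euler_to_quaternion(alpha, beta, gamma_e))

    @property
    def matrix(self) -> np.ndarray:
        return quaternion_to_matrix(self.quaternion)

    @property
    def euler(self) -> tuple[float, float, float]:
        return quaternion_to_euler(self.quaternion)

    def inverse(self) -> "Disposition":
        qc = quaternion_conjugate(self.quaternion)
        return Disposition(com=-quaternion_to_matrix(qc) @ self.com, quaternion=qc)

    def mirrored(self, plane: str = "xz") -> "Disposition":
        com = np.array(self.com)
        com[_PLANES[plane]] = -com[_PLANES[plane]]
        return Disposition(com=com, quaternion=mirror_quaternion(self.quaternion, plane))


def apply_disposition(s: Structure, d: Disposition) -> Structure:
    """Rotate about the structure's own COM, then translate the COM to d.com."""
    c = center_of_mass(s)
    coords = (s.coords - c) @ d.matrix.T + d.com
    return s.with_coords(coords)


def mirror_structure(s: Structure, plane: str = "xz") -> Structure:
    """Reflect coordinates through a coordinate plane.

    Topology, charges and masses are untouched and atom order is preserved,
    so the mirror of an L guest is its D enantiomer with index-wise atom
    correspondence. Applying the same mirror twice is the identity.
    """
    if plane not in _PLANES:
        raise DomainError(f"plane must be one of {sorted(_PLANES)}, got {plane!r}")
    coords = s.coords.copy()
    coords[:, _PLANES[plane]] = -coords[:, _PLANES[plane]]
    return s.with_coords(coords)


def signed_volume(coords: np.ndarray) -> float:
    """Signed volume of the tetrahedron spanned by four points.

    Its sign is a chirality indicator: it flips under mirror reflection.
    """
    p = np.asarray(coords, dtype=float)
    return float(np.linalg.det(p[1:] - p[0])) / 6.0
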