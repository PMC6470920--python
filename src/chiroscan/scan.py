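"""Exhaustive grid x orientation energy scanning.

The guest COM is stepped over a Cartesian grid in the host frame (the host
COM at the origin, Z along the cavity axis) and, at every grid point, the
interaction energy is evaluated for a deterministic set of guest
orientations.  The scan records at each point the minimum energy over
orientations and its argmin, and the Boltzmann-weighted average energy —
the surface a guest that does not always adopt the minimum-energy
orientation actually feels.  Derived products:

* the penetration potential W(Z): the minimum intermolecular energy over
  each plane Z = const, the curve the guest descends as it threads the
  cavity;
* the global minimum-energy complex (E_min) with its disposition and a
  full per-term breakdown;
* enantioselectivity maps: grid points where the L- and D-guest surfaces
  differ by more than a threshold, signed by which enantiomer is more
  stable.

Presets: ``coarse`` (0.5 Å spacing, 12x6x12 orientations) is the desk
default; ``full`` (0.1 Å, 36x18x36 = 23,328 orientations) is the
full-resolution variant and is compute-heavy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .constants import KB
from .errors import DomainError
from .forcefield import (
    EnergyBreakdown,
    ForceFieldParams,
    PairTable,
    SolventSpec,
    intermolecular_energy,
    intramolecular_energy,
)
from .rigid import (
    Disposition,
    apply_disposition,
    center_of_mass,
    euler_to_quaternion,
    mirror_quaternion,
    quaternion_to_matrix,
)
from .structure import Structure

#: named presets: (grid spacing Å, (n_alpha, n_beta, n_gamma))
PRESETS = {
    "coarse": (0.5, (12, 6, 12)),
    "full": (0.1, (36, 18, 36)),
}


# ---------------------------------------------------------------------------
# grid / orientations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Cartesian scan grid: per-axis (min, max) bounds in Å and spacing."""

    bounds: tuple = ((-5.0, 5.0), (-5.0, 5.0), (-5.0, 5.0))
    spacing: float = 0.1

    def __post_init__(self):
        if self.spacing <= 0:
            raise DomainError(f"grid spacing must be > 0, got {self.spacing}")
        for lo, hi in self.bounds:
            if hi < lo:
                raise DomainError(f"bad axis bounds ({lo}, {hi})")

    def axis(self, k: int) -> np.ndarray:
        lo, hi = self.bounds[k]
        n = int(round((hi - lo) / self.spacing)) + 1
        return lo + self.spacing * np.arange(n)

    @property
    def xs(self) -> np.ndarray:
        return self.axis(0)

    @property
    def ys(self) -> np.ndarray:
        return self.axis(1)

    @property
    def zs(self) -> np.ndarray:
        return self.axis(2)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.zs), len(self.ys), len(self.xs))

    @property
    def n_points(self) -> int:
        nz, ny, nx = self.shape
        return nx * ny * nz


@dataclass
class OrientationSet:
    """Deterministically ordered set of guest orientations.

    Built as a regular ZYZ Euler grid with alpha, gamma_e in [0, 2pi) and
    beta in [0, pi] (beta = 0 only, for a single beta point, so (1,1,1)
    yields the identity).  Orientation index = (i_alpha*n_beta + i_beta) *
    n_gamma + i_gamma.  The set may also hold arbitrary quaternions (e.g. a
    mirrored set), in which case ``eulers`` is None.
    """

    quaternions: np.ndarray
    counts: tuple[int, int, int] | None = None
    eulers: np.ndarray | None = None

    def __len__(self) -> int:
        return self.quaternions.shape[0]

    @property
    def matrices(self) -> np.ndarray:
        return np.stack([quaternion_to_matrix(q) for q in self.quaternions])

    def mirrored(self, plane: str = "xz") -> "OrientationSet":
        q = np.stack([mirror_quaternion(qq, plane) for qq in self.quaternions])
        return OrientationSet(quaternions=q, counts=self.counts, eulers=None)


def generate_orientations(n_alpha: int = 36, n_beta: int = 18, n_gamma: int = 36) -> OrientationSet:
    """Regular Euler-angle orientation grid.

    The default 36 x 18 x 36 = 23,328 orientations; the grid is uniform in
    Euler angles, not uniform on SO(3), because orientations are enumerated
    as Euler triples.
    """
    if min(n_alpha, n_beta, n_gamma) < 1:
        raise DomainError("orientation counts must be >= 1")
    alphas = 2.0 * np.pi * np.arange(n_alpha) / n_alpha
    betas = np.array([0.0]) if n_beta == 1 else np.linspace(0.0, np.pi, n_beta)
    gammas = 2.0 * np.pi * np.arange(n_gamma) / n_gamma
    eulers = np.array(
        [(a, b, g) for a in alphas for b in betas for g in gammas]
    )
    quats = np.stack([euler_to_quaternion(*e) for e in eulers])
    return OrientationSet(quaternions=quats, counts=(n_alpha, n_beta, n_gamma), eulers=eulers)


# ---------------------------------------------------------------------------
# cavity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CavityDef:
    """The cavity as a cylinder: radius r_c and half-height h_c about an
    origin on the host frame's Z axis."""

    r_c: float
    h_c: float
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.r_c <= 0 or self.h_c <= 0:
            raise DomainError("cavity radius and half-height must be > 0")

    def inside(self, coords: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the cavity cylinder."""
        r = np.atleast_2d(coords) - np.asarray(self.origin)
        return (r[:, 0] ** 2 + r[:, 1] ** 2 <= self.r_c ** 2) & (
            np.abs(r[:, 2]) <= self.h_c
        )


def classify_inclusion(d: Disposition, guest: Structure, cavity: CavityDef) -> str:
    """Label a guest disposition by the fraction of its atoms inside the
    cavity cylinder: 'inclusion' (all), 'partial' (some), 'external' (none)."""
    coords = apply_disposition(guest, d).coords
    inside = cavity.inside(coords)
    if inside.all():
        return "inclusion"
    if inside.any():
        return "partial"
    return "external"


# ---------------------------------------------------------------------------
# PES containers
# ---------------------------------------------------------------------------

@dataclass
class PESGrid:
    """Scan result: per-grid-point minimum / argmin-orientation / Boltzmann
    average, plus the global minimum and its disposition."""

    grid: GridSpec
    orientations: OrientationSet
    energy_kind: str  # 'total' | 'inter'
    temperature: float
    e_min: np.ndarray  # (nz, ny, nx)
    argmin_orientation: np.ndarray  # (nz, ny, nx) int
    boltzmann: np.ndarray  # (nz, ny, nx)
    global_min: float = np.inf
    global_min_index: tuple = ()  # (iz, iy, ix)
    global_min_disposition: Disposition | None = None
    global_min_breakdown: EnergyBreakdown | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: X, Y, Z, e_min, boltzmann, argmin_orientation."""
        zs, ys, xs = self.grid.zs, self.grid.ys, self.grid.xs
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        return pd.DataFrame(
            {
                "X": xx.ravel(),
                "Y": yy.ravel(),
                "Z": zz.ravel(),
                "e_min": self.e_min.ravel(),
                "boltzmann": self.boltzmann.ravel(),
                "argmin_orientation": self.argmin_orientation.ravel(),
            }
        )


@dataclass
class PenetrationCurve:
    """W(Z): per-Z-plane minimum of the point-minimum energies."""

    z: np.ndarray
    w: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Z": self.z, "W": self.w})


@dataclass
class EnantioMap:
    """Grid points where |E_L - E_D| exceeds a threshold.

    ``delta`` = E_L - E_D (negative: L more stable).  Projections keep, for
    each projected cell, the signed delta of largest magnitude.
    """

    threshold: float
    points: pd.DataFrame  # columns X, Y, Z, delta
    xy: pd.DataFrame
    xz: pd.DataFrame


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def scan(
    host: Structure,
    guest: Structure,
    ff: ForceFieldParams,
    solvent: SolventSpec,
    grid: GridSpec,
    orients: OrientationSet,
    energy_kind: str = "total",
    temperature: float = 293.0,
) -> PESGrid:
    """Fill a :class:`PESGrid` by exhaustive evaluation.

    ``energy_kind='inter'`` scans the intermolecular energy only (the mode
    the penetration potential is built from); ``'total'`` adds the
    (conformer-constant, rigid-body) intramolecular energies of host and
    guest, which shifts every point by the same amount.  Ties for minima are
    broken toward the lowest (Z, Y, X, orientation) index.
    """
    if energy_kind not in ("total", "inter"):
        raise DomainError(f"energy_kind must be 'total' or 'inter', got {energy_kind!r}")
    if temperature <= 0:
        raise DomainError("temperature must be > 0")
    table = PairTable.build(host, guest, ff, solvent)
    body = guest.coords - center_of_mass(guest)
    beta = 1.0 / (KB * temperature)
    emin, argo, s1, se = _kernels.scan_kernel(
        np.ascontiguousarray(body),
        np.ascontiguousarray(host.coords),
        table.A,
        table.B,
        table.C,
        table.D,
        table.qq,
        table.hb.astype(np.uint8),
        np.ascontiguousarray(orients.matrices),
        grid.xs,
        grid.ys,
        grid.zs,
        beta,
    )
    shape = grid.shape
    singular = emin >= _kernels.SINGULAR_ENERGY
    boltz = np.where(singular, np.inf, se / np.where(s1 > 0, s1, 1.0))
    emin = np.where(singular, np.inf, emin)

    offset = 0.0
    if energy_kind == "total":
        offset = (
            intramolecular_energy(host, ff).e_intra
            + intramolecular_energy(guest, ff).e_intra
        )
        emin = emin + offset
        boltz = boltz + offset

    pes = PESGrid(
        grid=grid,
        orientations=orients,
        energy_kind=energy_kind,
        temperature=temperature,
        e_min=emin.reshape(shape),
        argmin_orientation=argo.reshape(shape),
        boltzmann=boltz.reshape(shape),
    )
    # global minimum: first occurrence in (Z, Y, X) order
    flat = np.argmin(emin)
    if np.isfinite(emin[flat]):
        iz, iy, ix = np.unravel_index(flat, shape)
        o = int(argo[flat])
        d = Disposition(
            com=np.array([grid.xs[ix], grid.ys[iy], grid.zs[iz]]),
            quaternion=orients.quaternions[o],
        )
        pes.global_min = float(emin[flat])
        pes.global_min_index = (int(iz), int(iy), int(ix))
        pes.global_min_disposition = d
        placed = apply_disposition(guest, d)
        breakdown = intermolecular_energy(host, placed, ff, solvent)
        if energy_kind == "total":
            breakdown = (
                breakdown
                + intramolecular_energy(host, ff)
                + intramolecular_energy(placed, ff)
            )
        pes.global_min_breakdown = breakdown
    return pes


def boltzmann_pes(energies: np.ndarray, temperature: float, axis: int = -1) -> np.ndarray:
    """Boltzmann-weighted average energy over orientations.

    <E> = sum E exp(-E/kT) / sum exp(-E/kT), computed with the minimum
    shifted out of the exponent so large energies underflow harmlessly.
    """
    if temperature <= 0:
        raise DomainError("temperature must be > 0")
    e = np.asarray(energies, dtype=float)
    m = e.min(axis=axis, keepdims=True)
    w = np.exp(-(e - m) / (KB * temperature))
    return np.squeeze(
        (e * w).sum(axis=axis, keepdims=True) / w.sum(axis=axis, keepdims=True),
        axis=axis,
    )


def penetration_potential(pes: PESGrid) -> PenetrationCurve:
    """W(Z): minimum over each Z = const plane of the per-point minima."""
    if pes.energy_kind != "inter":
        raise DomainError(
            "the penetration potential is defined on an intermolecular-energy "
            f"scan; got energy_kind={pes.energy_kind!r}"
        )
    if pes.e_min.size == 0:
        raise DomainError("empty PES grid")
    w = pes.e_min.reshape(pes.e_min.shape[0], -1).min(axis=1)
    return PenetrationCurve(z=pes.grid.zs.copy(), w=w)


def enantioselectivity_map(
    pes_l: PESGrid, pes_d: PESGrid, threshold: float
) -> EnantioMap:
    """Signed L-D differences of the Boltzmann-averaged surfaces.

    Antisymmetric under swapping the two inputs.  Points with |delta| below
    the threshold are dropped; XY and XZ projections keep the largest-
    magnitude signed delta per projected cell.
    """
    if pes_l.grid != pes_d.grid:
        raise DomainError("enantioselectivity map requires identical grids")
    delta = pes_l.boltzmann - pes_d.boltzmann
    zs, ys, xs = pes_l.grid.zs, pes_l.grid.ys, pes_l.grid.xs
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    df = pd.DataFrame(
        {"X": xx.ravel(), "Y": yy.ravel(), "Z": zz.ravel(), "delta": delta.ravel()}
    )
    df = df[np.isfinite(df["delta"]) & (df["delta"].abs() >= threshold)].reset_index(
        drop=True
    )

    def _project(frame: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        if frame.empty:
            return frame[keys + ["delta"]]
        idx = frame.groupby(keys)["delta"].apply(lambda s: s.abs().idxmax())
        return frame.loc[idx.values, keys + ["delta"]].reset_index(drop=True)

    return EnantioMap(
        threshold=threshold,
        points=df,
        xy=_project(df, ["X", "Y"]),
        xz=_project(df, ["X", "Z"]),
    )
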