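"""Trajectory post-processing: residence time, binding free energy,
elution order, occupancy densities and most-probable configurations.

The binding free energy of one trajectory is

    F = -k_B T ln( sum_i exp(-W_i / k_B T) )

over the recorded interaction-energy samples W_i.  As written this is a
log-sum (not a log-mean): it decreases as more low-energy samples
accumulate and always lies at or below min(W_i).  It is evaluated verbatim
per trajectory and then averaged across the trajectories that actually
formed (at least partial) inclusion complexes, giving F_mean per
enantiomer; a log-mean-exp variant is available behind ``normalize=True``
for sensitivity checks.  The elution rule: dF = F_L - F_D > 0 means the D
enantiomer is the more tightly bound and the L enantiomer elutes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import KB
from .errors import DomainError
from .md import Trajectory
from .rigid import Disposition
from .scan import CavityDef, GridSpec

__all__ = [
    "residence_time",
    "is_included",
    "binding_free_energy",
    "elution_order",
    "EnantiomerStats",
    "ChiralReport",
    "aggregate",
    "position_probability_density",
    "OccupancyDensity",
    "most_probable_configuration",
]

#: |dF| below which the elution order is called a tie, kcal/mol.
ELUTION_TIE_TOL = 1e-6


def _inside_mask(traj: Trajectory, cavity: CavityDef) -> np.ndarray:
    """Per-frame flag: any guest atom inside the cavity cylinder
    (inclusion or partial per the cavity classification)."""
    mask = np.empty(traj.n_frames, dtype=bool)
    origin = np.asarray(cavity.origin)
    for k in range(traj.n_frames):
        r = traj.guest_coords(k) - origin
        inside = (r[:, 0] ** 2 + r[:, 1] ** 2 <= cavity.r_c ** 2) & (
            np.abs(r[:, 2]) <= cavity.h_c
        )
        mask[k] = bool(inside.any())
    return mask


def residence_time(traj: Trajectory, cavity: CavityDef) -> float:
    """Longest contiguous span (ps) of recorded frames with the guest at
    least partially inside the cavity — the lifetime of the stable complex,
    not the total time inside."""
    if traj.n_frames == 0:
        raise DomainError("trajectory has no frames")
    mask = _inside_mask(traj, cavity)
    best = run = 0
    for flag in mask:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best * traj.frame_spacing


def is_included(traj: Trajectory, cavity: CavityDef) -> bool:
    """Did the guest ever enter the cavity (totally or partially)?"""
    return bool(_inside_mask(traj, cavity).any())


def binding_free_energy(
    w_samples, temperature: float, normalize: bool = False
) -> float:
    """F = -k_B T ln sum_i exp(-W_i/k_B T)  (log-sum-exp, overflow-safe).

    ``normalize=True`` uses the mean instead of the sum
    (-k_B T ln mean exp), an alternative normalization for sensitivity
    analysis; the default is the verbatim sum.
    """
    w = np.asarray(w_samples, dtype=float)
    if w.size == 0:
        raise DomainError("empty sample list")
    if temperature <= 0:
        raise DomainError("temperature must be > 0")
    kt = KB * temperature
    ls = logsumexp(-w / kt)
    if normalize:
        ls -= np.log(w.size)
    return float(-kt * ls)


def elution_order(f_mean_l: float, f_mean_d: float, tol: float = ELUTION_TIE_TOL):
    """Elution label from mean binding free energies.

    dF = F_L - F_D.  dF > 0: D is more tightly bound, L elutes first
    ('L-first'); dF < 0: 'D-first'; |dF| < tol: 'tie'.
    Returns (label, dF).
    """
    if not (np.isfinite(f_mean_l) and np.isfinite(f_mean_d)):
        raise DomainError("binding free energies must be finite")
    df = f_mean_l - f_mean_d
    if abs(df) < tol:
        return "tie", df
    return ("L-first" if df > 0 else "D-first"), df


@dataclass
class EnantiomerStats:
    """Per-enantiomer aggregate over a trajectory set."""

    f_per_trajectory: list = field(default_factory=list)
    t_per_trajectory: list = field(default_factory=list)
    included: list = field(default_factory=list)  # bool per trajectory
    f_mean: float = np.nan  # over included trajectories
    t_mean: float = np.nan  # over included trajectories
    t_mean_all: float = np.nan  # over all trajectories
    n_trajectories: int = 0
    n_included: int = 0


@dataclass
class ChiralReport:
    """Chiral-discrimination summary for an enantiomer pair."""

    stats_l: EnantiomerStats
    stats_d: EnantiomerStats
    delta_f: float = np.nan  # F_L - F_D
    elution: str = "undetermined"
    temperature: float = 293.0

    def to_row(self, variant: str = "n/a", epsilon: float = 1.0) -> dict:
        return {
            "variant": variant,
            "epsilon": epsilon,
            "n_trajectories_L": self.stats_l.n_included,
            "n_trajectories_D": self.stats_d.n_included,
            "F_mean_L": self.stats_l.f_mean,
            "F_mean_D": self.stats_d.f_mean,
            "delta_F": self.delta_f,
            "elution": self.elution,
            "t_mean_L": self.stats_l.t_mean,
            "t_mean_D": self.stats_d.t_mean,
        }


def _stats(trajs, cavity: CavityDef, temperature: float) -> EnantiomerStats:
    st = EnantiomerStats(n_trajectories=len(trajs))
    for traj in trajs:
        st.f_per_trajectory.append(binding_free_energy(traj.W, temperature))
        st.t_per_trajectory.append(residence_time(traj, cavity))
        st.included.append(is_included(traj, cavity))
    st.n_included = int(np.sum(st.included))
    if st.t_per_trajectory:
        st.t_mean_all = float(np.mean(st.t_per_trajectory))
    if st.n_included:
        inc = np.asarray(st.included)
        st.f_mean = float(np.mean(np.asarray(st.f_per_trajectory)[inc]))
        st.t_mean = float(np.mean(np.asarray(st.t_per_trajectory)[inc]))
    return st


def aggregate(
    trajs_l,
    trajs_d,
    cavity: CavityDef,
    temperature: float = 293.0,
) -> ChiralReport:
    """Build the chiral report for matched L/D trajectory sets.

    F_mean and t_mean average over *included* trajectories only (those
    that were at least partially inside the cavity at some frame);
    external trajectories are counted but excluded.  t_mean over all
    trajectories is reported alongside.  If either enantiomer has no
    included trajectory the report is flagged 'undetermined'.
    """
    report = ChiralReport(
        stats_l=_stats(trajs_l, cavity, temperature),
        stats_d=_stats(trajs_d, cavity, temperature),
        temperature=temperature,
    )
    if report.stats_l.n_included and report.stats_d.n_included:
        report.elution, report.delta_f = elution_order(
            report.stats_l.f_mean, report.stats_d.f_mean
        )
    return report


@dataclass
class OccupancyDensity:
    """Normalized COM position histogram over grid voxels.

    ``density`` sums to 1 over in-grid frames; frames falling outside the
    grid are counted in ``n_overflow`` (and excluded from the
    normalization denominator only if every frame overflowed).
    """

    grid: GridSpec
    density: np.ndarray  # (nz, ny, nx)
    n_frames: int
    n_overflow: int

    def xz_projection(self) -> pd.DataFrame:
        proj = self.density.sum(axis=1)  # sum over Y
        zz, xx = np.meshgrid(self.grid.zs, self.grid.xs, indexing="ij")
        return pd.DataFrame({"X": xx.ravel(), "Z": zz.ravel(), "density": proj.ravel()})

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: X, Y, Z, density (one row per voxel)."""
        zz, yy, xx = np.meshgrid(
            self.grid.zs, self.grid.ys, self.grid.xs, indexing="ij"
        )
        return pd.DataFrame(
            {
                "X": xx.ravel(),
                "Y": yy.ravel(),
                "Z": zz.ravel(),
                "density": self.density.ravel(),
            }
        )


def position_probability_density(trajs, grid: GridSpec) -> OccupancyDensity:
    """Histogram of guest COM positions over grid voxels, normalized to
    total probability 1 — the number density in each volume element divided
    by the total number of recorded COM positions."""
    coms = np.concatenate([t.coms for t in trajs], axis=0)
    if coms.shape[0] == 0:
        raise DomainError("no frames to histogram")
    edges = []
    for k in range(3):
        ax = grid.axis(k)
        edges.append(np.concatenate([ax - grid.spacing / 2, [ax[-1] + grid.spacing / 2]]))
    hist, _ = np.histogramdd(coms, bins=edges)
    hist = hist.transpose(2, 1, 0)  # (nx,ny,nz) -> (nz,ny,nx)
    n_in = int(hist.sum())
    n_overflow = coms.shape[0] - n_in
    density = hist / n_in if n_in > 0 else hist
    return OccupancyDensity(
        grid=grid, density=density, n_frames=coms.shape[0], n_overflow=n_overflow
    )


def most_probable_configuration(
    trajs, density: OccupancyDensity
) -> list[Disposition]:
    """Representative disposition(s) of the modal density voxel(s).

    For each voxel tied at the maximum density, the orientations of all
    frames falling in that voxel are averaged (unit-quaternion mean via the
    largest eigenvector of the outer-product accumulation, sign-aligned to
    the first frame) and returned with the mean COM of those frames.
    """
    dens = density.density
    if dens.max() <= 0:
        raise DomainError("empty density")
    maxval = dens.max()
    modal = np.argwhere(np.isclose(dens, maxval, rtol=0.0, atol=1e-15))
    grid = density.grid
    xs, ys, zs = grid.xs, grid.ys, grid.zs
    half = grid.spacing / 2

    coms = np.concatenate([t.coms for t in trajs], axis=0)
    quats = np.concatenate([t.quaternions for t in trajs], axis=0)

    out = []
    for iz, iy, ix in modal:
        sel = (
            (np.abs(coms[:, 0] - xs[ix]) <= half)
            & (np.abs(coms[:, 1] - ys[iy]) <= half)
            & (np.abs(coms[:, 2] - zs[iz]) <= half)
        )
        q = quats[sel]
        if q.shape[0] == 0:
            continue
        signs = np.where(q @ q[0] < 0, -1.0, 1.0)
        q = q * signs[:, None]
        m = q.T @ q
        w, v = np.linalg.eigh(m)
        qbar = v[:, -1]
        if qbar @ q[0] < 0:
            qbar = -qbar
        qbar = qbar / np.linalg.norm(qbar)
        out.append(Disposition(com=coms[sel].mean(axis=0), quaternion=qbar))
    return out
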