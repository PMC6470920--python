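"""File I/O: structures (PDB/XYZ + metadata sidecar), force-field parameter
files, run configuration, energy reports and trajectory output.

Coordinate files carry what the format can hold — PDB (fixed format, 3
decimals) or XYZ (full precision).  Masses, charges, LJ types, H-bond
roles and the bonded topology do not fit either format and live in a YAML
sidecar written next to the coordinate file (``<file>.meta.yml``); reading
a bare PDB/XYZ without a sidecar falls back to inferred topology and
element-table masses, flagged on the returned structure.  Parameter files
are strict: unknown keys are rejected.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .forcefield import EnergyBreakdown, ForceFieldParams
from .md import MDConfig, Trajectory
from .scan import GridSpec, PESGrid, PenetrationCurve
from .structure import AtomRecord, ELEMENT_MASSES, Structure, infer_topology

__all__ = [
    "read_structure",
    "write_structure",
    "read_forcefield",
    "write_forcefield",
    "RunConfig",
    "write_energy_report",
    "write_pes_csv",
    "write_trajectory_xyz",
    "write_trajectory_csv",
]


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".meta.yml")


def write_structure(s: Structure, path, fmt: str | None = None) -> None:
    """Write coordinates (PDB or XYZ by extension/fmt) plus the metadata
    sidecar carrying charges, masses, types and topology."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        lines = []
        for a, (x, y, z) in zip(s.atoms, s.coords):
            name = (a.name or a.element)[:4]
            lines.append(
                f"HETATM{a.id + 1:5d} {name:<4s} LIG A{1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2s}"
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "xyz":
        lines = [str(s.n_atoms), s.conformer or "chiroscan structure"]
        for a, (x, y, z) in zip(s.atoms, s.coords):
            lines.append(f"{a.element:<2s} {x:.10f} {y:.10f} {z:.10f}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ParseError(f"unsupported structure format {fmt!r}")
    meta = {
        "conformer": s.conformer,
        "variant": s.variant,
        "atoms": [
            {
                "id": a.id,
                "element": a.element,
                "name": a.name,
                "mass": float(a.mass),
                "charge": float(a.charge),
                "lj_type": a.lj_type,
                "hbond_role": a.hbond_role,
            }
            for a in s.atoms
        ],
        "bonds": [[i, j, t] for i, j, t in s.bonds],
        "angles": [[i, j, k, t] for i, j, k, t in s.angles],
        "dihedrals": [[i, j, k, l, t] for i, j, k, l, t in s.dihedrals],
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def _read_pdb_coords(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        model = parser.get_structure("s", str(path))
    elements, names, coords = [], [], []
    for atom in model.get_atoms():
        el = (atom.element or atom.get_name()[0]).strip().capitalize()
        elements.append(el)
        names.append(atom.get_name())
        coords.append(atom.get_coord().astype(float))
    if not coords:
        raise ParseError(f"{path}: no atoms found")
    return elements, names, np.array(coords)


def _read_xyz_coords(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 1: expected an atom count") from None
    elements, names, coords = [], [], []
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {ln}: expected 'element x y z'")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}: line {ln}: bad coordinate") from None
        elements.append(parts[0].capitalize())
        names.append(parts[0])
        coords.append(xyz)
    if len(coords) != n:
        raise ParseError(f"{path}: expected {n} atoms, found {len(coords)}")
    return elements, names, np.array(coords)


def read_structure(path, fmt: str | None = None) -> Structure:
    """Read a structure; metadata comes from the sidecar when present,
    otherwise topology is inferred by the covalent-distance rule and the
    result flagged ``inferred_topology``."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        elements, names, coords = _read_pdb_coords(path)
    elif fmt == "xyz":
        elements, names, coords = _read_xyz_coords(path)
    else:
        raise ParseError(f"unsupported structure format {fmt!r}")

    side = _sidecar(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text())
        atoms = [
            AtomRecord(
                id=a["id"],
                element=a["element"],
                mass=a["mass"],
                charge=a["charge"],
                lj_type=a["lj_type"],
                hbond_role=a["hbond_role"],
                name=a.get("name", ""),
            )
            for a in meta["atoms"]
        ]
        if len(atoms) != len(coords):
            raise ParseError(f"{side}: atom count does not match {path}")
        return Structure(
            atoms=atoms,
            coords=coords,
            bonds=[tuple(b[:2]) + (b[2],) for b in meta.get("bonds", [])],
            angles=[tuple(a[:3]) + (a[3],) for a in meta.get("angles", [])],
            dihedrals=[tuple(d[:4]) + (d[4],) for d in meta.get("dihedrals", [])],
            conformer=meta.get("conformer", ""),
            variant=meta.get("variant", "n/a"),
        )
    atoms = [
        AtomRecord(
            id=i,
            element=el,
            mass=ELEMENT_MASSES.get(el, 1.0),
            name=nm,
        )
        for i, (el, nm) in enumerate(zip(elements, names))
    ]
    bare = Structure(atoms=atoms, coords=coords)
    return infer_topology(bare)


# ---------------------------------------------------------------------------
# force-field parameter files
# ---------------------------------------------------------------------------

_FF_KEYS = {"units", "coulomb_constant", "lj_pairs", "hbond_pairs", "bonds", "angles", "torsions"}
_FF_UNITS = {
    "energy": "kcal/mol",
    "length": "angstrom",
    "charge": "e",
    "angle": "rad",
}


def write_forcefield(ff: ForceFieldParams, path) -> None:
    doc = {
        "units": dict(_FF_UNITS),
        "coulomb_constant": float(ff.coulomb_constant),
        "lj_pairs": {f"{a},{b}": [float(x) for x in v] for (a, b), v in ff.lj_pairs.items()},
        "hbond_pairs": {f"{a},{b}": [float(x) for x in v] for (a, b), v in ff.hbond_pairs.items()},
        "bonds": {k: [float(x) for x in v] for k, v in ff.bonds.items()},
        "angles": {k: [float(x) for x in v] for k, v in ff.angles.items()},
        "torsions": {
            k: [[float(v_n), int(n), float(g)] for v_n, n, g in terms]
            for k, terms in ff.torsions.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_forcefield(path) -> ForceFieldParams:
    """Strict parse: unknown top-level keys and malformed entries are
    rejected."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: expected a mapping at the top level")
    unknown = set(doc) - _FF_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown keys {sorted(unknown)}")

    def _pair_key(key: str) -> tuple[str, str]:
        parts = [p.strip() for p in key.split(",")]
        if len(parts) != 2:
            raise ParseError(f"{path}: pair key {key!r} must be 'type1,type2'")
        return parts[0], parts[1]

    try:
        return ForceFieldParams(
            lj_pairs={_pair_key(k): tuple(map(float, v)) for k, v in doc.get("lj_pairs", {}).items()},
            hbond_pairs={_pair_key(k): tuple(map(float, v)) for k, v in doc.get("hbond_pairs", {}).items()},
            bonds={k: tuple(map(float, v)) for k, v in doc.get("bonds", {}).items()},
            angles={k: tuple(map(float, v)) for k, v in doc.get("angles", {}).items()},
            torsions={
                k: [(float(t[0]), int(t[1]), float(t[2])) for t in terms]
                for k, terms in doc.get("torsions", {}).items()
            },
            coulomb_constant=float(doc.get("coulomb_constant", 332.0522)),
        )
    except (TypeError, ValueError, IndexError) as exc:
        raise ParseError(f"{path}: malformed parameter entry ({exc})") from None


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a scan or MD run needs, round-trippable through YAML."""

    epsilon: float = 1.0
    variant: str = "NP"
    seed: int = 0
    preset: str = "coarse"
    dt: float = 0.001
    t_s: float = 50.0
    record_every: int = 100
    temperature: float = 293.0
    n_per_rim: int = 5
    grid_bounds: tuple = ((-5.0, 5.0), (-5.0, 5.0), (-5.0, 5.0))
    grid_spacing: float = 0.5

    def md_config(self, seed: int | None = None) -> MDConfig:
        return MDConfig(
            dt=self.dt,
            t_s=self.t_s,
            record_every=self.record_every,
            temperature=self.temperature,
            seed=self.seed if seed is None else seed,
        )

    def grid(self) -> GridSpec:
        return GridSpec(bounds=self.grid_bounds, spacing=self.grid_spacing)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["grid_bounds"] = [list(b) for b in self.grid_bounds]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ParseError(f"{path}: unknown keys {sorted(unknown)}")
        if "grid_bounds" in doc:
            doc["grid_bounds"] = tuple(tuple(b) for b in doc["grid_bounds"])
        return cls(**doc)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_energy_report(rows: list[tuple[str, EnergyBreakdown]], path) -> None:
    """CSV with the seven breakdown columns per labeled configuration."""
    records = []
    for label, b in rows:
        rec = {"label": label}
        rec.update(
            {
                "E_min": b.e_total,
                "E_LJ": b.e_lj,
                "E_ele": b.e_ele,
                "E_Hbond": b.e_hbond,
                "E_bond": b.e_bond,
                "E_angle": b.e_angle,
                "E_torsion": b.e_torsion,
            }
        )
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def write_pes_csv(pes: PESGrid, path, meta_path=None, extra_meta: dict | None = None) -> None:
    """Long-format CSV (X,Y,Z,e_min,boltzmann,...) + JSON metadata sidecar."""
    pes.to_frame().to_csv(path, index=False)
    meta = {
        "grid_bounds": [list(b) for b in pes.grid.bounds],
        "grid_spacing": pes.grid.spacing,
        "orientation_counts": list(pes.orientations.counts or []),
        "n_orientations": len(pes.orientations),
        "energy_kind": pes.energy_kind,
        "temperature": pes.temperature,
        "global_min": pes.global_min,
    }
    if extra_meta:
        meta.update(extra_meta)
    meta_path = Path(meta_path) if meta_path else Path(str(path) + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2))


def write_trajectory_xyz(traj: Trajectory, guest: Structure, path) -> None:
    """Extended XYZ: guest atoms per frame, comment line with time, W_i and
    kinetic energies."""
    buf = _io.StringIO()
    for k in range(traj.n_frames):
        coords = traj.guest_coords(k)
        buf.write(f"{guest.n_atoms}\n")
        buf.write(
            f"time_ps={traj.times[k]:.6f} W={traj.W[k]:.8f} "
            f"KE_trans={traj.ke_trans[k]:.8f} KE_rot={traj.ke_rot[k]:.8f}\n"
        )
        for a, (x, y, z) in zip(guest.atoms, coords):
            buf.write(f"{a.element:<2s} {x:.6f} {y:.6f} {z:.6f}\n")
    Path(path).write_text(buf.getvalue())


def write_trajectory_csv(traj: Trajectory, path) -> None:
    df = pd.DataFrame(
        {
            "time_ps": traj.times,
            "x": traj.coms[:, 0],
            "y": traj.coms[:, 1],
            "z": traj.coms[:, 2],
            "qw": traj.quaternions[:, 0],
            "qx": traj.quaternions[:, 1],
            "qy": traj.quaternions[:, 2],
            "qz": traj.quaternions[:, 3],
            "W": traj.W,
            "KE_trans": traj.ke_trans,
            "KE_rot": traj.ke_rot,
        }
    )
    df.to_csv(path, index=False)
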