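"""Topology, trajectory and condition-manifest I/O.

Formats
-------
* PDB — topology and multi-frame coordinates (MODEL/ENDMDL).  Files store
  ångström per the format convention; everything in memory is nm.  Parsing
  and atom selections go through MDAnalysis; writing uses an in-package
  fixed-column formatter (3 decimal places) so round trips are bit-exact at
  the format's precision.  Frame times for PDB trajectories come from a
  sidecar CSV (columns ``frame,time_ps``); if absent, a 10 ps interval is
  assumed with a logged warning.
* XYZ — a plain dialect whose per-frame comment line carries the time, e.g.
  ``t= 120.0 ps``; coordinates in Å, 3 decimals.
* CSV — condition manifests and outcome tables (pandas).

Residue numbering is 1-based as in PDB.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ManifestError",
    "Topology",
    "Trajectory",
    "ConditionSpec",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_manifest",
    "write_manifest",
    "AMINO_ACID_RESNAMES",
]

ANGSTROM_PER_NM = 10.0
DEFAULT_FRAME_INTERVAL_PS = 10.0

AMINO_ACID_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL".split()
)


class FormatError(ValueError):
    """A structure/coordinate file violates its format."""


class ManifestError(ValueError):
    """A condition manifest is missing columns or holds invalid values."""


@dataclass
class Topology:
    """Named atoms of the system, with the mononucleotide flagged as solute."""

    atom_ids: np.ndarray
    atom_names: list[str]
    elements: list[str]
    residue_names: list[str]
    residue_numbers: np.ndarray
    chain_ids: list[str]
    solute_flag: np.ndarray
    _universe: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=int)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.solute_flag = np.asarray(self.solute_flag, dtype=bool)
        if len(set(self.atom_ids.tolist())) != len(self.atom_ids):
            raise FormatError("atom ids are not unique")
        if not self.solute_flag.any():
            raise FormatError("topology contains no solute atoms")
        if self.solute_flag.all():
            raise FormatError("topology contains no protein atoms")

    @property
    def n_atoms(self) -> int:
        return int(len(self.atom_ids))

    @property
    def solute_indices(self) -> np.ndarray:
        return np.flatnonzero(self.solute_flag)

    @property
    def protein_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.solute_flag)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (residue_name, residue_number) pairs, in file order."""
        seen: dict[tuple[str, int], None] = {}
        for name, num in zip(self.residue_names, self.residue_numbers):
            seen.setdefault((name, int(num)), None)
        return list(seen)

    def select(self, residue_name: str | None = None,
               residue_number: int | None = None,
               atom_name: str | None = None) -> np.ndarray:
        """Indices of atoms matching all given (residue name, number, atom name)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue_name is not None:
            mask &= np.array([r == residue_name for r in self.residue_names])
        if residue_number is not None:
            mask &= self.residue_numbers == residue_number
        if atom_name is not None:
            mask &= np.array([a == atom_name for a in self.atom_names])
        return np.flatnonzero(mask)

    def select_atoms(self, selection: str) -> np.ndarray:
        """MDAnalysis selection-language query; returns atom indices."""
        return self._mda_universe().select_atoms(selection).ix

    def _mda_universe(self):
        if self._universe is None:
            import MDAnalysis as mda

            u = mda.Universe.empty(
                self.n_atoms,
                n_residues=self.n_atoms,
                atom_resindex=np.arange(self.n_atoms),
                trajectory=True,
            )
            u.add_TopologyAttr("name", self.atom_names)
            u.add_TopologyAttr("resname", self.residue_names)
            u.add_TopologyAttr("resid", self.residue_numbers)
            self._universe = u
        return self._universe


@dataclass
class Trajectory:
    """Per-frame solute+protein coordinates (nm) on a uniform time axis (ps)."""

    topology: Topology
    times: np.ndarray
    coordinates: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise FormatError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] != len(self.times):
            raise FormatError("number of frames and times differ")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"coordinate atom count {self.coordinates.shape[1]} does not "
                f"match topology atom count {self.topology.n_atoms}"
            )
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise FormatError("frame times are not strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-6):
                raise FormatError("frame times are not uniformly spaced")

    @property
    def n_frames(self) -> int:
        return int(len(self.times))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n_frames else 0.0

    def solute_coordinates(self, frame: int) -> np.ndarray:
        return self.coordinates[frame, self.topology.solute_indices]


@dataclass(frozen=True)
class ConditionSpec:
    """One simulation condition: release point, orientation and replicate."""

    height: float           # nm above the K8 ring along the pore axis
    translation: float      # nm lateral offset from the pore axis
    orientation: str        # "up" | "down" (phosphate orientation)
    replicate: int
    duration: float = 5000.0  # ps
    seed: int = 0
    trajectory_path: str | None = None

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ManifestError("height must be >= 0")
        if self.translation < 0:
            raise ManifestError("translation must be >= 0")
        if self.orientation not in ("up", "down"):
            raise ManifestError(
                f"orientation must be 'up' or 'down', got {self.orientation!r}"
            )
        if self.replicate < 1:
            raise ManifestError("replicate must be >= 1")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial, name, resname, chain, resnum, xyz_ang, element) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name_field} {resname:<3s} {chain:1s}{resnum:>4d}"
        f"    {xyz_ang[0]:8.3f}{xyz_ang[1]:8.3f}{xyz_ang[2]:8.3f}"
        f"  1.00  0.00          {element:>2s}"
    )


def write_topology(topology: Topology, path,
                   coordinates: np.ndarray | None = None) -> None:
    """Write a single-model PDB.  `coordinates` in nm; defaults to zeros."""
    coords = (
        np.zeros((topology.n_atoms, 3))
        if coordinates is None
        else np.asarray(coordinates, dtype=float)
    )
    lines = []
    for i in range(topology.n_atoms):
        lines.append(
            _pdb_atom_line(
                int(topology.atom_ids[i]),
                topology.atom_names[i],
                topology.residue_names[i],
                topology.chain_ids[i],
                int(topology.residue_numbers[i]),
                coords[i] * ANGSTROM_PER_NM,
                topology.elements[i],
            )
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path, solute_resnames: set[str] | None = None) -> Topology:
    """Parse a PDB topology via MDAnalysis.

    The solute (mononucleotide) is identified by residue name: either the
    explicit ``solute_resnames`` set, or by default any residue whose name is
    not a standard amino acid.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except (ValueError, IndexError, EOFError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise FormatError(f"no ATOM/HETATM records in {path}")

    resnames = [str(r) for r in u.atoms.resnames]
    if solute_resnames is None:
        solute = np.array([r not in AMINO_ACID_RESNAMES for r in resnames])
    else:
        solute = np.array([r in solute_resnames for r in resnames])
    if not solute.any():
        raise FormatError(f"no solute residue found in {path}")

    def _elements():
        try:
            return [str(e) for e in u.atoms.elements]
        except (AttributeError, mda.exceptions.NoDataError):
            return [str(n)[0] for n in u.atoms.names]

    return Topology(
        atom_ids=np.asarray(u.atoms.ids, dtype=int),
        atom_names=[str(n) for n in u.atoms.names],
        elements=_elements(),
        residue_names=resnames,
        residue_numbers=np.asarray(u.atoms.resids, dtype=int),
        chain_ids=[
            str(s) if str(s).strip() else "A"
            for s in getattr(u.atoms, "segids", ["A"] * len(u.atoms))
        ],
        solute_flag=solute,
        _universe=u,
    )


def write_trajectory(traj: Trajectory, path, times_csv=None) -> None:
    """Write a trajectory as multi-frame PDB (+ sidecar time CSV) or XYZ."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        _write_xyz(traj, path)
        return
    top = traj.topology
    lines = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:>4d}")
        for i in range(top.n_atoms):
            lines.append(
                _pdb_atom_line(
                    int(top.atom_ids[i]),
                    top.atom_names[i],
                    top.residue_names[i],
                    top.chain_ids[i],
                    int(top.residue_numbers[i]),
                    traj.coordinates[f, i] * ANGSTROM_PER_NM,
                    top.elements[i],
                )
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    if times_csv is None:
        times_csv = path.with_suffix(".times.csv")
    pd.DataFrame(
        {"frame": np.arange(traj.n_frames), "time_ps": traj.times}
    ).to_csv(times_csv, index=False)


def _write_xyz(traj: Trajectory, path: Path) -> None:
    top = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{top.n_atoms}\n")
            fh.write(f"t= {traj.times[f]:.3f} ps\n")
            for i in range(top.n_atoms):
                x, y, z = traj.coordinates[f, i] * ANGSTROM_PER_NM
                fh.write(f"{top.atom_names[i]:<4s} {x:12.3f} {y:12.3f} {z:12.3f}\n")


def read_trajectory(topology: Topology, path, times_csv=None) -> Trajectory:
    """Read a multi-frame PDB or XYZ coordinate series against a topology.

    Frames must be in time order; the frame interval is inferred from the
    time axis.  For PDB, times come from ``times_csv`` (default: the sidecar
    ``<name>.times.csv`` next to the file) or fall back to a 10 ps interval
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".xyz":
        times, coords = _read_xyz(path, topology.n_atoms)
    else:
        coords = _read_pdb_frames(path, topology.n_atoms)
        n = coords.shape[0]
        if times_csv is None:
            candidate = path.with_suffix(".times.csv")
            times_csv = candidate if candidate.exists() else None
        if times_csv is not None:
            tdf = pd.read_csv(times_csv)
            if len(tdf) != n:
                raise FormatError(
                    f"time index has {len(tdf)} rows for {n} frames"
                )
            times = tdf["time_ps"].to_numpy(dtype=float)
        else:
            logger.warning(
                "no frame-time index for %s; assuming %.0f ps interval",
                path, DEFAULT_FRAME_INTERVAL_PS,
            )
            times = np.arange(n) * DEFAULT_FRAME_INTERVAL_PS
    interval = float(times[1] - times[0]) if len(times) > 1 else DEFAULT_FRAME_INTERVAL_PS
    return Trajectory(
        topology=topology, times=times, coordinates=coords,
        frame_interval=interval,
    )


def _read_pdb_frames(path: Path, n_atoms: int) -> np.ndarray:
    frames: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:  # single-model file without MODEL records
                    current = []
                try:
                    current.append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                except ValueError as exc:
                    raise FormatError(
                        f"bad coordinate field at line {lineno} of {path}"
                    ) from exc
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(current)
                    current = None
    if current is not None and current:
        frames.append(current)
    if not frames:
        raise FormatError(f"no coordinate frames found in {path}")
    for i, fr in enumerate(frames):
        if len(fr) != n_atoms:
            raise FormatError(
                f"frame {i} of {path} has {len(fr)} atoms, expected {n_atoms}"
            )
    return np.asarray(frames, dtype=float) / ANGSTROM_PER_NM


def _read_xyz(path: Path, n_atoms: int) -> tuple[np.ndarray, np.ndarray]:
    times: list[float] = []
    frames: list[list[list[float]]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(
                f"expected atom count at line {i + 1} of {path}"
            ) from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = _parse_xyz_time(comment)
        if t is None:
            logger.warning("frame %d of %s has no time tag", frame_idx, path)
            t = frame_idx * DEFAULT_FRAME_INTERVAL_PS
        body = lines[i + 2:i + 2 + count]
        if len(body) < count:
            raise FormatError(
                f"frame {frame_idx} of {path} is truncated "
                f"({len(body)} of {count} atoms)"
            )
        coords = []
        for row in body:
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(
                    f"frame {frame_idx} of {path}: bad atom row {row!r}"
                )
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if count != n_atoms:
            raise FormatError(
                f"frame {frame_idx} of {path} has {count} atoms, "
                f"expected {n_atoms}"
            )
        frames.append(coords)
        times.append(t)
        i += 2 + count
        frame_idx += 1
    if not frames:
        raise FormatError(f"no frames in {path}")
    return np.asarray(times), np.asarray(frames, dtype=float) / ANGSTROM_PER_NM


def _parse_xyz_time(comment: str) -> float | None:
    tokens = comment.replace("=", "= ").split()
    for j, tok in enumerate(tokens):
        if tok in ("t=", "time=") and j + 1 < len(tokens):
            try:
                return float(tokens[j + 1])
            except ValueError:
                return None
    return None


# ---------------------------------------------------------------------------
# Condition manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("height", "translation", "orientation", "replicate",
                    "trajectory_path", "seed")


def read_manifest(path) -> list[ConditionSpec]:
    """Read a condition manifest CSV into ConditionSpecs.

    Required columns: height, translation, orientation, replicate,
    trajectory_path, seed.  An optional ``units`` column ("nm" | "angstrom")
    sets the length unit of height/translation (default nm); an optional
    ``duration_ps`` column overrides the 5 ns default.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} missing columns: {missing}")
    if df.empty:
        logger.warning("manifest %s is empty", path)
        return []
    specs = []
    for idx, row in df.iterrows():
        units = str(row.get("units", "nm")).strip().lower()
        if units in ("nm", "nan", ""):
            scale = 1.0
        elif units in ("angstrom", "ang", "a", "å"):
            scale = 0.1
        else:
            raise ManifestError(f"row {idx}: unknown units {units!r}")
        orientation = str(row["orientation"]).strip().lower()
        if orientation not in ("up", "down"):
            raise ManifestError(
                f"row {idx}: unknown orientation token {row['orientation']!r}"
            )
        tp = row["trajectory_path"]
        specs.append(
            ConditionSpec(
                height=float(row["height"]) * scale,
                translation=float(row["translation"]) * scale,
                orientation=orientation,
                replicate=int(row["replicate"]),
                duration=float(row.get("duration_ps", 5000.0))
                if not pd.isna(row.get("duration_ps", np.nan)) else 5000.0,
                seed=int(row["seed"]),
                trajectory_path=None if pd.isna(tp) else str(tp),
            )
        )
    return specs


def write_manifest(specs: list[ConditionSpec], path) -> None:
    pd.DataFrame(
        [
            {
                "height": s.height,
                "translation": s.translation,
                "orientation": s.orientation,
                "replicate": s.replicate,
                "trajectory_path": s.trajectory_path or "",
                "seed": s.seed,
                "units": "nm",
                "duration_ps": s.duration,
            }
            for s in specs
        ]
    ).to_csv(path, index=False)
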