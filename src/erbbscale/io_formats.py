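"""Structure/trajectory I/O and tabular reports.

Everything downstream of this module consumes only the in-memory types
defined here: :class:`Atom`, :class:`StructureModel` (a static set of
atoms with optional periodic box) and :class:`TrajectoryEnsemble`
(frames of coordinates over a fixed topology).

Coordinates are always in Angstrom internally.  The XTC dialect stores
nanometres on disk; conversion happens at the read/write boundary (via
MDAnalysis unit handling).  Residue numbering is taken verbatim from
the file (author numbering) and never renumbered, because the residue
labels used throughout the kinase literature (L834, K721, ...) are
author numbers.  Alternate-location indicators: conformer 'A' or blank
is kept, all others are dropped, so a file always yields a single
deterministic conformer.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from erbbscale.errors import (
    EmptyInputError,
    ParseError,
    SchemaError,
    ShapeError,
    UsageError,
)

#: Residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``residue_id`` is the author residue number taken verbatim from the
    source file; ``position`` is in Angstrom.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ShapeError(f"atom position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise UsageError(f"atom {self.serial} has non-finite position {pos}")
        if not self.element:
            raise UsageError(f"atom {self.serial} has empty element symbol")
        object.__setattr__(self, "position", pos)

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESNAMES


@dataclass
class StructureModel:
    """An ordered list of atoms plus optional periodic box (Angstrom)."""

    atoms: list[Atom]
    box: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise UsageError("atom serials are not unique")
        if self.box is not None:
            box = np.asarray(self.box, dtype=float)
            if box.shape != (3,):
                raise ShapeError(f"box must be a 3-vector, got shape {box.shape}")
            if not np.all(box > 0):
                raise UsageError(f"box components must be > 0, got {box}")
            self.box = box

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate matrix in Angstrom."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.vstack([a.position for a in self.atoms])

    def water_indices(self) -> np.ndarray:
        """Indices of atoms belonging to water residues."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.is_water], dtype=int
        )

    def water_oxygen_indices(self) -> np.ndarray:
        """Indices of water oxygen atoms (one per water molecule)."""
        return np.array(
            [
                i
                for i, a in enumerate(self.atoms)
                if a.is_water and a.element.upper() == "O"
            ],
            dtype=int,
        )

    def count_waters(self) -> int:
        """Number of distinct water residues."""
        seen = {
            (a.chain, a.residue_id, a.residue_name)
            for a in self.atoms
            if a.is_water
        }
        return len(seen)

    def select(self, atom_name: str | None = None, heavy: bool = False) -> np.ndarray:
        """Indices of atoms by name (e.g. ``"CA"``) and/or heavy-atom filter."""
        idx = []
        for i, a in enumerate(self.atoms):
            if atom_name is not None and a.name != atom_name:
                continue
            if heavy and a.element.upper() == "H":
                continue
            idx.append(i)
        return np.array(idx, dtype=int)

    def residue_atom_indices(
        self, residue_ids: Iterable[int], heavy: bool = True, exclude_water: bool = True
    ) -> np.ndarray:
        """Indices of (heavy) atoms in the given author residue numbers."""
        wanted = set(residue_ids)
        idx = []
        for i, a in enumerate(self.atoms):
            if a.residue_id not in wanted:
                continue
            if heavy and a.element.upper() == "H":
                continue
            if exclude_water and a.is_water:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)


@dataclass
class TrajectoryEnsemble:
    """Frames of coordinates over a fixed topology.

    ``frames`` is (n_frames, n_atoms, 3) in Angstrom; ``timestep`` is
    picoseconds per frame.
    """

    topology: StructureModel
    frames: np.ndarray
    timestep: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ShapeError(
                f"frames must have shape (n_frames, n_atoms, 3), got {frames.shape}"
            )
        if frames.shape[0] < 1:
            raise UsageError("a trajectory needs at least one frame")
        if frames.shape[1] != self.topology.n_atoms:
            raise ShapeError(
                f"frame atom count {frames.shape[1]} does not match topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.timestep <= 0:
            raise UsageError(f"timestep must be > 0, got {self.timestep}")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])


# ---------------------------------------------------------------------------
# PDB reading / writing (ATOM/HETATM/MODEL/CRYST1 subset)
# ---------------------------------------------------------------------------


def _parse_float(text: str, what: str, lineno: int, line: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"line {lineno}: malformed {what} field {text.strip()!r}: {line.rstrip()}"
        ) from None


def _guess_element(atom_name: str, residue_name: str) -> str:
    """Element from the atom-name column when columns 77-78 are absent."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if residue_name in WATER_RESNAMES and stripped[0] == "O":
        return "O"
    two = stripped[:2].upper()
    if two in {"CL", "BR", "NA", "MG", "ZN", "FE", "CA"} and len(atom_name.strip()) <= 2:
        # Only trust two-letter elements for short names (CA in a protein is Calpha).
        if two != "CA":
            return two.capitalize()
    return stripped[0].upper()


def _parse_pdb_atom(line: str, lineno: int) -> Atom | None:
    """Parse one ATOM/HETATM record; returns None for dropped altlocs."""
    padded = line.rstrip("\n").ljust(80)
    altloc = padded[16]
    if altloc not in (" ", "A"):
        return None
    name = padded[12:16].strip()
    resname = padded[17:20].strip()
    try:
        serial = int(padded[6:11])
    except ValueError:
        raise ParseError(
            f"line {lineno}: malformed serial field {padded[6:11].strip()!r}"
        ) from None
    try:
        resid = int(padded[22:26])
    except ValueError:
        raise ParseError(
            f"line {lineno}: malformed residue number {padded[22:26].strip()!r}"
        ) from None
    x = _parse_float(padded[30:38], "x coordinate", lineno, line)
    y = _parse_float(padded[38:46], "y coordinate", lineno, line)
    z = _parse_float(padded[46:54], "z coordinate", lineno, line)
    element = padded[76:78].strip() or _guess_element(name, resname)
    chain = padded[21] if padded[21] != " " else "A"
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        residue_id=resid,
        chain=chain,
        position=np.array([x, y, z]),
    )


def read_structure(path: str | Path, dialect: str = "pdb") -> StructureModel:
    """Read a structure file into a :class:`StructureModel`.

    Atoms are returned in file order; waters stay in the model and are
    identifiable by residue name (HOH/WAT/TIP3/SOL).  A CRYST1 record,
    if present, populates the box.  For multi-model files only the
    first MODEL is read (use :func:`read_trajectory` for all frames).
    """
    if dialect != "pdb":
        raise UsageError(f"unknown structure dialect {dialect!r}; supported: pdb")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    atoms: list[Atom] = []
    box: np.ndarray | None = None
    in_first_model = True
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                padded = line.ljust(80)
                box = np.array(
                    [
                        _parse_float(padded[6:15], "box a", lineno, line),
                        _parse_float(padded[15:24], "box b", lineno, line),
                        _parse_float(padded[24:33], "box c", lineno, line),
                    ]
                )
            elif rec == "MODEL":
                if saw_model:
                    in_first_model = False
                saw_model = True
            elif rec == "ENDMDL":
                in_first_model = False
            elif rec in ("ATOM", "HETATM") and in_first_model:
                atom = _parse_pdb_atom(line, lineno)
                if atom is not None:
                    atoms.append(atom)
    if not atoms:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    return StructureModel(atoms=atoms, box=box, label=path.stem)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as PDB (single model)."""
    path = Path(path)
    with open(path, "w") as fh:
        if model.box is not None:
            a, b, c = model.box
            fh.write(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        _write_pdb_atoms(fh, model)
        fh.write("END\n")


def _write_pdb_atoms(fh, model: StructureModel, coords: np.ndarray | None = None) -> None:
    xyz = model.coords if coords is None else coords
    for atom, pos in zip(model.atoms, xyz):
        record = "HETATM" if atom.is_water else "ATOM  "
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        fh.write(
            f"{record}{atom.serial:5d} {name:<4s} {atom.residue_name:<3s} "
            f"{atom.chain}{atom.residue_id:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}\n"
        )


# ---------------------------------------------------------------------------
# Trajectory reading / writing (DCD, XTC, multi-model PDB)
# ---------------------------------------------------------------------------

_TRAJ_DIALECTS = ("dcd", "xtc", "multi-model-pdb")


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("dcd", "xtc"):
        return suffix
    if suffix in ("pdb",):
        return "multi-model-pdb"
    raise UsageError(
        f"cannot infer trajectory dialect from {path.name!r}; "
        f"pass one of {_TRAJ_DIALECTS}"
    )


def _read_multimodel_pdb(path: Path) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    current: list[np.ndarray] | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if current:
                    frames.append(np.vstack(current))
                current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    if saw_model:
                        continue
                    current = []
                atom = _parse_pdb_atom(line, lineno)
                if atom is not None:
                    current.append(atom.position)
    if current:
        frames.append(np.vstack(current))
    if not frames:
        raise EmptyInputError(f"{path}: no coordinate frames found")
    return frames


def read_trajectory(
    path: str | Path,
    topology: StructureModel,
    dialect: str | None = None,
    timestep: float | None = None,
) -> TrajectoryEnsemble:
    """Read a coordinate trajectory over the given topology.

    Frames come back in file order and in Angstrom regardless of the
    dialect-native unit (XTC is nanometre on disk).  ``timestep``
    overrides the file's frame spacing; the fallback is the file value
    when available, else 1 ps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in _TRAJ_DIALECTS:
        raise UsageError(
            f"unknown trajectory dialect {dialect!r}; supported: {_TRAJ_DIALECTS}"
        )

    if dialect == "multi-model-pdb":
        raw_frames = _read_multimodel_pdb(path)
        n_atoms = {f.shape[0] for f in raw_frames}
        if n_atoms != {topology.n_atoms}:
            raise ShapeError(
                f"trajectory has frames with {sorted(n_atoms)} atoms but the "
                f"topology has {topology.n_atoms}"
            )
        frames = np.stack(raw_frames)
        dt = timestep if timestep is not None else 1.0
        return TrajectoryEnsemble(topology=topology, frames=frames, timestep=dt)

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms=topology.n_atoms, trajectory=True)
        try:
            u.load_new(str(path), format=dialect.upper())
        except ValueError as exc:
            # MDAnalysis raises on atom-count mismatch at load time.
            raise ShapeError(
                f"trajectory atom count does not match topology atom count "
                f"{topology.n_atoms}: {exc}"
            ) from None
        frames = []
        file_dt = 1.0
        for ts in u.trajectory:
            if ts.positions.shape[0] != topology.n_atoms:
                raise ShapeError(
                    f"frame has {ts.positions.shape[0]} atoms but topology has "
                    f"{topology.n_atoms}"
                )
            frames.append(ts.positions.astype(float).copy())
        try:
            file_dt = float(u.trajectory.dt) or 1.0
        except Exception:
            file_dt = 1.0
    dt = timestep if timestep is not None else file_dt
    return TrajectoryEnsemble(topology=topology, frames=np.stack(frames), timestep=dt)


def write_trajectory(
    traj: TrajectoryEnsemble, path: str | Path, dialect: str | None = None
) -> None:
    """Write a TrajectoryEnsemble as DCD, XTC or multi-model PDB."""
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in _TRAJ_DIALECTS:
        raise UsageError(
            f"unknown trajectory dialect {dialect!r}; supported: {_TRAJ_DIALECTS}"
        )

    if dialect == "multi-model-pdb":
        with open(path, "w") as fh:
            if traj.topology.box is not None:
                a, b, c = traj.topology.box
                fh.write(
                    f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
                )
            for i in range(traj.n_frames):
                fh.write(f"MODEL     {i + 1:4d}\n")
                _write_pdb_atoms(fh, traj.topology, traj.frames[i])
                fh.write("ENDMDL\n")
            fh.write("END\n")
        return

    import MDAnalysis as mda

    box = traj.topology.box
    if box is None:
        # XTC requires a box on disk; a generous dummy box is recorded.
        dims = np.array([1000.0, 1000.0, 1000.0, 90.0, 90.0, 90.0])
    else:
        dims = np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0])

    kwargs = {}
    if dialect == "xtc":
        # 5 stored decimal places (in nm) so round trips hold to < 1e-3 A.
        kwargs["precision"] = 5
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms=traj.n_atoms, trajectory=True)
        with mda.Writer(
            str(path), n_atoms=traj.n_atoms, format=dialect.upper(), dt=traj.timestep, **kwargs
        ) as writer:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.frames[i]
                u.trajectory.ts.dimensions = dims
                u.trajectory.ts.frame = i
                u.trajectory.ts.dt = traj.timestep
                writer.write(u.atoms)


# ---------------------------------------------------------------------------
# Tabular reports
# ---------------------------------------------------------------------------


def write_report(
    records: Sequence[dict],
    path: str | Path,
    format: str = "csv",
    fieldnames: Sequence[str] | None = None,
) -> int:
    """Write flat key-value records as CSV (RFC-4180) or JSON.

    All records must share one key set; ``fieldnames`` declares the
    schema explicitly (required to write a header-only CSV for zero
    records).  Returns the number of records written.
    """
    if format not in ("csv", "json"):
        raise UsageError(f"unknown report format {format!r}; supported: csv, json")
    records = list(records)
    if records:
        keys = list(records[0].keys())
        keyset = set(keys)
        for i, rec in enumerate(records[1:], start=2):
            if set(rec.keys()) != keyset:
                extra = sorted(set(rec.keys()) - keyset)
                missing = sorted(keyset - set(rec.keys()))
                raise SchemaError(
                    f"record {i} does not match the schema of record 1; "
                    f"extra keys: {extra}, missing keys: {missing}"
                )
        if fieldnames is not None and set(fieldnames) != keyset:
            raise SchemaError(
                f"declared fieldnames {sorted(fieldnames)} do not match record "
                f"keys {sorted(keyset)}"
            )
        fieldnames = fieldnames or keys
    elif fieldnames is None:
        raise SchemaError(
            "zero records require an explicit fieldnames schema to write a header"
        )

    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(fieldnames))
            writer.writeheader()
            for rec in records:
                writer.writerow(rec)
    else:
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1, default=_json_default)
            fh.write("\n")
    return len(records)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
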