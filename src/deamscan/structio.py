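"""Structures, trajectories and atom selection.

All downstream geometry modules consume the types defined here.  Coordinates
are in Angstrom; residue numbering is 1-based as in PDB files; nucleotide atom
names use the PDB prime convention (``C1'``).

Trajectories are exchanged as multi-model PDB files (text, diffable): one
MODEL per frame, identical atom ordering in every model.  MODEL 1 provides
the topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    EmptyStructureError,
    PdbParseError,
    TrajectoryInconsistencyError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomSelector",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "select",
    "atom_indices",
]


@dataclass(frozen=True)
class Atom:
    """A single atom as carried by a PDB ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    res_name: str
    res_num: int
    chain: str
    coord: tuple[float, float, float]

    def __post_init__(self):
        name = self.name.strip()
        if not name:
            raise ValueError("atom name empty after whitespace stripping")
        object.__setattr__(self, "name", name)
        if self.res_num < 1:
            raise ValueError(f"res_num must be >= 1, got {self.res_num}")
        if not all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {name}")
        object.__setattr__(self, "coord", tuple(float(c) for c in self.coord))

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain, res_num, name) — unique within a Structure."""
        return (self.chain, self.res_num, self.name)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class Structure:
    """An ordered collection of atoms."""

    atoms: list[Atom]
    title: str = ""

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials in structure")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (chain, res_num, name) triples: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array."""
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, coord=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(atoms=atoms, title=self.title if title is None else title)


@dataclass
class Trajectory:
    """A topology plus per-frame coordinate sets (Angstrom)."""

    topology: Structure
    frames: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        n = len(self.topology.atoms)
        frames = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise TrajectoryInconsistencyError(
                    f"frame {i + 1} has shape {f.shape}, expected ({n}, 3)"
                )
            frames.append(f)
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class AtomSelector:
    """Conjunction of optional atom-field filters; at least one must be set."""

    chain: str | None = None
    res_num: int | None = None
    res_name: str | None = None
    name: str | None = None

    def __post_init__(self):
        if all(v is None for v in (self.chain, self.res_num, self.res_name, self.name)):
            raise ValueError("at least one selector field must be set")

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.res_num is not None and atom.res_num != self.res_num:
            return False
        if self.res_name is not None and atom.res_name != self.res_name:
            return False
        if self.name is not None and atom.name != self.name:
            return False
        return True


def select(structure_or_atoms, sel: AtomSelector | None) -> list[Atom]:
    """Atoms matching all set selector fields, in input order.

    ``sel=None`` returns the input atom list unchanged.  An empty result is
    valid (no error).
    """
    atoms = (
        structure_or_atoms.atoms
        if isinstance(structure_or_atoms, Structure)
        else list(structure_or_atoms)
    )
    if sel is None:
        return list(atoms)
    return [a for a in atoms if sel.matches(a)]


def atom_indices(structure: Structure, sel: AtomSelector | None) -> list[int]:
    """Indices (into structure.atoms / frame rows) of matching atoms."""
    if sel is None:
        return list(range(len(structure.atoms)))
    return [i for i, a in enumerate(structure.atoms) if sel.matches(a)]


# --------------------------------------------------------------------------
# PDB fixed-column IO (ATOM/HETATM/MODEL/ENDMDL subset)
# --------------------------------------------------------------------------

_TWO_LETTER_ELEMENTS = {"ZN", "FE", "MG", "MN", "CL", "BR", "NA", "CA2"}


def _infer_element(name: str) -> str:
    """Element symbol from an atom name (PDB conventions)."""
    stripped = name.strip()
    upper = stripped.upper()
    if upper in ("ZN", "FE", "MG", "MN", "NA"):
        return upper.capitalize()
    # leading digits (e.g. 1HD1) mean hydrogen naming variants
    core = upper.lstrip("0123456789")
    if not core:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    return core[0]


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, float]:
    """Parse one ATOM/HETATM record -> (atom, altloc, occupancy)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        res_name = line[17:21].strip()
        chain = line[21:22]
        res_num = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element_field = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if icode:
        raise PdbParseError(f"insertion code {icode!r} at line {lineno} is not supported")
    element = element_field.capitalize() if element_field else _infer_element(name)
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_num=res_num,
        chain=chain,
        coord=(x, y, z),
    )
    return atom, altloc, occupancy


def _resolve_altlocs(records: list[tuple[Atom, str, float]]) -> list[Atom]:
    """Keep the highest-occupancy altloc per (chain, res_num, name); first on tie."""
    best: dict[tuple[str, int, str], tuple[float, int, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for pos, (atom, _altloc, occ) in enumerate(records):
        key = atom.key
        if key not in best:
            best[key] = (occ, pos, atom)
            order.append(key)
        elif occ > best[key][0]:
            best[key] = (occ, best[key][1], atom)  # keep original position
    picked = sorted((best[k][1], best[k][2]) for k in order)
    return [a for _, a in picked]


def _parse_models(path) -> tuple[list[list[tuple[Atom, str, float]]], str]:
    models: list[list[tuple[Atom, str, float]]] = []
    current: list[tuple[Atom, str, float]] = []
    in_model = False
    saw_model_record = False
    title = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec == "TITLE":
                title = (title + " " + raw[10:].strip()).strip()
            elif rec == "MODEL":
                if current:
                    models.append(current)
                    current = []
                in_model = True
                saw_model_record = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(raw.rstrip("\n"), lineno))
    if current or (not models and not saw_model_record):
        models.append(current)
    del in_model
    return models, title


def read_pdb(path) -> Structure:
    """Read a Structure from a PDB file (first MODEL only)."""
    models, title = _parse_models(path)
    first = models[0] if models else []
    atoms = _resolve_altlocs(first)
    if not atoms:
        raise EmptyStructureError(f"no ATOM/HETATM records found in {path}")
    structure = Structure(atoms=atoms, title=title)
    logger.info("read %d atoms from %s", len(atoms), path)
    return structure


def read_trajectory(path) -> Trajectory:
    """Read a multi-model PDB as a Trajectory (topology = MODEL 1)."""
    models, title = _parse_models(path)
    models = [m for m in models if m]
    if not models:
        raise EmptyStructureError(f"no ATOM/HETATM records found in {path}")
    atom_models = [_resolve_altlocs(m) for m in models]
    topo_atoms = atom_models[0]
    topology = Structure(atoms=topo_atoms, title=title)
    n = len(topo_atoms)
    ref_keys = [a.key for a in topo_atoms]
    frames = []
    for i, atoms in enumerate(atom_models, start=1):
        if len(atoms) != n:
            raise TrajectoryInconsistencyError(
                f"model {i} has {len(atoms)} atoms, expected {n} (model 1)"
            )
        if [a.key for a in atoms] != ref_keys:
            raise TrajectoryInconsistencyError(
                f"model {i} atom ordering differs from model 1"
            )
        frames.append(np.array([a.coord for a in atoms], dtype=float))
    logger.info("read trajectory: %d frames x %d atoms from %s", len(frames), n, path)
    return Trajectory(topology=topology, frames=frames)


def _format_atom_line(atom: Atom, serial: int) -> str:
    name = atom.name
    # conventional alignment: names of <=3 chars with 1-letter elements start in column 14
    if len(name) >= 4 or len(atom.element) == 2:
        padded = f"{name:<4s}"
    else:
        padded = f" {name:<3s}"
    x, y, z = atom.coord
    element = atom.element.upper().rjust(2)[:2]
    return (
        f"ATOM  {serial:5d} {padded[:4]}{'':1s}{atom.res_name:<4.4s}"
        f"{atom.chain:1.1s}{atom.res_num:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element}\n"
    )


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as a single-model PDB file."""
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title}\n")
        for i, atom in enumerate(structure.atoms, start=1):
            fh.write(_format_atom_line(atom, i))
        fh.write("END\n")
    logger.info("wrote %d atoms to %s", len(structure.atoms), path)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB (one MODEL per frame)."""
    with open(path, "w") as fh:
        if traj.topology.title:
            fh.write(f"TITLE     {traj.topology.title}\n")
        for m, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (atom, xyz) in enumerate(zip(traj.topology.atoms, frame), start=1):
                fh.write(_format_atom_line(replace(atom, coord=tuple(xyz)), i))
            fh.write("ENDMDL\n")
        fh.write("END\n")
    logger.info(
        "wrote trajectory: %d frames x %d atoms to %s",
        traj.n_frames,
        len(traj.topology.atoms),
        path,
    )
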