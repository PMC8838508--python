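"""Structures and trajectories: PDB / multi-frame XYZ I/O and atom selection.

The readers are deliberately strict: fixed-column PDB records per the wwPDB
3.3 convention (first MODEL only, altLoc blank or 'A'), and multi-frame XYZ
with a constant atom count.  Parse failures report the offending line or
frame so malformed inputs fail loudly instead of shifting columns silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "StructureIOError",
    "PDBParseError",
    "XYZParseError",
    "EmptySelectionError",
    "read_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "select_atoms",
    "is_calpha",
    "name_is",
]


class StructureIOError(ValueError):
    """Base class for structure/trajectory I/O failures."""


class PDBParseError(StructureIOError):
    pass


class XYZParseError(StructureIOError):
    pass


class EmptySelectionError(StructureIOError):
    pass


# Average atomic masses (amu) for elements that occur in protein PDB files
# and in the azide/elastic-network fixtures.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "NA": 22.99, "CL": 35.45, "K": 39.098, "X": 0.0,
}

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL".split()
)


@dataclass(frozen=True)
class Atom:
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str = ""
    mass: float = 0.0
    charge: float = 0.0


@dataclass
class Structure:
    """Named atoms with residue identifiers and one set of coordinates (Å)."""

    atoms: list[Atom]
    coordinates: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise StructureIOError(
                f"coordinate array shape {self.coordinates.shape} does not "
                f"match {len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureIOError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])


@dataclass
class Trajectory:
    """Ordered frames of Cartesian coordinates with a fixed timestep.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Å; ``timestep`` is
    the sampling interval in fs.  ``topology`` optionally links the frames
    to a :class:`Structure` carrying atom metadata.
    """

    coordinates: np.ndarray
    timestep: float
    topology: Structure | None = None
    elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise StructureIOError(
                f"trajectory coordinates must be (n_frames, n_atoms, 3), "
                f"got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise StructureIOError("trajectory needs at least one frame")
        if self.timestep <= 0:
            raise StructureIOError(f"timestep must be > 0 fs, got {self.timestep}")
        if not self.elements:
            self.elements = ["X"] * self.coordinates.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in fs (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.timestep


def _mass_for(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), 0.0)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_pdb(path: str | Path) -> Structure:
    """Read ATOM/HETATM records of the first model of a PDB file.

    Coordinates are taken from the fixed columns (31–54); occupancy and
    B-factor are ignored.  Alternate locations other than blank or 'A' are
    skipped so each atom appears once.  The two-character charge column
    (79–80, e.g. ``1-``) is parsed when present.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise PDBParseError(f"{path}: empty file")

    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "ENDMDL":
            break  # first model only
        if record not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"{path}:{lineno}: truncated {record} record")
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(
                f"{path}:{lineno}: malformed coordinate field: {exc}"
            ) from None
        try:
            resnum = int(line[22:26])
        except ValueError:
            raise PDBParseError(
                f"{path}:{lineno}: malformed residue number "
                f"{line[22:26]!r}"
            ) from None
        name = line[12:16].strip()
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(name)
        charge = 0.0
        if len(line) >= 80:
            raw = line[78:80].strip()
            if raw:
                try:
                    charge = float(raw[::-1]) if raw[-1] in "+-" else float(raw)
                except ValueError:
                    charge = 0.0
        atoms.append(
            Atom(
                name=name,
                residue_name=line[17:20].strip(),
                residue_number=resnum,
                chain_id=line[21].strip(),
                element=element,
                mass=_mass_for(element),
                charge=charge,
            )
        )
        coords.append((x, y, z))

    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms=atoms, coordinates=np.array(coords))


def read_xyz_trajectory(path: str | Path, timestep: float) -> Trajectory:
    """Read a multi-frame XYZ file (count line, comment line, atom lines).

    Every frame must carry the same atom count; a deviating frame raises
    :class:`XYZParseError` naming the 0-based frame index.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] = []
    pos = 0
    frame_idx = 0
    n_atoms: int | None = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise XYZParseError(
                f"{path}: frame {frame_idx}: expected atom-count line, "
                f"got {lines[pos]!r}"
            ) from None
        if n_atoms is None:
            n_atoms = count
        elif count != n_atoms:
            raise XYZParseError(
                f"{path}: frame {frame_idx}: atom count {count} differs "
                f"from first frame ({n_atoms})"
            )
        block = lines[pos + 2 : pos + 2 + count]
        if len(block) < count:
            raise XYZParseError(
                f"{path}: frame {frame_idx}: truncated (expected {count} "
                f"atom lines, found {len(block)})"
            )
        frame = np.empty((count, 3))
        for i, atom_line in enumerate(block):
            parts = atom_line.split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path}: frame {frame_idx}: malformed atom line "
                    f"{atom_line!r}"
                )
            if frame_idx == 0:
                elements.append(parts[0])
            try:
                frame[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise XYZParseError(
                    f"{path}: frame {frame_idx}: non-numeric coordinate in "
                    f"{atom_line!r}"
                ) from None
        frames.append(frame)
        pos += 2 + count
        frame_idx += 1

    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    return Trajectory(
        coordinates=np.stack(frames), timestep=timestep, elements=elements
    )


def write_xyz_trajectory(
    traj: Trajectory, path: str | Path, comment: str = "frame"
) -> None:
    """Write a Trajectory as multi-frame XYZ with fixed 10-decimal precision."""
    path = Path(path)
    with path.open("w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n{comment} {k}\n")
            for el, (x, y, z) in zip(traj.elements, traj.coordinates[k]):
                fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


def select_atoms(
    structure: Structure, selector: Callable[[Atom], bool]
) -> np.ndarray:
    """Return indices (in structure order) of atoms matching the predicate.

    Raises :class:`EmptySelectionError` when nothing matches — downstream
    correlation/RMSF stages require at least two sites.
    """
    idx = np.array(
        [i for i, atom in enumerate(structure.atoms) if selector(atom)],
        dtype=int,
    )
    if idx.size == 0:
        raise EmptySelectionError("selection matched no atoms")
    return idx


def is_calpha(atom: Atom) -> bool:
    """Cα selector: atom named CA in a standard amino-acid residue."""
    return atom.name == "CA" and atom.residue_name in STANDARD_AMINO_ACIDS


def name_is(*names: str) -> Callable[[Atom], bool]:
    """Build a selector matching any of the given atom names."""
    wanted = frozenset(names)
    return lambda atom: atom.name in wanted


def residue_numbers(structure: Structure, selection: Sequence[int] | Iterable[int]) -> np.ndarray:
    """Residue numbers of the selected atoms, in selection order."""
    return np.array(
        [structure.atoms[i].residue_number for i in selection], dtype=int
    )
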