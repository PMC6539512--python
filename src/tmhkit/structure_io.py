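"""Minimal multi-model PDB I/O.

Reads and writes the fixed-column ATOM/HETATM/MODEL/ENDMDL subset of the PDB
format and exposes trajectories as ordered frame sequences.  Author residue
numbering is kept verbatim; insertion codes are rejected.  HETATM records
(e.g. a sodium ion, residue name ``NA``) land in the same atom list as protein
atoms so that ion-to-residue distances can be measured like any other pair.

The parser is intentionally strict and line-oriented: malformed coordinate
fields raise :class:`PDBParseError` naming the offending line number, and an
inconsistent atom count across MODEL blocks raises :class:`TopologyError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Trajectory",
    "PDBParseError",
    "TopologyError",
    "AtomLookupError",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "get_atom",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
#: residue names accepted besides the 20 standard amino acids
OTHER_RES = {"HOH", "NA", "CL", "K", "MG", "CA", "ZN"}


class PDBParseError(ValueError):
    """Malformed PDB record; message carries the 1-based line number."""


class TopologyError(ValueError):
    """Frames of a trajectory disagree on atom identity/ordering."""


class AtomLookupError(KeyError):
    """Requested (chain, res_seq, atom_name) not present in a model."""


class PDBFormatError(ValueError):
    """Structure cannot be encoded in fixed-column PDB."""


@dataclass(slots=True)
class AtomRecord:
    """One atom: identity plus Cartesian position in Å."""

    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    position: np.ndarray
    hetatm: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite or malformed position for atom {self.atom_name}")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if self.res_name not in STANDARD_AA and self.res_name not in OTHER_RES:
            raise ValueError(f"unsupported residue name {self.res_name!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.atom_name)


@dataclass
class StructureModel:
    """A single frame: an ordered atom list with unique (chain, res_seq, atom_name)."""

    atoms: list[AtomRecord]
    model_id: int = 1

    _index: dict[tuple[str, int, str], int] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.model_id < 1:
            raise ValueError("model_id must be >= 1")
        self._index = {}
        for i, a in enumerate(self.atoms):
            if a.key in self._index:
                raise ValueError(f"duplicate atom {a.key} in model {self.model_id}")
            self._index[a.key] = i

    def atom_index(self, chain: str, res_seq: int, atom_name: str) -> int:
        try:
            return self._index[(chain, res_seq, atom_name)]
        except KeyError:
            raise AtomLookupError(
                f"atom (chain={chain!r}, res_seq={res_seq}, atom_name={atom_name!r}) not found"
            ) from None

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


class Trajectory:
    """Ordered sequence of StructureModels sharing (when flagged) one topology.

    Internally the coordinates live in one ``(n_frames, n_atoms, 3)`` array so
    that per-frame metrics vectorize; ``frames`` materializes
    :class:`StructureModel` views on demand.
    """

    def __init__(
        self,
        frames: Sequence[StructureModel] | None = None,
        frame_times: Sequence[float] | None = None,
        *,
        topology: Sequence[AtomRecord] | None = None,
        coords: np.ndarray | None = None,
        topology_invariant: bool = True,
    ) -> None:
        if frames is not None:
            if not frames:
                raise ValueError("trajectory needs at least one frame")
            ref = [a.key for a in frames[0].atoms]
            if topology_invariant:
                for f in frames[1:]:
                    if [a.key for a in f.atoms] != ref:
                        raise TopologyError(
                            f"frame {f.model_id} atom ordering differs from frame 1"
                        )
            self.topology = list(frames[0].atoms)
            self._coords = np.stack([f.coordinates() for f in frames])
        else:
            if topology is None or coords is None:
                raise ValueError("provide either frames or (topology, coords)")
            coords = np.asarray(coords, dtype=float)
            if coords.ndim != 3 or coords.shape[1] != len(topology) or coords.shape[2] != 3:
                raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
            self.topology = list(topology)
            self._coords = coords
        self.topology_invariant = topology_invariant
        n = self._coords.shape[0]
        if frame_times is None:
            self.frame_times = np.arange(n, dtype=float)
        else:
            self.frame_times = np.asarray(frame_times, dtype=float)
            if self.frame_times.shape != (n,):
                raise ValueError("frame_times length must equal frame count")
            if n > 1 and not np.all(np.diff(self.frame_times) > 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self._coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self._coords.shape[1]

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array, Å."""
        return self._coords

    def frame(self, i: int) -> StructureModel:
        atoms = [
            AtomRecord(a.chain, a.res_seq, a.res_name, a.atom_name, a.element,
                       self._coords[i, j].copy(), a.hetatm)
            for j, a in enumerate(self.topology)
        ]
        return StructureModel(atoms, model_id=i + 1)

    @property
    def frames(self) -> list[StructureModel]:
        return [self.frame(i) for i in range(self.n_frames)]

    def atom_index(self, chain: str, res_seq: int, atom_name: str) -> int:
        for j, a in enumerate(self.topology):
            if a.key == (chain, res_seq, atom_name):
                return j
        raise AtomLookupError(
            f"atom (chain={chain!r}, res_seq={res_seq}, atom_name={atom_name!r}) not in topology"
        )


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: record too short for coordinates")
    icode = line[26].strip()
    if icode:
        raise PDBParseError(f"line {lineno}: insertion codes are not supported ({icode!r})")
    try:
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed numeric field ({exc})") from None
    atom_name = line[12:16].strip()
    res_name = line[17:20].strip()
    chain = line[21].strip() or "A"
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the leading alphabetic character of the atom name
        element = next((c for c in atom_name if c.isalpha()), "X")
    try:
        return AtomRecord(
            chain=chain, res_seq=res_seq, res_name=res_name, atom_name=atom_name,
            element=element, position=np.array([x, y, z]),
            hetatm=line.startswith("HETATM"),
        )
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: {exc}") from None


def read_pdb(path: str | Path, frame_times: Sequence[float] | None = None) -> Trajectory:
    """Read a single- or multi-model PDB file into a :class:`Trajectory`.

    One :class:`StructureModel` is produced per MODEL block (a single model if
    the file has no MODEL records).  ``frame_times`` defaults to the frame
    index when no time metadata is supplied.
    """
    path = Path(path)
    models: list[StructureModel] = []
    atoms: list[AtomRecord] = []
    in_model = False
    saw_model_records = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model_records = True
                if atoms:
                    raise PDBParseError(f"line {lineno}: MODEL opened before previous ENDMDL")
                in_model = True
            elif rec == "ENDMDL":
                models.append(StructureModel(atoms, model_id=len(models) + 1))
                atoms = []
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                atoms.append(_parse_atom_line(line, lineno))
            # all other records (REMARK, TER, END, ...) are ignored
    if atoms:
        if saw_model_records and in_model:
            raise PDBParseError("final MODEL block not closed by ENDMDL")
        models.append(StructureModel(atoms, model_id=len(models) + 1))
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    ref = [a.key for a in models[0].atoms]
    for m in models[1:]:
        if [a.key for a in m.atoms] != ref:
            raise TopologyError(f"model {m.model_id} atom set/order differs from model 1")
    return Trajectory(models, frame_times=frame_times)


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    if a.res_seq > 9999 or a.res_seq < -999:
        raise PDBFormatError(f"residue number {a.res_seq} not encodable in PDB columns")
    if serial > 99999:
        serial = serial % 99999 + 1
    record = "HETATM" if a.hetatm else "ATOM  "
    name = a.atom_name
    # PDB convention: 1-letter element names start at column 14
    name_field = f" {name:<3s}" if len(name) < 4 and len(a.element) == 1 else f"{name:<4s}"
    x, y, z = a.position
    if max(abs(x), abs(y), abs(z)) >= 10000:
        raise PDBFormatError("coordinate magnitude exceeds PDB fixed columns")
    return (
        f"{record}{serial:>5d} {name_field}{'':1s}{a.res_name:>3s} {a.chain:1s}"
        f"{a.res_seq:>4d}{'':4s}{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"{'':10s}{a.element:>2s}"
    )


def write_pdb(traj: Trajectory | StructureModel, path: str | Path) -> Path:
    """Write a trajectory (or single model) as fixed-column PDB.

    MODEL/ENDMDL bracketing is emitted only when there is more than one frame.
    Coordinates are written to 3 decimals.
    """
    if isinstance(traj, StructureModel):
        traj = Trajectory([traj])
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    multi = traj.n_frames > 1
    lines: list[str] = []
    for i in range(traj.n_frames):
        if multi:
            lines.append(f"MODEL {i + 1:>8d}")
        serial = 0
        for j, a in enumerate(traj.topology):
            serial += 1
            rec = AtomRecord(a.chain, a.res_seq, a.res_name, a.atom_name, a.element,
                             traj.coords[i, j], a.hetatm)
            lines.append(_format_atom_line(rec, serial))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def get_atom(model: StructureModel, chain: str, res_seq: int, atom_name: str) -> np.ndarray:
    """Exact lookup of one atom position by (chain, res_seq, atom_name)."""
    return model.atoms[model.atom_index(chain, res_seq, atom_name)].position
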