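"""Structures, trajectories, selections.

PDB parsing/writing is delegated to :mod:`biotite`; this module wraps the
result into light domain objects that the scanner, the simulator and the
tunnel code consume, and adds van der Waals radii (Bondi-style table) at
load time. Multi-model PDB files double as the trajectory interchange
format: ``read_structure(path, model="all")`` returns a :class:`Trajectory`
whenever more than one model is present.

Residue numbering is the author numbering of the input file and is never
remapped; selections and reports refer to it directly.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as pdbio
import biotite.structure.io.pdbx as pdbxio

from .geometry import pairwise_distance  # re-exported convenience

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Trajectory",
    "ParseError",
    "TrajectoryAssemblyError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "write_trajectory",
    "select",
    "pairwise_distance",
    "VDW_RADII",
]

logger = logging.getLogger(__name__)

#: Bondi-style van der Waals radii (Å) by element symbol.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

#: Radius assigned to elements missing from the table (with a logged warning).
DEFAULT_VDW_RADIUS = 1.5

_warned_elements: set[str] = set()


class ParseError(ValueError):
    """Raised on a malformed PDB record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class TrajectoryAssemblyError(ValueError):
    """Raised when models of a multi-model file differ in atom count."""


class SelectionError(ValueError):
    """Raised for an unknown selection keyword."""


def vdw_radius(element: str) -> float:
    el = element.strip().upper()
    r = VDW_RADII.get(el)
    if r is None:
        if el not in _warned_elements:
            logger.warning(
                "unknown element %r: using default vdW radius %.2f Å",
                element,
                DEFAULT_VDW_RADIUS,
            )
            _warned_elements.add(el)
        return DEFAULT_VDW_RADIUS
    return r


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    hetero: bool = False
    vdw_radius: float = field(default=0.0)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if self.vdw_radius <= 0.0:
            self.vdw_radius = vdw_radius(self.element or self.name[:1])


@dataclass
class Residue:
    """Group of atoms sharing (chain, res_id, res_name), in file order."""

    chain: str
    res_id: int
    res_name: str
    atoms: list[Atom]
    atom_indices: np.ndarray

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_id, self.res_name)


class Structure:
    """Ordered atom list with residue grouping and cached coordinates."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: list[Atom] = list(atoms)
        self._residues: list[Residue] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def residues(self) -> list[Residue]:
        if self._residues is None:
            groups: dict[tuple, Residue] = {}
            order: list[tuple] = []
            for i, a in enumerate(self.atoms):
                key = (a.chain, a.res_id, a.res_name)
                if key not in groups:
                    groups[key] = Residue(a.chain, a.res_id, a.res_name, [], np.empty(0, int))
                    order.append(key)
                groups[key].atoms.append(a)
            for key in order:
                res = groups[key]
                res.atom_indices = np.array(
                    [i for i, a in enumerate(self.atoms) if (a.chain, a.res_id, a.res_name) == key],
                    dtype=int,
                )
            self._residues = [groups[k] for k in order]
        return self._residues

    def residue(self, chain: str, res_id: int) -> Residue:
        for r in self.residues:
            if r.chain == chain and r.res_id == res_id:
                return r
        raise KeyError(f"no residue {chain}/{res_id}")

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, float).reshape(-1, 3)
        if len(coords) != len(self.atoms):
            raise ValueError("coordinate count mismatch")
        atoms = [
            Atom(
                a.serial, a.name, a.element, a.res_name, a.res_id, a.chain,
                c.copy(), a.occupancy, a.b_factor, a.hetero, a.vdw_radius,
            )
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms)


@dataclass
class Trajectory:
    """Stack of frames sharing one topology.

    ``coords`` has shape (F, N, 3) in Å; ``temperature`` is the simulation
    temperature label in K (``None`` when unknown, e.g. an ingested file
    without metadata); ``frame_spacing`` is an opaque time label.
    """

    coords: np.ndarray
    topology: Structure
    temperature: float | None = None
    frame_spacing: float | str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must have shape (F, N, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError("frame atom count does not match topology")
        if self.temperature is not None and self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.coords[frame]


# ---------------------------------------------------------------------------
# reading / writing

_COORD_SLICES = [(30, 38), (38, 46), (46, 54)]


def _prevalidate_pdb(text: str) -> list[int]:
    """Check ATOM/HETATM coordinate fields; return atom counts per model.

    Raises :class:`ParseError` with a line number on the first malformed
    record — biotite's own errors do not carry one.
    """
    counts: list[int] = []
    current = 0
    in_model = False
    seen_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if seen_model:
                counts.append(current)
            seen_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError("truncated ATOM/HETATM record", lineno)
            for lo, hi in _COORD_SLICES:
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"unparsable coordinate field {line[lo:hi]!r}", lineno
                    ) from None
            try:
                int(line[22:26])
            except ValueError:
                raise ParseError(f"unparsable residue number {line[22:26]!r}", lineno) from None
            current += 1
    counts.append(current)
    return counts


def _atoms_from_array(arr: bst.AtomArray) -> list[Atom]:
    n = arr.array_length()
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    occ = (
        arr.get_annotation("occupancy")
        if "occupancy" in arr.get_annotation_categories()
        else np.ones(n)
    )
    bf = (
        arr.get_annotation("b_factor")
        if "b_factor" in arr.get_annotation_categories()
        else np.zeros(n)
    )
    atoms = []
    for i in range(n):
        element = str(arr.element[i]).strip()
        atoms.append(
            Atom(
                serial=int(serials[i]),
                name=str(arr.atom_name[i]),
                element=element or str(arr.atom_name[i])[:1],
                res_name=str(arr.res_name[i]),
                res_id=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]),
                coords=np.array(arr.coord[i], dtype=float),
                occupancy=float(occ[i]),
                b_factor=float(bf[i]),
                hetero=bool(arr.hetero[i]),
            )
        )
    return atoms


def read_structure(
    path: str | Path | io.StringIO,
    model: int | str = "all",
    temperature: float | None = None,
):
    """Read a PDB (or mmCIF) file into a Structure or Trajectory.

    Parameters
    ----------
    path:
        File path (``.pdb``, ``.cif`` honoured by suffix) or a text buffer
        containing PDB records.
    model:
        ``"all"`` (default) returns a :class:`Structure` for single-model
        files and a :class:`Trajectory` for multi-model files; a 1-based
        integer returns that model as a :class:`Structure`.
    temperature:
        Optional temperature label (K) attached to a returned Trajectory.
    """
    if isinstance(path, io.StringIO):
        text = path.getvalue()
        suffix = ".pdb"
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        suffix = path.suffix.lower()

    if suffix in (".cif", ".mmcif"):
        f = pdbxio.CIFFile.read(io.StringIO(text))
        stack = pdbxio.get_structure(f, model=None, altloc="occupancy")
        counts = [stack.array_length()] * stack.stack_depth()
        get_model = lambda m: stack[m - 1]  # noqa: E731
        n_models = stack.stack_depth()
    else:
        counts = _prevalidate_pdb(text)
        f = pdbio.PDBFile.read(io.StringIO(text))
        n_models = f.get_model_count()
        extra = ["atom_id", "b_factor", "occupancy"]

        def get_model(m, _f=f, _extra=extra):
            return _f.get_structure(model=m, altloc="occupancy", extra_fields=_extra)

    if isinstance(model, int):
        if not 1 <= model <= n_models:
            raise ValueError(f"model {model} out of range 1..{n_models}")
        return Structure(_atoms_from_array(get_model(model)))
    if model != "all":
        raise ValueError("model must be an integer or 'all'")

    if n_models == 1:
        return Structure(_atoms_from_array(get_model(1)))

    if len(set(counts)) > 1:
        bad = [i + 1 for i, c in enumerate(counts) if c != counts[0]]
        raise TrajectoryAssemblyError(
            f"models differ in atom count (first mismatch at models {bad}); "
            f"counts={counts}"
        )
    template = Structure(_atoms_from_array(get_model(1)))
    if suffix in (".cif", ".mmcif"):
        frames = stack.coord
    else:
        frames = f.get_coord(model=None)  # one pass over all models
    return Trajectory(np.asarray(frames), template, temperature=temperature)


def _to_atom_array(structure: Structure, coords: np.ndarray | None = None) -> bst.AtomArray:
    n = len(structure)
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords if coords is not None else structure.coords, np.float32)
    arr.chain_id = np.array([a.chain for a in structure.atoms])
    arr.res_id = np.array([a.res_id for a in structure.atoms])
    arr.res_name = np.array([a.res_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element.upper() for a in structure.atoms])
    arr.hetero = np.array([a.hetero for a in structure.atoms])
    arr.set_annotation("b_factor", np.array([a.b_factor for a in structure.atoms]))
    arr.set_annotation("occupancy", np.array([a.occupancy for a in structure.atoms]))
    arr.set_annotation("atom_id", np.array([a.serial for a in structure.atoms]))
    return arr


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a single-model PDB file."""
    f = pdbio.PDBFile()
    f.set_structure(_to_atom_array(structure))
    f.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB file."""
    arrays = [_to_atom_array(traj.topology, traj.coords[i]) for i in range(traj.n_frames)]
    stack = bst.stack(arrays)
    f = pdbio.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# ---------------------------------------------------------------------------
# selections

_RANGE_RE = re.compile(r"^(-?\d+):(-?\d+)$")


def _clause_mask(structure: Structure, clause: str) -> np.ndarray:
    clause = clause.strip()
    negate = False
    while clause.startswith("not "):
        negate = not negate
        clause = clause[4:].strip()
    parts = clause.split(None, 1)
    key = parts[0].lower()
    arg = parts[1] if len(parts) > 1 else None
    atoms = structure.atoms
    n = len(atoms)

    if key == "all":
        mask = np.ones(n, bool)
    elif key == "hetatm":
        mask = np.array([a.hetero for a in atoms])
    elif key == "protein":
        mask = np.array([not a.hetero for a in atoms])
    elif key in ("name", "resname", "chain"):
        if arg is None:
            raise SelectionError(f"selector {key!r} needs an argument")
        wanted = {w.strip() for w in arg.split(",")}
        attr = {"name": "name", "resname": "res_name", "chain": "chain"}[key]
        mask = np.array([getattr(a, attr) in wanted for a in atoms])
    elif key == "resid":
        if arg is None:
            raise SelectionError("selector 'resid' needs an argument")
        ids: set[int] = set()
        lo_hi: list[tuple[int, int]] = []
        for tok in arg.split(","):
            tok = tok.strip()
            m = _RANGE_RE.match(tok)
            if m:
                lo_hi.append((int(m.group(1)), int(m.group(2))))
            else:
                ids.add(int(tok))
        mask = np.array(
            [a.res_id in ids or any(lo <= a.res_id <= hi for lo, hi in lo_hi) for a in atoms]
        )
    else:
        raise SelectionError(f"unknown selection keyword {key!r}")
    return ~mask if negate else mask


def select(structure: Structure, selector: str) -> np.ndarray:
    """Resolve a selection expression to a sorted array of atom indices.

    Clauses are joined with ``and``; supported keywords: ``name``,
    ``resid`` (single ids, comma lists, ``lo:hi`` inclusive ranges),
    ``chain``, ``resname``, ``hetatm``, ``protein``, ``all``; any clause
    may be prefixed with ``not``. Example:
    ``"resid 10:437 and name CA"``.
    """
    if not selector or not selector.strip():
        raise SelectionError("empty selector")
    mask = np.ones(len(structure), bool)
    for clause in re.split(r"\s+and\s+", selector.strip()):
        mask &= _clause_mask(structure, clause)
    return np.nonzero(mask)[0]
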