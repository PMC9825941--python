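"""Trajectory reading/writing, atom selections and periodic-box geometry.

All coordinates are stored internally in nanometres (the GROMACS
convention); Angstrom-based formats (PDB, XYZ) are converted at the file
boundary.  Only cubic periodic boxes are supported — the simulation
protocol this package serves places the solute in a cubic cell — and
triclinic input is rejected explicitly.

File I/O is delegated to MDAnalysis; this module owns the in-memory frame
model (:class:`Trajectory`) that every downstream stage consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, SelectionError, StructuralError

logger = logging.getLogger(__name__)

#: residue names recognized as water solvent
SOLVENT_RESNAMES = frozenset({"SOL", "HOH", "WAT"})

#: atom names making up the peptide backbone ("backbone" selection keyword);
#: the carbonyl O and all hydrogens are excluded
BACKBONE_NAMES = ("N", "CA", "C")

NM_PER_ANGSTROM = 0.1

_TWO_LETTER_ELEMENTS = {"CL", "NA", "MG", "FE", "ZN", "BR", "CA2"}


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``molecule_id`` groups atoms into covalent units: each water residue is
    its own molecule, consecutive non-solvent residues in the same segment
    form one molecule (a peptide chain).
    """

    index: int
    name: str
    residue_name: str
    residue_index: int
    molecule_id: int
    element: str


@dataclass
class Frame:
    """Coordinates (n_atoms, 3) in nm, optional cubic box edge (nm), time (ps)."""

    coordinates: np.ndarray
    box: float | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructuralError(
                f"frame coordinates must be (n, 3), got {self.coordinates.shape}"
            )
        if self.box is not None and self.box <= 0:
            raise StructuralError(f"box edge must be positive, got {self.box}")


@dataclass
class Trajectory:
    """Ordered frames over a shared topology.

    ``superposed`` is set by the superposition stage so that covariance
    construction can warn when roto-translations have not been removed.
    """

    topology: list[AtomRecord]
    frames: list[Frame]
    superposed: bool = False

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructuralError("a trajectory needs at least one frame")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise StructuralError(
                    f"frame {i} has {fr.coordinates.shape[0]} atoms, topology has {n}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """Stack all frames into an (n_frames, n_atoms, 3) array (nm)."""
        return np.stack([fr.coordinates for fr in self.frames])

    def molecule_indices(self, molecule_id: int) -> np.ndarray:
        return np.array(
            [a.index for a in self.topology if a.molecule_id == molecule_id],
            dtype=int,
        )


@dataclass(frozen=True)
class Selection:
    """An ordered, duplicate-free subset of topology atom indices (0-based)."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise SelectionError(f"selection {self.expression!r} matched no atoms")
        if np.unique(idx).size != idx.size:
            raise SelectionError(f"selection {self.expression!r} has duplicate indices")

    def __len__(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def minimum_image(d: np.ndarray, box: float) -> np.ndarray:
    """Wrap displacement(s) ``d`` (nm) into the primary cubic cell.

    Each component of the result lies in (-box/2, box/2].  Accepts a single
    3-vector or an (..., 3) array.
    """
    if box <= 0:
        raise ValueError(f"box edge must be positive, got {box}")
    d = np.asarray(d, dtype=float)
    w = d - box * np.round(d / box)
    # np.round leaves exact half-edges at -box/2; fold them onto +box/2
    return np.where(w <= -0.5 * box, w + box, w)


# ---------------------------------------------------------------------------
# selection grammar:  expr := term (('and'|'or') term)* ; 'not' binds tightest
# primaries: name A B.. | resname A B.. | resid 1 3-5 | molid 0 1 | backbone | water
# ---------------------------------------------------------------------------

_KEYWORDS = {"name", "resname", "resid", "molid", "backbone", "water", "solvent",
             "and", "or", "not", "all"}


def select(traj: Trajectory, expression: str) -> Selection:
    """Evaluate a selection expression against the trajectory topology.

    The grammar is deliberately small: ``name``/``resname`` followed by a
    list of labels, ``resid`` with numbers or inclusive ranges (``1-2``),
    ``molid`` with molecule ids, the keywords ``backbone`` (N, CA, C per
    residue), ``water``/``solvent`` and ``all``, combined with ``and``,
    ``or`` and ``not``.
    """
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    mask, pos = _parse_or(traj, tokens, 0)
    if pos != len(tokens):
        raise SelectionError(
            f"could not parse selection {expression!r} near token {tokens[pos]!r}"
        )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return Selection(indices=idx, expression=expression)


def _parse_or(traj, tokens, pos):
    mask, pos = _parse_and(traj, tokens, pos)
    while pos < len(tokens) and tokens[pos] == "or":
        rhs, pos = _parse_and(traj, tokens, pos + 1)
        mask = mask | rhs
    return mask, pos


def _parse_and(traj, tokens, pos):
    mask, pos = _parse_not(traj, tokens, pos)
    while pos < len(tokens) and tokens[pos] == "and":
        rhs, pos = _parse_not(traj, tokens, pos + 1)
        mask = mask & rhs
    return mask, pos


def _parse_not(traj, tokens, pos):
    if pos < len(tokens) and tokens[pos] == "not":
        mask, pos = _parse_not(traj, tokens, pos + 1)
        return ~mask, pos
    return _parse_primary(traj, tokens, pos)


def _collect_args(tokens, pos):
    args = []
    while pos < len(tokens) and tokens[pos] not in _KEYWORDS:
        args.append(tokens[pos])
        pos += 1
    return args, pos


def _parse_primary(traj, tokens, pos):
    if pos >= len(tokens):
        raise SelectionError("selection expression ended unexpectedly")
    tok = tokens[pos]
    top = traj.topology
    if tok == "all":
        return np.ones(len(top), dtype=bool), pos + 1
    if tok == "backbone":
        names = set(BACKBONE_NAMES)
        return np.array([a.name in names for a in top]), pos + 1
    if tok in ("water", "solvent"):
        return np.array([a.residue_name in SOLVENT_RESNAMES for a in top]), pos + 1
    if tok in ("name", "resname"):
        args, newpos = _collect_args(tokens, pos + 1)
        if not args:
            raise SelectionError(f"{tok!r} needs at least one argument")
        wanted = set(args)
        attr = "name" if tok == "name" else "residue_name"
        return np.array([getattr(a, attr) in wanted for a in top]), newpos
    if tok in ("resid", "molid"):
        args, newpos = _collect_args(tokens, pos + 1)
        if not args:
            raise SelectionError(f"{tok!r} needs at least one argument")
        wanted: set[int] = set()
        for arg in args:
            if "-" in arg[1:]:
                lo, hi = arg.split("-", 1)
                wanted.update(range(int(lo), int(hi) + 1))
            else:
                wanted.add(int(arg))
        attr = "residue_index" if tok == "resid" else "molecule_id"
        return np.array([getattr(a, attr) in wanted for a in top]), newpos
    raise SelectionError(f"unknown selection token {tok!r}")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if stripped[:2] in _TWO_LETTER_ELEMENTS:
        return stripped[:2].capitalize()
    return stripped[:1] if stripped else "X"


def _assign_molecule_ids(resindices, resnames, segindices) -> np.ndarray:
    """Group atoms into molecules: one per water residue, one per run of
    consecutive non-solvent residues within a segment."""
    n = len(resindices)
    mol = np.empty(n, dtype=int)
    current = -1
    prev_res = prev_seg = None
    prev_solvent = True
    for i in range(n):
        res, seg = resindices[i], segindices[i]
        is_solvent = resnames[i] in SOLVENT_RESNAMES
        if res != prev_res or seg != prev_seg:
            new_molecule = (
                is_solvent
                or prev_solvent
                or seg != prev_seg
                or (prev_res is not None and res != prev_res + 1)
            )
            if new_molecule:
                current += 1
            prev_res, prev_seg, prev_solvent = res, seg, is_solvent
        mol[i] = current
    return mol


def _box_edge_from_dimensions(dims) -> float | None:
    if dims is None:
        return None
    dims = np.asarray(dims, dtype=float)
    if np.all(dims[:3] == 0):
        return None
    if np.allclose(dims, [1, 1, 1, 90, 90, 90]):
        return None  # placeholder unit cell written for non-periodic data
    lx, ly, lz, alpha, beta, gamma = dims
    if not (np.allclose([alpha, beta, gamma], 90.0, atol=1e-3)):
        raise FormatError("triclinic boxes are not supported (cubic cells only)")
    if not np.allclose([lx, ly], [ly, lz], rtol=1e-6, atol=1e-6):
        raise FormatError(
            f"non-cubic box edges ({lx:.4f}, {ly:.4f}, {lz:.4f} A) are not supported"
        )
    return float(lx) * NM_PER_ANGSTROM


def read_trajectory(path: str | Path, topology_path: str | Path | None = None) -> Trajectory:
    """Read a trajectory, inferring the format from the file extension.

    Supported: XYZ trajectory, multi-model PDB, GRO (single frame) and
    XTC (``topology_path`` pointing at a GRO/PDB required).  Coordinates
    are returned in nm regardless of the on-disk unit.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FormatError(f"trajectory file not found: {path}")
    suffix = path.suffix.lower()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if suffix == ".xtc":
                if topology_path is None:
                    raise FormatError("XTC trajectories need a GRO/PDB topology file")
                universe = mda.Universe(str(topology_path), str(path))
            elif topology_path is not None:
                universe = mda.Universe(str(topology_path), str(path))
            elif suffix in (".xyz", ".pdb", ".gro"):
                universe = mda.Universe(str(path))
            else:
                raise FormatError(f"unsupported trajectory format {suffix!r}")
    except FormatError:
        raise
    except Exception as exc:  # MDAnalysis raises a zoo of parse errors
        raise FormatError(f"could not read {path}: {exc}") from exc

    atoms = universe.atoms
    n = len(atoms)
    if n == 0:
        raise FormatError(f"{path} contains no atoms")

    names = [str(x) for x in atoms.names] if hasattr(atoms, "names") else ["X"] * n
    try:
        resnames = [str(x) for x in atoms.resnames]
    except Exception:
        resnames = ["UNK"] * n
    try:
        resids = [int(x) for x in atoms.resids]
    except Exception:
        resids = [1] * n
    try:
        resindices = list(atoms.resindices)
    except Exception:
        resindices = [0] * n
    try:
        segindices = list(atoms.segindices)
    except Exception:
        segindices = [0] * n

    mol_ids = _assign_molecule_ids(resindices, resnames, segindices)
    topology = [
        AtomRecord(
            index=i,
            name=names[i],
            residue_name=resnames[i],
            residue_index=resids[i],
            molecule_id=int(mol_ids[i]),
            element=_guess_element(names[i]),
        )
        for i in range(n)
    ]

    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in universe.trajectory:
            box = _box_edge_from_dimensions(ts.dimensions)
            frames.append(
                Frame(
                    coordinates=ts.positions.astype(float) * NM_PER_ANGSTROM,
                    box=box,
                    time=float(getattr(ts, "time", 0.0) or 0.0),
                )
            )
    if suffix == ".pdb" and all(fr.box is None for fr in frames):
        # the multi-model reader only honours CRYST1 inside MODEL blocks;
        # recover a header-level cell record for the whole trajectory
        box = _pdb_header_box(path)
        if box is not None:
            for fr in frames:
                fr.box = box
    return Trajectory(topology=topology, frames=frames)


def _pdb_header_box(path: Path) -> float | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                dims = [float(line[6 + 9 * i:15 + 9 * i]) for i in range(3)]
                angles = [float(line[33 + 7 * i:40 + 7 * i]) for i in range(3)]
                return _box_edge_from_dimensions(np.array(dims + angles))
            if line.startswith(("MODEL", "ATOM", "HETATM")):
                break
    return None


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _as_universe(traj: Trajectory):
    """Build an MDAnalysis Universe mirroring the trajectory (coords in A)."""
    import MDAnalysis as mda

    top = traj.topology
    n = len(top)
    resindex_keys: list[tuple[int, int]] = []
    atom_resindex = np.empty(n, dtype=int)
    for i, a in enumerate(top):
        key = (a.molecule_id, a.residue_index)
        if not resindex_keys or resindex_keys[-1] != key:
            resindex_keys.append(key)
        atom_resindex[i] = len(resindex_keys) - 1
    n_res = len(resindex_keys)

    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=n_res,
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in top])
    u.add_TopologyAttr("elements", [a.element for a in top])
    first_atom_of_res = np.searchsorted(atom_resindex, np.arange(n_res))
    u.add_TopologyAttr("resnames", [top[i].residue_name for i in first_atom_of_res])
    u.add_TopologyAttr("resids", [top[i].residue_index for i in first_atom_of_res])

    coords = traj.coordinate_array() / NM_PER_ANGSTROM
    boxes = []
    for fr in traj.frames:
        if fr.box is None:
            boxes.append(np.zeros(6))
        else:
            edge = fr.box / NM_PER_ANGSTROM
            boxes.append(np.array([edge, edge, edge, 90.0, 90.0, 90.0]))
    u.load_new(coords.astype(np.float32), dimensions=np.array(boxes), format="memory")
    return u


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write all frames as multi-model PDB or XYZ (from the extension)."""
    import MDAnalysis as mda

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".pdb", ".xyz"):
        raise FormatError(f"unsupported output format {suffix!r} (use .pdb or .xyz)")
    u = _as_universe(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    logger.info("wrote %d frame(s) to %s", traj.n_frames, path)


def subset_trajectory(traj: Trajectory, frame_indices) -> Trajectory:
    """A new trajectory holding only the given frames (topology shared)."""
    frames = [traj.frames[int(i)] for i in frame_indices]
    return Trajectory(topology=traj.topology, frames=frames, superposed=traj.superposed)
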