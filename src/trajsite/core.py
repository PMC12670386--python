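"""Coordinate data model, structure/trajectory I/O and region annotation.

Internal units are nanometres (coordinates) and nanoseconds (times)
everywhere; angstroms appear only at PDB/PDBQT I/O boundaries and in
docking-box output, matching the docking-engine convention.

Residue numbering is 1-based and inclusive, exactly as in the source
files; structures are never renumbered on ingestion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "RegionSpec",
    "ParseError",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "trajectory_from_mdanalysis",
    "assign_regions",
    "sample_frames",
    "STANDARD_AMINO_ACIDS",
    "WATER_NAMES",
    "ION_NAMES",
    "BACKBONE_ATOM_NAMES",
]

ANGSTROM_PER_NM = 10.0

STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL HSD HSE HSP HID HIE HIP MSE CYX""".split()
)
WATER_NAMES = frozenset("HOH SOL WAT TIP3 TIP4 TIP5 H2O SPC".split())
ION_NAMES = frozenset("NA CL K MG CA ZN FE MN SOD CLA POT CAL LIT RUB CES BR I F".split())

#: Backbone heavy atoms used for fitting/RMSD selections.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O"})

# deliberately excludes CA (ambiguous with the alpha-carbon atom name);
# calcium ions should carry an explicit element column
_TWO_LETTER_ELEMENTS = frozenset("CL BR NA MG ZN FE MN SE".split())


class ParseError(ValueError):
    """Raised on a malformed record; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyStructureError(ValueError):
    """Raised when a structure file contains no coordinate records."""


def infer_element(name: str) -> str:
    """Guess an element symbol from an atom name (PDB conventions)."""
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if stripped[:2] in _TWO_LETTER_ELEMENTS and stripped == stripped[:2]:
        return stripped[:2].capitalize()
    return stripped[0]


@dataclass(frozen=True, slots=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_seq: int
    residue_name: str
    chain: str

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if self.residue_seq < 1:
            raise ValueError(f"residue_seq must be >= 1, got {self.residue_seq}")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.residue_seq)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


ResidueKey = tuple[str, int]


class Topology:
    """Ordered atom list plus residue table and per-residue region labels.

    Region labels come from :func:`assign_regions`; before annotation
    ``region_of`` is empty.  Non-protein residues are classified at
    construction: anything that is not a standard amino acid, water or a
    monoatomic ion is treated as a ligand (overridable through
    ``ligand_names``).
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        region_of: Mapping[ResidueKey, str] | None = None,
        ligand_names: Iterable[str] = (),
    ):
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        seen: set[tuple[str, int, str]] = set()
        self.residues: list[tuple[str, int, str]] = []
        res_seen: set[ResidueKey] = set()
        for atom in self.atoms:
            ident = (atom.chain, atom.residue_seq, atom.name)
            if ident in seen:
                raise ValueError(f"duplicate atom {ident} in topology")
            seen.add(ident)
            key = atom.residue_key
            if key not in res_seen:
                res_seen.add(key)
                self.residues.append((atom.chain, atom.residue_seq, atom.residue_name))
        self.region_of: dict[ResidueKey, str] = dict(region_of or {})
        self._extra_ligand_names = frozenset(n.upper() for n in ligand_names)
        self._res_atom_indices: dict[ResidueKey, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            self._res_atom_indices.setdefault(atom.residue_key, []).append(i)

    # -- basic introspection -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_keys(self) -> list[ResidueKey]:
        return [(c, s) for c, s, _ in self.residues]

    def residue_name(self, key: ResidueKey) -> str:
        for c, s, n in self.residues:
            if (c, s) == key:
                return n
        raise KeyError(f"residue {key} not in topology")

    def atom_indices(self, residue: ResidueKey) -> list[int]:
        try:
            return list(self._res_atom_indices[residue])
        except KeyError:
            raise KeyError(f"residue {residue} not in topology") from None

    # -- residue classification ---------------------------------------------

    def is_protein_residue(self, key: ResidueKey) -> bool:
        return self.residue_name(key).upper() in STANDARD_AMINO_ACIDS

    def residue_class(self, key: ResidueKey) -> str:
        """One of ``protein``, ``water``, ``ion``, ``ligand``."""
        name = self.residue_name(key).upper()
        if name in self._extra_ligand_names:
            return "ligand"
        if name in STANDARD_AMINO_ACIDS:
            return "protein"
        if name in WATER_NAMES:
            return "water"
        if name in ION_NAMES:
            return "ion"
        return "ligand"

    def protein_residues(self) -> list[ResidueKey]:
        return [k for k in self.residue_keys() if self.residue_class(k) == "protein"]

    def ligand_residues(self) -> list[ResidueKey]:
        return [k for k in self.residue_keys() if self.residue_class(k) == "ligand"]

    # -- atom selections (integer index arrays) ------------------------------

    def select(
        self,
        names: Iterable[str] | None = None,
        elements: Iterable[str] | None = None,
        residues: Iterable[ResidueKey] | None = None,
        heavy: bool = False,
    ) -> np.ndarray:
        names_set = {n.upper() for n in names} if names is not None else None
        elem_set = {e.upper() for e in elements} if elements is not None else None
        res_set = set(residues) if residues is not None else None
        out = []
        for i, atom in enumerate(self.atoms):
            if names_set is not None and atom.name.upper() not in names_set:
                continue
            if elem_set is not None and atom.element.upper() not in elem_set:
                continue
            if res_set is not None and atom.residue_key not in res_set:
                continue
            if heavy and atom.is_hydrogen:
                continue
            out.append(i)
        return np.asarray(out, dtype=int)

    def backbone_indices(self, residues: Iterable[ResidueKey] | None = None) -> np.ndarray:
        keys = set(residues) if residues is not None else set(self.protein_residues())
        return self.select(names=BACKBONE_ATOM_NAMES, residues=keys)

    def ca_indices(self, residues: Iterable[ResidueKey] | None = None) -> np.ndarray:
        keys = set(residues) if residues is not None else set(self.protein_residues())
        return self.select(names={"CA"}, residues=keys)

    def residues_in_region(self, label: str) -> list[ResidueKey]:
        return [k for k in self.residue_keys() if self.region_of.get(k) == label]

    def residue_index_of_atoms(self) -> np.ndarray:
        """Per-atom index into ``self.residues`` (handy for vectorized code)."""
        lookup = {(c, s): i for i, (c, s, _) in enumerate(self.residues)}
        return np.asarray([lookup[a.residue_key] for a in self.atoms], dtype=int)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self.atoms == other.atoms and self.region_of == other.region_of

    def __repr__(self) -> str:
        return f"<Topology {self.n_atoms} atoms, {self.n_residues} residues>"


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates (nm) with timestamps (ns)."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3), nm
    times: np.ndarray  # (n_frames,), ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords carry {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.coords[frame]


@dataclass(frozen=True)
class RegionSpec:
    """Inclusive 1-based residue ranges labelled by region.

    Ranges sharing a label may be disjoint (a transmembrane bundle is many
    ranges); overlapping ranges with *different* labels are rejected.
    """

    ranges: tuple[tuple[str, int, int], ...]

    def __init__(self, ranges: Iterable[tuple[str, int, int]]):
        norm = tuple((str(lbl), int(a), int(b)) for lbl, a, b in ranges)
        for lbl, first, last in norm:
            if first > last:
                raise ValueError(f"range {lbl} {first}:{last} has first > last")
            if first < 1:
                raise ValueError(f"range {lbl} starts below residue 1")
        for i, (la, a0, a1) in enumerate(norm):
            for lb, b0, b1 in norm[i + 1 :]:
                if la != lb and a0 <= b1 and b0 <= a1:
                    raise ValueError(
                        f"overlapping ranges with different labels: "
                        f"{la} {a0}:{a1} vs {lb} {b0}:{b1}"
                    )
        object.__setattr__(self, "ranges", norm)

    def label_for(self, residue_seq: int) -> str | None:
        for lbl, first, last in self.ranges:
            if first <= residue_seq <= last:
                return lbl
        return None

    def labels(self) -> list[str]:
        seen: list[str] = []
        for lbl, _, _ in self.ranges:
            if lbl not in seen:
                seen.append(lbl)
        return seen


def assign_regions(topology: Topology, spec: RegionSpec, default: str = "cytoplasmic") -> Topology:
    """Label every residue: protein residues by the covering range (else
    ``default``); ligands as ``ligand``; water/ions as ``solvent``.

    Returns a new Topology sharing the atom tuple.
    """
    region_of: dict[ResidueKey, str] = {}
    for key in topology.residue_keys():
        cls = topology.residue_class(key)
        if cls == "protein":
            region_of[key] = spec.label_for(key[1]) or default
        elif cls == "ligand":
            region_of[key] = "ligand"
        else:
            region_of[key] = "solvent"
    out = Topology(topology.atoms, region_of=region_of)
    out._extra_ligand_names = topology._extra_ligand_names
    return out


def sample_frames(
    traj_or_times: "Trajectory | np.ndarray | Sequence[float]",
    discard_ns: float,
    stride_ns: float,
    boundary: str = "inclusive",
) -> list[int]:
    """Indices of frames at time >= discard (or > discard for
    ``boundary='exclusive'``), greedily spaced >= stride_ns apart; the first
    qualifying frame is always included.

    The discard-boundary convention is exposed because sampling protocols in
    the literature are ambiguous about whether the frame exactly at the
    discard time is kept.
    """
    if stride_ns <= 0:
        raise ValueError("stride_ns must be > 0")
    if boundary not in ("inclusive", "exclusive"):
        raise ValueError("boundary must be 'inclusive' or 'exclusive'")
    times = traj_or_times.times if isinstance(traj_or_times, Trajectory) else np.asarray(traj_or_times, float)
    eps = 1e-9
    picked: list[int] = []
    last_t = -math.inf
    for i, t in enumerate(times):
        if boundary == "inclusive":
            if t < discard_ns - eps:
                continue
        else:
            if t <= discard_ns + eps:
                continue
        if t >= last_t + stride_ns - eps:
            picked.append(i)
            last_t = t
    return picked


# ---------------------------------------------------------------------------
# PDB reading/writing
# ---------------------------------------------------------------------------


def _parse_pdb_atom_line(line: str, lineno: int) -> tuple[Atom, np.ndarray]:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # some writers overflow the serial column; tolerate
    name = line[12:16].strip()
    res_name = line[17:20].strip() or line[17:21].strip()
    chain = line[21:22].strip() or "A"
    try:
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"malformed ATOM/HETATM record: {exc}", lineno) from None
    element = line[76:78].strip() if len(line) >= 77 else ""
    if not element:
        element = infer_element(name)
    element = element.capitalize() if len(element) > 1 else element.upper()
    atom = Atom(serial=serial, name=name, element=element, residue_seq=res_seq,
                residue_name=res_name, chain=chain)
    return atom, np.array([x, y, z]) / ANGSTROM_PER_NM


def _read_pdb_models(path: Path) -> list[tuple[list[Atom], np.ndarray]]:
    """All MODEL blocks of a PDB file as (atoms, coords-nm) pairs."""
    models: list[tuple[list[Atom], list[np.ndarray]]] = []
    atoms: list[Atom] = []
    xyz: list[np.ndarray] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if atoms and not in_model:
                    models.append((atoms, xyz))
                    atoms, xyz = [], []
                in_model = True
            elif rec == "ENDMDL":
                models.append((atoms, xyz))
                atoms, xyz = [], []
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                atom, pos = _parse_pdb_atom_line(line, lineno)
                atoms.append(atom)
                xyz.append(pos)
    if atoms:
        models.append((atoms, xyz))
    return [(a, np.asarray(x)) for a, x in models if a]


def _read_gro(path: Path) -> tuple[list[Atom], np.ndarray]:
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 2:
        raise EmptyStructureError(f"empty structure: {path}")
    try:
        n_atoms = int(lines[1])
    except ValueError as exc:
        raise ParseError(f"bad atom count: {exc}", 2) from None
    atoms: list[Atom] = []
    xyz: list[list[float]] = []
    for i in range(n_atoms):
        lineno = 3 + i
        line = lines[2 + i]
        try:
            res_seq = int(line[0:5])
            res_name = line[5:10].strip()
            name = line[10:15].strip()
            serial = int(line[15:20])
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed GRO record: {exc}", lineno) from None
        atoms.append(Atom(serial=serial, name=name, element=infer_element(name),
                          residue_seq=res_seq, residue_name=res_name, chain="A"))
        xyz.append([x, y, z])
    return atoms, np.asarray(xyz)


def read_structure(path: str | Path, format: str | None = None) -> tuple[Topology, np.ndarray]:
    """Read a single-structure PDB or GRO file.

    Returns ``(topology, coords_nm)``; PDB angstroms are converted to nm,
    GRO is already nm.  Atom order is preserved exactly.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "gro":
        atoms, coords = _read_gro(path)
    elif fmt == "pdb":
        models = _read_pdb_models(path)
        if not models:
            raise EmptyStructureError(f"empty structure: {path}")
        atoms, coords = models[0]
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")
    if not atoms:
        raise EmptyStructureError(f"empty structure: {path}")
    return Topology(atoms), np.asarray(coords)


def write_structure(path: str | Path, topology: Topology, coords_nm: np.ndarray) -> None:
    """Write a PDB snapshot (coordinates converted nm -> angstrom)."""
    coords = np.asarray(coords_nm, dtype=float) * ANGSTROM_PER_NM
    with open(path, "w") as fh:
        fh.write(_pdb_block(topology, coords))
        fh.write("END\n")


def _pdb_block(topology: Topology, coords_angstrom: np.ndarray) -> str:
    lines = []
    for i, atom in enumerate(topology.atoms):
        record = "ATOM" if topology.residue_class(atom.residue_key) == "protein" else "HETATM"
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        x, y, z = coords_angstrom[i]
        lines.append(
            f"{record:<6s}{(i + 1) % 100000:>5d} {name:<4s}{atom.residue_name:>4s} "
            f"{atom.chain[:1]}{atom.residue_seq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element.upper():>2s}\n"
        )
    return "".join(lines)


# ---------------------------------------------------------------------------
# Trajectory I/O: multi-model PDB and a documented plain-text frame format
# ---------------------------------------------------------------------------

_PLAIN_MAGIC = "# trajsite-frames 1"


def read_trajectory(
    path: str | Path,
    topology: Topology,
    format: str | None = None,
    start_ns: float = 0.0,
    stride_ns: float = 1.0,
) -> Trajectory:
    """Read a multi-model PDB or plain-frames trajectory against a topology.

    Frame times come from the file when the format carries them (the plain
    format does); otherwise from ``(start_ns, stride_ns)``.  A frame whose
    atom count differs from the topology raises, naming the frame.
    """
    path = Path(path)
    fmt = format
    if fmt is None:
        suffix = path.suffix.lstrip(".").lower()
        fmt = "frames" if suffix in ("txt", "frames", "dat") else suffix
    if fmt == "pdb":
        models = _read_pdb_models(path)
        if not models:
            raise EmptyStructureError(f"no models in {path}")
        frames = []
        for k, (atoms, coords) in enumerate(models, start=1):
            if len(atoms) != topology.n_atoms:
                raise ValueError(
                    f"frame {k}: atom count {len(atoms)} does not match "
                    f"topology ({topology.n_atoms})"
                )
            frames.append(coords)
        times = start_ns + stride_ns * np.arange(len(frames))
        return Trajectory(topology, np.asarray(frames), times)
    if fmt == "frames":
        return _read_plain_frames(path, topology)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def _read_plain_frames(path: Path, topology: Topology) -> Trajectory:
    frames: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _PLAIN_MAGIC:
            raise ParseError(f"not a plain-frames file (header {header!r})", 1)
        natoms_line = fh.readline().split()
        if len(natoms_line) != 3 or natoms_line[1] != "natoms":
            raise ParseError("expected '# natoms <n>'", 2)
        n_atoms = int(natoms_line[2])
        if n_atoms != topology.n_atoms:
            raise ValueError(
                f"file declares {n_atoms} atoms but topology has {topology.n_atoms}"
            )
        lineno = 2
        while True:
            line = fh.readline()
            lineno += 1
            if not line:
                break
            line = line.strip()
            if not line:
                continue
            if not line.startswith("t "):
                raise ParseError(f"expected frame header 't <ns>', got {line!r}", lineno)
            times.append(float(line.split()[1]))
            block = np.empty((n_atoms, 3))
            for i in range(n_atoms):
                row = fh.readline()
                lineno += 1
                if not row:
                    raise ParseError(
                        f"frame {len(frames)}: truncated after {i} of {n_atoms} atoms",
                        lineno,
                    )
                vals = row.split()
                if len(vals) != 3:
                    raise ParseError(f"frame {len(frames)}: expected 3 coordinates", lineno)
                block[i] = [float(v) for v in vals]
            frames.append(block)
    if not frames:
        raise EmptyStructureError(f"no frames in {path}")
    return Trajectory(topology, np.asarray(frames), np.asarray(times))


def write_trajectory(path: str | Path, traj: Trajectory, format: str = "frames") -> None:
    """Write a trajectory as plain-frames text or multi-model PDB."""
    path = Path(path)
    if format == "frames":
        with open(path, "w") as fh:
            fh.write(_PLAIN_MAGIC + "\n")
            fh.write(f"# natoms {traj.n_atoms}\n")
            for f in range(traj.n_frames):
                fh.write(f"t {traj.times[f]:.6f}\n")
                np.savetxt(fh, traj.coords[f], fmt="%.6f")
    elif format == "pdb":
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"MODEL     {f + 1:>4d}\n")
                fh.write(_pdb_block(traj.topology, traj.coords[f] * ANGSTROM_PER_NM))
                fh.write("ENDMDL\n")
            fh.write("END\n")
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")


def trajectory_from_mdanalysis(universe, topology: Topology | None = None) -> Trajectory:
    """Adapter for compressed MD formats (XTC/TRR/DCD) via MDAnalysis.

    MDAnalysis is imported lazily so the package has no binary-format
    dependency; pass a ``Universe`` built from whatever files you have.
    """
    if topology is None:
        atoms = []
        for i, a in enumerate(universe.atoms):
            try:
                element = a.element
            except Exception:
                element = infer_element(a.name)
            chain = getattr(a, "segid", "") or "A"
            atoms.append(Atom(serial=i + 1, name=a.name, element=element,
                              residue_seq=int(a.resid), residue_name=a.resname,
                              chain=str(chain)[:1]))
        topology = Topology(atoms)
    frames, times = [], []
    for ts in universe.trajectory:
        if len(universe.atoms) != topology.n_atoms:
            raise ValueError("atom count mismatch between universe and topology")
        frames.append(universe.atoms.positions / ANGSTROM_PER_NM)
        times.append(ts.time / 1000.0)  # MDAnalysis ps -> ns
    times_arr = np.asarray(times)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        times_arr = np.arange(len(frames), dtype=float)
    return Trajectory(topology, np.asarray(frames), times_arr)


def region_table(topology: Topology) -> "list[tuple[str, int, str, str]]":
    """(chain, residue_seq, residue_name, region) rows for TSV export."""
    rows = []
    for chain, seq, name in topology.residues:
        rows.append((chain, seq, name, topology.region_of.get((chain, seq), "")))
    return rows
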