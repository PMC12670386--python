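"""Docking search-box construction and pose bookkeeping.

The box protocol: rotate the receptor so its principal axis lies on z,
take the CA centroid of the transmembrane residues and the CA centroid of
the extracellular residues, and center an axis-aligned box (default
15 x 15 x 25 angstrom total edge lengths, the docking-engine convention)
at the midpoint between the two centroids.

Pose files are PDBQT-style multi-MODEL blocks whose affinity rides on a
``REMARK VINA RESULT`` line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ANGSTROM_PER_NM, EmptyStructureError, ParseError, Topology, infer_element
from . import contacts as _contacts

__all__ = [
    "DEFAULT_BOX_DIMS_ANGSTROM",
    "DockingBox",
    "Pose",
    "PoseSet",
    "principal_axis_to_z",
    "build_box",
    "read_poses",
    "write_poses",
    "filter_poses",
    "representative_pose",
]

#: Default box edge lengths (x, y, z) in angstrom.
DEFAULT_BOX_DIMS_ANGSTROM = (15.0, 15.0, 25.0)


@dataclass(frozen=True)
class DockingBox:
    center: tuple[float, float, float]  # angstrom
    dims: tuple[float, float, float] = DEFAULT_BOX_DIMS_ANGSTROM  # angstrom

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError("box dimensions must be positive")

    def vina_config(self) -> str:
        cx, cy, cz = self.center
        sx, sy, sz = self.dims
        return (
            f"center_x = {cx:.3f}\ncenter_y = {cy:.3f}\ncenter_z = {cz:.3f}\n"
            f"size_x = {sx:.3f}\nsize_y = {sy:.3f}\nsize_z = {sz:.3f}\n"
        )


@dataclass(frozen=True)
class Pose:
    """One docking pose: ligand coordinates (nm) plus predicted affinity."""

    coords: np.ndarray  # (n_atoms, 3) nm
    affinity: float  # kcal/mol
    source_structure: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.affinity):
            raise ValueError("affinity must be finite")


@dataclass
class PoseSet:
    poses: list[Pose]
    atom_names: tuple[str, ...] = ()
    elements: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = {p.coords.shape[0] for p in self.poses}
        if len(counts) > 1:
            raise ValueError(f"inconsistent ligand atom counts across poses: {counts}")

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def affinities(self) -> np.ndarray:
        return np.asarray([p.affinity for p in self.poses])

    @property
    def heavy_mask(self) -> np.ndarray:
        if not self.elements:
            return np.ones(self.poses[0].coords.shape[0], bool)
        return np.asarray([e.upper() != "H" for e in self.elements])


def principal_axis_to_z(
    coordinates: np.ndarray,
    toward: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a point cloud about its centroid so the direction of maximal
    variance is parallel to z.

    ``toward`` fixes the sign convention: positive z points from the cloud
    centroid to that reference point (e.g. the extracellular centroid).
    Returns (rotated coordinates, rotation matrix); distances are
    preserved.
    """
    X = np.asarray(coordinates, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("need an (n >= 3, 3) coordinate array")
    center = X.mean(axis=0)
    Xc = X - center
    cov = Xc.T @ Xc
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        raise ValueError("degenerate geometry: zero variance cloud")
    axis = evecs[:, -1]
    if toward is not None:
        if np.dot(axis, np.asarray(toward, float) - center) < 0:
            axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    rotated = center + Xc @ R.T
    return rotated, R


def build_box(
    topology: Topology,
    coordinates: np.ndarray,
    tm_label: str = "transmembrane",
    ec_label: str = "extracellular",
    dims: Sequence[float] = DEFAULT_BOX_DIMS_ANGSTROM,
    half_extent: bool = False,
) -> DockingBox:
    """Docking box centered at the midpoint of the TM and EC CA centroids.

    Coordinates are nm; the returned box is in angstrom.  ``half_extent``
    doubles the edge lengths for callers reading "dimension in each
    direction around the center" as half-extents.
    """
    coords = np.asarray(coordinates, dtype=float)
    centroids = []
    for label in (tm_label, ec_label):
        ca = topology.ca_indices(residues=topology.residues_in_region(label))
        if ca.size == 0:
            raise ValueError(f"region {label!r} has no CA atoms")
        centroids.append(coords[ca].mean(axis=0))
    center_nm = 0.5 * (centroids[0] + centroids[1])
    edges = tuple(2.0 * d for d in dims) if half_extent else tuple(float(d) for d in dims)
    return DockingBox(center=tuple(center_nm * ANGSTROM_PER_NM), dims=edges)


# ---------------------------------------------------------------------------
# PDBQT-style pose I/O
# ---------------------------------------------------------------------------


def read_poses(path: str | Path) -> PoseSet:
    """Read a multi-pose PDBQT-style file (MODEL blocks with
    ``REMARK VINA RESULT`` affinity lines), preserving file order."""
    path = Path(path)
    poses: list[Pose] = []
    names: list[str] = []
    elements: list[str] = []
    affinity: float | None = None
    coords: list[list[float]] = []
    cur_names: list[str] = []
    cur_elements: list[str] = []
    in_model = False

    def _close(lineno: int) -> None:
        nonlocal affinity, coords, cur_names, cur_elements
        if not coords:
            raise ParseError("pose with no atoms", lineno)
        if affinity is None:
            raise ParseError(f"pose {len(poses) + 1} has no affinity record", lineno)
        poses.append(Pose(coords=np.asarray(coords) / ANGSTROM_PER_NM,
                          affinity=affinity, index=len(poses)))
        if not names:
            names.extend(cur_names)
            elements.extend(cur_elements)
        affinity, coords, cur_names, cur_elements = None, [], [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
            elif rec == "ENDMDL":
                _close(lineno)
                in_model = False
            elif line.startswith("REMARK VINA RESULT:"):
                try:
                    affinity = float(line.split()[3])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"bad affinity record: {exc}", lineno) from None
            elif rec in ("ATOM", "HETATM"):
                name = line[12:16].strip()
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise ParseError(f"malformed atom record: {exc}", lineno) from None
                coords.append([x, y, z])
                cur_names.append(name)
                cur_elements.append(infer_element(name))
    if coords and in_model:
        _close(lineno)
    if not poses:
        raise EmptyStructureError(f"no poses in {path}")
    return PoseSet(poses=poses, atom_names=tuple(names), elements=tuple(elements))


def write_poses(path: str | Path, poses: PoseSet, residue_name: str = "LIG") -> None:
    with open(path, "w") as fh:
        for k, pose in enumerate(poses, start=1):
            fh.write(f"MODEL {k}\n")
            fh.write(f"REMARK VINA RESULT: {pose.affinity:10.1f} {0.0:10.3f} {0.0:10.3f}\n")
            xyz = pose.coords * ANGSTROM_PER_NM
            for i in range(xyz.shape[0]):
                name = poses.atom_names[i] if poses.atom_names else f"C{i + 1}"
                fh.write(
                    f"HETATM{i + 1:>5d} {name:<4s}{residue_name:>4s} L   1    "
                    f"{xyz[i, 0]:8.3f}{xyz[i, 1]:8.3f}{xyz[i, 2]:8.3f}\n"
                )
            fh.write("ENDMDL\n")


def filter_poses(
    poses: PoseSet,
    max_affinity: float | None = None,
    min_affinity: float | None = None,
) -> PoseSet:
    """Keep poses with affinity strictly below ``max_affinity`` (the
    "better than" reading) and/or strictly above ``min_affinity``.
    Idempotent and order-preserving."""
    kept = [
        p for p in poses
        if (max_affinity is None or p.affinity < max_affinity)
        and (min_affinity is None or p.affinity > min_affinity)
    ]
    return PoseSet(poses=kept, atom_names=poses.atom_names, elements=poses.elements)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def representative_pose(
    poses: PoseSet,
    receptor_topology: Topology,
    receptor_coords: np.ndarray,
    cutoff: float = _contacts.CONTACT_CUTOFF_NM,
    contact_sets: Sequence[set] | None = None,
) -> Pose:
    """The pose whose residue-contact set is most similar (mean Jaccard) to
    all other poses' sets; ties broken by best (lowest) affinity, then file
    order.

    ``contact_sets`` can pre-supply per-pose contacts (e.g. when each pose
    was docked against a different receptor frame).
    """
    if len(poses) == 0:
        raise ValueError("empty pose set")
    if contact_sets is None:
        contact_sets = [
            _contacts.residue_contacts(receptor_topology, receptor_coords, p.coords,
                                       cutoff=cutoff, ligand_is_heavy=poses.heavy_mask)
            for p in poses
        ]
    if len(contact_sets) != len(poses):
        raise ValueError("one contact set per pose required")
    n = len(poses)
    if n == 1:
        return poses.poses[0]
    scores = np.empty(n)
    for i in range(n):
        scores[i] = np.mean([_jaccard(contact_sets[i], contact_sets[j])
                             for j in range(n) if j != i])
    order = sorted(range(n), key=lambda i: (-round(scores[i], 12),
                                            poses.poses[i].affinity, i))
    return poses.poses[order[0]]
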