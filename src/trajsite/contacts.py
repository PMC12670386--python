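"""Residue-ligand contact detection and occupancy/retention statistics.

A residue is in contact when at least one of its atoms lies within the
cutoff (0.4 nm default) of any ligand atom; heavy atoms only by default.
The fast path uses a KD-tree over ligand atoms; tests check it against a
brute-force all-pairs scan, which is also exported here as
:func:`residue_contacts_bruteforce` so the oracle stays available.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import ResidueKey, Topology, Trajectory

__all__ = [
    "CONTACT_CUTOFF_NM",
    "HBOND_DISTANCE_NM",
    "HBOND_ANGLE_DEG",
    "ContactRecord",
    "BindingSite",
    "residue_contacts",
    "residue_contacts_bruteforce",
    "contacts_per_frame",
    "interaction_probability",
    "conserved_contact_fraction",
    "retention_series",
    "hydrophobic_occurrence",
    "hbond_occurrence",
    "contact_count_histogram",
    "resolve_window",
]

#: Generic residue-ligand contact cutoff (nm): 4 angstrom.
CONTACT_CUTOFF_NM = 0.4
#: Geometric hydrogen-bond criteria (donor-acceptor distance, H-D-A angle).
HBOND_DISTANCE_NM = 0.35
HBOND_ANGLE_DEG = 30.0


@dataclass(frozen=True)
class ContactRecord:
    """Contacts of one frame, with independent per-class flags."""

    frame: int
    residues: frozenset
    hydrophobic: frozenset = frozenset()
    hbond: frozenset = frozenset()


@dataclass(frozen=True)
class BindingSite:
    """Ordered set of (residue_seq, residue_name) pairs defining a site."""

    residues: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("binding site must be non-empty")
        seqs = [seq for seq, _ in self.residues]
        if len(set(seqs)) != len(seqs):
            raise ValueError("binding site residues must be unique")

    def keys(self, chain: str = "A") -> list[ResidueKey]:
        return [(chain, seq) for seq, _ in self.residues]


def _receptor_atom_table(
    topology: Topology,
    atom_policy: str,
    exclude_residues: set[ResidueKey],
) -> tuple[np.ndarray, list[ResidueKey]]:
    """(atom indices, parallel residue keys) for contact-eligible atoms."""
    if atom_policy not in ("heavy", "all"):
        raise ValueError("atom_policy must be 'heavy' or 'all'")
    idx, keys = [], []
    for i, atom in enumerate(topology.atoms):
        key = atom.residue_key
        if key in exclude_residues:
            continue
        if topology.residue_class(key) != "protein":
            continue
        if atom_policy == "heavy" and atom.is_hydrogen:
            continue
        idx.append(i)
        keys.append(key)
    return np.asarray(idx, dtype=int), keys


def residue_contacts(
    topology: Topology,
    receptor_coords: np.ndarray,
    ligand_coords: np.ndarray,
    cutoff: float = CONTACT_CUTOFF_NM,
    atom_policy: str = "heavy",
    ligand_is_heavy: np.ndarray | None = None,
) -> set[ResidueKey]:
    """Receptor residues with any eligible atom within ``cutoff`` of any
    ligand atom.  ``ligand_is_heavy`` masks ligand hydrogens under the
    heavy-atom policy when ligand elements are known."""
    lig = np.asarray(ligand_coords, dtype=float)
    if lig.size == 0:
        raise ValueError("ligand has no atoms")
    if atom_policy == "heavy" and ligand_is_heavy is not None:
        lig = lig[np.asarray(ligand_is_heavy, bool)]
        if lig.size == 0:
            raise ValueError("ligand has no heavy atoms")
    rec_idx, rec_keys = _receptor_atom_table(topology, atom_policy, set())
    if rec_idx.size == 0:
        return set()
    tree = cKDTree(lig)
    d, _ = tree.query(np.asarray(receptor_coords)[rec_idx], k=1,
                      distance_upper_bound=cutoff + 1e-12)
    hit = d <= cutoff
    return {rec_keys[i] for i in np.flatnonzero(hit)}


def residue_contacts_bruteforce(
    topology: Topology,
    receptor_coords: np.ndarray,
    ligand_coords: np.ndarray,
    cutoff: float = CONTACT_CUTOFF_NM,
    atom_policy: str = "heavy",
    ligand_is_heavy: np.ndarray | None = None,
) -> set[ResidueKey]:
    """All-pairs reference implementation of :func:`residue_contacts`."""
    lig = np.asarray(ligand_coords, dtype=float)
    if lig.size == 0:
        raise ValueError("ligand has no atoms")
    if atom_policy == "heavy" and ligand_is_heavy is not None:
        lig = lig[np.asarray(ligand_is_heavy, bool)]
    rec = np.asarray(receptor_coords)
    out: set[ResidueKey] = set()
    for i, atom in enumerate(topology.atoms):
        key = atom.residue_key
        if topology.residue_class(key) != "protein":
            continue
        if atom_policy == "heavy" and atom.is_hydrogen:
            continue
        if key in out:
            continue
        for q in lig:
            if np.linalg.norm(rec[i] - q) <= cutoff:
                out.add(key)
                break
    return out


def _ligand_atom_indices(topology: Topology, ligand_residue: ResidueKey,
                         atom_policy: str) -> np.ndarray:
    lig = np.asarray(topology.atom_indices(ligand_residue), dtype=int)
    if atom_policy == "heavy":
        lig = np.asarray([i for i in lig if not topology.atoms[i].is_hydrogen], int)
    if lig.size == 0:
        raise ValueError(f"ligand residue {ligand_residue} has no eligible atoms")
    return lig


def resolve_window(n_frames: int, window=None, equilibrium_fraction: float = 0.25) -> np.ndarray:
    """Frame indices for a statistics window.

    ``window`` may be None (drop the first ``equilibrium_fraction`` of
    frames, the default equilibration discard), a slice, or an explicit
    index iterable.
    """
    if window is None:
        start = int(np.floor(n_frames * equilibrium_fraction))
        idx = np.arange(start, n_frames)
    elif isinstance(window, slice):
        idx = np.arange(n_frames)[window]
    else:
        idx = np.asarray(list(window), dtype=int)
    if idx.size == 0:
        raise ValueError("empty frame window")
    return idx


def _contact_matrix(
    traj: Trajectory,
    ligand_residue: ResidueKey,
    cutoff: float,
    atom_policy: str,
    frame_idx: np.ndarray,
) -> tuple[np.ndarray, list[ResidueKey]]:
    """Boolean (n_frames, n_residues) residue-in-contact matrix, chunked
    broadcasting over frames (fast path; the brute-force scan is the test
    oracle)."""
    lig = _ligand_atom_indices(traj.topology, ligand_residue, atom_policy)
    rec_idx, rec_keys = _receptor_atom_table(traj.topology, atom_policy, {ligand_residue})
    unique_keys: list[ResidueKey] = []
    bounds = [0]
    for i, key in enumerate(rec_keys):
        if not unique_keys or key != unique_keys[-1]:
            unique_keys.append(key)
            if i:
                bounds.append(i)
    cut2 = cutoff * cutoff
    hits = np.empty((frame_idx.size, len(unique_keys)), dtype=bool)
    chunk = max(1, int(5e6 // max(rec_idx.size * lig.size, 1)))
    for s in range(0, frame_idx.size, chunk):
        sel = frame_idx[s : s + chunk]
        rec = traj.coords[sel][:, rec_idx, :]
        lg = traj.coords[sel][:, lig, :]
        d2 = np.sum((rec[:, :, None, :] - lg[:, None, :, :]) ** 2, axis=-1)
        atom_hit = d2.min(axis=2) <= cut2
        hits[s : s + chunk] = np.logical_or.reduceat(atom_hit, bounds, axis=1)
    # merge runs of the same residue (atoms of a residue are normally
    # contiguous, but nothing above requires it)
    if len(set(unique_keys)) != len(unique_keys):
        merged: dict[ResidueKey, np.ndarray] = {}
        for j, key in enumerate(unique_keys):
            merged[key] = hits[:, j] if key not in merged else merged[key] | hits[:, j]
        unique_keys = list(merged)
        hits = np.stack(list(merged.values()), axis=1)
    return hits, unique_keys


def contacts_per_frame(
    traj: Trajectory,
    ligand_residue: ResidueKey,
    cutoff: float = CONTACT_CUTOFF_NM,
    atom_policy: str = "heavy",
    frames: Iterable[int] | None = None,
) -> list[set[ResidueKey]]:
    frame_idx = np.arange(traj.n_frames) if frames is None else np.asarray(list(frames), int)
    hits, keys = _contact_matrix(traj, ligand_residue, cutoff, atom_policy, frame_idx)
    return [{keys[j] for j in np.flatnonzero(row)} for row in hits]


def interaction_probability(
    traj: Trajectory,
    ligand_residue: ResidueKey,
    cutoff: float = CONTACT_CUTOFF_NM,
    window=None,
    atom_policy: str = "heavy",
) -> "dict[ResidueKey, float]":
    """Per-residue percentage of window frames in contact with the ligand."""
    idx = resolve_window(traj.n_frames, window, equilibrium_fraction=0.0) if window is not None \
        else np.arange(traj.n_frames)
    hits, keys = _contact_matrix(traj, ligand_residue, cutoff, atom_policy, idx)
    frac = 100.0 * hits.mean(axis=0)
    probs = {key: 0.0 for key in traj.topology.protein_residues()}
    for key, value in zip(keys, frac):
        probs[key] = float(value)
    return probs


def conserved_contact_fraction(frame_contacts: set, reference_contacts: set) -> float:
    """100 x |frame intersection reference| / |reference|."""
    if not reference_contacts:
        raise ValueError("reference contact set is empty")
    return 100.0 * len(set(frame_contacts) & set(reference_contacts)) / len(reference_contacts)


def retention_series(
    traj: Trajectory,
    ligand_residue: ResidueKey,
    reference_contacts: set | None = None,
    cutoff: float = CONTACT_CUTOFF_NM,
    atom_policy: str = "heavy",
) -> np.ndarray:
    """Per-frame conserved-contact fraction against a reference set.

    The reference defaults to the first frame's contacts (the docking-pose
    configuration a complex simulation was started from); pass an explicit
    set for cross-pose comparisons.
    """
    sets = contacts_per_frame(traj, ligand_residue, cutoff, atom_policy)
    ref = sets[0] if reference_contacts is None else set(reference_contacts)
    return np.asarray([conserved_contact_fraction(s, ref) for s in sets])


def hydrophobic_occurrence(
    traj: Trajectory,
    residue: ResidueKey,
    ligand_residue: ResidueKey,
    cutoff: float = CONTACT_CUTOFF_NM,
    window=None,
) -> float:
    """Percentage of window frames with >= 1 carbon-carbon pair within the
    cutoff between the residue and the ligand."""
    top = traj.topology
    res_c = np.asarray([i for i in top.atom_indices(residue)
                        if top.atoms[i].element.upper() == "C"], int)
    lig_c = np.asarray([i for i in top.atom_indices(ligand_residue)
                        if top.atoms[i].element.upper() == "C"], int)
    idx = resolve_window(traj.n_frames, window, equilibrium_fraction=0.0) if window is not None \
        else np.arange(traj.n_frames)
    if res_c.size == 0 or lig_c.size == 0:
        return 0.0
    hits = 0
    for f in idx:
        a = traj.coords[f][res_c]
        b = traj.coords[f][lig_c]
        d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
        if np.any(d2 <= cutoff * cutoff):
            hits += 1
    return 100.0 * hits / idx.size


def hbond_present(
    donor_pos: np.ndarray,
    hydrogen_pos: np.ndarray,
    acceptor_pos: np.ndarray,
    d_cut: float = HBOND_DISTANCE_NM,
    angle_cut: float = HBOND_ANGLE_DEG,
) -> bool:
    """Geometric H-bond criterion: donor-acceptor distance <= d_cut and
    hydrogen-donor-acceptor angle (at the donor) <= angle_cut degrees."""
    da = np.asarray(acceptor_pos, float) - np.asarray(donor_pos, float)
    dist = float(np.linalg.norm(da))
    if dist > d_cut:
        return False
    dh = np.asarray(hydrogen_pos, float) - np.asarray(donor_pos, float)
    nh = np.linalg.norm(dh)
    if nh == 0 or dist == 0:
        return False
    cosang = float(np.dot(dh, da) / (nh * dist))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return bool(angle <= angle_cut)


def hbond_occurrence(
    traj: Trajectory,
    donor_group: tuple[int, int],
    acceptor: int | Sequence[int],
    d_cut: float = HBOND_DISTANCE_NM,
    angle_cut: float = HBOND_ANGLE_DEG,
    window=None,
) -> float:
    """Percentage of window frames where the donor (D, H) hydrogen-bonds to
    any of the acceptor atoms."""
    d_idx, h_idx = donor_group
    top = traj.topology
    if top.atoms[h_idx].element.upper() != "H":
        raise ValueError(f"atom {h_idx} ({top.atoms[h_idx].name}) is not a hydrogen")
    if top.atoms[d_idx].element.upper() not in ("N", "O"):
        raise ValueError("donor must be nitrogen or oxygen")
    acceptors = [acceptor] if isinstance(acceptor, (int, np.integer)) else list(acceptor)
    idx = resolve_window(traj.n_frames, window, equilibrium_fraction=0.0) if window is not None \
        else np.arange(traj.n_frames)
    hits = 0
    for f in idx:
        coords = traj.coords[f]
        if any(hbond_present(coords[d_idx], coords[h_idx], coords[a], d_cut, angle_cut)
               for a in acceptors):
            hits += 1
    return 100.0 * hits / idx.size


def contact_count_histogram(contact_sets: Sequence[set]) -> "dict[int, int]":
    """Histogram over poses/frames of contact-set sizes."""
    if len(contact_sets) == 0:
        raise ValueError("need at least one contact set")
    out: dict[int, int] = {}
    for s in contact_sets:
        out[len(s)] = out.get(len(s), 0) + 1
    return dict(sorted(out.items()))
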