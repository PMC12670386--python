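"""Synthetic receptor-ligand systems with known ground truth.

Generates a coarse helical backbone receptor (N, CA, C, O per residue), a
six-heavy-atom diketone ligand with controllable cis/trans population
(O-O ~ 0.28 nm cis, ~ 0.34 nm trans, straddling the 0.32 nm classifier
boundary), per-residue Bernoulli contact schedules and a displaced mobile
region -- every statistic the analysis stages compute is configured here
explicitly, so recovery can be asserted at known tolerances.

No physical realism is attempted: when a contact is scheduled, the
ligand's designated atom is simply teleported next to the target residue.
The generator targets the *statistics* of the analyses only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import Atom, RegionSpec, Topology, Trajectory, assign_regions
from .docking import Pose, PoseSet

__all__ = [
    "SynthSpec",
    "LIGAND_ATOM_NAMES",
    "LIGAND_ELEMENTS",
    "cis_template",
    "trans_template",
    "make_receptor",
    "make_trajectory",
    "make_pose_set",
]

LIGAND_RESIDUE_NAME = "DKT"
LIGAND_ATOM_NAMES = ("C1", "C2", "C3", "C4", "O1", "O2")
LIGAND_ELEMENTS = ("C", "C", "C", "C", "O", "O")
#: Order in which ligand atoms are dedicated to scheduled contacts; carbons
#: first so the O-O conformer descriptor survives up to four schedules.
_CONTACT_ATOM_ORDER = (0, 3, 1, 2, 4, 5)

_HELIX_RADIUS = 1.0  # nm
_HELIX_OMEGA = 1.0  # rad per residue
_HELIX_RISE = 0.15  # nm per residue
_CONTACT_DISTANCE = 0.3  # nm, placement distance from the target CA
_BACKBONE_OFFSETS = {
    "N": np.array([0.07, 0.07, -0.05]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([-0.07, 0.05, 0.05]),
    "O": np.array([-0.10, -0.06, 0.09]),
}


def _diketone(o_o_separation_sign: float) -> np.ndarray:
    """Planar diketone template; the sign flips O2 across the C-C axis
    (same side -> cis, opposite -> trans)."""
    c_c = 0.151
    c_o = 0.121
    ox = c_o * 0.5  # cos 60
    oy = c_o * np.sqrt(3) / 2  # sin 60
    return np.array([
        [-c_c, 0.0, 0.0],  # C1 methyl
        [0.0, 0.0, 0.0],  # C2 carbonyl
        [c_c, 0.0, 0.0],  # C3 carbonyl
        [2 * c_c, 0.0, 0.0],  # C4 methyl
        [-ox, oy, 0.0],  # O1 on C2
        [c_c + ox, o_o_separation_sign * oy, 0.0],  # O2 on C3
    ])


def cis_template() -> np.ndarray:
    """O-O distance ~ 0.28 nm (below the 0.32 nm boundary)."""
    return _diketone(+1.0)


def trans_template() -> np.ndarray:
    """O-O distance ~ 0.34 nm (above the 0.32 nm boundary)."""
    return _diketone(-1.0)


@dataclass(frozen=True)
class SynthSpec:
    n_residues: int = 40
    region_layout: RegionSpec | None = None
    default_region: str = "cytoplasmic"
    n_frames: int = 100
    seed: int = 0
    noise_sigma: float = 0.01  # nm, per-axis Gaussian jitter on every atom
    mobile_residues: tuple[int, ...] = ()
    mobile_amplitude: float = 0.0  # nm
    contact_schedule: Mapping[int, float] = field(default_factory=dict)
    cis_probability: float = 0.0
    dt_ns: float = 0.1
    contact_cutoff: float = 0.4  # nm, used only for feasibility checking

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.noise_sigma < 0 or self.mobile_amplitude < 0:
            raise ValueError("noise and amplitude must be non-negative")
        if not 0.0 <= self.cis_probability <= 1.0:
            raise ValueError("cis_probability must be in [0, 1]")
        for res, p in self.contact_schedule.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occupancy probability for residue {res} not in [0, 1]")
            if not 1 <= res <= self.n_residues:
                raise ValueError(f"scheduled residue {res} outside 1..{self.n_residues}")
        if len(self.contact_schedule) > len(LIGAND_ATOM_NAMES):
            raise ValueError(
                f"at most {len(LIGAND_ATOM_NAMES)} residues can be scheduled "
                f"(one dedicated ligand atom each)"
            )
        for res in self.mobile_residues:
            if not 1 <= res <= self.n_residues:
                raise ValueError(f"mobile residue {res} outside 1..{self.n_residues}")


def make_receptor(spec: SynthSpec) -> tuple[Topology, np.ndarray]:
    """Coarse helical backbone with 4 atoms (N, CA, C, O) per residue,
    region-annotated from the spec's layout.  Deterministic: the geometry
    depends only on ``n_residues``."""
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1
    for i in range(spec.n_residues):
        seq = i + 1
        angle = _HELIX_OMEGA * i
        ca = np.array([
            _HELIX_RADIUS * np.cos(angle),
            _HELIX_RADIUS * np.sin(angle),
            _HELIX_RISE * i,
        ])
        for name in ("N", "CA", "C", "O"):
            atoms.append(Atom(serial=serial, name=name, element=name[0],
                              residue_seq=seq, residue_name="GLY" if name == "N" else "GLY",
                              chain="A"))
            coords.append(ca + _BACKBONE_OFFSETS[name])
            serial += 1
    topology = Topology(atoms)
    layout = spec.region_layout or RegionSpec([("transmembrane", 1, spec.n_residues)])
    topology = assign_regions(topology, layout, default=spec.default_region)
    return topology, np.asarray(coords)


def _radial_direction(residue_seq: int) -> np.ndarray:
    angle = _HELIX_OMEGA * (residue_seq - 1)
    return np.array([np.cos(angle), np.sin(angle), 0.0])


def _contact_point(ca: np.ndarray, residue_seq: int) -> np.ndarray:
    return ca + _CONTACT_DISTANCE * _radial_direction(residue_seq)


def _check_contact_feasibility(spec: SynthSpec, topology: Topology,
                               coords: np.ndarray) -> None:
    """A scheduled contact point must be close to its own residue only."""
    margin = spec.contact_cutoff + 4.0 * spec.noise_sigma + 0.05
    for res in spec.contact_schedule:
        ca_idx = topology.select(names={"CA"}, residues={("A", res)})
        point = _contact_point(coords[ca_idx[0]], res)
        for i, atom in enumerate(topology.atoms):
            if atom.residue_seq == res:
                continue
            if np.linalg.norm(coords[i] - point) < margin:
                raise ValueError(
                    f"contact geometry infeasible for residue {res}: point "
                    f"clashes with residue {atom.residue_seq}"
                )


def _ligand_topology(spec: SynthSpec, receptor: Topology) -> Topology:
    atoms = list(receptor.atoms)
    seq = spec.n_residues + 1
    for j, (name, element) in enumerate(zip(LIGAND_ATOM_NAMES, LIGAND_ELEMENTS)):
        atoms.append(Atom(serial=len(atoms) + 1, name=name, element=element,
                          residue_seq=seq, residue_name=LIGAND_RESIDUE_NAME, chain="A"))
    region_of = dict(receptor.region_of)
    region_of[("A", seq)] = "ligand"
    return Topology(atoms, region_of=region_of)


def _parking_origin(spec: SynthSpec) -> np.ndarray:
    return np.array([0.0, 0.0, _HELIX_RISE * spec.n_residues + 2.0])


def make_trajectory(spec: SynthSpec, receptor: tuple[Topology, np.ndarray] | None = None) -> Trajectory:
    """Trajectory over the receptor plus ligand with configured statistics.

    Per frame: Gaussian jitter on every atom; the mobile region is rigidly
    displaced by amplitude x sin(2 pi f / n_frames + random phase) along a
    random fixed direction; the ligand starts from a cis or trans template
    (cis with ``cis_probability``) parked above the helix, and each
    scheduled residue's dedicated ligand atom is either placed 0.3 nm from
    that residue's (jittered) CA with its occupancy probability, or left
    parked beyond the cutoff.
    """
    if receptor is None:
        receptor = make_receptor(spec)
    rec_top, rec_coords = receptor
    _check_contact_feasibility(spec, rec_top, rec_coords)
    topology = _ligand_topology(spec, rec_top)
    rng = np.random.default_rng(spec.seed)
    n_rec = rec_top.n_atoms
    n_lig = len(LIGAND_ATOM_NAMES)
    F = spec.n_frames

    coords = np.empty((F, n_rec + n_lig, 3))
    coords[:, :n_rec, :] = rec_coords[None, :, :]
    coords[:, :n_rec, :] += rng.normal(0.0, spec.noise_sigma, size=(F, n_rec, 3))

    if spec.mobile_residues and spec.mobile_amplitude > 0:
        mobile_atoms = rec_top.select(residues={("A", r) for r in spec.mobile_residues})
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = spec.mobile_amplitude * np.sin(2.0 * np.pi * np.arange(F) / F + phase)
        coords[:, mobile_atoms, :] += amp[:, None, None] * direction[None, None, :]

    # ligand: conformer draw, then schedule-driven atom placement
    cis_draws = rng.random(F) < spec.cis_probability
    parking = _parking_origin(spec)
    cis = cis_template() + parking
    trans = trans_template() + parking
    coords[:, n_rec:, :] = np.where(cis_draws[:, None, None], cis[None], trans[None])

    scheduled = sorted(spec.contact_schedule)
    ca_index = {res: int(rec_top.select(names={"CA"}, residues={("A", res)})[0])
                for res in scheduled}
    for slot, res in enumerate(scheduled):
        atom_offset = n_rec + _CONTACT_ATOM_ORDER[slot]
        draws = rng.random(F) < spec.contact_schedule[res]
        radial = _radial_direction(res)
        targets = coords[:, ca_index[res], :] + _CONTACT_DISTANCE * radial[None, :]
        coords[draws, atom_offset, :] = targets[draws]

    times = spec.dt_ns * np.arange(F)
    return Trajectory(topology, coords, times)


def make_pose_set(
    spec: SynthSpec,
    receptor: tuple[Topology, np.ndarray] | None = None,
    n_poses: int = 10,
    affinities: Sequence[float] | None = None,
    contact_sets: Sequence[Sequence[int]] | None = None,
    seed: int | None = None,
) -> PoseSet:
    """Docking poses with controlled residue-contact sets and affinities.

    Contact sets default to random subsets of the scheduled residues;
    affinities default to draws from Normal(-2.5, 1.5) kcal/mol.  The
    ligand geometry per pose reuses the trajectory placement rules, so
    contact detection recovers exactly the configured sets.
    """
    if receptor is None:
        receptor = make_receptor(spec)
    rec_top, rec_coords = receptor
    _check_contact_feasibility(spec, rec_top, rec_coords)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    pool = sorted(spec.contact_schedule) or []
    if contact_sets is None:
        if not pool:
            raise ValueError("no contact schedule and no explicit contact sets")
        contact_sets = []
        for _ in range(n_poses):
            size = int(rng.integers(1, len(pool) + 1))
            contact_sets.append(sorted(rng.choice(pool, size=size, replace=False)))
    n_poses = len(contact_sets)
    if affinities is None:
        affinities = rng.normal(-2.5, 1.5, size=n_poses)
    if len(affinities) != n_poses:
        raise ValueError("one affinity per pose required")

    parking = _parking_origin(spec)
    template = trans_template() + parking
    ca_lookup = {r: int(rec_top.select(names={"CA"}, residues={("A", r)})[0])
                 for cs in contact_sets for r in cs}
    poses = []
    for p, (residues, affinity) in enumerate(zip(contact_sets, affinities)):
        residues = sorted(int(r) for r in residues)
        if len(residues) > len(LIGAND_ATOM_NAMES):
            raise ValueError(f"pose {p}: more contacts than ligand atoms")
        xyz = template.copy()
        for slot, res in enumerate(residues):
            xyz[_CONTACT_ATOM_ORDER[slot]] = _contact_point(
                rec_coords[ca_lookup[res]], res)
        poses.append(Pose(coords=xyz, affinity=float(affinity),
                          source_structure="synthetic", index=p))
    return PoseSet(poses=poses, atom_names=LIGAND_ATOM_NAMES, elements=LIGAND_ELEMENTS)
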